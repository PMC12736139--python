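"""Tabular and network I/O with strict validation.

All tables are tab-separated UTF-8 text with a ``.`` decimal point and no
quoting; scientific notation is accepted on read.  Readers never coerce bad
cells to NaN — any non-numeric value, negative abundance, duplicate
identifier or ragged row is an error that names the offending coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Covariate columns expected in sample metadata, in canonical order.
COVARIATE_COLUMNS = [
    "age",
    "sex",
    "smoking",
    "alcohol",
    "physical_activity",
    "grains",
    "vegetables",
    "fruits",
    "dairy",
    "animal_products",
    "beans_nuts",
]

METADATA_COLUMNS = ["group", "region"] + COVARIATE_COLUMNS


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix.

    ``values[i, j]`` is the abundance of taxon ``taxon_ids[j]`` in sample
    ``sample_ids[i]``.  When ``relative`` is True every row sums to one
    (within 1e-6) and represents fractions of the community.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    relative: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if self.relative and len(self.taxon_ids):
            bad = np.abs(self.values.sum(axis=1) - 1.0) > 1e-6
            if bad.any():
                k = int(np.argmax(bad))
                raise ValueError(
                    f"relative-abundance row {self.sample_ids[k]!r} sums to "
                    f"{self.values[k].sum():.8g}, not 1"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each taxon is present (> 0)."""
        return pd.Series((self.values > 0).mean(axis=0), index=self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.taxon_ids)

    def select_taxa(self, taxa: Sequence[str]) -> "AbundanceTable":
        idx = [self.taxon_ids.index(t) for t in taxa]
        return AbundanceTable(
            list(self.sample_ids), list(taxa), self.values[:, idx], relative=False
        )

    def select_samples(self, keep: np.ndarray) -> "AbundanceTable":
        ids = [s for s, k in zip(self.sample_ids, keep) if k]
        return AbundanceTable(ids, list(self.taxon_ids), self.values[keep], self.relative)


@dataclass
class FunctionTable:
    """Samples x functional features (EC numbers, KOs, pathways)."""

    sample_ids: list[str]
    function_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.function_ids, "function")
        if np.any(self.values < 0):
            raise ValueError("function abundances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.function_ids)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id {x!r}")
        seen.add(x)


def close_rows(values: np.ndarray) -> np.ndarray:
    """Renormalize each row to sum to one (compositional closure)."""
    values = np.asarray(values, dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        k = int(np.argmax(sums.ravel() <= 0))
        raise ValueError(f"row {k} has non-positive total; cannot close")
    return values / sums


def _read_strict_tsv(path) -> pd.DataFrame:
    """Read a TSV with an index column, rejecting ragged or non-numeric rows."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        try:
            out[col] = df[col].astype(float)
        except ValueError:
            for row, cell in df[col].items():
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at row {row!r}, column {col!r} in {path}"
                    ) from None
            raise
    return out


def read_abundance(path, min_prevalence: float = 0.0, relative: bool = True) -> AbundanceTable:
    """Read an abundance TSV and apply an (inclusive) prevalence filter.

    Taxa present (value > 0) in a fraction of samples *strictly below*
    ``min_prevalence`` are dropped, i.e. a taxon at exactly the threshold is
    retained.  Rows are re-closed to sum one when ``relative``.
    """
    df = _read_strict_tsv(path)
    table = AbundanceTable(
        [str(s) for s in df.index],
        [str(t) for t in df.columns],
        df.to_numpy(dtype=float),
        relative=False,
    )
    prev = table.prevalence()
    keep = prev[prev >= min_prevalence].index.tolist()
    dropped = [t for t in table.taxon_ids if t not in set(keep)]
    if dropped:
        logger.info(
            "prevalence filter (>= %.3g) dropped %d of %d taxa: %s",
            min_prevalence, len(dropped), table.n_taxa, ", ".join(dropped),
        )
    sub = table.to_frame()[keep].to_numpy()
    if relative:
        sub = close_rows(sub)
    return AbundanceTable(table.sample_ids, keep, sub, relative=relative)


def write_abundance(table: AbundanceTable, path) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata; requires group, region and all covariates."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing columns: {missing}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in metadata")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.rename_axis("sample_id").to_csv(path, sep="\t")


def read_functions(path) -> FunctionTable:
    df = _read_strict_tsv(path)
    return FunctionTable(
        [str(s) for s in df.index], [str(f) for f in df.columns], df.to_numpy(dtype=float)
    )


def write_functions(table: FunctionTable, path) -> None:
    table.to_frame().rename_axis("sample_id").to_csv(path, sep="\t")


def check_sample_universe(table: AbundanceTable, metadata: pd.DataFrame) -> None:
    """Every abundance sample must have exactly one metadata row."""
    meta_ids = set(map(str, metadata.index))
    missing = [s for s in table.sample_ids if s not in meta_ids]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")


def pair_name(taxon_a: str, taxon_b: str) -> str:
    """Orientation-free pair label: members in lexicographic order."""
    a, b = sorted((taxon_a, taxon_b))
    return f"{a}-{b}"


EDGE_TABLE_COLUMNS = [
    "pair",
    "TE_nonMetS",
    "TE_MetS",
    "seTE_nonMetS",
    "seTE_MetS",
    "Q",
    "I2",
    "hetero_p",
    "fdr_nonMetS",
    "fdr_MetS",
    "is_differential",
    "direction_change",
]


def write_edge_table(edges, path) -> None:
    """Write differential edges as a TSV with the canonical column layout."""
    rows = []
    for e in edges:
        rows.append({
            "pair": pair_name(*e.pair),
            "TE_nonMetS": e.te_non_mets,
            "TE_MetS": e.te_mets,
            "seTE_nonMetS": e.se_non_mets,
            "seTE_MetS": e.se_mets,
            "Q": e.q,
            "I2": e.i2,
            "hetero_p": e.hetero_p,
            "fdr_nonMetS": e.fdr_non_mets,
            "fdr_MetS": e.fdr_mets,
            "is_differential": e.is_differential,
            "direction_change": e.direction_change,
        })
    pd.DataFrame(rows, columns=EDGE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def export_network(pooled, fdr_cut: float, path, format: str = "graphml",
                   phylum: dict[str, str] | None = None) -> nx.Graph:
    """Export the significant co-abundance network (edges with FDR < cut).

    Nodes are taxa incident to at least one passing edge; edges carry the
    pooled Fisher-Z effect, its standard error and a "+"/"-" sign attribute.
    """
    if format not in ("graphml", "json"):
        raise ValueError(f"unknown format {format!r}; supported: graphml, json")
    g = nx.Graph()
    for edge in pooled:
        if edge.fdr is None or not edge.fdr < fdr_cut:
            continue
        a, b = edge.pair
        g.add_edge(a, b, TE=float(edge.te), seTE=float(edge.se_te),
                   sign="+" if edge.te >= 0 else "-")
    if phylum:
        for node in g.nodes:
            if node in phylum:
                g.nodes[node]["phylum"] = phylum[node]
    if format == "graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            json.dump(nx.node_link_data(g, edges="links"), fh, indent=1)
    return g
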