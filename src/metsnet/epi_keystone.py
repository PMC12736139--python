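"""Keystone-candidate screening from cross-sectional presence/absence (EPI).

A keystone taxon's presence should reshape the abundance profiles of the
rest of the community.  For each candidate (prevalence within a window,
default [0.25, 0.75]) the samples are split by the candidate's presence,
the remaining taxa are renormalized, and three indicators quantify how
different the two partitions look:

D1    Bray-Curtis distance between the partitions' mean renormalized profiles.
D2    mean two-sample Kolmogorov-Smirnov statistic over the remaining taxa.
Qmod  Newman modularity of the presence bipartition on a k-nearest-neighbour
      sample graph built from Bray-Curtis similarity of renormalized profiles.

Each indicator is compared against the 95th percentile of its permutation
null (presence labels shuffled, prevalence preserved); exceeding the null
flags the taxon as a keystone candidate under that indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform

from .io_formats import AbundanceTable, close_rows

logger = logging.getLogger(__name__)

PREVALENCE_WINDOW = (0.25, 0.75)


@dataclass
class KeystoneResult:
    taxon: str
    prevalence: float
    d1: float
    d2: float
    qmod: float
    null_d1: float
    null_d2: float
    null_qmod: float
    is_keystone_d1: bool
    is_keystone_d2: bool
    is_keystone_q: bool


def epi_candidates(table: AbundanceTable,
                   window: tuple[float, float] = PREVALENCE_WINDOW) -> list[str]:
    """Taxa whose prevalence lies in the closed window [lo, hi]."""
    prev = table.prevalence()
    lo, hi = window
    return [t for t in table.taxon_ids if lo <= prev[t] <= hi]


def _renormalized_others(table: AbundanceTable, taxon: str) -> tuple[np.ndarray, np.ndarray]:
    """Presence mask of the candidate and the others' renormalized profiles."""
    df = table.to_frame()
    present = df[taxon].to_numpy() > 0
    others = df.drop(columns=[taxon]).to_numpy()
    return present, close_rows(others)


def ks_statistic_columns(inside: np.ndarray, outside: np.ndarray) -> np.ndarray:
    """Two-sample KS statistic of every column, vectorized across columns.

    Equals ``scipy.stats.ks_2samp(...).statistic`` column by column (ties
    handled by evaluating the ECDF difference only where the pooled sorted
    value changes); vectorization keeps permutation nulls affordable.
    """
    n1, n0 = inside.shape[0], outside.shape[0]
    pooled = np.concatenate([inside, outside], axis=0)
    from_inside = np.zeros((n1 + n0, 1)); from_inside[:n1] = 1.0
    order = np.argsort(pooled, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(pooled, order, axis=0)
    ind1 = np.take_along_axis(np.broadcast_to(from_inside, pooled.shape), order, axis=0)
    cdf_gap = np.abs(np.cumsum(ind1, axis=0) / n1
                     - np.cumsum(1.0 - ind1, axis=0) / n0)
    valid = np.ones_like(cdf_gap, dtype=bool)
    valid[:-1] = sorted_vals[:-1] != sorted_vals[1:]
    return (cdf_gap * valid).max(axis=0)


def _indicators(present: np.ndarray, others: np.ndarray,
                knn_graph: "_SampleGraph | None") -> tuple[float, float, float]:
    inside, outside = others[present], others[~present]
    d1 = float(braycurtis(inside.mean(axis=0), outside.mean(axis=0)))
    d2 = float(ks_statistic_columns(inside, outside).mean())
    qmod = knn_graph.modularity(present) if knn_graph is not None else 0.0
    return d1, d2, qmod


class _SampleGraph:
    """Symmetrized kNN sample graph with O(n^2) bipartition modularity.

    Edge weight is Bray-Curtis similarity (1 - distance).  Newman modularity
    of a two-block partition is evaluated directly on the dense weight
    matrix so permutation nulls reuse the graph.
    """

    def __init__(self, others: np.ndarray, k: int):
        dist = squareform(pdist(others, metric="braycurtis"))
        n = dist.shape[0]
        w = np.zeros((n, n))
        order = np.argsort(dist, axis=1)
        for i in range(n):
            for j in order[i, 1:k + 1]:
                w[i, j] = w[j, i] = max(1.0 - dist[i, j], 1e-9)
        self.w = w
        self.strength = w.sum(axis=1)
        self.total = w.sum() / 2.0

    def modularity(self, present: np.ndarray) -> float:
        m = self.total
        q = 0.0
        for mask in (present, ~present):
            e_in = self.w[np.ix_(mask, mask)].sum() / 2.0
            d_c = self.strength[mask].sum()
            q += e_in / m - (d_c / (2.0 * m)) ** 2
        return float(q)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.w.shape[0]))
        ii, jj = np.nonzero(np.triu(self.w, 1))
        g.add_weighted_edges_from((int(i), int(j), self.w[i, j])
                                  for i, j in zip(ii, jj))
        return g


def _knn_graph(others: np.ndarray, k: int) -> _SampleGraph:
    return _SampleGraph(others, k)


def epi_indicators(table: AbundanceTable, taxon: str, knn: int = 10,
                   compute_qmod: bool = True):
    """(D1, D2, Qmod) for one candidate taxon; needs >=5 samples per side."""
    present, others = _renormalized_others(table, taxon)
    if present.sum() < 5 or (~present).sum() < 5:
        raise ValueError(f"{taxon}: fewer than 5 samples on one side of the split")
    graph = _knn_graph(others, knn) if compute_qmod else None
    return _indicators(present, others, graph)


def epi_null(table: AbundanceTable, taxon: str, b: int = 200, seed: int = 0,
             knn: int = 10, compute_qmod: bool = True, quantile: float = 0.95,
             return_draws: bool = False):
    """Permutation-null quantiles of the three indicators for one taxon.

    Presence labels are permuted uniformly (prevalence preserved exactly);
    the renormalized profiles and the kNN graph do not depend on the labels,
    so they are built once.
    """
    if b < 1:
        raise ValueError("need at least 1 permutation")
    rng = np.random.default_rng(seed)
    present, others = _renormalized_others(table, taxon)
    graph = _knn_graph(others, knn) if compute_qmod else None
    draws = np.empty((b, 3))
    for t in range(b):
        perm = rng.permutation(present)
        draws[t] = _indicators(perm, others, graph)
    if return_draws:
        return draws
    q = np.quantile(draws, quantile, axis=0)
    return float(q[0]), float(q[1]), float(q[2])


def screen_keystones(table: AbundanceTable, permutations: int = 200, seed: int = 0,
                     knn: int = 10, window: tuple[float, float] = PREVALENCE_WINDOW,
                     compute_qmod: bool = True) -> list[KeystoneResult]:
    """Run the full EPI screen over all candidate taxa."""
    prev = table.prevalence()
    results = []
    for ci, taxon in enumerate(epi_candidates(table, window)):
        try:
            d1, d2, qmod = epi_indicators(table, taxon, knn=knn,
                                          compute_qmod=compute_qmod)
        except ValueError as err:
            logger.info("skipping %s: %s", taxon, err)
            continue
        n1, n2, nq = epi_null(table, taxon, b=permutations,
                              seed=int(np.random.SeedSequence([seed, ci]).generate_state(1)[0] % 2**31),
                              knn=knn, compute_qmod=compute_qmod)
        results.append(KeystoneResult(
            taxon=taxon, prevalence=float(prev[taxon]),
            d1=d1, d2=d2, qmod=qmod, null_d1=n1, null_d2=n2, null_qmod=nq,
            is_keystone_d1=d1 > n1, is_keystone_d2=d2 > n2,
            is_keystone_q=compute_qmod and qmod > nq,
        ))
    return results


def keystones_to_frame(results: list[KeystoneResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
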