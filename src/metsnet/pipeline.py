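"""End-to-end orchestration of the differential co-abundance analysis.

Stage order: prevalence filter -> per-(group, region) latent correlation ->
per-group random-effects pooling with BH FDR -> between-group differential
edges -> covariate adjustment of the involved genera -> EPI keystone screen
-> abundance/function group tests -> interaction variance decomposition.
Each stage writes one TSV and the run ends with a manifest (config hash,
seed, stage checksums) sufficient to re-run any stage in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance_diff, cclasso, edge_heterogeneity, edge_meta
from . import epi_keystone, io_formats, partial_corr, variance_decomposition
from .io_formats import AbundanceTable

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    prevalence_min: float = 0.10
    fdr_cut: float = 0.05
    i2_cut: float = 0.75
    hetero_p_cut: float = 0.05
    epi_window: tuple[float, float] = (0.25, 0.75)
    epi_permutations: int = 200
    epi_knn: int = 10
    lambda_grid: tuple[float, ...] = (0.001, 0.005, 0.01, 0.05, 0.1)
    fixed_lambda: float | None = None  # skip CV when set
    cv_folds: int = 5
    cclasso_tol: float = 1e-6
    cclasso_max_iter: int = 5000
    eligible: str = "union"
    run_keystone: bool = True
    run_function_tests: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("prevalence_min", "fdr_cut", "i2_cut", "hetero_p_cut"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1); got {v}")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    region_estimates: pd.DataFrame
    pooled: dict
    networks: dict
    differential: list
    diff_summary: dict
    adjusted: list
    keystones: list
    genus_tests: list
    function_tests: list
    decomposition: list
    manifest: dict = field(default_factory=dict)


def infer_region_networks(abundance: AbundanceTable, metadata: pd.DataFrame,
                          config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """Fit one latent correlation matrix per (group, region) stratum."""
    frames = []
    lambdas = {}
    groups = sorted(metadata["group"].unique())
    regions = sorted(metadata["region"].unique())
    meta = metadata.loc[abundance.sample_ids]
    for group in groups:
        group_regions = sorted(meta.loc[meta["group"] == group, "region"].unique())
        if len(group_regions) < 2:
            raise ValueError(
                f"group {group!r} has {len(group_regions)} region(s); "
                "meta-analytic pooling needs at least 2")
        for region in regions:
            keep = ((meta["group"] == group) & (meta["region"] == region)).to_numpy()
            if keep.sum() == 0:
                continue
            sub = AbundanceTable(
                [s for s, k in zip(abundance.sample_ids, keep) if k],
                list(abundance.taxon_ids),
                io_formats.close_rows(abundance.values[keep]), relative=True)
            sub = cclasso.zero_replace(sub)
            if config.fixed_lambda is not None:
                lam = config.fixed_lambda
            else:
                lam = cclasso.select_lambda(sub, config.lambda_grid,
                                            k_folds=config.cv_folds, seed=config.seed,
                                            tol=config.cclasso_tol,
                                            max_iter=config.cclasso_max_iter)
            lc = cclasso.fit_latent_correlation(sub, lam, group=group, region=region,
                                                tol=config.cclasso_tol,
                                                max_iter=config.cclasso_max_iter)
            lambdas[(group, region)] = lam
            frames.append(cclasso.edges_from_matrix(lc))
            logger.info("network %s/%s: n=%d lambda=%g nonzero=%d",
                        group, region, lc.n, lam,
                        int((np.abs(np.triu(lc.rho, 1)) > 1e-10).sum()))
    return pd.concat(frames, ignore_index=True), lambdas


def run_all(abundance: AbundanceTable, metadata: pd.DataFrame, config: PipelineConfig,
            functions=None, function_kinds=None, out_dir=None) -> PipelineResult:
    """Execute every stage; write stage TSVs and a manifest when out_dir given."""
    config.validate()
    io_formats.check_sample_universe(abundance, metadata)
    meta = metadata.loc[abundance.sample_ids]
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        if out is not None:
            path = out / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written[name] = _checksum(path)

    # 1. prevalence filter
    prev = abundance.prevalence()
    keep = prev[prev >= config.prevalence_min].index.tolist()
    filtered = AbundanceTable(list(abundance.sample_ids), keep,
                              io_formats.close_rows(abundance.to_frame()[keep].to_numpy()),
                              relative=True)
    logger.info("prevalence filter: kept %d of %d taxa", filtered.n_taxa, abundance.n_taxa)

    # 2-3. per-stratum networks, per-group pooling
    region_estimates, lambdas = infer_region_networks(filtered, meta, config)
    emit("region_edges", region_estimates)
    pooled, networks = {}, {}
    for group, sub in region_estimates.groupby("group"):
        pooled[group] = edge_meta.pool_group_edges(sub, group)
        networks[group] = edge_meta.significant_network(pooled[group], config.fdr_cut)
        logger.info("group %s: %d/%d edges significant (FDR<%g), positive fraction %s",
                    group, networks[group].n_edges, len(pooled[group]), config.fdr_cut,
                    networks[group].positive_fraction)
        emit(f"pooled_{group}", edge_meta.pooled_to_frame(pooled[group]))

    # 4. differential edges
    differential = edge_heterogeneity.compare_groups(
        pooled["nonMetS"], pooled["MetS"], eligible=config.eligible,
        fdr_cut=config.fdr_cut, i2_cut=config.i2_cut, p_cut=config.hetero_p_cut)
    diff_summary = edge_heterogeneity.call_differential(differential)
    logger.info("differential edges: %d of %d eligible, %d genera",
                diff_summary["n_differential"], len(differential),
                diff_summary["n_genera"])
    if out is not None:
        io_formats.write_edge_table(differential, out / "differential_edges.tsv")
        written["differential_edges"] = _checksum(out / "differential_edges.tsv")

    # 5. covariate adjustment of the genera in differential edges
    adjusted = []
    diff_pairs = [e.pair for e in diff_summary["edges"]]
    if diff_pairs:
        genera = sorted({t for p in diff_pairs for t in p})
        logx = np.log(cclasso.zero_replace(filtered).to_frame()[genera])
        adjusted = partial_corr.adjust_edges(logx, meta, diff_pairs)
        emit("adjusted_edges", partial_corr.adjusted_to_frame(adjusted))

    # 6. EPI keystone screen
    keystones = []
    if config.run_keystone:
        keystones = epi_keystone.screen_keystones(
            filtered, permutations=config.epi_permutations, seed=config.seed,
            knn=config.epi_knn, window=config.epi_window)
        emit("keystones", epi_keystone.keystones_to_frame(keystones))

    # 7. abundance (and function) group tests
    diff_genera = sorted({t for p in diff_pairs for t in p})
    genus_tests = []
    if diff_genera:
        genus_tests = abundance_diff.test_features(
            filtered.to_frame()[diff_genera], meta, feature_kind="genus")
        emit("genus_tests", abundance_diff.results_to_frame(genus_tests))
    function_tests = []
    if functions is not None and config.run_function_tests:
        fdf = functions.to_frame().loc[abundance.sample_ids]
        kinds = function_kinds or {f: "function" for f in fdf.columns}
        for kind in sorted(set(kinds.values())):
            cols = [f for f in fdf.columns if kinds[f] == kind]
            function_tests += abundance_diff.test_features(fdf[cols], meta,
                                                           feature_kind=kind)
        emit("function_tests", abundance_diff.results_to_frame(function_tests))

    # 8. variance decomposition on significant functions x differential pairs
    decomposition = []
    if functions is not None and diff_pairs:
        sig_funcs = [r.feature_id for r in function_tests
                     if r.fdr is not None and r.fdr < config.fdr_cut]
        target_funcs = sig_funcs or list(functions.function_ids)
        fdf = functions.to_frame().loc[abundance.sample_ids, target_funcs]
        decomposition = variance_decomposition.batch_decompose(
            diff_pairs, fdf, filtered.to_frame(), function_kinds)
        emit("variance_decomposition",
             variance_decomposition.decomposition_to_frame(decomposition))

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()).hexdigest()[:16],
        "seed": config.seed,
        "n_samples": filtered.n_samples,
        "n_taxa": filtered.n_taxa,
        "lambdas": {f"{g}/{r}": lam for (g, r), lam in lambdas.items()},
        "n_edges_significant": {g: networks[g].n_edges for g in networks},
        "positive_fraction": {g: networks[g].positive_fraction for g in networks},
        "n_differential": diff_summary["n_differential"],
        "stage_checksums": written,
    }
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(region_estimates=region_estimates, pooled=pooled,
                          networks=networks, differential=differential,
                          diff_summary=diff_summary, adjusted=adjusted,
                          keystones=keystones, genus_tests=genus_tests,
                          function_tests=function_tests, decomposition=decomposition,
                          manifest=manifest)
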