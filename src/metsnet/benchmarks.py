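"""Synthetic recovery and calibration experiments for the pipeline.

Each function runs one self-contained experiment at the study conditions the
package targets (three regions, two groups, planted network structure) and
returns summary numbers.  They back both the test suite and the
reproduction script, so the measured quantities are computed in exactly one
place.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .cclasso import fit_latent_correlation, zero_replace
from .edge_heterogeneity import between_group_heterogeneity
from .edge_meta import pool_random_effects
from .epi_keystone import epi_candidates, epi_indicators, epi_null
from .pipeline import PipelineConfig, run_all
from .synthetic_data import (SimulationConfig, generate_dataset,
                             plant_keystone, taxon_names)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def cclasso_support_recovery(seeds, p: int = 20, n: int = 500,
                             n_edges: int = 10, lam: float = 0.01) -> list[float]:
    """AUC of ranking taxon pairs by |rho| against the planted support.

    Ten disjoint pairs with |rho| in [0.5, 0.8] are planted per seed.
    """
    aucs = []
    names = taxon_names(p)
    for seed in seeds:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(p)
        pairs = [(names[perm[2 * i]], names[perm[2 * i + 1]])
                 for i in range(n_edges)]
        rhos = rng.uniform(0.5, 0.8, n_edges) * rng.choice([-1.0, 1.0], n_edges)
        cfg = SimulationConfig(
            p=p, n_per_stratum={("nonMetS", "region1"): n},
            base_edge_density=0.0, depth=50_000,
            differential_pairs=[(a, b, r, r) for (a, b), r in zip(pairs, rhos)],
            seed=seed)
        ds = generate_dataset(cfg)
        lc = fit_latent_correlation(zero_replace(ds.abundance), lam)
        truth = {tuple(sorted(pr)) for pr in pairs}
        scores, labels = [], []
        for i in range(p):
            for j in range(i + 1, p):
                scores.append(abs(lc.rho[i, j]))
                labels.append(tuple(sorted((names[i], names[j]))) in truth)
        aucs.append(_rank_auc(np.array(scores), np.array(labels)))
    return aucs


def planted_differential_recovery(seeds, p: int = 15, n_per_stratum: int = 200,
                                  rho_strong: float = 0.6, rho_weak: float = 0.2,
                                  n_planted: int = 5, lam: float = 0.01):
    """End-to-end recovery of planted differential edges.

    Plants ``n_planted`` pairs whose latent correlation differs between the
    groups (Fisher-Z gap ~0.49) and runs the full pipeline; returns per-seed
    (recall, false calls) over the planted truth.
    """
    names = taxon_names(p)
    results = []
    for seed in seeds:
        pairs = [(names[2 * i], names[2 * i + 1]) for i in range(n_planted)]
        cfg = SimulationConfig(
            p=p,
            n_per_stratum={(g, r): n_per_stratum
                           for g in ("nonMetS", "MetS")
                           for r in ("region1", "region2", "region3")},
            base_edge_density=0.05, depth=20_000, mean_log_sd=2.0,
            differential_pairs=[(a, b, rho_strong, rho_weak) for a, b in pairs],
            seed=seed)
        ds = generate_dataset(cfg)
        pc = PipelineConfig(fixed_lambda=lam, run_keystone=False, seed=seed)
        res = run_all(ds.abundance, ds.metadata, pc)
        called = {tuple(sorted(e.pair)) for e in res.diff_summary["edges"]}
        truth = {tuple(sorted(pr)) for pr in pairs}
        results.append((len(called & truth), len(called - truth)))
    return results


def heterogeneity_null_calibration(seed: int, n_edges: int = 2000) -> dict:
    """Uniformity of the differential test's p-value under no group difference.

    Each null edge gets a common true pooled effect and two group estimates
    drawn at their nominal standard errors (the test's declared inputs);
    returns the KS distance from uniform and the nominal rejection rate.
    """
    rng = np.random.default_rng(seed)
    mu = rng.normal(0.0, 0.3, n_edges)
    se_a = rng.uniform(0.03, 0.12, n_edges)
    se_b = rng.uniform(0.03, 0.12, n_edges)
    ps = []
    for i in range(n_edges):
        te_a = mu[i] + rng.normal(0, se_a[i])
        te_b = mu[i] + rng.normal(0, se_b[i])
        _, _, p = between_group_heterogeneity(te_a, se_a[i], te_b, se_b[i])
        ps.append(p)
    ps = np.array(ps)
    return {"ks": float(stats.kstest(ps, "uniform").statistic),
            "reject_at_05": float(np.mean(ps < 0.05))}


def pooled_heterogeneity_null(seed: int, n_edges: int = 2000, n: int = 200,
                              k_regions: int = 3) -> dict:
    """Same calibration but with the DL pooling stage included.

    tau^2 truncation at zero makes the pooled standard errors slightly
    conservative, so the rejection rate sits below nominal.
    """
    rng = np.random.default_rng(seed)
    rho = rng.uniform(-0.5, 0.5, n_edges)

    def sample_r(k):
        out = np.empty((n_edges, k))
        for j in range(k):
            x = rng.standard_normal((n, n_edges))
            e = rng.standard_normal((n, n_edges))
            y = rho * x + np.sqrt(1 - rho**2) * e
            xm, ym = x - x.mean(0), y - y.mean(0)
            out[:, j] = (xm * ym).sum(0) / np.sqrt(
                (xm**2).sum(0) * (ym**2).sum(0))
        return out

    ra, rb = sample_r(k_regions), sample_r(k_regions)
    ps = []
    for i in range(n_edges):
        ea = pool_random_effects([(ra[i, j], n) for j in range(k_regions)])
        eb = pool_random_effects([(rb[i, j], n) for j in range(k_regions)])
        _, _, p = between_group_heterogeneity(ea.te, ea.se_te, eb.te, eb.se_te)
        ps.append(p)
    ps = np.array(ps)
    return {"ks": float(stats.kstest(ps, "uniform").statistic),
            "reject_at_05": float(np.mean(ps < 0.05))}


def epi_null_false_flag_rate(seed: int, permutations: int = 200,
                             n_cohorts: int = 1) -> dict:
    """Flag rate of the EPI screen on cohorts with no planted keystone.

    Uses the weak-coupling regime (low latent variance, mild depth
    variation) in which a window taxon's presence is sampling-driven and
    hence genuinely unassociated with the rest of the community.  Flags
    are pooled over ``n_cohorts`` independent cohorts.
    """
    from .epi_keystone import screen_keystones

    flags = []
    n_candidates = 0
    for k in range(n_cohorts):
        cfg = SimulationConfig(p=30, n_per_stratum={("nonMetS", "region1"): 250},
                               base_edge_density=0.0, depth=1000,
                               mean_log_sd=1.5, latent_sd=0.2, depth_cv=0.08,
                               seed=seed + k)
        ds = generate_dataset(cfg)
        res = screen_keystones(ds.abundance, permutations=permutations,
                               seed=seed + k)
        n_candidates += len(res)
        flags += [f for r in res
                  for f in (r.is_keystone_d1, r.is_keystone_d2, r.is_keystone_q)]
    return {"rate": float(np.mean(flags)) if flags else 0.0,
            "n_candidates": n_candidates}


def keystone_recovery(seeds, shift: float = 1.0, n: int = 400) -> dict:
    """D1 detection of a planted keystone vs a co-resident null taxon."""
    hits, null_hits = [], []
    for seed in seeds:
        cfg = SimulationConfig(p=40, n_per_stratum={("nonMetS", "region1"): n},
                               base_edge_density=0.0, depth=1000,
                               mean_log_sd=2.0, latent_sd=0.2, depth_cv=0.08,
                               seed=seed)
        ds = generate_dataset(cfg)
        cands = epi_candidates(ds.abundance)
        if len(cands) < 2:
            continue
        key, null_tax = cands[0], cands[1]
        means = ds.abundance.to_frame().mean().sort_values(ascending=False)
        targets = [t for t in means.index if t not in (key, null_tax)][8:11]
        planted = plant_keystone(ds, key, {t: shift for t in targets})
        for tax, sink in ((key, hits), (null_tax, null_hits)):
            d1, _, _ = epi_indicators(planted.abundance, tax, compute_qmod=False)
            n1, _, _ = epi_null(planted.abundance, tax, b=200, seed=seed + 100,
                                compute_qmod=False)
            sink.append(d1 > n1)
    return {"keystone_rate": float(np.mean(hits)),
            "null_rate": float(np.mean(null_hits)), "n_seeds": len(hits)}


def variance_decomposition_null(seed: int, n: int = 400,
                                n_functions: int = 120) -> dict:
    """Fraction of null (pair, function) interactions called at FDR < 0.05."""
    import pandas as pd

    from .variance_decomposition import batch_decompose

    rng = np.random.default_rng(seed)
    genus = pd.DataFrame(rng.lognormal(0, 1, (n, 6)),
                         index=[f"S{i}" for i in range(n)],
                         columns=[f"g{j}" for j in range(6)])
    funcs = pd.DataFrame(rng.lognormal(0, 1, (n, n_functions)),
                         index=genus.index,
                         columns=[f"f{j}" for j in range(n_functions)])
    results = batch_decompose([("g0", "g1"), ("g2", "g3")], funcs, genus)
    return {"fdr_positive_fraction":
            float(np.mean([r.fdr_interaction < 0.05 for r in results])),
            "n_tests": len(results)}
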