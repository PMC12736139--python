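"""Random-effects meta-analysis of network edges across regions.

Each genus pair's latent correlation is estimated once per region.  Within a
group the per-region estimates are pooled on the Fisher-Z scale with a
DerSimonian-Laird random-effects model: z_i = atanh(r_i) with standard error
1/sqrt(n_i - 3), between-region variance tau^2 by method of moments, and the
pooled effect TE as the inverse-variance weighted mean under weights
1/(se_i^2 + tau^2).  Benjamini-Hochberg FDR is computed over all pairs of a
group, and the significant network is the edge set with FDR below the cut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import pair_name


def fisher_z(r):
    """Variance-stabilizing Fisher-Z transform, z = 1/2 ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError(f"|r| must be < 1 for the Fisher-Z transform; got {r[np.abs(r) >= 1][:3]}")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse transform, r = tanh(z)."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


@dataclass
class PooledEdge:
    """Meta-analytic summary of one edge within one group."""

    pair: tuple[str, str]
    group: str
    te: float          # pooled Fisher-Z effect
    se_te: float       # its standard error
    tau2: float        # between-region variance (DerSimonian-Laird)
    q_regions: float   # within-group Cochran's Q across regions
    p_q: float         # chi-square tail probability of q_regions
    z: float           # Wald statistic TE / seTE
    p: float           # two-sided normal p of the Wald test
    fdr: float | None = None
    k: int = 0         # number of regions pooled

    @property
    def name(self) -> str:
        return pair_name(*self.pair)


def pool_random_effects(estimates: Sequence[tuple[float, int]],
                        pair: tuple[str, str] = ("a", "b"),
                        group: str = "") -> PooledEdge:
    """DerSimonian-Laird random-effects pooling of per-region correlations.

    ``estimates`` is a sequence of (r, n) with n >= 4 per region; at least
    two regions are required for pooling to be defined.
    """
    if len(estimates) < 2:
        raise ValueError("pooling requires at least 2 regions")
    r = np.array([e[0] for e in estimates], dtype=float)
    n = np.array([e[1] for e in estimates], dtype=float)
    if np.any(n < 4):
        raise ValueError("each region needs n >= 4 for se = 1/sqrt(n-3)")
    z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    se2 = 1.0 / (n - 3.0)
    w = 1.0 / se2
    k = len(z)
    z_fe = float(np.sum(w * z) / np.sum(w))
    q = float(np.sum(w * (z - z_fe) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (se2 + tau2)
    te = float(np.sum(w_star * z) / np.sum(w_star))
    se_te = float(1.0 / np.sqrt(np.sum(w_star)))
    wald = te / se_te
    p = float(2 * stats.norm.sf(abs(wald)))
    p_q = float(stats.chi2.sf(q, k - 1))
    return PooledEdge(pair=tuple(pair), group=group, te=te, se_te=se_te,
                      tau2=tau2, q_regions=q, p_q=p_q, z=wald, p=p, k=k)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pool_group_edges(region_estimates: pd.DataFrame, group: str) -> list[PooledEdge]:
    """Pool every edge of one group across its regions and attach BH FDR.

    ``region_estimates`` needs columns taxon_i, taxon_j, r, n (one row per
    region per pair).  The FDR family is all pairs present in the table.
    """
    pooled: list[PooledEdge] = []
    for (ti, tj), sub in region_estimates.groupby(["taxon_i", "taxon_j"], sort=True):
        est = list(zip(sub["r"].tolist(), sub["n"].tolist()))
        pooled.append(pool_random_effects(est, pair=(ti, tj), group=group))
    fdr = bh_fdr([e.p for e in pooled])
    for e, q in zip(pooled, fdr):
        e.fdr = float(q)
    return pooled


@dataclass
class NetworkSummary:
    """Edge counts, sign composition and per-taxon degree of a network."""

    edges: list[PooledEdge]
    n_edges: int
    positive_fraction: float | None
    degree: dict[str, int] = field(default_factory=dict)


def significant_network(pooled: Sequence[PooledEdge], cut: float = 0.05) -> NetworkSummary:
    """Edges with FDR < cut, plus the summaries reported for each group."""
    sig = [e for e in pooled if e.fdr is not None and e.fdr < cut]
    degree: dict[str, int] = {}
    for e in sig:
        for t in e.pair:
            degree[t] = degree.get(t, 0) + 1
    pos_frac = (sum(e.te > 0 for e in sig) / len(sig)) if sig else None
    return NetworkSummary(edges=sig, n_edges=len(sig),
                          positive_fraction=pos_frac, degree=degree)


def pooled_to_frame(pooled: Sequence[PooledEdge]) -> pd.DataFrame:
    return pd.DataFrame({
        "pair": [e.name for e in pooled],
        "taxon_i": [e.pair[0] for e in pooled],
        "taxon_j": [e.pair[1] for e in pooled],
        "group": [e.group for e in pooled],
        "TE": [e.te for e in pooled],
        "seTE": [e.se_te for e in pooled],
        "tau2": [e.tau2 for e in pooled],
        "Q_regions": [e.q_regions for e in pooled],
        "p_Q": [e.p_q for e in pooled],
        "z": [e.z for e in pooled],
        "p": [e.p for e in pooled],
        "fdr": [e.fdr for e in pooled],
    })
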