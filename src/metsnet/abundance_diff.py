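"""Between-group abundance testing with rank-normalization and adjustment.

Each feature (genus or predicted functional feature) is inverse-rank
transformed to normal scores, residualized on the covariates by OLS, and the
residuals compared between groups with the Wilcoxon rank-sum test.  BH FDR
is applied separately within each feature kind (genus, EC, KO, pathway).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .edge_meta import bh_fdr

BLOM_OFFSET = 0.375


def inverse_rank_transform(values, offset: float = BLOM_OFFSET) -> np.ndarray:
    """Normal scores: Phi^{-1}((rank - offset) / (n + 1 - 2*offset)).

    Ties get average ranks.  A constant vector has no order information and
    is rejected.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if np.all(v == v[0]):
        raise ValueError("constant vector: inverse rank transform is degenerate")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (v.size + 1 - 2 * offset))


def covariate_residualize(values, covariates) -> np.ndarray:
    """OLS residuals of values on [intercept + covariates]."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    design = np.column_stack([np.ones(len(y)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient covariate design (rank {rank} < {design.shape[1]} columns); "
            "check for collinear or constant covariates")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; exact enumeration for tiny samples.

    Returns (W, p) where W is the rank-sum of the first sample.  The exact
    null distribution is used when n_a + n_b <= 12 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)  # U -> rank-sum W
    return w, float(res.pvalue)


@dataclass
class FeatureTestResult:
    feature_id: str
    feature_kind: str
    statistic: float
    p: float
    fdr: float | None
    direction: int  # sign of (median residual MetS - median residual non-MetS)


def test_features(values: pd.DataFrame, metadata: pd.DataFrame,
                  feature_kind: str, covariate_columns=None) -> list[FeatureTestResult]:
    """Run transform -> residualize -> rank-sum for every feature column.

    The FDR family is the set of features passed in one call, so callers
    keep genera, ECs, KOs and pathways in separate calls.
    """
    from .partial_corr import encode_covariates

    meta = metadata.loc[values.index]
    cov = encode_covariates(meta, covariate_columns).to_numpy()
    is_mets = (meta["group"] == "MetS").to_numpy()
    results = []
    for fid in values.columns:
        y = inverse_rank_transform(values[fid].to_numpy())
        resid = covariate_residualize(y, cov)
        w, p = wilcoxon_rank_sum(resid[is_mets], resid[~is_mets])
        direction = int(np.sign(np.median(resid[is_mets]) - np.median(resid[~is_mets])))
        results.append(FeatureTestResult(feature_id=str(fid), feature_kind=feature_kind,
                                         statistic=w, p=p, fdr=None, direction=direction))
    fdr = bh_fdr([r.p for r in results])
    for r, q in zip(results, fdr):
        r.fdr = float(q)
    return results


def results_to_frame(results: list[FeatureTestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
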