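"""Covariate adjustment of co-abundance edges via partial correlation.

The correlation matrix over [genera in differential edges + covariates] is
inverted; the negated, rescaled off-diagonal of the precision matrix is the
partial correlation of each pair given everything else (the classical
cor2pcor relation).  A Cochran's Q test on the Fisher-Z scale then compares
each edge's coefficient before and after adjustment: p > 0.05 means the
edge is robust to the measured covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .edge_heterogeneity import between_group_heterogeneity
from .io_formats import COVARIATE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class AdjustedEdge:
    pair: tuple[str, str]
    r_raw: float
    r_partial: float
    q_adjustment: float
    p_adjustment: float
    robust: bool
    n: int


def encode_covariates(metadata: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Numeric covariate design: ordinal levels as 0..k-1, binaries as 0/1."""
    columns = list(columns) if columns is not None else list(COVARIATE_COLUMNS)
    out = pd.DataFrame(index=metadata.index)
    for col in columns:
        v = metadata[col]
        if v.dtype == object:
            levels = sorted(v.unique())
            out[col] = v.map({lev: i for i, lev in enumerate(levels)}).astype(float)
        else:
            out[col] = v.astype(float)
    return out


def correlation_matrix(genera_values: pd.DataFrame,
                       covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation over [genera + covariates], complete cases only."""
    joint = pd.concat([genera_values, covariates], axis=1).dropna()
    sd = joint.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    return joint.corr(method="pearson")


def partial_from_full(m: np.ndarray) -> np.ndarray:
    """Partial correlations from a full correlation matrix (cor2pcor).

    pcor_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj) with Omega = M^{-1};
    a singular M falls back to the pseudo-inverse with a warning.
    """
    m = np.asarray(m, dtype=float)
    try:
        omega = np.linalg.inv(m)
    except np.linalg.LinAlgError:
        logger.warning("correlation matrix singular; using pseudo-inverse")
        omega = np.linalg.pinv(m)
    d = np.sqrt(np.abs(np.diag(omega)))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


def adjustment_q_test(r_raw: float, r_partial: float, n: int) -> tuple[float, float]:
    """Cochran's Q (df=1) comparing an edge before vs after adjustment.

    Both coefficients are Fisher-Z transformed with se = 1/sqrt(n-3); the
    same samples produced both, so the same se applies to each.
    """
    if n <= 3:
        raise ValueError("adjustment test needs n > 3")
    for r in (r_raw, r_partial):
        if abs(r) >= 1:
            raise ValueError(f"|r| must be < 1; got {r}")
    se = 1.0 / np.sqrt(n - 3.0)
    q, _, p = between_group_heterogeneity(np.arctanh(r_raw), se,
                                          np.arctanh(r_partial), se)
    return q, p


def adjust_edges(abundance_log: pd.DataFrame, metadata: pd.DataFrame,
                 pairs: list[tuple[str, str]], robust_p: float = 0.05) -> list[AdjustedEdge]:
    """Re-estimate the listed genus pairs as partial correlations.

    ``abundance_log`` holds log abundances (zero-replaced) of the genera
    involved in differential edges.  Conditioning is on all covariates and
    all other included genera simultaneously, which is what inverting the
    full joint correlation matrix yields.
    """
    cov = encode_covariates(metadata.loc[abundance_log.index])
    full = correlation_matrix(abundance_log, cov)
    pcor = partial_from_full(full.to_numpy())
    pcor = pd.DataFrame(pcor, index=full.index, columns=full.columns)
    n = abundance_log.shape[0]
    out = []
    for a, b in pairs:
        r_raw = float(full.loc[a, b])
        r_partial = float(pcor.loc[a, b])
        q, p = adjustment_q_test(r_raw, r_partial, n)
        out.append(AdjustedEdge(pair=(a, b), r_raw=r_raw, r_partial=r_partial,
                                q_adjustment=q, p_adjustment=p,
                                robust=p > robust_p, n=n))
    return out


def adjusted_to_frame(edges: list[AdjustedEdge]) -> pd.DataFrame:
    return pd.DataFrame({
        "pair": [f"{min(e.pair)}-{max(e.pair)}" for e in edges],
        "r_raw": [e.r_raw for e in edges],
        "r_partial": [e.r_partial for e in edges],
        "Q_adjustment": [e.q_adjustment for e in edges],
        "p_adjustment": [e.p_adjustment for e in edges],
        "robust": [e.robust for e in edges],
        "n": [e.n for e in edges],
    })
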