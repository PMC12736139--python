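"""Latent correlation inference for compositional data (CCLasso-style).

Relative abundances are compositions: only ratios are informative, so naive
correlations of the parts are spurious.  Following the latent-variable view,
the log-composition covariance S differs from the latent log-basis
covariance Sigma only in the direction of the all-ones vector, which the
centering projector P = I - (1/p) 11' removes.  We therefore estimate

    minimize_{Sigma PSD, symmetric}  1/2 || P (Sigma - S) P ||_F^2
                                     + lambda * sum_{i<j} |sigma_ij|

and rescale the minimizer to a correlation matrix.  The problem is solved
by consensus ADMM over three blocks with closed-form proximal steps:
(a) the quadratic data-fit term (a projection-weighted average),
(b) the PSD cone (eigenvalue truncation),
(c) the elementwise L1 penalty on off-diagonals (soft thresholding).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import AbundanceTable, close_rows

logger = logging.getLogger(__name__)


@dataclass
class LatentCorrelation:
    """Estimated latent correlation matrix for one (group, region) stratum."""

    taxon_ids: list[str]
    rho: np.ndarray
    lam: float
    n: int
    group: str = ""
    region: str = ""
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        p = len(self.taxon_ids)
        if self.rho.shape != (p, p):
            raise ValueError("rho must be p x p")


def zero_replace(table: AbundanceTable) -> AbundanceTable:
    """Replace zeros by half the smallest nonzero value, then re-close.

    CCLasso needs strictly positive compositions for the log transform.
    A sample with no nonzero counts cannot be repaired and is an error.
    """
    v = table.values.copy()
    zero_rows = ~(v > 0).any(axis=1)
    if zero_rows.any():
        k = int(np.argmax(zero_rows))
        raise ValueError(f"sample {table.sample_ids[k]!r} is all zeros")
    nz_min = v[v > 0].min()
    v[v == 0] = 0.5 * nz_min
    return AbundanceTable(list(table.sample_ids), list(table.taxon_ids),
                          close_rows(v), relative=True)


def log_composition_covariance(table: AbundanceTable) -> np.ndarray:
    """Empirical covariance of log relative abundances (requires positivity)."""
    if np.any(table.values <= 0):
        raise ValueError("composition must be strictly positive; run zero_replace first")
    logx = np.log(table.values)
    return np.cov(logx, rowvar=False, ddof=1)


def _center(m: np.ndarray) -> np.ndarray:
    """Apply the compositional projector on both sides: P m P."""
    return m - m.mean(axis=0, keepdims=True) - m.mean(axis=1, keepdims=True) + m.mean()


def _prox_quadratic(v: np.ndarray, s_centered: np.ndarray, rho: float) -> np.ndarray:
    # argmin_x 1/2 ||P(x - S)P||^2 + rho/2 ||x - v||^2; the map x -> PxP is an
    # orthogonal projector in Frobenius space, so the two components split.
    pv = _center(v)
    return v - pv + (s_centered + rho * pv) / (1.0 + rho)


def _prox_psd(v: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((v + v.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def _prox_l1_offdiag(v: np.ndarray, thr: float) -> np.ndarray:
    out = np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)
    np.fill_diagonal(out, np.diag(v))
    return out


def fit_latent_covariance(s: np.ndarray, lam: float, tol: float = 1e-6,
                          max_iter: int = 2000) -> tuple[np.ndarray, bool, int]:
    """Solve the penalized PSD fit to a log-composition covariance S."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    p = s.shape[0]
    sc = _center(s)
    admm_rho = 1.0
    z = s.copy()
    x = [z.copy() for _ in range(3)]
    u = [np.zeros_like(s) for _ in range(3)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x[0] = _prox_quadratic(z - u[0], sc, admm_rho)
        x[1] = _prox_psd(z - u[1])
        x[2] = _prox_l1_offdiag(z - u[2], lam / admm_rho)
        z_new = (x[0] + u[0] + x[1] + u[1] + x[2] + u[2]) / 3.0
        z_new = (z_new + z_new.T) / 2.0
        for i in range(3):
            u[i] += x[i] - z_new
        if np.max(np.abs(z_new - z)) < tol:
            z = z_new
            converged = True
            break
        z = z_new
    # final polish: certify PSD and sparsity pattern on the consensus iterate
    sigma = _prox_psd(_prox_l1_offdiag(z, lam / admm_rho))
    return sigma, converged, it


def covariance_to_correlation(sigma: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(sigma), 1e-12, None))
    rho = sigma / np.outer(d, d)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def fit_latent_correlation(table: AbundanceTable, lam: float, tol: float = 1e-6,
                           max_iter: int = 2000, group: str = "",
                           region: str = "") -> LatentCorrelation:
    """Estimate the latent correlation matrix of one abundance table."""
    s = log_composition_covariance(table)
    sigma, converged, n_iter = fit_latent_covariance(s, lam, tol=tol, max_iter=max_iter)
    if not converged:
        logger.warning("CCLasso did not converge in %d iterations (lambda=%g)",
                       max_iter, lam)
    return LatentCorrelation(
        taxon_ids=list(table.taxon_ids),
        rho=covariance_to_correlation(sigma),
        lam=lam, n=table.n_samples, group=group, region=region,
        converged=converged, n_iter=n_iter,
    )


def select_lambda(table: AbundanceTable, grid, k_folds: int = 5,
                  seed: int = 0, tol: float = 1e-6, max_iter: int = 2000) -> float:
    """Pick the penalty by k-fold cross-validated data-fit loss.

    The held-out loss for each fold is 1/2 ||P (Sigma_train - S_test) P||_F^2.
    Fold assignment is deterministic given the seed.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    n = table.n_samples
    if n < k_folds:
        raise ValueError(f"n={n} samples cannot be split into {k_folds} folds")
    if len(grid) == 1:
        return float(grid[0])
    rng = np.random.default_rng(seed)
    fold = rng.permutation(np.arange(n) % k_folds)
    losses = np.zeros(len(grid))
    for f in range(k_folds):
        test = fold == f
        train = AbundanceTable(
            [s for s, t in zip(table.sample_ids, ~test) if t],
            list(table.taxon_ids), close_rows(table.values[~test]), relative=True)
        s_test = log_composition_covariance(
            AbundanceTable([s for s, t in zip(table.sample_ids, test) if t],
                           list(table.taxon_ids), close_rows(table.values[test]),
                           relative=True))
        s_train = log_composition_covariance(train)
        for gi, lam in enumerate(grid):
            sigma, _, _ = fit_latent_covariance(s_train, lam, tol=tol, max_iter=max_iter)
            resid = _center(sigma - s_test)
            losses[gi] += 0.5 * np.sum(resid**2)
    best = int(np.argmin(losses))
    return float(grid[best])


def edges_from_matrix(lc: LatentCorrelation):
    """One (r, n) estimate per unordered taxon pair, diagonal excluded."""
    from .edge_meta import pair_name  # local import avoids a cycle

    rows = []
    p = len(lc.taxon_ids)
    for i in range(p):
        for j in range(i + 1, p):
            ti, tj = sorted((lc.taxon_ids[i], lc.taxon_ids[j]))
            rows.append({
                "pair": pair_name(ti, tj),
                "taxon_i": ti, "taxon_j": tj,
                "r": float(lc.rho[i, j]), "n": lc.n,
                "group": lc.group, "region": lc.region,
            })
    import pandas as pd

    return pd.DataFrame(rows, columns=["pair", "taxon_i", "taxon_j", "r", "n",
                                       "group", "region"])
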