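"""Extra variance in functional features explained by genus interactions.

For a functional feature Y and two genera x1, x2 (all inverse-rank
transformed), two nested OLS models are compared:

    additive:     Y = a + b1*x1 + b2*x2 + e
    interaction:  Y = a + b1*x1 + b2*x2 + b12*x1*x2 + e

var_ind and var_int are the models' R^2; extra_var = var_int - var_ind is
the interaction's contribution, and its nested F-test on (1, n-4) degrees
of freedom gives p_interaction.  p_ind is the additive model's overall
F-test on (2, n-3).  BH FDR is applied within each feature kind.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance_diff import inverse_rank_transform
from .edge_meta import bh_fdr


@dataclass
class VarianceDecompResult:
    pair: tuple[str, str]
    function_id: str
    var_ind: float
    var_int: float
    extra_var: float
    share: float | None      # extra_var / var_int, absent when var_int == 0
    p_ind: float
    p_interaction: float
    fdr: float | None = None
    fdr_interaction: float | None = None
    n: int = 0


def _r2(y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0


def fit_nested_models(y, x1, x2, pair=("a", "b"), function_id="",
                      transform: bool = True) -> VarianceDecompResult:
    """Fit the additive and interaction models for one (pair, feature).

    Inputs are inverse-rank transformed unless ``transform`` is False (for
    callers that pre-transform).  x1 and x2 must not be identical — the
    interaction is degenerate then.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    n = y.size
    if n <= 10:
        raise ValueError("nested model comparison needs n > 10")
    if np.allclose(x1, x2):
        raise ValueError("x1 and x2 are identical; interaction model is degenerate")
    if transform:
        y = inverse_rank_transform(y)
        x1 = inverse_rank_transform(x1)
        x2 = inverse_rank_transform(x2)
    ones = np.ones(n)
    d_add = np.column_stack([ones, x1, x2])
    d_int = np.column_stack([ones, x1, x2, x1 * x2])
    var_ind = _r2(y, d_add)
    var_int = max(_r2(y, d_int), var_ind)  # guard FP jitter; R^2 is monotone
    extra = var_int - var_ind

    # additive model's overall F on (2, n-3)
    if var_ind >= 1.0:
        p_ind = 0.0
    else:
        f_ind = (var_ind / 2) / ((1 - var_ind) / (n - 3))
        p_ind = float(stats.f.sf(f_ind, 2, n - 3))
    # interaction term's nested F on (1, n-4)
    if var_int >= 1.0:
        p_int = 0.0 if extra > 0 else 1.0
    else:
        f_int = extra / ((1 - var_int) / (n - 4))
        p_int = float(stats.f.sf(f_int, 1, n - 4))

    share = (extra / var_int) if var_int > 0 else None
    return VarianceDecompResult(pair=tuple(pair), function_id=str(function_id),
                                var_ind=var_ind, var_int=var_int, extra_var=extra,
                                share=share, p_ind=p_ind, p_interaction=p_int, n=n)


def decomposition_share(result: VarianceDecompResult) -> float | None:
    """Fraction of the interaction model's R^2 contributed by the interaction."""
    if result.var_int <= 0:
        return None
    return result.extra_var / result.var_int


def batch_decompose(pairs, function_values: pd.DataFrame,
                    genus_values: pd.DataFrame,
                    function_kinds: dict[str, str] | None = None) -> list[VarianceDecompResult]:
    """One decomposition per (genus pair, function), BH within feature kind.

    ``function_kinds`` maps function_id -> kind (EC/KO/pathway); all
    functions form a single FDR family when omitted.
    """
    for a, b in pairs:
        for t in (a, b):
            if t not in genus_values.columns:
                raise ValueError(f"unknown taxon id {t!r}")
    results = []
    for fid in function_values.columns:
        y = function_values[fid].to_numpy()
        for a, b in pairs:
            results.append(fit_nested_models(
                y, genus_values[a].to_numpy(), genus_values[b].to_numpy(),
                pair=(a, b), function_id=fid))
    kinds = function_kinds or {}
    by_kind: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        by_kind.setdefault(kinds.get(r.function_id, "all"), []).append(i)
    for members in by_kind.values():
        fdr_ind = bh_fdr([results[i].p_ind for i in members])
        fdr_int = bh_fdr([results[i].p_interaction for i in members])
        for i, qa, qb in zip(members, fdr_ind, fdr_int):
            results[i].fdr = float(qa)
            results[i].fdr_interaction = float(qb)
    return results


def decomposition_to_frame(results: list[VarianceDecompResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "pair": [f"{min(r.pair)}-{max(r.pair)}" for r in results],
        "function": [r.function_id for r in results],
        "var_ind": [r.var_ind for r in results],
        "var_int": [r.var_int for r in results],
        "extra_var": [r.extra_var for r in results],
        "share": [r.share for r in results],
        "p_ind": [r.p_ind for r in results],
        "p_interaction": [r.p_interaction for r in results],
        "fdr": [r.fdr for r in results],
        "fdr_interaction": [r.fdr_interaction for r in results],
        "n": [r.n for r in results],
    })
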