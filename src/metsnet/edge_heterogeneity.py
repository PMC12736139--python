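"""Between-group heterogeneity testing of pooled edges (differential edges).

For each genus pair the two groups' pooled Fisher-Z effects are compared
with a fixed-effect Cochran's Q on one degree of freedom:

    w_g = 1 / seTE_g^2,   zbar = (w_a TE_a + w_b TE_b) / (w_a + w_b)
    Q = w_a (TE_a - zbar)^2 + w_b (TE_b - zbar)^2,   I^2 = max(0, (Q-1)/Q)

An edge is called differential when I^2 > 0.75 and the chi-square(1) tail
probability of Q is below 0.05 — both thresholds pre-specified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .edge_meta import PooledEdge, pair_name

I2_CUT = 0.75
HETERO_P_CUT = 0.05


@dataclass
class DifferentialEdge:
    """Between-group comparison of one pooled edge."""

    pair: tuple[str, str]
    te_non_mets: float
    te_mets: float
    se_non_mets: float
    se_mets: float
    q: float
    i2: float
    hetero_p: float
    is_differential: bool
    direction_change: bool
    fdr_non_mets: float | None = None
    fdr_mets: float | None = None

    @property
    def name(self) -> str:
        return pair_name(*self.pair)


def between_group_heterogeneity(te_a: float, se_a: float,
                                te_b: float, se_b: float) -> tuple[float, float, float]:
    """Cochran's Q, I^2 and chi-square(1) p for two pooled effects.

    Group a is non-MetS and group b is MetS by convention, but the
    statistics are symmetric in the two groups.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError(f"standard errors must be positive; got {se_a}, {se_b}")
    w_a, w_b = 1.0 / se_a**2, 1.0 / se_b**2
    zbar = (w_a * te_a + w_b * te_b) / (w_a + w_b)
    q = w_a * (te_a - zbar) ** 2 + w_b * (te_b - zbar) ** 2
    i2 = max(0.0, (q - 1.0) / q) if q > 0 else 0.0
    p = float(stats.chi2.sf(q, df=1))
    return float(q), float(i2), p


def differential_edge(pair, te_non_mets, se_non_mets, te_mets, se_mets,
                      fdr_non_mets=None, fdr_mets=None,
                      i2_cut: float = I2_CUT, p_cut: float = HETERO_P_CUT) -> DifferentialEdge:
    q, i2, p = between_group_heterogeneity(te_non_mets, se_non_mets, te_mets, se_mets)
    return DifferentialEdge(
        pair=tuple(pair),
        te_non_mets=te_non_mets, te_mets=te_mets,
        se_non_mets=se_non_mets, se_mets=se_mets,
        q=q, i2=i2, hetero_p=p,
        is_differential=(i2 > i2_cut and p < p_cut),
        direction_change=(np.sign(te_non_mets) != np.sign(te_mets)),
        fdr_non_mets=fdr_non_mets, fdr_mets=fdr_mets,
    )


def compare_groups(pooled_non_mets: Sequence[PooledEdge],
                   pooled_mets: Sequence[PooledEdge],
                   eligible: str = "union", fdr_cut: float = 0.05,
                   i2_cut: float = I2_CUT, p_cut: float = HETERO_P_CUT) -> list[DifferentialEdge]:
    """Heterogeneity-test the eligible edge set between the two groups.

    ``eligible`` selects which pairs are tested: "union" (significant at
    ``fdr_cut`` in either group — the default), "intersection" (both), or
    "all" (every pair present in both groups).
    """
    if eligible not in ("union", "intersection", "all"):
        raise ValueError(f"eligible must be union|intersection|all, got {eligible!r}")
    a = {e.name: e for e in pooled_non_mets}
    b = {e.name: e for e in pooled_mets}
    common = set(a) & set(b)
    if eligible == "all":
        names = common
    else:
        sig_a = {k for k in common if a[k].fdr is not None and a[k].fdr < fdr_cut}
        sig_b = {k for k in common if b[k].fdr is not None and b[k].fdr < fdr_cut}
        names = (sig_a | sig_b) if eligible == "union" else (sig_a & sig_b)
    out = []
    for name in sorted(names):
        ea, eb = a[name], b[name]
        out.append(differential_edge(
            ea.pair, ea.te, ea.se_te, eb.te, eb.se_te,
            fdr_non_mets=ea.fdr, fdr_mets=eb.fdr, i2_cut=i2_cut, p_cut=p_cut,
        ))
    return out


def call_differential(edges: Sequence[DifferentialEdge]) -> dict:
    """Edges passing both thresholds, with the incident-genus summary."""
    hits = [e for e in edges if e.is_differential]
    genera = sorted({t for e in hits for t in e.pair})
    return {
        "edges": hits,
        "n_differential": len(hits),
        "genera": genera,
        "n_genera": len(genera),
        "n_direction_change": sum(e.direction_change for e in hits),
    }
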