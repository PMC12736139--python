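import numpy as np
import pytest

from metsnet.io_formats import AbundanceTable, close_rows
from metsnet.synthetic_data import SimulationConfig, generate_dataset


def rank_auc(scores, labels) -> float:
    """AUC of scores for binary labels via the rank (Mann-Whitney) formula."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = labels.sum(), (~labels).sum()
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    return (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def clr_correlation(values: np.ndarray) -> np.ndarray:
    """Sample correlation of centered log-ratio transformed compositions."""
    v = np.asarray(values, dtype=float)
    v = np.where(v > 0, v, 0.5 * v[v > 0].min())
    logv = np.log(close_rows(v))
    clr = logv - logv.mean(axis=1, keepdims=True)
    return np.corrcoef(clr, rowvar=False)


@pytest.fixture(scope="session")
def one_stratum_dataset():
    """Small single-stratum cohort with one strong planted edge."""
    cfg = SimulationConfig(
        p=5, n_per_stratum={("nonMetS", "region1"): 2000},
        base_edge_density=0.0, depth=100_000, depth_cv=0.0,
        differential_pairs=[("g000", "g001", 0.8, 0.8)], seed=1)
    return generate_dataset(cfg)


@pytest.fixture()
def tiny_table():
    values = close_rows(np.array([
        [1.0, 2.0, 3.0, 0.0],
        [2.0, 1.0, 0.0, 1.0],
        [1.0, 1.0, 1.0, 1.0],
        [3.0, 0.0, 1.0, 2.0],
    ]))
    return AbundanceTable([f"S{i}" for i in range(4)],
                          ["gA", "gB", "gC", "gD"], values, relative=True)
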