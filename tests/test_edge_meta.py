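import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsnet.edge_meta import (PooledEdge, bh_fdr, fisher_z, inverse_fisher_z,
                               pool_group_edges, pool_random_effects,
                               significant_network)


def dl_scalar_oracle(rs, ns):
    """Deliberately plain scalar implementation of DerSimonian-Laird pooling."""
    import math

    zs = [0.5 * math.log((1 + r) / (1 - r)) for r in rs]
    vs = [1.0 / (n - 3) for n in ns]
    ws = [1.0 / v for v in vs]
    zbar = sum(w * z for w, z in zip(ws, zs)) / sum(ws)
    q = sum(w * (z - zbar) ** 2 for w, z in zip(ws, zs))
    k = len(zs)
    denom = sum(ws) - sum(w * w for w in ws) / sum(ws)
    tau2 = max(0.0, (q - (k - 1)) / denom)
    wstar = [1.0 / (v + tau2) for v in vs]
    te = sum(w * z for w, z in zip(wstar, zs)) / sum(wstar)
    se = 1.0 / math.sqrt(sum(wstar))
    return te, se, tau2, q


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_log_three(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3), abs=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_symmetry(self):
        assert fisher_z(-0.3) == -fisher_z(0.3)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)

    def test_roundtrip_identity(self):
        grid = np.linspace(-0.99, 0.99, 199)
        np.testing.assert_allclose(inverse_fisher_z(fisher_z(grid)), grid,
                                   atol=1e-12)


class TestPoolRandomEffects:
    def test_three_identical_regions_closed_form(self):
        e = pool_random_effects([(0.3, 50)] * 3)
        assert e.te == pytest.approx(np.arctanh(0.3), abs=1e-10)
        assert e.te == pytest.approx(0.30952, abs=1e-5)
        assert e.tau2 == 0.0
        assert e.q_regions == pytest.approx(0.0, abs=1e-20)
        assert e.se_te == pytest.approx(1 / np.sqrt(3 * 47), abs=1e-12)

    def test_matches_scalar_oracle(self):
        te, se, tau2, q = dl_scalar_oracle([0.3, 0.5], [50, 60])
        e = pool_random_effects([(0.3, 50), (0.5, 60)])
        assert e.te == pytest.approx(te, abs=1e-10)
        assert e.se_te == pytest.approx(se, abs=1e-10)
        assert e.tau2 == pytest.approx(tau2, abs=1e-10)
        assert e.q_regions == pytest.approx(q, abs=1e-10)

    def test_duplicated_region_shrinks_se(self):
        z = np.arctanh(0.4)
        for k in (2, 5):
            e = pool_random_effects([(0.4, 80)] * k)
            assert e.te == pytest.approx(z, abs=1e-12)
            assert e.se_te == pytest.approx(1 / np.sqrt(k * 77), abs=1e-12)

    def test_fewer_than_two_regions_rejected(self):
        with pytest.raises(ValueError, match="2 regions"):
            pool_random_effects([(0.3, 50)])

    def test_tiny_region_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            pool_random_effects([(0.3, 50), (0.2, 3)])

    def test_pooled_te_within_z_range(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = rng.integers(2, 6)
            rs = rng.uniform(-0.8, 0.8, k)
            ns = rng.integers(10, 500, k)
            e = pool_random_effects(list(zip(rs, ns)))
            zs = np.arctanh(rs)
            assert zs.min() - 1e-12 <= e.te <= zs.max() + 1e-12
            assert e.tau2 >= 0
            assert e.fdr is None or e.fdr >= e.p

    def test_matches_r_metafor(self, tmp_path):
        rng = np.random.default_rng(3)
        cases = []
        for _ in range(5):
            k = int(rng.integers(2, 5))
            cases.append((rng.uniform(-0.7, 0.7, k), rng.integers(20, 300, k)))
        lines = ["library(metafor)"]
        for r, n in cases:
            rv = ",".join(map(str, r))
            nv = ",".join(map(str, n))
            lines.append(
                f'res <- rma(yi=atanh(c({rv})), vi=1/(c({nv})-3), method="DL"); '
                'cat(sprintf("%.14f %.14f %.14f\\n", res$beta, res$se, res$tau2))')
        script = tmp_path / "dl.R"
        script.write_text("\n".join(lines) + "\n")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        for line, (r, n) in zip(out.stdout.strip().splitlines(), cases):
            te, se, tau2 = map(float, line.split())
            e = pool_random_effects(list(zip(r, n)))
            assert e.te == pytest.approx(te, abs=1e-10)
            assert e.se_te == pytest.approx(se, abs=1e-10)
            assert e.tau2 == pytest.approx(tau2, abs=1e-10)


class TestBhFdr:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_step_up(self):
        def brute(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                adj[i] = prev
            return adj

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute(p), atol=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.floats(-0.99, 0.99))
def test_fisher_z_roundtrip_property(r):
    assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
def test_bh_preserves_p_value_order(ps):
    adj = bh_fdr(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-15)


class TestSignificantNetwork:
    def _edges(self, specs):
        return [PooledEdge(pair=pair, group="g", te=te, se_te=0.1, tau2=0,
                           q_regions=0, p_q=1, z=0, p=p, fdr=fdr)
                for pair, te, p, fdr in specs]

    def test_all_null_gives_empty_network(self):
        net = significant_network(self._edges([(("a", "b"), 0.1, 1.0, 1.0)]))
        assert net.n_edges == 0
        assert net.positive_fraction is None

    def test_degree_counts_shared_taxon(self):
        net = significant_network(self._edges([
            (("hub", "b"), 0.2, 0.001, 0.01), (("hub", "c"), 0.2, 0.001, 0.01),
            (("hub", "d"), -0.2, 0.001, 0.01)]))
        assert net.degree["hub"] == 3
        assert net.positive_fraction == pytest.approx(2 / 3)


def test_pool_group_edges_attaches_fdr_over_all_pairs():
    import pandas as pd

    rows = []
    rng = np.random.default_rng(0)
    for ti, tj in [("a", "b"), ("a", "c"), ("b", "c")]:
        for region in range(3):
            rows.append({"taxon_i": ti, "taxon_j": tj,
                         "r": rng.uniform(-0.3, 0.3), "n": 100})
    pooled = pool_group_edges(pd.DataFrame(rows), "nonMetS")
    assert len(pooled) == 3
    assert all(e.fdr is not None and e.fdr >= e.p for e in pooled)
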