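import numpy as np
import pytest

from conftest import clr_correlation
from metsnet.epi_keystone import epi_indicators, epi_null
from metsnet.synthetic_data import (FunctionEffect, SimulationConfig,
                                    check_correlation_matrix, generate_dataset,
                                    generate_function_profile, plant_keystone,
                                    taxon_names)


def _single_stratum(n, **kw):
    kw.setdefault("n_per_stratum", {("nonMetS", "region1"): n})
    return SimulationConfig(**kw)


class TestGenerateDataset:
    def test_rows_close_to_one(self):
        ds = generate_dataset(_single_stratum(50, p=20, seed=0))
        np.testing.assert_allclose(ds.abundance.values.sum(axis=1), 1.0, atol=1e-9)

    def test_seed_determinism(self):
        cfg = _single_stratum(40, p=10, seed=7,
                              function_effects=[FunctionEffect("f1", "g000", "g001",
                                                               1.0, 0.5, 0.2)])
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        np.testing.assert_array_equal(a.abundance.values, b.abundance.values)
        assert a.metadata.equals(b.metadata)
        np.testing.assert_array_equal(a.functions.values, b.functions.values)

    def test_independence_case_has_small_clr_correlations(self):
        cfg = _single_stratum(2000, p=8, base_edge_density=0.0, depth=100_000,
                              depth_cv=0.0, mean_log_sd=1.0, seed=2)
        ds = generate_dataset(cfg)
        corr = clr_correlation(ds.abundance.values)
        off = corr[~np.eye(8, dtype=bool)]
        # clr centering induces a small negative bias ~ -1/(p-1)
        assert np.all(np.abs(off + 1 / 7) < 0.1)

    def test_planted_pair_has_largest_clr_correlation(self, one_stratum_dataset):
        corr = clr_correlation(one_stratum_dataset.abundance.values)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        assert {i, j} == {0, 1}

    def test_group_and_region_partition_samples(self):
        cfg = SimulationConfig(p=6, seed=3, n_per_stratum={
            ("nonMetS", "region1"): 10, ("nonMetS", "region2"): 10,
            ("MetS", "region1"): 10, ("MetS", "region2"): 10})
        ds = generate_dataset(cfg)
        counts = ds.metadata.groupby(["group", "region"]).size()
        assert counts.sum() == ds.abundance.n_samples
        assert (counts == 10).all()

    def test_covariate_effect_shifts_taxon(self):
        cfg = _single_stratum(800, p=6, seed=4, base_edge_density=0.0,
                              depth=50_000,
                              covariate_effects=[("age", "g000", 1.0)])
        ds = generate_dataset(cfg)
        r = np.corrcoef(ds.metadata["age"], ds.latent_log["g000"])[0, 1]
        assert r > 0.5

    def test_planted_rho_at_least_one_rejected(self):
        cfg = _single_stratum(20, p=4, differential_pairs=[("g000", "g001", 1.0, 0.5)])
        with pytest.raises(ValueError, match="< 1"):
            generate_dataset(cfg)

    def test_non_psd_matrix_rejected_with_eigenvalue(self):
        m = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            check_correlation_matrix(m)


class TestPlantedEdgeRecoverability:
    def test_planted_pair_beats_null_pairs(self):
        # |rho|=0.7 planted pair should top the non-edge clr-correlation
        # distribution in nearly every replicate
        wins = 0
        for seed in range(20):
            cfg = _single_stratum(1000, p=15, base_edge_density=0.0,
                                  depth=50_000, mean_log_sd=1.0, seed=seed,
                                  differential_pairs=[("g002", "g003", 0.7, 0.7)])
            ds = generate_dataset(cfg)
            corr = np.abs(clr_correlation(ds.abundance.values))
            planted = corr[2, 3]
            mask = np.triu(np.ones_like(corr, dtype=bool), 1)
            mask[2, 3] = False
            wins += planted > np.quantile(corr[mask], 0.95)
        assert wins >= 19


class TestFunctionProfile:
    def test_unknown_taxon_named_in_error(self):
        ds = generate_dataset(_single_stratum(30, p=4, seed=1))
        with pytest.raises(ValueError, match="gXYZ"):
            generate_function_profile(ds, FunctionEffect("f", "gXYZ", "g001"))

    def test_same_taxon_twice_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            FunctionEffect("f", "g000", "g000")

    def test_noiseless_linear_function_is_affine_in_latent(self):
        ds = generate_dataset(_single_stratum(200, p=4, seed=1))
        y = generate_function_profile(
            ds, FunctionEffect("f", "g000", "g001", beta1=1.0, noise_sd=0.0))
        z = ds.latent_log["g000"]
        r2 = np.corrcoef(y, z)[0, 1] ** 2
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert y.min() >= 0


@pytest.fixture(scope="module")
def base():
    return generate_dataset(_single_stratum(
        300, p=30, seed=8, base_edge_density=0.0, depth=1000,
        mean_log_sd=2.0, latent_sd=0.2, depth_cv=0.08))


class TestPlantKeystone:
    def _candidate(self, ds):
        prev = ds.abundance.prevalence()
        return prev[(prev >= 0.3) & (prev <= 0.7)].index[0]

    def test_shift_on_candidate_rejected(self, base):
        tax = self._candidate(base)
        with pytest.raises(ValueError, match="candidate"):
            plant_keystone(base, tax, {tax: 1.0})

    def test_prevalence_window_enforced(self, base):
        prev = base.abundance.prevalence()
        common = prev.idxmax()
        other = [t for t in base.abundance.taxon_ids if t != common][0]
        with pytest.raises(ValueError, match="window"):
            plant_keystone(base, common, {other: 1.0},
                           prevalence_window=(0.25, 0.75))

    def test_zero_shift_not_flagged(self, base):
        tax = self._candidate(base)
        planted = plant_keystone(base, tax, {})
        d1, _, _ = epi_indicators(planted.abundance, tax, compute_qmod=False)
        n1, _, _ = epi_null(planted.abundance, tax, b=200, seed=3,
                            compute_qmod=False)
        assert d1 <= n1

    def test_candidate_presence_pattern_preserved(self, base):
        tax = self._candidate(base)
        other = [t for t in base.abundance.taxon_ids if t != tax][0]
        planted = plant_keystone(base, tax, {other: 1.0})
        before = base.abundance.to_frame()[tax] > 0
        after = planted.abundance.to_frame()[tax] > 0
        assert (before == after).all()

    def test_strong_shift_flagged_by_d1(self, base):
        tax = self._candidate(base)
        means = base.abundance.to_frame().mean().sort_values(ascending=False)
        targets = [t for t in means.index if t != tax][8:11]
        planted = plant_keystone(base, tax, {t: 1.0 for t in targets})
        d1, _, _ = epi_indicators(planted.abundance, tax, compute_qmod=False)
        n1, _, _ = epi_null(planted.abundance, tax, b=200, seed=3,
                            compute_qmod=False)
        assert d1 > n1


def test_taxon_names_are_unique():
    names = taxon_names(93)
    assert len(set(names)) == 93
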