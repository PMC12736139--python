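import numpy as np
import pandas as pd
import pytest

from metsnet.datasets import variance_decomposition_table
from metsnet.variance_decomposition import (VarianceDecompResult,
                                            batch_decompose,
                                            decomposition_share,
                                            fit_nested_models)


class TestFitNestedModels:
    def test_reported_extra_variance_arithmetic(self):
        for _, row in variance_decomposition_table().iterrows():
            assert abs((row["var_int"] - row["var_ind"]) - row["extra_var"]) <= 1e-8

    def test_identical_regressors_rejected(self):
        x = np.random.default_rng(0).normal(0, 1, 50)
        with pytest.raises(ValueError, match="identical"):
            fit_nested_models(x * 2, x, x, transform=False)

    def test_small_n_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(ValueError, match="n > 10"):
            fit_nested_models(x, x + 1, x * 2)

    def test_noiseless_linear_model_r2_one(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(0, 1, 600), rng.normal(0, 1, 600)
        res = fit_nested_models(2.0 * x1 + 0.5, x1, x2, transform=False)
        assert res.var_ind == pytest.approx(1.0, abs=1e-9)

    def test_pure_interaction_dominates(self):
        rng = np.random.default_rng(2)
        x1, x2 = rng.normal(0, 1, 600), rng.normal(0, 1, 600)
        res = fit_nested_models(x1 * x2, x1, x2, transform=False)
        assert res.extra_var > 0.5
        assert res.p_interaction < 1e-10
        assert res.var_ind < 0.05

    def test_null_r2_is_small(self):
        small = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 1, 600)
            x1, x2 = rng.normal(0, 1, 600), rng.normal(0, 1, 600)
            res = fit_nested_models(y, x1, x2)
            small += res.var_int < 0.03
        assert small >= 18

    def test_nesting_invariant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            y = rng.normal(0, 1, 60)
            x1, x2 = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
            res = fit_nested_models(y, x1, x2, transform=False)
            assert 0 <= res.var_ind <= res.var_int <= 1
            assert res.extra_var >= 0

    def test_scale_invariance_of_r2(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 100)
        x1, x2 = rng.normal(0, 1, 100), rng.normal(0, 1, 100)
        a = fit_nested_models(y, x1, x2, transform=False)
        b = fit_nested_models(1e4 * y, x1, x2, transform=False)
        assert a.var_ind == pytest.approx(b.var_ind, abs=1e-12)
        assert a.var_int == pytest.approx(b.var_int, abs=1e-12)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x1, x2 = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        y = 0.4 * x1 - 0.2 * x2 + 0.3 * x1 * x2 + rng.normal(0, 1, 200)
        res = fit_nested_models(y, x1, x2, transform=False)
        ref_add = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2]))).fit()
        ref_int = sm.OLS(y, sm.add_constant(
            np.column_stack([x1, x2, x1 * x2]))).fit()
        assert res.var_ind == pytest.approx(ref_add.rsquared, abs=1e-10)
        assert res.var_int == pytest.approx(ref_int.rsquared, abs=1e-10)
        assert res.p_ind == pytest.approx(ref_add.f_pvalue, abs=1e-10)
        ftest = ref_int.compare_f_test(ref_add)
        assert res.p_interaction == pytest.approx(ftest[1], abs=1e-10)


class TestDecompositionShare:
    def test_reported_share_is_184_percent(self):
        res = VarianceDecompResult(pair=("Neglecta", "Anaerotignum"),
                                   function_id="EC:2.5.1.46",
                                   var_ind=0.0390983, var_int=0.04792689,
                                   extra_var=0.00882859, share=None,
                                   p_ind=0.0, p_interaction=0.0)
        assert decomposition_share(res) == pytest.approx(0.1842, abs=5e-5)

    def test_zero_extra_gives_zero_share(self):
        res = VarianceDecompResult(("a", "b"), "f", 0.2, 0.2, 0.0, None, 0, 0)
        assert decomposition_share(res) == 0.0

    def test_pure_interaction_gives_share_one(self):
        res = VarianceDecompResult(("a", "b"), "f", 0.0, 0.3, 0.3, None, 0, 0)
        assert decomposition_share(res) == pytest.approx(1.0)

    def test_zero_var_int_reported_absent(self):
        res = VarianceDecompResult(("a", "b"), "f", 0.0, 0.0, 0.0, None, 0, 0)
        assert decomposition_share(res) is None


class TestBatchDecompose:
    def _tables(self, rng, n=400, effect_pair=None, beta12=0.0):
        genus = pd.DataFrame(rng.lognormal(0, 1, (n, 6)),
                             index=[f"S{i}" for i in range(n)],
                             columns=[f"g{j}" for j in range(6)])
        funcs = pd.DataFrame(rng.lognormal(0, 1, (n, 2)),
                             index=genus.index, columns=["f0", "f1"])
        if effect_pair is not None:
            a, b = effect_pair
            za = np.log(genus[a])
            zb = np.log(genus[b])
            za = (za - za.mean()) / za.std()
            zb = (zb - zb.mean()) / zb.std()
            funcs["f0"] = np.exp(beta12 * za * zb + rng.normal(0, 1, n) * 0.7)
        return genus, funcs

    def test_result_count(self):
        rng = np.random.default_rng(0)
        genus, funcs = self._tables(rng)
        pairs = [("g0", "g1"), ("g2", "g3"), ("g4", "g5")]
        assert len(batch_decompose(pairs, funcs, genus)) == 6

    def test_missing_taxon_named(self):
        rng = np.random.default_rng(0)
        genus, funcs = self._tables(rng)
        with pytest.raises(ValueError, match="gQQ"):
            batch_decompose([("g0", "gQQ")], funcs, genus)

    def test_generating_pair_has_largest_extra_var(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genus, funcs = self._tables(rng, n=600, effect_pair=("g0", "g1"),
                                        beta12=0.3)
            pairs = [("g0", "g1"), ("g2", "g3"), ("g4", "g5")]
            results = [r for r in batch_decompose(pairs, funcs, genus)
                       if r.function_id == "f0"]
            best = max(results, key=lambda r: r.extra_var)
            wins += set(best.pair) == {"g0", "g1"}
        assert wins >= 8

    def test_all_null_fdr_positive_fraction_small(self):
        rng = np.random.default_rng(42)
        n = 400
        genus = pd.DataFrame(rng.lognormal(0, 1, (n, 6)),
                             index=[f"S{i}" for i in range(n)],
                             columns=[f"g{j}" for j in range(6)])
        funcs = pd.DataFrame(rng.lognormal(0, 1, (n, 120)),
                             index=genus.index,
                             columns=[f"f{j}" for j in range(120)])
        results = batch_decompose([("g0", "g1"), ("g2", "g3")], funcs, genus)
        frac = np.mean([r.fdr_interaction < 0.05 for r in results])
        assert frac <= 0.05

    def test_fdr_families_follow_function_kinds(self):
        rng = np.random.default_rng(1)
        genus, funcs = self._tables(rng)
        kinds = {"f0": "EC", "f1": "KO"}
        results = batch_decompose([("g0", "g1")], funcs, genus,
                                  function_kinds=kinds)
        # single-member families: BH leaves each p unchanged
        for r in results:
            assert r.fdr == pytest.approx(r.p_ind, abs=1e-12)
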