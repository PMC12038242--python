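"""Differential expression: size factors, dispersion, Wald test, BH, CLR."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from circkit import de
from circkit.synth import simulate_cohort_matrix


def _two_group_design(n_a, n_b):
    idx = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return pd.DataFrame({"class": ["A"] * n_a + ["B"] * n_b}, index=idx), idx


class TestSizeFactors:
    def test_doubled_sample_gets_double_factor(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 100, size=50)
        m = pd.DataFrame({"A": base, "B": 2 * base})
        f = de.size_factors(m)
        assert f["B"] / f["A"] == pytest.approx(2.0)

    def test_identical_samples_equal_factors(self):
        m = pd.DataFrame({"A": [5, 10, 20], "B": [5, 10, 20], "C": [5, 10, 20]})
        assert de.size_factors(m).nunique() == 1

    def test_matches_hand_enumeration_on_toy_matrix(self):
        """Brute-force median-of-ratios on a 3-feature matrix."""
        m = pd.DataFrame({"A": [2, 4, 16], "B": [8, 4, 4], "C": [4, 16, 8]},
                         index=["f1", "f2", "f3"])
        counts = m.to_numpy(dtype=float)
        geo = np.exp(np.mean(np.log(counts), axis=1))
        expected = np.median(counts / geo[:, None], axis=0)
        got = de.size_factors(m)
        assert np.allclose(got.to_numpy(), expected)

    def test_scale_equivariance_of_factor_ratios(self):
        """Scaling one sample by c scales its factor c-fold relative to the
        others (absolute factors shift because the per-feature geometric
        mean reference also absorbs a c**(1/m) share)."""
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.integers(5, 60, size=(40, 4)), columns=list("ABCD"))
        f = de.size_factors(m)
        m2 = m.copy()
        m2["C"] = m2["C"] * 3
        f2 = de.size_factors(m2)
        assert (f2["C"] / f2["A"]) / (f["C"] / f["A"]) == pytest.approx(3.0)
        assert f2["B"] / f2["A"] == pytest.approx(f["B"] / f["A"])

    def test_fallback_without_positive_feature(self):
        m = pd.DataFrame({"A": [0, 5], "B": [5, 0]})
        with pytest.warns(UserWarning):
            f = de.size_factors(m)
        assert (f > 0).all()


class TestDispersion:
    def test_constant_feature_floored(self):
        m = pd.DataFrame({c: [7] for c in "ABCD"})
        f = pd.Series(1.0, index=m.columns)
        assert de.estimate_dispersion(m, f).iloc[0] == de.ALPHA_FLOOR

    def test_poisson_feature_near_floor(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.poisson(200, size=(300, 40)))
        f = pd.Series(1.0, index=m.columns)
        alpha = de.estimate_dispersion(m, f)
        assert alpha.median() < 0.01

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(4)
        alpha_true, mu, n = 0.1, 200.0, 50
        size = 1 / alpha_true
        m = pd.DataFrame(rng.negative_binomial(size, size / (size + mu), size=(500, n)))
        f = pd.Series(1.0, index=m.columns)
        est = de.estimate_dispersion(m, f).median()
        assert 0.05 <= est <= 0.2


class TestNbWaldTest:
    def test_identical_groups_null(self):
        m = pd.DataFrame(
            {"a0": [50, 10], "a1": [50, 10], "b0": [50, 10], "b1": [50, 10]},
            index=["f1", "f2"],
        )
        design, _ = _two_group_design(2, 2)
        res = de.nb_wald_test(m, design, ("class", "A", "B"))
        assert np.allclose(res["log2FoldChange"], 0.0)
        assert (res["pvalue"] > 0.99).all()

    def test_label_swap_flips_sign_keeps_pvalue(self):
        cm = simulate_cohort_matrix(200, 6, 20, effect_log2fc=1.5, dispersion=0.1, seed=5)
        fwd = de.nb_wald_test(cm.counts, cm.design, ("class", "healthy", "disease"))
        rev = de.nb_wald_test(cm.counts, cm.design, ("class", "disease", "healthy"))
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"], equal_nan=True)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], equal_nan=True)

    def test_all_zero_feature_is_na(self):
        m = pd.DataFrame(
            {"a0": [0, 5], "a1": [0, 8], "b0": [0, 9], "b1": [0, 4]}, index=["z", "ok"]
        )
        design, _ = _two_group_design(2, 2)
        res = de.nb_wald_test(m, design, ("class", "A", "B"))
        assert np.isnan(res.loc["z", "pvalue"])
        assert np.isfinite(res.loc["ok", "pvalue"])

    def test_recovery_of_planted_effect(self):
        cm = simulate_cohort_matrix(1000, 10, 50, effect_log2fc=2.0, dispersion=0.1, seed=6)
        res = de.nb_wald_test(cm.counts, cm.design, ("class", "healthy", "disease"))
        med = res.loc[cm.truth["informative"], "log2FoldChange"].median()
        assert abs(med - 2.0) < 0.3


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert de.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(de.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_nan_passthrough(self):
        out = de.bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1]) and np.isfinite(out[0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_statsmodels(self, pvals):
        ours = de.bh_adjust(pvals)
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_monotone_step_up_property(self):
        rng = np.random.default_rng(7)
        p = rng.random(200)
        adj = de.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert ((adj >= 0) & (adj <= 1)).all()


class TestDifferentialClr:
    def _clr_frame(self, rng, n_feat, vals_a, vals_b):
        data = {}
        for i, v in enumerate(vals_a):
            data[f"a{i}"] = v
        for i, v in enumerate(vals_b):
            data[f"b{i}"] = v
        return pd.DataFrame(data, index=[f"c{i}" for i in range(n_feat)])

    def test_identical_groups_pvalue_one(self):
        col = [1.0, 2.0, 0.5]
        clr = self._clr_frame(None, 3, [col] * 3, [col] * 3)
        design, _ = _two_group_design(3, 3)
        res = de.differential_clr(clr, design, ("class", "A", "B"), seed=1)
        assert np.allclose(res["log2FoldChange"], 0.0)
        assert (res["pvalue"] == 1.0).all()

    def test_planted_fourfold_ratio_statistic_near_two(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0.5, 2.0, size=20)
        vals_a = [base * rng.normal(1, 0.02, size=20) for _ in range(4)]
        vals_b = [4 * base * rng.normal(1, 0.02, size=20) for _ in range(4)]
        clr = self._clr_frame(rng, 20, vals_a, vals_b)
        design, _ = _two_group_design(4, 4)
        res = de.differential_clr(clr, design, ("class", "A", "B"), seed=2)
        assert res["log2FoldChange"].median() == pytest.approx(2.0, abs=0.15)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(9)
        clr = pd.DataFrame(
            rng.lognormal(0, 1, size=(150, 12)),
            index=[f"c{i}" for i in range(150)],
            columns=[f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)],
        )
        design, _ = _two_group_design(6, 6)
        res = de.differential_clr(clr, design, ("class", "A", "B"), seed=3)
        ks = stats.kstest(res["pvalue"], "uniform")
        assert ks.pvalue > 0.01

    def test_degenerate_permutation_space_is_na(self):
        clr = pd.DataFrame({"a0": [1.0], "a1": [1.0], "b0": [2.0], "b1": [2.0]}, index=["c"])
        design, _ = _two_group_design(2, 2)
        res = de.differential_clr(clr, design, ("class", "A", "B"), seed=4)
        assert np.isnan(res["pvalue"]).all()  # C(4,2)=6 < 20 arrangements


class TestClassifySignificant:
    def test_partition(self):
        res = pd.DataFrame(
            {
                "log2FoldChange": [1.2, 1.2, -3.0, 0.5, np.nan],
                "padj": [0.01, 0.2, 1e-5, 0.001, 0.01],
            },
            index=list("abcde"),
        )
        out = de.classify_significant(res)
        assert out.tolist() == ["up", "unchanged", "down", "unchanged", "unchanged"]

    def test_up_down_excess_recovered(self):
        """Planting 13x more up- than down-regulated features yields a
        matching excess among the significant calls."""
        rng = np.random.default_rng(10)
        n_up, n_down = 130, 10
        effects = np.concatenate([np.full(n_up, 2.0), np.full(n_down, -2.0)])
        cm = simulate_cohort_matrix(
            2000, 8, n_up + n_down, effect_log2fc=effects, dispersion=0.05, seed=11
        )
        res = de.nb_wald_test(cm.counts, cm.design, ("class", "healthy", "disease"))
        calls = de.classify_significant(res)
        ratio = (calls == "up").sum() / max((calls == "down").sum(), 1)
        assert 13 * 0.7 <= ratio <= 13 * 1.3
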