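"""Differential-expression engine: filtering rules, size factors,
NB-GLM fits against an independent maximum-likelihood oracle, the
composite-null Wald test, and BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import colonysig as cs
from colonysig.de import NBExpressionModel

from conftest import split_metadata


def _counts(values, samples=None):
    values = np.atleast_2d(values)
    cols = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                        columns=cols)


class TestFilterLowExpression:
    def test_rules(self):
        counts = _counts([
            [0, 0, 0, 0, 0, 0],   # all zero: removed
            [2, 1, 1, 0, 0, 0],   # group A mean 1.33: retained
            [1, 1, 0, 1, 1, 0],   # both means < 1: removed
            [0, 0, 0, 5, 5, 5],   # group B mean 5: retained
        ])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        kept = cs.filter_low_expression(counts, groups)
        assert list(kept.index) == ["g1", "g3"]

    def test_missing_grouping_errors(self):
        counts = _counts([[1, 2]])
        with pytest.raises(ValueError):
            cs.filter_low_expression(counts, pd.Series({"s0": "A"}))


class TestSizeFactors:
    def test_identical_samples(self):
        counts = _counts(np.tile([[4], [7], [2]], (1, 3)))
        assert np.allclose(cs.size_factors(counts), 1.0)

    def test_doubled_sample(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(50, size=(500, 1))
        counts = _counts(np.hstack([base, 2 * base]))
        sf = cs.size_factors(counts)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0, abs=1e-9)

    def test_single_gene_hand_computation(self):
        counts = _counts([[4, 9]])
        sf = cs.size_factors(counts)
        expected = np.array([4 / 6, 9 / 6])
        expected /= np.exp(np.mean(np.log(expected)))
        assert np.allclose(sf, expected, atol=1e-12)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(4)
        counts = _counts(rng.poisson(20, size=(200, 8)))
        sf = cs.size_factors(counts)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            cs.size_factors(_counts([[0, 0], [0, 0]]))


class TestFitNBGLM:
    def test_null_contrast_near_zero(self):
        rng = np.random.default_rng(10)
        y = rng.negative_binomial(10, 10 / (10 + 100), size=100)
        X = np.column_stack([np.ones(100), np.repeat([0, 1], 50)])
        coef, se, alpha = cs.fit_nb_glm(y, X, np.ones(100))
        assert abs(coef[1]) < 0.05 * 4  # |log2 ratio| small under the null

    def test_matches_statsmodels_mle_oracle(self):
        """Coefficients agree with an independent NB2 MLE on small data."""
        import statsmodels.api as sm
        rng = np.random.default_rng(12)
        X = np.column_stack([np.ones(30), np.repeat([0.0, 1.0], 15)])
        mu = np.exp(3.0 + 0.8 * X[:, 1])
        y = rng.negative_binomial(1 / 0.1, 1 / (1 + 0.1 * mu))
        coef, se, alpha = cs.fit_nb_glm(y, X, np.ones(30))
        oracle = sm.NegativeBinomial(y, X).fit(disp=0)
        assert np.allclose(coef * np.log(2), oracle.params[:2], atol=5e-3)

    def test_poisson_limit_dispersion(self):
        rng = np.random.default_rng(13)
        y = rng.poisson(80, size=100)
        X = np.ones((100, 1))
        _, _, alpha = cs.fit_nb_glm(y, X, np.ones(100))
        assert alpha < 0.05

    def test_fixed_dispersion_closed_form_group_ratio(self):
        """With unit size factors and fixed dispersion, the binary-covariate
        coefficient is the log2 ratio of group means (MLE closed form)."""
        rng = np.random.default_rng(14)
        y = np.concatenate([rng.poisson(40, 25), rng.poisson(160, 25)]).astype(float)
        X = np.column_stack([np.ones(50), np.repeat([0.0, 1.0], 25)])
        coef, _, _ = cs.fit_nb_glm(y, X, np.ones(50), dispersion=0.05)
        expected = np.log2(y[25:].mean() / y[:25].mean())
        assert coef[1] == pytest.approx(expected, abs=1e-6)

    def test_design_validation(self):
        y = np.arange(6)
        with pytest.raises(ValueError):
            cs.fit_nb_glm(y, np.ones((6, 1)) * [[1, 1]], np.ones(6))  # rank deficient
        with pytest.raises(ValueError):
            cs.fit_nb_glm(y[:2], np.ones((2, 2)), np.ones(2))  # n <= p


class TestWaldTest:
    def test_point_null_center(self):
        assert cs.wald_test(0.0, 1.0, 0.0) == pytest.approx(1.0)

    def test_composite_null_boundary(self):
        assert cs.wald_test(1.5, 0.5, 1.5) == pytest.approx(1.0)
        assert cs.wald_test(-1.5, 0.5, 1.5) == pytest.approx(1.0)

    def test_composite_null_value(self):
        p = cs.wald_test(2.5, 0.5, 1.5)
        assert p == pytest.approx(2 * (1 - stats.norm.cdf(2.0)), abs=1e-12)

    def test_se_validation(self):
        with pytest.raises(ValueError):
            cs.wald_test(1.0, 0.0)

    @given(st.floats(-4, 4), st.floats(0.1, 2), st.floats(0, 2))
    @settings(max_examples=100, deadline=None)
    def test_p_decreases_as_theta_shrinks(self, effect, se, theta):
        """Raising the threshold can only raise the p-value."""
        p_low = cs.wald_test(effect, se, 0.0)
        p_high = cs.wald_test(effect, se, theta)
        assert p_high >= p_low - 1e-12


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert cs.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_computed_stepup(self):
        assert np.allclose(cs.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(cs.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_definition(self, ps):
        """BH equals max_{k>=i} min(1, n p_(k) / k) mapped back to input order."""
        p = np.asarray(ps)
        adj = cs.bh_adjust(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        sorted_adj = np.minimum(1, p[order] * n / np.arange(1, n + 1))
        brute_sorted = np.minimum.accumulate(sorted_adj[::-1])[::-1]
        brute = np.empty(n)
        brute[order] = brute_sorted
        assert np.allclose(adj, brute, atol=1e-12)


class TestRunDE:
    @pytest.fixture(scope="class")
    def planted(self, request):
        truth = cs.make_truth(n_genes=400, n_role=40, n_effort=0, n_modules=0,
                              module_size=0, role_log2fc=2.0, seed=61)
        meta = split_metadata(19, 64, seed=61)
        counts = cs.generate_counts(meta, truth, seed=62)
        design = cs.DesignSpec({"role": "categorical"}, "role",
                               {"role": "non_reproductive"})
        return counts, meta, truth, design

    def test_recall_and_theta_monotonicity(self, planted):
        counts, meta, truth, design = planted
        sig = {}
        for theta in (0.0, np.log2(1.5), 1.5):
            res = cs.run_de(counts, meta, design, theta=theta)
            sig[theta] = set(res.significant())
        planted_set = set(truth.role_effects)
        recall = len(sig[0.0] & planted_set) / len(planted_set)
        assert recall >= 0.9
        assert sig[1.5] <= sig[np.log2(1.5)] <= sig[0.0]

    def test_significant_sets_respect_bh_rule(self, planted):
        counts, meta, _, design = planted
        res = cs.run_de(counts, meta, design)
        t = res.table
        assert (t.loc[res.significant(), "p_adj"] < 0.05).all()
        assert (t["p_adj"].dropna() >= t["p"].dropna() - 1e-12).all()

    def test_degenerate_design_errors(self, planted):
        counts, meta, _, _ = planted
        meta2 = meta.copy()
        meta2["role"] = "non_reproductive"
        with pytest.raises(ValueError):
            cs.run_de(counts, meta2, "role", contrast="role")

    def test_result_roundtrip(self, planted, tmp_path):
        counts, meta, _, design = planted
        res = cs.run_de(counts, meta, design)
        res.to_tsv(tmp_path / "de.tsv")
        back = cs.DEResults.from_tsv(tmp_path / "de.tsv")
        pd.testing.assert_frame_equal(res.table, back.table, check_dtype=False,
                                      check_names=False)
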