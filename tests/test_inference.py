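"""Nonparametric tests, logistic regression and PCA against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import rank_sum_exact_p, signed_rank_exact_p
from sociorank.inference import (
    EXACT,
    NORMAL_APPROX,
    fit_logistic,
    group_summary,
    logistic_score_permutation,
    pca_standardized,
    spearman_corr,
    wilcoxon_paired,
    wilcoxon_unpaired,
)

finite_vec = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False), min_size=3, max_size=12
)


class TestWilcoxonPaired:
    def test_identical_vectors_are_degenerate(self):
        res = wilcoxon_paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0 and res.n_effective == 0

    def test_six_unit_shifts_give_exact_two_over_sixtyfour(self):
        x = np.arange(6.0)
        res = wilcoxon_paired(x, x + 1)
        assert res.method == EXACT
        assert res.p_value == pytest.approx(2 / 64)

    def test_matches_full_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 11))
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            d = x - y
            d_nz = d[d != 0]
            if len(np.unique(np.abs(d_nz))) < len(d_nz):
                continue
            assert wilcoxon_paired(x, y).p_value == pytest.approx(
                signed_rank_exact_p(d), abs=1e-12
            )

    def test_tied_ranks_still_enumerated_exactly(self):
        # all |differences| equal: midrank enumeration, not the approximation
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = wilcoxon_paired(x, x + np.array([1.0, 1.0, -1.0, 1.0, -1.0, 1.0]))
        assert res.method == EXACT
        assert res.p_value == pytest.approx(signed_rank_exact_p(np.array([-1.0, -1.0, 1.0, -1.0, 1.0, -1.0])))

    def test_large_samples_use_normal_approximation(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        res = wilcoxon_paired(x, y)
        assert res.method == NORMAL_APPROX
        assert 0 <= res.p_value <= 1

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0, 2.0], [1.0])


class TestWilcoxonUnpaired:
    def test_fully_separated_small_groups(self):
        res = wilcoxon_unpaired([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.method == EXACT
        assert res.p_value == pytest.approx(2 / 20)

    def test_identical_groups_give_p_one(self):
        res = wilcoxon_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_full_enumeration_oracle(self, rng):
        for _ in range(30):
            nx_, ny = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            x, y = rng.normal(size=nx_), rng.normal(size=ny)
            assert wilcoxon_unpaired(x, y).p_value == pytest.approx(
                rank_sum_exact_p(x, y), abs=1e-12
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_unpaired([], [1.0])

    @given(finite_vec, finite_vec)
    def test_p_values_always_in_unit_interval(self, x, y):
        assert 0 <= wilcoxon_unpaired(x, y).p_value <= 1
        if len(x) == len(y):
            assert 0 <= wilcoxon_paired(x, y).p_value <= 1


class TestSpearman:
    def test_strictly_monotone_pairs(self):
        assert spearman_corr([1, 2, 3, 4], [10, 20, 25, 90]).rho == pytest.approx(1.0)
        assert spearman_corr([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_constant_input_is_degenerate(self):
        res = spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.rho)

    def test_invariance_under_monotone_transforms(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman_corr(x, y)
        warped = spearman_corr(np.exp(x / 3), 5 * y - 2)
        assert warped.rho == pytest.approx(base.rho, abs=1e-12)
        assert warped.p_value == pytest.approx(base.p_value, abs=1e-12)


class TestLogistic:
    def test_constant_outcome_rejected(self):
        X = pd.DataFrame({"intercept": [1.0] * 4, "x": [0.0, 1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(X, [1, 1, 1, 1])

    def test_rank_deficient_design_names_collinear_terms(self):
        X = pd.DataFrame(
            {"intercept": [1.0] * 6, "a": [1, 2, 3, 4, 5, 6.0], "b": [2, 4, 6, 8, 10, 12.0]}
        )
        with pytest.raises(ValueError, match="a|b"):
            fit_logistic(X, [0, 1, 0, 1, 0, 1])

    def test_two_by_two_table_recovers_log_odds_ratio(self):
        # cells (exposed/unexposed x outcome): 3,1,1,3 -> OR = 9
        x = [1] * 4 + [0] * 4
        y = [1, 1, 1, 0, 1, 0, 0, 0]
        X = pd.DataFrame({"intercept": 1.0, "exposed": np.asarray(x, float)})
        fit = fit_logistic(X, y)
        assert fit.term("exposed")["estimate"] == pytest.approx(np.log(9.0), abs=1e-6)
        assert fit.converged and not fit.separated

    def test_wald_identities_hold(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=60)})
        y = (rng.random(60) < 1 / (1 + np.exp(-X["x"]))).astype(float)
        fit = fit_logistic(X, y)
        assert np.allclose(fit.z_value, fit.estimate / fit.std_error)
        assert ((fit.p_value >= 0) & (fit.p_value <= 1)).all()

    def test_recovers_known_coefficients_within_three_se(self):
        """n = 500 simulations recover each coefficient within 3 SE
        (allowing a single 3-SE excursion across all seeds/terms)."""
        true = np.array([-0.5, 1.0, -0.8])
        misses = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                {"intercept": 1.0, "x1": rng.normal(size=500), "x2": rng.normal(size=500)}
            )
            eta = X.to_numpy() @ true
            y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logistic(X, y)
            misses += int((np.abs(fit.estimate - true) > 3 * fit.std_error).sum())
        assert misses <= 1

    def test_separation_is_flagged(self):
        X = pd.DataFrame({"intercept": [1.0] * 6, "x": [-3, -2, -1, 1, 2, 3.0]})
        fit = fit_logistic(X, [0, 0, 0, 1, 1, 1])
        assert fit.separated


class TestScorePermutation:
    def test_detects_a_strong_association(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = (rng.random(30) < 1 / (1 + np.exp(-3 * x))).astype(float)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        res = logistic_score_permutation(X, y, "x", n_perm=499, rng=rng)
        assert res["p_value"] < 0.05

    def test_independent_covariate_is_not_flagged(self):
        rng = np.random.default_rng(4)
        y = (rng.random(30) < 0.5).astype(float)
        X = pd.DataFrame({"intercept": 1.0, "x": rng.normal(size=30)})
        res = logistic_score_permutation(X, y, "x", n_perm=499, rng=rng)
        assert res["p_value"] > 0.05

    def test_constant_outcome_is_degenerate(self):
        X = pd.DataFrame({"intercept": [1.0] * 5, "x": np.arange(5.0)})
        res = logistic_score_permutation(X, [1, 1, 1, 1, 1], "x")
        assert np.isnan(res["p_value"])


class TestPCA:
    def test_two_perfectly_correlated_variables(self):
        t = np.arange(10.0)
        res = pca_standardized(pd.DataFrame({"a": t, "b": 3 * t + 1}))
        assert res.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-12)
        assert abs(res.loadings[0, 0]) == pytest.approx(abs(res.loadings[1, 0]))
        assert res.loadings[:, 0].max() > 0  # sign convention

    def test_uncorrelated_limit_has_unit_eigenvalues(self, rng):
        df = pd.DataFrame(rng.normal(size=(4000, 3)), columns=list("abc"))
        res = pca_standardized(df)
        assert np.allclose(res.eigenvalues, 1.0, atol=0.15)

    def test_reconstruction_and_spectral_identities(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)) @ rng.normal(size=(5, 5)))
        df.columns = [f"v{i}" for i in range(5)]
        res = pca_standardized(df)
        z = (df - df.mean()) / df.std(ddof=1)
        assert np.allclose(res.scores @ res.loadings.T, z.to_numpy(), atol=1e-10)
        assert res.eigenvalues.sum() == pytest.approx(5.0)
        assert res.proportion.sum() == pytest.approx(1.0)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-10)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_zero_variance_variable_is_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [7.0, 7.0, 7.0]})
        with pytest.raises(ValueError, match="flat"):
            pca_standardized(df)

    def test_listwise_deletion_is_reported(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        df.loc[0, "a"] = np.nan
        assert pca_standardized(df).n_dropped_rows == 1


class TestGroupSummary:
    def test_constant_group(self):
        s = group_summary([3.9] * 14)
        assert (s["median"], s["min"], s["max"]) == (3.9, 3.9, 3.9)

    def test_single_value(self):
        s = group_summary([2.5])
        assert s["median"] == s["min"] == s["max"] == s["mean"] == 2.5

    def test_matches_sorting_oracle(self, rng):
        v = rng.normal(size=31)
        s = group_summary(v)
        ordered = np.sort(v)
        assert s["min"] == ordered[0] and s["max"] == ordered[-1]
        assert s["median"] == ordered[15]
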