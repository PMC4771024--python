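"""Proportional-odds fitting, Wald inference, assumption checks, indices."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import seqmorph as sm
from seqmorph import ordinal_inference as oi
from seqmorph.errors import ValidationError

# 12-row toy dataset: 3 outcome categories, one binary predictor
TOY_Y = np.array([0, 0, 0, 1, 1, 2, 2, 2, 1, 0, 2, 1])
TOY_X = np.array([0, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1, 0], dtype=float)[:, None]


def toy_loglik(params, y=TOY_Y, x=TOY_X[:, 0]):
    """Independent cumulative-logit log-likelihood for the toy data."""
    t1, t2, b = params
    if t2 <= t1:
        return -np.inf
    def cdf(a):
        return 1.0 / (1.0 + np.exp(-a))
    ll = 0.0
    for yi, xi in zip(y, x):
        cum = [0.0, cdf(t1 - b * xi), cdf(t2 - b * xi), 1.0]
        p = cum[yi + 1] - cum[yi]
        ll += np.log(max(p, 1e-300))
    return ll


class TestProportionalOddsFit:
    def test_matches_brute_force_maximization(self):
        """Newton fit attains the numerically maximized toy likelihood."""
        fit = oi.fit_proportional_odds(TOY_Y, TOY_X)
        res = optimize.minimize(
            lambda p: -toy_loglik(p), x0=[-0.5, 0.5, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert fit.loglik >= -res.fun - 1e-6  # never below the oracle optimum
        np.testing.assert_allclose(
            np.r_[fit.thresholds, fit.slopes], res.x, atol=1e-4
        )

    def test_never_below_coarse_grid(self):
        """Fitted log-likelihood dominates every point of a parameter grid."""
        fit = oi.fit_proportional_odds(TOY_Y, TOY_X)
        grid = np.linspace(-2, 2, 9)
        best = max(
            toy_loglik((t1, t2, b))
            for t1 in grid for t2 in grid for b in grid if t2 > t1
        )
        assert fit.loglik >= best - 1e-9

    def test_binary_outcome_reduces_to_logistic(self, rng):
        import statsmodels.api as smapi

        x = rng.normal(size=(80, 2))
        y = (x @ [1.0, -0.6] + rng.logistic(size=80) > 0).astype(int)
        fit = oi.fit_proportional_odds(y, x)
        ref = smapi.Logit(y, np.column_stack([np.ones(80), x])).fit(disp=False)
        np.testing.assert_allclose(fit.slopes, ref.params[1:], atol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.cov))[1:], ref.bse[1:], atol=1e-6
        )

    def test_cross_check_against_statsmodels_ordered_model(self, rng):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        x = rng.normal(size=(100, 2))
        u = x @ [0.8, -0.5] + rng.logistic(size=100)
        y = np.digitize(u, [-1, 0, 1.2])
        fit = oi.fit_proportional_odds(y, x)
        ref = OrderedModel(y, x, distr="logit").fit(method="bfgs", disp=False)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_single_category_raises(self):
        with pytest.raises(ValidationError, match="single"):
            oi.fit_proportional_odds(np.ones(10), np.arange(10.0)[:, None])

    def test_rank_deficient_raises(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        y = np.r_[np.zeros(5), np.ones(5)]
        with pytest.raises(ValidationError, match="rank"):
            oi.fit_proportional_odds(y, x)

    def test_predictor_shift_invariance(self, rng):
        """Adding a constant to predictors shifts thresholds only."""
        x = rng.normal(size=(90, 1))
        u = 0.9 * x[:, 0] + rng.logistic(size=90)
        y = np.digitize(u, [-0.5, 0.8])
        f0 = oi.fit_proportional_odds(y, x)
        f1 = oi.fit_proportional_odds(y, x + 3.7)
        np.testing.assert_allclose(f0.slopes, f1.slopes, atol=1e-8)
        np.testing.assert_allclose(
            f1.thresholds - f0.thresholds, 3.7 * f0.slopes[0], atol=1e-6
        )
        w0, w1 = oi.wald_omnibus(f0)[0], oi.wald_omnibus(f1)[0]
        assert w0 == pytest.approx(w1, abs=1e-6)

    def test_singleton_clusters_match_plain_fit(self, rng):
        x = rng.normal(size=(60, 1))
        y = np.digitize(x[:, 0] + rng.logistic(size=60), [-1, 1])
        plain = oi.fit_proportional_odds(y, x)
        robust = oi.fit_proportional_odds(y, x, cluster_ids=np.arange(60))
        np.testing.assert_allclose(plain.params, robust.params, atol=1e-12)
        assert robust.cov_robust is not None


class TestWaldAndOddsRatios:
    def _toy_fit(self):
        return oi.fit_proportional_odds(TOY_Y, TOY_X)

    def test_zero_coefficients_give_zero_chi2(self):
        fit = self._toy_fit()
        fit.slopes = np.zeros_like(fit.slopes)
        chi2, df, p = oi.wald_omnibus(fit)
        assert chi2 == 0.0 and p == 1.0

    def test_single_df_block_equals_squared_z(self):
        fit = self._toy_fit()
        chi2, df, _ = oi.wald_omnibus(fit, which=[0])
        se = np.sqrt(fit.slope_cov[0, 0])
        assert df == 1
        assert chi2 == pytest.approx((fit.slopes[0] / se) ** 2, abs=1e-10)

    def test_omnibus_matches_explicit_matrix_algebra(self, rng):
        x = rng.normal(size=(120, 2))
        y = np.digitize(x @ [0.7, -0.4] + rng.logistic(size=120), [-1, 1])
        fit = oi.fit_proportional_odds(y, x)
        chi2, df, p = oi.wald_omnibus(fit)
        b = fit.slopes
        oracle = float(b @ np.linalg.inv(fit.slope_cov) @ b)
        assert df == 2
        assert chi2 == pytest.approx(oracle, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(oracle, 2), rel=1e-10)

    def test_odds_ratio_hand_computation(self):
        fit = self._toy_fit()
        or_, lo, hi = oi.odds_ratio_ci(fit, [1.0])
        se = np.sqrt(fit.slope_cov[0, 0])
        z = stats.norm.ppf(0.975)
        assert or_ == pytest.approx(np.exp(fit.slopes[0]), rel=1e-12)
        assert lo == pytest.approx(np.exp(fit.slopes[0] - z * se), rel=1e-10)
        assert hi == pytest.approx(np.exp(fit.slopes[0] + z * se), rel=1e-10)

    def test_odds_ratio_reciprocity(self):
        fit = self._toy_fit()
        or_f, lo_f, hi_f = oi.odds_ratio_ci(fit, [1.0])
        or_r, lo_r, hi_r = oi.odds_ratio_ci(fit, [-1.0])
        assert or_f * or_r == pytest.approx(1.0, rel=1e-12)
        assert lo_f * hi_r == pytest.approx(1.0, rel=1e-10)
        assert hi_f * lo_r == pytest.approx(1.0, rel=1e-10)

    def test_zero_contrast_gives_unit_or_symmetric_ci(self):
        fit = self._toy_fit()
        fit.slopes = np.zeros_like(fit.slopes)
        or_, lo, hi = oi.odds_ratio_ci(fit, [1.0])
        assert or_ == 1.0
        assert np.log(lo) == pytest.approx(-np.log(hi), abs=1e-12)

    def test_raising_high_ratings_never_lowers_high_vs_low_or(self, cohort18):
        ratings = sm.simulate_ratings(cohort18, seed=77)
        _, table0 = oi.fit_group_rmolr(ratings, "speech", aggregated=False)
        bumped = ratings.copy()
        mask = bumped["condition"] == "high"
        bumped.loc[mask, "rating"] = np.minimum(bumped.loc[mask, "rating"] + 1, 7)
        _, table1 = oi.fit_group_rmolr(bumped, "speech", aggregated=False)
        or0 = table0.set_index("contrast").loc["high_vs_low", "odds_ratio"]
        or1 = table1.set_index("contrast").loc["high_vs_low", "odds_ratio"]
        assert or1 >= or0 - 1e-9


class TestParallelLines:
    def test_df_formula_and_nonnegativity(self, cohort18):
        ratings = sm.simulate_ratings(cohort18, seed=55)
        speech = ratings[ratings["category"] == "speech"]
        X = oi.condition_dummies(speech["condition"])
        J = speech["rating"].nunique()
        chi2, df, p = oi.parallel_lines_test(speech["rating"].to_numpy(), X)
        assert df == 2 * (J - 2)
        assert chi2 >= 0.0
        assert 0.0 <= p <= 1.0

    def test_j_below_three_raises(self):
        y = np.r_[np.zeros(6), np.ones(6)]
        X = oi.condition_dummies(["low"] * 4 + ["mid"] * 4 + ["high"] * 4)
        with pytest.raises(ValidationError, match="J < 3"):
            oi.parallel_lines_test(y, X)

    def test_non_categorical_design_rejected(self, rng):
        y = np.digitize(rng.normal(size=30), [-0.5, 0.5])
        with pytest.raises(ValidationError, match="categorical"):
            oi.parallel_lines_test(y, rng.normal(size=(30, 1)))

    def test_size_near_nominal_under_proportional_odds(self):
        """Under the proportional-odds generative model the test rejects at
        about the nominal 5% rate."""
        rejections = 0
        n_reps = 200
        rng = np.random.default_rng(2024)
        conditions = np.repeat(["low", "mid", "high"], 30)
        z = np.repeat([0.0, 1.0, 2.0], 30)
        X = oi.condition_dummies(conditions)
        cuts = np.array([-1.0, 0.0, 1.0, 2.0])
        for _ in range(n_reps):
            u = 0.8 * z + rng.logistic(size=z.size)
            y = np.searchsorted(cuts, u)
            try:
                _, _, p = oi.parallel_lines_test(y, X)
            except ValidationError:  # J<3 draw, extremely rare
                continue
            rejections += p < 0.05
        rate = rejections / n_reps
        sd = np.sqrt(0.05 * 0.95 / n_reps)
        assert rate <= 0.05 + 3 * sd
        assert rate >= 0.05 - 3 * sd


class TestCollinearity:
    def test_orthogonal_predictors(self):
        X = np.column_stack([np.r_[np.ones(4), -np.ones(4)],
                             np.r_[np.ones(2), -np.ones(2), np.ones(2), -np.ones(2)]])
        out = oi.collinearity_diagnostics(X)
        np.testing.assert_allclose(out["vif"], 1.0, atol=1e-12)
        np.testing.assert_allclose(out["tolerance"], 1.0, atol=1e-12)

    def test_duplicated_predictor_flagged(self):
        x = np.arange(10.0)
        out = oi.collinearity_diagnostics(np.column_stack([x, x]))
        assert np.isinf(out["vif"]).all()

    def test_balanced_three_group_dummies_closed_form(self):
        """Two balanced dummies for 3 equal groups: R^2 = 1/4, VIF = 4/3."""
        X = oi.condition_dummies(np.repeat(["low", "mid", "high"], 6))
        out = oi.collinearity_diagnostics(X)
        np.testing.assert_allclose(out["vif"], 4.0 / 3.0, atol=1e-12)
        np.testing.assert_allclose(out["tolerance"], 0.75, atol=1e-12)


class TestSensitivityIndex:
    def test_null_indices_near_chi2_median(self, make_null_ratings):
        """With no condition effect the per-subject index follows chi2(2):
        the median over null subjects sits near 2*ln2 = 1.386."""
        values = []
        for s in range(8):
            _, ratings = make_null_ratings(18, seed=700 + s)
            idx = sm.sensitivity_indices(ratings)
            values.extend(idx.loc[idx["valid"], "wald_chi2"])
        med = float(np.median(values))
        assert 0.9 <= med <= 2.0

    def test_perfectly_ordered_ratings_flagged_invalid(self):
        df = pd.DataFrame(
            {
                "subject_id": "s1",
                "condition": np.repeat(["low", "mid", "high"], 10),
                "rating": np.repeat([1, 4, 7], 10),
            }
        )
        out = sm.subject_sensitivity(df)
        assert not out.valid
        assert out.message

    def test_higher_discriminability_gives_larger_index(self, cohort18, ratings18):
        from scipy.stats import spearmanr

        idx = sm.sensitivity_indices(ratings18)
        merged = cohort18.merge(idx, on="subject_id")
        merged = merged[merged["valid"]]
        rho = spearmanr(merged["discrimination"], merged["wald_chi2"]).statistic
        assert rho > 0.8


class TestAggregationAndReliability:
    def test_round_half_away_from_zero(self):
        ratings = pd.DataFrame(
            {
                "subject_id": ["s1"] * 2 + ["s2"] * 2,
                "category": "speech",
                "condition": "low",
                "trial_index": [0, 1] * 2,
                "rating": [3, 4, 5, 5],
            }
        )
        out = oi.aggregate_group_table(ratings)
        assert out.loc[out["subject_id"] == "s1", "rating"].item() == 4  # 3.5 -> 4
        assert out.loc[out["subject_id"] == "s2", "rating"].item() == 5

    def test_design_arithmetic(self, ratings18):
        out = oi.aggregate_group_table(ratings18[ratings18["category"] == "speech"])
        assert len(out) == 18 * 3

    def test_duplicated_halves_give_unit_reliability(self, ratings18):
        doubled = pd.concat(
            [
                ratings18.assign(trial_index=ratings18["trial_index"] * 2),
                ratings18.assign(trial_index=ratings18["trial_index"] * 2 + 1),
            ]
        )
        out = oi.split_half_reliability(doubled)
        np.testing.assert_allclose(out["split_half"], 1.0, atol=1e-12)

    def test_independent_halves_average_near_zero(self):
        rng = np.random.default_rng(99)
        coefs = []
        for _ in range(25):
            ratings = pd.DataFrame(
                {
                    "subject_id": np.repeat([f"s{i}" for i in range(12)], 20),
                    "category": "speech",
                    "condition": "low",
                    "trial_index": np.tile(np.arange(20), 12),
                    "rating": rng.integers(1, 8, 240),
                }
            )
            coefs.append(oi.split_half_reliability(ratings)["pearson_r"].item())
        assert abs(float(np.mean(coefs))) < 0.15

    def test_discriminable_raters_are_reliable(self, ratings18):
        out = oi.split_half_reliability(ratings18)
        high = out.set_index("condition").loc["high", "split_half"]
        assert high > 0.8

    def test_too_few_subjects_flagged(self):
        ratings = pd.DataFrame(
            {
                "subject_id": ["s1"] * 4 + ["s2"] * 4,
                "category": "speech",
                "condition": "low",
                "trial_index": list(range(4)) * 2,
                "rating": [1, 2, 3, 4] * 2,
            }
        )
        out = oi.split_half_reliability(ratings)
        assert not out["valid"].item()


class TestNormalityCheck:
    def test_size_near_nominal_for_gaussian(self):
        rng = np.random.default_rng(31)
        rejections = sum(
            oi.normality_check(rng.normal(size=18))[1] < 0.05 for _ in range(300)
        )
        rate = rejections / 300
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 300)

    def test_skewed_samples_detected(self):
        rng = np.random.default_rng(32)
        rejections = sum(
            oi.normality_check(rng.exponential(size=30) ** 2)[1] < 0.05
            for _ in range(100)
        )
        assert rejections / 100 > 0.8

    def test_constant_input_raises(self):
        with pytest.raises(ValidationError, match="constant"):
            oi.normality_check(np.ones(18))
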