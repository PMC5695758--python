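"""Three-level mixed models: estimates, ICCs, stratified and per-survey slopes."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hazshift.multilevel_models import (
    blup_survey_slopes,
    compute_iccs,
    fit_stratified,
    fit_three_level,
    predict_at,
    survey_fixed_effects_slopes,
    with_derived_strata,
)
from hazshift.synthetic_data import generate_linear_units


@pytest.fixture(scope="module")
def noisy_units():
    return generate_linear_units(seed=3)


@pytest.fixture(scope="module")
def noisy_fit(noisy_units):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_three_level(noisy_units, "sd")


def exact_units(beta0=2.10, beta1=-0.20, n_surveys=6):
    return generate_linear_units(
        n_countries=3,
        surveys_per_country=n_surveys // 3,
        beta0=beta0,
        beta1=beta1,
        sd_country=0.0,
        sd_survey_intercept=0.0,
        sd_survey_slope=0.0,
        sd_residual=0.0,
        x_jitter=0.0,
        seed=0,
    )


class TestFitThreeLevel:
    def test_exact_linear_data_recovered_exactly(self):
        fit = fit_three_level(exact_units(), "sd")
        assert fit.slope == pytest.approx(-0.20, abs=1e-8)
        assert fit.intercept == pytest.approx(2.10, abs=1e-8)
        for v in (fit.var_country, fit.var_survey_intercept, fit.var_survey_slope, fit.var_residual):
            assert v == pytest.approx(0.0, abs=1e-6)

    def test_estimates_close_to_truth_on_noisy_data(self, noisy_fit):
        assert noisy_fit.slope == pytest.approx(-0.20, abs=0.03)
        assert noisy_fit.intercept == pytest.approx(2.10, abs=0.08)
        assert noisy_fit.converged

    def test_variance_components_recovered(self, noisy_fit):
        # generating values: country 0.01, survey intercept 0.01, slope 0.0025, resid 0.01
        assert noisy_fit.var_residual == pytest.approx(0.01, rel=0.3)
        assert noisy_fit.var_survey_slope == pytest.approx(0.0025, rel=0.8)

    def test_unit_order_invariance(self, noisy_units):
        shuffled = noisy_units.sample(frac=1.0, random_state=1).reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_three_level(noisy_units, "sd")
            b = fit_three_level(shuffled, "sd")
        assert a.slope == pytest.approx(b.slope, abs=1e-6)
        assert a.var_residual == pytest.approx(b.var_residual, rel=1e-4)

    def test_sign_reversal_convention(self, noisy_units):
        """Negating the unit means must exactly negate the fitted slope."""
        flipped = noisy_units.assign(mean=-noisy_units["mean"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_three_level(noisy_units, "sd")
            b = fit_three_level(flipped, "sd")
        assert a.slope == pytest.approx(-b.slope, abs=1e-6)

    def test_requires_two_surveys(self):
        one = generate_linear_units(n_countries=1, surveys_per_country=1, seed=0)
        with pytest.raises(ValueError):
            fit_three_level(one, "sd")


class TestPredictAt:
    @pytest.mark.parametrize(
        "intercept,slope,mean_haz,expected",
        [
            (2.10, -0.20, -2.0, 1.70),
            (-0.046, -0.98, -2.0, -2.006),
            (3.29, -0.28, -2.0, 2.73),
            (3.40, -0.31, -2.0, 2.78),
        ],
    )
    def test_printed_coefficient_arithmetic(self, intercept, slope, mean_haz, expected):
        assert predict_at((intercept, slope), mean_haz) == pytest.approx(expected, abs=1e-9)

    def test_prediction_at_zero_is_intercept(self, noisy_fit):
        assert predict_at(noisy_fit, 0.0) == noisy_fit.intercept

    def test_ci_contains_point_and_shrinks_at_zero(self, noisy_fit):
        val, (lo, hi) = predict_at(noisy_fit, -2.0, with_ci=True)
        assert lo < val < hi


class TestICCs:
    @pytest.mark.parametrize(
        "vc,vs,vr,expected",
        [
            (0.0, 0.0, 1.0, (0.0, 0.0)),
            (2.0, 3.0, 0.0, (0.4, 1.0)),
            (1.0, 3.0, 1.0, (0.2, 0.8)),
        ],
    )
    def test_ratio_arithmetic(self, vc, vs, vr, expected):
        assert compute_iccs(vc, vs, vr) == pytest.approx(expected)

    def test_total_zero_flagged_missing(self):
        icc_c, icc_s = compute_iccs(0.0, 0.0, 0.0)
        assert np.isnan(icc_c) and np.isnan(icc_s)

    def test_ordering_invariant_on_fit(self, noisy_fit):
        assert 0.0 <= noisy_fit.icc_country <= noisy_fit.icc_survey_in_country <= 1.0


class TestStratified:
    def test_single_stratum_equals_unstratified(self, noisy_units, noisy_fit):
        units = noisy_units.assign(onegroup="all")
        st = fit_stratified(units, "sd", "onegroup")
        assert len(st) == 1
        assert st["slope"].iloc[0] == pytest.approx(noisy_fit.slope, abs=0.005)

    def test_two_strata_recovery(self):
        a = generate_linear_units(n_countries=10, surveys_per_country=4, beta1=-0.1, seed=10)
        b = generate_linear_units(n_countries=10, surveys_per_country=4, beta1=-0.3, seed=11)
        b = b.assign(
            survey_id="B" + b["survey_id"], country_id="B" + b["country_id"]
        )
        units = pd.concat([a.assign(grp="A"), b.assign(grp="B")], ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = fit_stratified(units, "sd", "grp").set_index("stratum")
        assert st.loc["A", "ci_low"] <= -0.1 <= st.loc["A", "ci_high"]
        assert st.loc["B", "ci_low"] <= -0.3 <= st.loc["B", "ci_high"]

    def test_stratum_label_invariance(self, noisy_units):
        units = noisy_units.assign(grp=np.where(noisy_units["country_id"] < "C012", "x", "y"))
        relabeled = units.assign(grp=units["grp"].map({"x": "uu", "y": "vv"}))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_stratified(units, "sd", "grp").sort_values("stratum")["slope"].to_numpy()
            b = fit_stratified(relabeled, "sd", "grp").sort_values("stratum")["slope"].to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_small_stratum_flagged_excluded(self, noisy_units):
        grp = np.where(noisy_units["survey_id"] == "C000-S0", "tiny", "rest")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st = fit_stratified(noisy_units.assign(grp=grp), "sd", "grp").set_index("stratum")
        assert not st.loc["tiny", "included"]
        assert np.isnan(st.loc["tiny", "slope"])

    def test_derived_strata_columns(self, medium_units):
        out = with_derived_strata(medium_units)
        assert set(out["size_class"].unique()) <= {"small", "medium", "large"}
        assert set(out["baseline_tertile"].unique()) <= {"low", "middle", "high"}
        assert out["year_period"].notna().all()


class TestPerSurveySlopes:
    def test_exact_line_zero_width_ci(self):
        x = np.linspace(0, 2, 8)
        units = pd.DataFrame(
            {
                "survey_id": "s0", "country_id": "c0",
                "mean": -x, "sd": 1.0 + 0.04 * x,
            }
        )
        out = survey_fixed_effects_slopes(units, "sd").iloc[0]
        assert out["slope"] == pytest.approx(0.04, abs=1e-12)
        assert out["ci_high"] - out["ci_low"] == pytest.approx(0.0, abs=1e-9)

    def test_no_predictor_variation_flagged(self):
        units = pd.DataFrame(
            {"survey_id": "s0", "country_id": "c0", "mean": [-1.0] * 5, "sd": np.arange(5.0)}
        )
        out = survey_fixed_effects_slopes(units, "sd").iloc[0]
        assert not out["identified"] and np.isnan(out["slope"])

    def test_opposite_slopes_sign_recovery(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = np.linspace(0, 2, 12)
            units = pd.DataFrame(
                {
                    "survey_id": np.repeat(["a", "b"], 12),
                    "country_id": "c0",
                    "mean": np.tile(-x, 2),
                    "sd": np.concatenate(
                        [1 + 0.2 * x + r.normal(0, 0.05, 12), 1 - 0.2 * x + r.normal(0, 0.05, 12)]
                    ),
                }
            )
            out = survey_fixed_effects_slopes(units, "sd").set_index("survey_id")
            hits += (out.loc["a", "slope"] > 0) and (out.loc["b", "slope"] < 0)
        assert hits >= 95


class TestBlups:
    def test_shrinkage_inequality(self, noisy_units, noisy_fit):
        ols = survey_fixed_effects_slopes(noisy_units, "sd")
        blups = blup_survey_slopes(noisy_fit)
        assert blups["blup_slope"].std(ddof=1) <= ols["slope"].std(ddof=1)

    def test_degenerate_random_slope_gives_fixed_slope(self):
        # exact linear data: the random-slope variance estimates to ~0,
        # so every survey's BLUP shrinks fully to the fixed slope
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_three_level(exact_units(), "sd")
        assert fit.var_survey_slope == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.blup_slopes, fit.slope, atol=1e-6)

    def test_blups_cover_every_survey(self, noisy_units, noisy_fit):
        assert set(noisy_fit.blup_slopes.index) == set(noisy_units["survey_id"])
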