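"""Banding, plausibility filtering and weighted-parameter estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hazshift.distribution_params import (
    BandingConfig,
    assign_age_band,
    build_survey_age_units,
    filter_plausible,
    weighted_params,
    weighted_quantile,
)


def replication_oracle(values, int_weights):
    """Unweighted estimators on the weight-replicated sample."""
    expanded = np.repeat(np.asarray(values, float), np.asarray(int_weights, int))
    return (
        expanded.mean(),
        np.percentile(expanded, 50),
        expanded.std(ddof=0),
        np.percentile(expanded, 5),
        np.percentile(expanded, 95),
    )


class TestAgeBands:
    @pytest.mark.parametrize(
        "age,expected",
        [(0, 0), (91, 0), (92, 1), (182, 1), (183, 2), (1095, 11), (1096, -1), (-1, -1)],
    )
    def test_band_boundaries_91_3_days(self, age, expected):
        assert assign_age_band(age) == expected

    def test_vectorised_matches_scalar(self):
        ages = np.arange(0, 1200, 7)
        bands = assign_age_band(ages)
        assert list(bands) == [assign_age_band(int(a)) for a in ages]

    def test_12_bands_cover_0_to_36_months(self):
        bands = assign_age_band(np.arange(0, 1096))
        in_range = bands[bands >= 0]
        assert set(in_range) == set(range(12))
        # only the sliver above 12 * 91.3 = 1095.6 days is out of range
        assert (bands == -1).sum() == 0  # integer days: 1095 < 1095.6

    def test_alternate_band_widths(self):
        cfg_1m = BandingConfig(band_width_days=30.44, n_bands=36)
        cfg_6m = BandingConfig(band_width_days=182.6, n_bands=6)
        assert assign_age_band(1095, cfg_1m) == 35
        assert assign_age_band(1095, cfg_6m) == 5


class TestPlausibilityFilter:
    def test_default_limit_9(self):
        df = pd.DataFrame({"haz": [-9.5, 0.0, 9.5]})
        kept, excluded = filter_plausible(df, 9)
        assert list(kept["haz"]) == [0.0]
        assert excluded == 2

    def test_sensitivity_limit_6(self):
        df = pd.DataFrame({"haz": [-6.5, -5.9]})
        kept, _ = filter_plausible(df, 6)
        assert list(kept["haz"]) == [-5.9]

    def test_empty_input(self):
        df = pd.DataFrame({"haz": []})
        kept, excluded = filter_plausible(df, 9)
        assert len(kept) == 0 and excluded == 0


class TestWeightedParams:
    def test_single_value_degenerate(self):
        p = weighted_params([2.5], [7.0])
        assert p.mean == p.median == p.p5 == p.p95 == 2.5
        assert p.sd == 0.0

    def test_unit_weights_reduce_to_unweighted(self, rng):
        x = rng.normal(size=101)
        p = weighted_params(x, np.ones_like(x))
        assert p.mean == pytest.approx(x.mean(), abs=1e-12)
        assert p.sd == pytest.approx(x.std(ddof=0), abs=1e-12)
        assert p.median == pytest.approx(np.percentile(x, 50), abs=1e-12)
        assert p.p5 == pytest.approx(np.percentile(x, 5), abs=1e-12)
        assert p.p95 == pytest.approx(np.percentile(x, 95), abs=1e-12)

    def test_equal_weights_mean_sd_scale_invariant(self, rng):
        x = rng.normal(size=50)
        a = weighted_params(x, np.full(50, 3.7))
        assert a.mean == pytest.approx(x.mean(), abs=1e-12)
        assert a.sd == pytest.approx(x.std(ddof=0), abs=1e-12)

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-9, 9, allow_nan=False, width=32),
                st.integers(1, 20),
            ),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_integer_weight_replication_oracle(self, data):
        x = np.array([v for v, _ in data], dtype=float)
        w = np.array([c for _, c in data], dtype=float)
        mean, med, sd, p5, p95 = replication_oracle(x, w)
        p = weighted_params(x, w)
        assert p.mean == pytest.approx(mean, abs=1e-12)
        assert p.sd == pytest.approx(sd, abs=1e-12)
        assert p.median == pytest.approx(med, abs=1e-9)
        assert p.p5 == pytest.approx(p5, abs=1e-9)
        assert p.p95 == pytest.approx(p95, abs=1e-9)

    def test_spec_two_point_case(self):
        # values {0, 10} with weights {19, 1}: p5 sits inside the heavy atom
        assert weighted_quantile([0, 10], [19, 1], 0.05)[0] == pytest.approx(0.0, abs=1e-12)
        assert weighted_params([0, 10], [19, 1]).mean == pytest.approx(0.5)

    @given(
        c=st.floats(0.1, 10, allow_nan=False),
        shift=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_and_shift_equivariance(self, c, shift, seed):
        r = np.random.default_rng(seed)
        x = r.normal(size=40)
        w = r.uniform(0.5, 2.0, size=40)
        base = weighted_params(x, w)
        scaled = weighted_params(c * x, w)
        assert scaled.sd == pytest.approx(c * base.sd, rel=1e-9, abs=1e-12)
        assert scaled.p5 == pytest.approx(c * base.p5, rel=1e-9, abs=1e-12)
        shifted = weighted_params(x + shift, w)
        assert shifted.mean == pytest.approx(base.mean + shift, abs=1e-9)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-12)
        assert (shifted.p95 - shifted.mean) == pytest.approx(base.p95 - base.mean, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_params([], [])
        with pytest.raises(ValueError):
            weighted_params([1.0], [0.0])

    def test_large_gaussian_band_tail_distances(self):
        # dp5 and dp95 both approach the normal 1.645 at n = 100,000
        x = np.random.default_rng(99).standard_normal(100_000)
        p = weighted_params(x, np.ones_like(x))
        assert abs((p.mean - p.p5) - 1.645) < 0.03
        assert abs((p.p95 - p.mean) - 1.645) < 0.03


class TestSurveyAgeUnits:
    def test_only_populated_bands_get_units(self):
        records = pd.DataFrame(
            {
                "country_id": ["A"] * 4,
                "survey_id": ["A-S0"] * 4,
                "survey_year": [2000] * 4,
                "age_days": [10, 20, 500, 510],  # bands 0 and 5
                "haz": [0.0, 1.0, -1.0, -2.0],
                "weight": [1.0] * 4,
            }
        )
        meta = pd.DataFrame(
            {
                "survey_id": ["A-S0"], "country_id": ["A"], "survey_year": [2000],
                "region": ["r"], "income_class": ["i"], "n_children": [4],
                "baseline_mean_haz": [0.5],
            }
        )
        units = build_survey_age_units(records, meta)
        assert sorted(units["band_index"]) == [0, 5]

    def test_single_child_unit_degenerate(self):
        records = pd.DataFrame(
            {
                "country_id": ["A"], "survey_id": ["A-S0"], "survey_year": [2000],
                "age_days": [100], "haz": [-1.3], "weight": [2.0],
            }
        )
        meta = pd.DataFrame(
            {
                "survey_id": ["A-S0"], "country_id": ["A"], "survey_year": [2000],
                "region": ["r"], "income_class": ["i"], "n_children": [1],
                "baseline_mean_haz": [np.nan],
            }
        )
        u = build_survey_age_units(records, meta).iloc[0]
        assert u["sd"] == 0.0 and u["p5"] == u["p95"] == u["mean"] == -1.3

    def test_missing_meta_is_referential_error(self, small_dataset):
        records, meta = small_dataset
        with pytest.raises(KeyError):
            build_survey_age_units(records, meta.iloc[:2])

    def test_unit_invariants(self, small_units):
        u = small_units
        assert (u["p5"] <= u["median"] + 1e-12).all()
        assert (u["median"] <= u["p95"] + 1e-12).all()
        np.testing.assert_allclose(u["dp5"] + u["dp95"], u["p95"] - u["p5"], atol=1e-12)
        assert (u["sd"] >= 0).all()
        assert (u["n"] >= 1).all()

    def test_exclusion_accounting(self, small_dataset):
        records, meta = small_dataset
        records = records.copy()
        records.loc[records.index[:3], "haz"] = 12.0  # implausible
        units = build_survey_age_units(records, meta)
        a = units.attrs
        assert a["n_excluded_plausibility"] == 3
        assert a["n_records_in"] == a["n_records_banded"] + 3 + a["n_excluded_age_range"]
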