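"""Synthetic DHS-like multi-survey child anthropometry generator.

Real DHS microdata are access-restricted, so analyses of HAZ distributions
across surveys need a stand-in with the same hierarchical structure:
countries containing surveys containing children, with probability
sampling weights. This module generates such datasets with configurable
age trajectories for the true mean HAZ, the true biological SD, and an
age-specific measurement-error SD, so that every downstream stage
(banding, weighted distribution parameters, pooled summaries, multilevel
models) can be exercised and validated against known truth.

Defaults emulate the scale of the DHS compilation analysed here:
64 countries, 179 surveys, per-survey child counts with median ~3159
(range 351-27352), ages 0-36 months, a mean HAZ that declines from about
-0.4 at birth to about -2 by 36 months, and measurement error that is
larger in early infancy than in toddlers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from hazshift.curves import CurveSpec, curve_from_spec, validate_nonnegative
from hazshift.errors import ConfigurationError

RECORD_COLUMNS = ["country_id", "survey_id", "survey_year", "age_days", "haz", "weight"]
META_COLUMNS = [
    "survey_id",
    "country_id",
    "survey_year",
    "region",
    "income_class",
    "n_children",
    "baseline_mean_haz",
]

#: Categorical survey covariates; proportions mimic the composition of the
#: DHS compilation (region and income are country-level, year is survey-level).
DEFAULT_COVARIATE_SCHEME: dict = {
    "region": {
        "Sub-Saharan Africa": 0.57,
        "Latin America and Caribbean": 0.18,
        "Europe and Central Asia": 0.08,
        "South Asia": 0.08,
        "Middle East and North Africa": 0.06,
        "East Asia and Pacific": 0.03,
    },
    "income_class": {
        "Low income": 0.60,
        "Lower middle income": 0.33,
        "Upper middle income": 0.07,
    },
    "year_period": {
        (1993, 1994): 0.04,
        (1995, 1999): 0.22,
        (2000, 2004): 0.19,
        (2005, 2009): 0.25,
        (2010, 2015): 0.30,
    },
}

#: True mean HAZ trajectory: most faltering happens before 24 months.
DEFAULT_MEAN_HAZ_CURVE: dict = {
    "kind": "piecewise_linear",
    "ages_days": [0.0, 730.0, 1095.0],
    "values": [-0.40, -1.90, -2.00],
}

#: True (biological) HAZ SD, constant with age by default.
DEFAULT_SD_CURVE: dict = {"kind": "constant", "value": 1.2}

#: Measurement-error SD added to the true HAZ, declining with age
#: (age ascertainment and length measurement are noisiest in infancy).
DEFAULT_MEASUREMENT_ERROR_CURVE: dict = {
    "kind": "linear",
    "age0": 0.0,
    "value0": 0.8,
    "age1": 1095.0,
    "value1": 0.2,
}

#: Per-survey child counts: right-skewed like real survey sizes.
DEFAULT_CHILDREN_PER_SURVEY: dict = {
    "kind": "lognormal",
    "median": 3159,
    "iqr": 2495,
    "min": 351,
    "max": 27352,
}

WEIGHT_SCHEMES = ("uniform", "lognormal-dispersed", "lognormal-haz-correlated")


@dataclass
class GeneratorConfig:
    """Configuration of the hierarchical synthetic dataset.

    ``surveys_per_country`` may be an int, a per-country list, or None, in
    which case a fixed allocation is used whose totals match the DHS
    compilation (for 64 countries: 179 surveys, with 25% of countries
    contributing one survey, 20% two, and the rest three or four).
    """

    n_countries: int = 64
    surveys_per_country: Union[int, Sequence[int], None] = None
    children_per_survey: Union[int, Sequence[int], Mapping] = field(
        default_factory=lambda: dict(DEFAULT_CHILDREN_PER_SURVEY)
    )
    age_range_days: tuple[int, int] = (0, 1096)
    mean_haz_curve: CurveSpec = field(default_factory=lambda: dict(DEFAULT_MEAN_HAZ_CURVE))
    sd_curve: CurveSpec = field(default_factory=lambda: dict(DEFAULT_SD_CURVE))
    measurement_error_curve: CurveSpec = field(
        default_factory=lambda: dict(DEFAULT_MEASUREMENT_ERROR_CURVE)
    )
    weight_scheme: str = "lognormal-dispersed"
    weight_dispersion: float = 0.5
    covariate_scheme: Mapping = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SCHEME))
    seed: int = 0

    def validate(self) -> None:
        if self.n_countries < 0:
            raise ConfigurationError("n_countries must be >= 0")
        lo, hi = self.age_range_days
        if not (0 <= lo < hi <= 1096):
            raise ConfigurationError("age_range_days must be within [0, 1096)")
        if self.weight_scheme not in WEIGHT_SCHEMES:
            raise ConfigurationError(f"unknown weight scheme {self.weight_scheme!r}")
        if self.weight_dispersion < 0:
            raise ConfigurationError("weight_dispersion must be >= 0")
        validate_nonnegative(self.sd_curve, (lo, hi), "sd")
        validate_nonnegative(self.measurement_error_curve, (lo, hi), "measurement_error")
        curve_from_spec(self.mean_haz_curve)  # raises on malformed spec


def _default_survey_allocation(n_countries: int, total_target: int | None = None) -> np.ndarray:
    """Fixed per-country survey counts summing to ~(179/64) per country.

    25% of countries get 1 survey, 20% get 2, the remainder get 3 or 4 so
    the total matches ``round(179 * n / 64)`` (exactly 179 for n=64).
    """
    if n_countries == 0:
        return np.zeros(0, dtype=int)
    if total_target is None:
        total_target = round(179 * n_countries / 64)
    n1 = round(0.25 * n_countries)
    n2 = round(0.20 * n_countries)
    k = n_countries - n1 - n2
    counts = [1] * n1 + [2] * n2
    if k > 0:
        rest = total_target - (n1 + 2 * n2)
        fours = min(max(rest - 3 * k, 0), k)
        counts += [4] * fours + [3] * (k - fours)
        # adjust the last entry if rounding left a remainder
        counts[-1] += total_target - sum(counts)
        counts[-1] = max(counts[-1], 1)
    return np.asarray(counts, dtype=int)


def _resolve_children_counts(spec, n_surveys: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, Mapping):
        if spec.get("kind") != "lognormal":
            raise ConfigurationError(f"unknown children_per_survey kind {spec.get('kind')!r}")
        median = float(spec["median"])
        iqr = float(spec["iqr"])
        mu = math.log(median)
        # IQR of lognormal: exp(mu) * 2 sinh(z75 * sigma), z75 = 0.6745
        sigma = math.asinh(iqr / (2.0 * median)) / 0.6745
        draws = rng.lognormal(mu, sigma, size=n_surveys)
        return np.clip(np.round(draws), spec.get("min", 1), spec.get("max", np.inf)).astype(int)
    counts = np.broadcast_to(np.asarray(spec, dtype=int), (n_surveys,)).copy()
    if np.any(counts < 0):
        raise ConfigurationError("children_per_survey must be >= 0")
    return counts


def _sample_categorical(probs: Mapping, size: int, rng: np.random.Generator) -> np.ndarray:
    labels = list(probs.keys())
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=size, p=p)
    return np.asarray([labels[i] for i in idx], dtype=object)


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(tag)]).generate_state(1)[0]) % (2**31)


def generate_multisurvey_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (child-record table, survey-meta table).

    Children are sampled uniformly over the configured age range; each
    child's observed HAZ is ``mean_haz_curve(age) + sd_curve(age) * Z +
    measurement error``. Identical (config, seed) gives identical tables.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_structure, rng_haz = [np.random.default_rng(s) for s in ss.spawn(2)]

    # --- survey structure ---------------------------------------------------
    if config.surveys_per_country is None:
        per_country = _default_survey_allocation(config.n_countries)
    else:
        per_country = np.broadcast_to(
            np.asarray(config.surveys_per_country, dtype=int), (config.n_countries,)
        ).copy()
    if np.any(per_country < 0):
        raise ConfigurationError("surveys_per_country must be >= 0")
    n_surveys = int(per_country.sum())

    country_ids = np.asarray([f"C{i:03d}" for i in range(config.n_countries)], dtype=object)
    survey_country = np.repeat(country_ids, per_country)
    within_idx = np.concatenate([np.arange(k) for k in per_country]) if n_surveys else np.zeros(0, int)
    survey_ids = np.asarray(
        [f"{c}-S{j}" for c, j in zip(survey_country, within_idx)], dtype=object
    )

    scheme = config.covariate_scheme
    region_by_country = _sample_categorical(scheme["region"], config.n_countries, rng_structure)
    income_by_country = _sample_categorical(scheme["income_class"], config.n_countries, rng_structure)
    country_pos = {c: i for i, c in enumerate(country_ids)}
    periods = _sample_categorical(scheme["year_period"], n_surveys, rng_structure)
    years = np.asarray(
        [int(rng_structure.integers(p[0], p[1] + 1)) for p in periods], dtype=int
    ) if n_surveys else np.zeros(0, int)

    counts = _resolve_children_counts(config.children_per_survey, n_surveys, rng_structure)

    # --- children -----------------------------------------------------------
    n_total = int(counts.sum())
    survey_of_child = np.repeat(np.arange(n_surveys), counts)
    lo, hi = config.age_range_days
    ages = rng_haz.integers(lo, hi, size=n_total)
    mean_fn = curve_from_spec(config.mean_haz_curve)
    sd_fn = curve_from_spec(config.sd_curve)
    haz_true = mean_fn(ages) + sd_fn(ages) * rng_haz.standard_normal(n_total)

    records = pd.DataFrame(
        {
            "country_id": survey_country[survey_of_child] if n_total else np.array([], object),
            "survey_id": survey_ids[survey_of_child] if n_total else np.array([], object),
            "survey_year": years[survey_of_child] if n_total else np.array([], int),
            "age_days": ages.astype(int),
            "haz": haz_true,
            "weight": np.ones(n_total),
        },
        columns=RECORD_COLUMNS,
    )
    records = inject_measurement_error(
        records, config.measurement_error_curve, seed=_child_seed(config.seed, 1)
    )
    records = simulate_design_weights(
        records,
        config.weight_scheme,
        seed=_child_seed(config.seed, 2),
        dispersion=config.weight_dispersion,
    )

    # --- survey meta (baseline mean = weighted mean HAZ in the 0-3 month band)
    baseline = np.full(n_surveys, np.nan)
    if n_total:
        in_band0 = records["age_days"].to_numpy() < 91.3
        w = records["weight"].to_numpy()
        h = records["haz"].to_numpy()
        for i in range(n_surveys):
            m = in_band0 & (survey_of_child == i)
            if m.any():
                baseline[i] = np.average(h[m], weights=w[m])
    meta = pd.DataFrame(
        {
            "survey_id": survey_ids,
            "country_id": survey_country,
            "survey_year": years,
            "region": region_by_country[[country_pos[c] for c in survey_country]]
            if n_surveys
            else np.array([], object),
            "income_class": income_by_country[[country_pos[c] for c in survey_country]]
            if n_surveys
            else np.array([], object),
            "n_children": counts,
            "baseline_mean_haz": baseline,
        },
        columns=META_COLUMNS,
    )
    return records, meta


def inject_measurement_error(records: pd.DataFrame, error_curve: CurveSpec, seed: int) -> pd.DataFrame:
    """Add independent zero-mean Gaussian noise with age-specific SD to haz.

    Returns a new table; the input is not modified.
    """
    out = records.copy()
    if len(out) == 0:
        return out
    ages = out["age_days"].to_numpy()
    err_fn = curve_from_spec(error_curve)
    err_sd = err_fn(ages)
    if np.any(err_sd < 0):
        raise ConfigurationError("measurement-error SD must be >= 0 at all ages")
    rng = np.random.default_rng(seed)
    out["haz"] = out["haz"].to_numpy() + err_sd * rng.standard_normal(len(out))
    return out


def simulate_design_weights(
    records: pd.DataFrame, scheme: str, seed: int, dispersion: float = 0.5
) -> pd.DataFrame:
    """Attach positive sampling weights, normalised to mean 1 within survey.

    ``uniform`` gives equal weights. ``lognormal-dispersed`` draws
    log-normal weights independent of HAZ (weighted estimators stay
    unbiased for the configured truth). ``lognormal-haz-correlated`` makes
    log-weights correlate with HAZ (correlation ~0.5 on the log scale) and
    exists only to stress-test weighting code.
    """
    if scheme not in WEIGHT_SCHEMES:
        raise ConfigurationError(f"unknown weight scheme {scheme!r}")
    out = records.copy()
    n = len(out)
    if n == 0:
        return out
    if scheme == "uniform" or dispersion == 0:
        out["weight"] = 1.0
        return out
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    if scheme == "lognormal-haz-correlated":
        haz = out["haz"].to_numpy()
        hstd = (haz - haz.mean()) / (haz.std() or 1.0)
        z = 0.5 * hstd + np.sqrt(1 - 0.25) * z
    w = np.exp(dispersion * z)
    # normalise to mean 1 per survey so weight scale is comparable across surveys
    grp = pd.Series(w, index=out.index).groupby(out["survey_id"]).transform("mean")
    out["weight"] = w / grp.to_numpy()
    return out


def generate_linear_units(
    n_countries: int = 25,
    surveys_per_country: int = 4,
    n_units_per_survey: int = 12,
    outcome: str = "sd",
    beta0: float = 2.10,
    beta1: float = -0.20,
    sd_country: float = 0.1,
    sd_survey_intercept: float = 0.1,
    sd_survey_slope: float = 0.05,
    sd_residual: float = 0.1,
    x_range: tuple[float, float] = (0.0, 2.0),
    x_jitter: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Survey-age units drawn directly from the three-level linear model.

    Bypasses child-level sampling: each unit's predictor x (= -mean HAZ,
    spanning the typical 0-to-2 decline over the age bands) and outcome are
    generated from ``outcome = beta0 + u_country + a_survey +
    (beta1 + b_survey) x + e`` with independent Gaussian effects. Used for
    parameter-recovery validation of the mixed-model stage, where the true
    fixed slope and variance components must be known exactly.
    """
    rng = np.random.default_rng(seed)
    n_surveys = n_countries * surveys_per_country
    u_c = np.repeat(rng.normal(0, sd_country, n_countries), surveys_per_country)
    a_s = rng.normal(0, sd_survey_intercept, n_surveys)
    b_s = rng.normal(0, sd_survey_slope, n_surveys)
    x = np.tile(np.linspace(*x_range, n_units_per_survey), n_surveys)
    x = x + rng.normal(0, x_jitter, x.size)
    y = (
        beta0
        + np.repeat(u_c + a_s, n_units_per_survey)
        + (beta1 + np.repeat(b_s, n_units_per_survey)) * x
        + rng.normal(0, sd_residual, x.size)
    )
    country = np.repeat([f"C{i:03d}" for i in range(n_countries)], surveys_per_country)
    return pd.DataFrame(
        {
            "survey_id": np.repeat([f"{c}-S{j % surveys_per_country}" for j, c in enumerate(country)],
                                   n_units_per_survey),
            "country_id": np.repeat(country, n_units_per_survey),
            "band_index": np.tile(np.arange(n_units_per_survey), n_surveys),
            "mean": -x,
            outcome: y,
        }
    )


def desk_scale_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A small configuration for examples and quick runs.

    Same curve shapes as the full-scale default, but 4 countries x 2
    surveys x ~500 children.
    """
    cfg = GeneratorConfig(
        n_countries=4,
        surveys_per_country=2,
        children_per_survey=500,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
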