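"""Three-level linear mixed models of HAZ distribution parameters.

Outcomes are per-unit distribution parameters (SD, median, dp5, dp95);
the predictor is the sign-reversed unit mean HAZ, x = -mean, so that a
positive slope means the outcome increases as the population mean HAZ
declines. The hierarchy is survey-age units within surveys within
countries: a country random intercept plus survey-level random intercept
and random slope on x, estimated by REML (statsmodels MixedLM, with the
survey-level effects entering as independent variance components).

Also provided: fixed-effects predictions at a given mean HAZ, intraclass
correlation coefficients, stratified (interaction) slope models,
per-survey ordinary-least-squares slopes for forest plots, and shrunken
(BLUP) per-survey slopes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from hazshift.errors import ConvergenceError

OUTCOMES = ("sd", "median", "dp5", "dp95")
PREDICTOR = "x_negmean"
STRATIFIERS = ("region", "income_class", "year_period", "size_class", "baseline_tertile")

_VC_INT = "sv_int"
_VC_SLOPE = "sv_slope"
_SLOPE_KEY = re.compile(r"^sv_slope\[C\(survey_id\)\[(.+)\]:x_negmean\]$")
_INT_KEY = re.compile(r"^sv_int\[C\(survey_id\)\[(.+)\]\]$")


@dataclass
class MultilevelFit:
    outcome: str
    slope: float
    slope_se: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_se: float
    intercept_ci: tuple[float, float]
    var_country: float
    var_survey_intercept: float
    var_survey_slope: float
    var_residual: float
    icc_country: float
    icc_survey_in_country: float
    blup_slopes: pd.Series
    blup_intercepts: pd.Series
    converged: bool
    n_units: int
    n_surveys: int
    n_countries: int
    fit_warnings: list = field(default_factory=list, repr=False)
    result: object = field(default=None, repr=False)

    def summary_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "slope": self.slope,
            "slope_ci_low": self.slope_ci[0],
            "slope_ci_high": self.slope_ci[1],
            "intercept": self.intercept,
            "intercept_ci_low": self.intercept_ci[0],
            "intercept_ci_high": self.intercept_ci[1],
            "icc_country": self.icc_country,
            "icc_survey_in_country": self.icc_survey_in_country,
            "converged": self.converged,
        }


def prepare_model_frame(units: pd.DataFrame, outcome: str) -> pd.DataFrame:
    if outcome not in units.columns:
        raise ValueError(f"outcome {outcome!r} not found in units table")
    df = units[["survey_id", "country_id", "mean", outcome]].copy()
    df[PREDICTOR] = -df["mean"]
    if not np.isfinite(df[outcome].to_numpy()).all():
        raise ValueError(f"outcome {outcome!r} contains non-finite values")
    return df


def compute_iccs(
    var_country: float, var_survey_intercept: float, var_residual: float
) -> tuple[float, float]:
    """Intercept-level variance proportions at predictor value 0.

    icc_country is the share of unit-level variance from country
    clustering; icc_survey_in_country the share from country plus survey
    clustering. With a random slope in the model, variance depends on the
    predictor; the convention here evaluates it at x = 0. Total variance 0
    is undefined and returned as (nan, nan).
    """
    total = var_country + var_survey_intercept + var_residual
    if total <= 0:
        return (float("nan"), float("nan"))
    return (var_country / total, (var_country + var_survey_intercept) / total)


def fit_three_level(
    units: pd.DataFrame,
    outcome: str,
    reml: bool = True,
    random_slope: bool = True,
    icc_from_random_intercepts_only: bool = False,
) -> MultilevelFit:
    """REML fit of outcome ~ x with country and survey random effects.

    The survey random intercept and random slope are modelled as
    independent variance components (MixedLM cannot profile a covariance
    between components nested below the top grouping level). Fixed-effect
    CIs use the normal approximation. Non-convergence is flagged on the
    returned fit rather than raised, as long as estimates exist.
    """
    df = prepare_model_frame(units, outcome)
    if df["survey_id"].nunique() < 2:
        raise ValueError("fit_three_level requires at least 2 surveys")
    vc = {_VC_INT: "0 + C(survey_id)"}
    if random_slope:
        vc[_VC_SLOPE] = f"0 + C(survey_id):{PREDICTOR}"
    model = smf.mixedlm(
        f"{outcome} ~ {PREDICTOR}", df, groups="country_id", re_formula="1", vc_formula=vc
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = model.fit(reml=reml, method="lbfgs", maxiter=200)
        except Exception as exc:  # pragma: no cover - depends on optimizer internals
            raise ConvergenceError(f"mixed model for {outcome!r} failed: {exc}") from exc
    fit_warnings = [str(w.message) for w in caught]

    fe = result.fe_params
    bse = result.bse_fe
    z = stats.norm.ppf(0.975)
    vcomp = dict(zip(model.exog_vc.names, result.vcomp))
    var_country = float(result.cov_re.iloc[0, 0])
    var_sv_int = float(vcomp.get(_VC_INT, 0.0))
    var_sv_slope = float(vcomp.get(_VC_SLOPE, 0.0))
    var_resid = float(result.scale)

    if icc_from_random_intercepts_only and random_slope:
        ri = fit_three_level(units, outcome, reml=reml, random_slope=False)
        icc_c, icc_s = ri.icc_country, ri.icc_survey_in_country
    else:
        icc_c, icc_s = compute_iccs(var_country, var_sv_int, var_resid)

    blup_slopes, blup_intercepts = _extract_blups(result, float(fe[PREDICTOR]), float(fe["Intercept"]))
    # surveys lacking a predicted deviation shrink fully to the fixed effect
    all_surveys = pd.Index(sorted(df["survey_id"].unique()), name="survey_id")
    blup_slopes = blup_slopes.reindex(all_surveys).fillna(float(fe[PREDICTOR]))
    blup_intercepts = blup_intercepts.reindex(all_surveys).fillna(float(fe["Intercept"]))

    return MultilevelFit(
        outcome=outcome,
        slope=float(fe[PREDICTOR]),
        slope_se=float(bse[PREDICTOR]),
        slope_ci=(float(fe[PREDICTOR] - z * bse[PREDICTOR]), float(fe[PREDICTOR] + z * bse[PREDICTOR])),
        intercept=float(fe["Intercept"]),
        intercept_se=float(bse["Intercept"]),
        intercept_ci=(
            float(fe["Intercept"] - z * bse["Intercept"]),
            float(fe["Intercept"] + z * bse["Intercept"]),
        ),
        var_country=var_country,
        var_survey_intercept=var_sv_int,
        var_survey_slope=var_sv_slope,
        var_residual=var_resid,
        icc_country=icc_c,
        icc_survey_in_country=icc_s,
        blup_slopes=blup_slopes,
        blup_intercepts=blup_intercepts,
        converged=bool(result.converged),
        n_units=len(df),
        n_surveys=int(df["survey_id"].nunique()),
        n_countries=int(df["country_id"].nunique()),
        fit_warnings=fit_warnings,
        result=result,
    )


def _extract_blups(result, fixed_slope: float, fixed_intercept: float):
    slopes, intercepts = {}, {}
    for _, effects in result.random_effects.items():
        for key, val in effects.items():
            m = _SLOPE_KEY.match(str(key))
            if m:
                slopes[m.group(1)] = fixed_slope + float(val)
                continue
            m = _INT_KEY.match(str(key))
            if m:
                intercepts[m.group(1)] = fixed_intercept + float(val)
    return (
        pd.Series(slopes, name="blup_slope").sort_index(),
        pd.Series(intercepts, name="blup_intercept").sort_index(),
    )


def blup_survey_slopes(fit: MultilevelFit) -> pd.DataFrame:
    """Per-survey BLUP slopes: fixed slope + predicted random deviation.

    Shrinkage guarantees these have no larger spread than the per-survey
    OLS slopes; with a degenerate (zero) random-slope variance every
    survey's BLUP equals the fixed slope.
    """
    return fit.blup_slopes.rename("blup_slope").rename_axis("survey_id").reset_index()


def predict_at(fit, mean_haz: float, with_ci: bool = False):
    """Fixed-effects prediction of the outcome at a given mean HAZ.

    ``fit`` is a MultilevelFit or an ``(intercept, slope)`` pair; the
    prediction is intercept + slope * (-mean_haz), following the
    sign-reversal convention.
    """
    if hasattr(fit, "intercept"):
        intercept, slope = fit.intercept, fit.slope
        result = fit.result
    else:
        intercept, slope = fit
        result = None
    x = -float(mean_haz)
    value = intercept + slope * x
    if not with_ci:
        return value
    if result is None:
        raise ValueError("CI requires a fitted model, not bare coefficients")
    cov = np.asarray(result.cov_params())[:2, :2]
    var = cov[0, 0] + x**2 * cov[1, 1] + 2 * x * cov[0, 1]
    z = stats.norm.ppf(0.975)
    half = z * np.sqrt(max(var, 0.0))
    return value, (value - half, value + half)


def with_derived_strata(units: pd.DataFrame) -> pd.DataFrame:
    """Add survey-level stratifier columns derived from unit metadata.

    * ``year_period``: calendar bins 1993-94 / 1995-99 / 2000-04 /
      2005-09 / 2010-15 (open-ended outside).
    * ``size_class``: tertiles of survey child count (small/medium/large).
    * ``baseline_tertile``: tertiles of the survey's mean HAZ in the 0-3
      month band (low/middle/high).
    """
    out = units.copy()
    yr = out["survey_year"].astype(int)
    bins = [-np.inf, 1994, 1999, 2004, 2009, np.inf]
    labels = ["1993-94", "1995-99", "2000-04", "2005-09", "2010-15"]
    out["year_period"] = pd.cut(yr, bins=bins, labels=labels).astype(str)
    surveys = out.drop_duplicates("survey_id")
    for src, dst, lab in [
        ("survey_n_children", "size_class", ["small", "medium", "large"]),
        ("baseline_mean_haz", "baseline_tertile", ["low", "middle", "high"]),
    ]:
        if surveys[src].nunique() >= 3:
            tert = pd.qcut(surveys[src], 3, labels=lab, duplicates="drop")
            out[dst] = out["survey_id"].map(dict(zip(surveys["survey_id"], tert.astype(str))))
        else:
            out[dst] = lab[1]
    return out


def fit_stratified(
    units: pd.DataFrame, outcome: str, stratifier: str, reml: bool = True
) -> pd.DataFrame:
    """Stratum-specific slopes from a single interaction model.

    One mixed model with stratum main effects and stratum-by-x
    interactions; the random structure (country intercept, survey
    intercept and slope) is shared across strata. Strata with fewer than
    two surveys are excluded and reported with a flag.
    """
    if stratifier not in units.columns:
        units = with_derived_strata(units)
    if stratifier not in units.columns:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    df = units[["survey_id", "country_id", "mean", outcome, stratifier]].copy()
    df[PREDICTOR] = -df["mean"]
    df = df.rename(columns={stratifier: "stratum"})
    per_stratum_surveys = df.groupby("stratum")["survey_id"].nunique()
    small = per_stratum_surveys[per_stratum_surveys < 2].index.tolist()
    kept = df[~df["stratum"].isin(small)].copy()
    if kept["stratum"].nunique() == 0:
        raise ValueError("no stratum has >= 2 surveys")

    vc = {_VC_INT: "0 + C(survey_id)", _VC_SLOPE: f"0 + C(survey_id):{PREDICTOR}"}
    model = smf.mixedlm(
        f"{outcome} ~ C(stratum) + {PREDICTOR}:C(stratum)",
        kept,
        groups="country_id",
        re_formula="1",
        vc_formula=vc,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml, method="lbfgs", maxiter=200)
    z = stats.norm.ppf(0.975)
    rows = []
    pat = re.compile(rf"^{PREDICTOR}:C\(stratum\)\[(.+)\]$")
    for name, coef in result.fe_params.items():
        m = pat.match(str(name))
        if not m:
            continue
        se = float(result.bse_fe[name])
        rows.append(
            {
                "stratum": m.group(1),
                "n_surveys": int(per_stratum_surveys.get(m.group(1), 0)),
                "slope": float(coef),
                "ci_low": float(coef - z * se),
                "ci_high": float(coef + z * se),
                "included": True,
            }
        )
    for s in small:
        rows.append(
            {"stratum": s, "n_surveys": int(per_stratum_surveys[s]), "slope": np.nan,
             "ci_low": np.nan, "ci_high": np.nan, "included": False}
        )
    out = pd.DataFrame(rows).sort_values("stratum").reset_index(drop=True)
    out.attrs["converged"] = bool(result.converged)
    return out


def survey_fixed_effects_slopes(units: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Per-survey OLS slope of outcome on x = -mean, with 95% CI.

    Equivalent to the fixed-effects model saturated with survey-by-x
    interactions; used for forest plots. Surveys without predictor
    variation get a flagged missing slope; the CI needs at least 3 units
    (residual df >= 1) and collapses to zero width on an exact linear fit.
    """
    df = prepare_model_frame(units, outcome)
    rows = []
    for sid, grp in df.groupby("survey_id", sort=True):
        x = grp[PREDICTOR].to_numpy()
        y = grp[outcome].to_numpy()
        n = len(grp)
        sxx = float(np.sum((x - x.mean()) ** 2))
        if n < 2 or sxx == 0.0:
            rows.append({"survey_id": sid, "n": n, "slope": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "identified": False})
            continue
        slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
        resid = y - (y.mean() + slope * (x - x.mean()))
        if n > 2:
            s2 = float(np.sum(resid**2) / (n - 2))
            se = float(np.sqrt(s2 / sxx))
            tcrit = stats.t.ppf(0.975, n - 2)
            lo, hi = slope - tcrit * se, slope + tcrit * se
        else:
            se, lo, hi = np.nan, np.nan, np.nan
        rows.append({"survey_id": sid, "n": n, "slope": slope, "se": se,
                     "ci_low": lo, "ci_high": hi, "identified": True})
    return pd.DataFrame(rows)


def icc_parametric_bootstrap(
    fit: MultilevelFit, units: pd.DataFrame, n_boot: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Percentile CIs for the ICCs by simulating from the fitted model.

    New outcomes are drawn on the observed design using the REML variance
    components and fixed effects, and the model is refitted to each draw.
    """
    df = prepare_model_frame(units, fit.outcome)
    rng = np.random.default_rng(seed)
    surveys = df["survey_id"].to_numpy()
    countries = df["country_id"].to_numpy()
    x = df[PREDICTOR].to_numpy()
    sv_list = pd.unique(surveys)
    c_list = pd.unique(countries)
    iccs = []
    for _ in range(n_boot):
        u_c = dict(zip(c_list, rng.normal(0, np.sqrt(max(fit.var_country, 0)), len(c_list))))
        a_s = dict(zip(sv_list, rng.normal(0, np.sqrt(max(fit.var_survey_intercept, 0)), len(sv_list))))
        b_s = dict(zip(sv_list, rng.normal(0, np.sqrt(max(fit.var_survey_slope, 0)), len(sv_list))))
        y = (
            fit.intercept
            + fit.slope * x
            + np.vectorize(u_c.get)(countries)
            + np.vectorize(a_s.get)(surveys)
            + np.vectorize(b_s.get)(surveys) * x
            + rng.normal(0, np.sqrt(max(fit.var_residual, 0)), len(df))
        )
        boot_units = units.copy()
        boot_units[fit.outcome] = y
        bf = fit_three_level(boot_units, fit.outcome)
        iccs.append((bf.icc_country, bf.icc_survey_in_country))
    arr = np.asarray(iccs, dtype=float)
    lo, hi = np.nanpercentile(arr, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "icc": ["icc_country", "icc_survey_in_country"],
            "estimate": [fit.icc_country, fit.icc_survey_in_country],
            "ci_low": lo,
            "ci_high": hi,
            "n_boot": n_boot,
        }
    )
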