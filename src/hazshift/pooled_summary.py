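"""Pooled cross-survey summaries of HAZ distribution parameters by age band.

For each age band and each distributional parameter, the pooled estimate
is the unweighted mean over all survey-age units in the band (units are
deliberately not weighted by their child counts: the inference is at the
survey level). The 95% CI accounts for clustering of surveys within
country using cluster-robust (sandwich) standard errors with country as
the cluster; a country-random-intercept alternative is available via
``method="random_intercept"``. The normal critical value is used with at
least 30 country clusters, otherwise t with (clusters - 1) df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from hazshift.distribution_params import PARAM_COLUMNS

NORMAL_CLUSTER_THRESHOLD = 30


@dataclass
class AgeBandSummary:
    band_index: int
    parameter: str
    pooled_mean: float
    ci_low: float
    ci_high: float
    n_units: int
    n_countries: int


def cluster_robust_mean_ci(
    values, clusters, alpha: float = 0.05, method: str = "cluster_robust"
) -> tuple[float, float, float]:
    """Mean of *values* with a CI robust to clustering.

    The sandwich variance of the mean is ``J/(J-1) * sum_j (sum_{i in j}
    e_ij)^2 / n^2`` (the CR1 estimator for an intercept-only regression,
    as computed by statsmodels OLS with ``cov_type="cluster"``).
    """
    y = np.asarray(values, dtype=float)
    codes = pd.factorize(np.asarray(clusters))[0]
    n_clusters = int(codes.max()) + 1
    mean = float(y.mean())
    if method == "random_intercept" and n_clusters > 1 and len(y) > n_clusters:
        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": y, "g": codes})
        try:
            res = smf.mixedlm("y ~ 1", df, groups="g").fit(reml=True, method="lbfgs")
            mean, se = float(res.fe_params.iloc[0]), float(res.bse_fe.iloc[0])
        except np.linalg.LinAlgError:
            # singular random-intercept fit (tiny bands): fall back to sandwich
            return cluster_robust_mean_ci(values, clusters, alpha, "cluster_robust")
    elif n_clusters > 1:
        res = sm.OLS(y, np.ones((len(y), 1))).fit(
            cov_type="cluster", cov_kwds={"groups": codes}
        )
        se = float(res.bse[0])
    else:
        se = float(y.std(ddof=1) / np.sqrt(len(y))) if len(y) > 1 else 0.0
    if np.isnan(se):
        se = 0.0
    if n_clusters >= NORMAL_CLUSTER_THRESHOLD:
        crit = stats.norm.ppf(1 - alpha / 2)
    else:
        crit = stats.t.ppf(1 - alpha / 2, max(n_clusters - 1, 1))
    return mean, mean - crit * se, mean + crit * se


def pool_age_band(
    units: pd.DataFrame,
    parameter: str,
    band_index: int,
    method: str = "cluster_robust",
) -> AgeBandSummary:
    """Pool one parameter over all survey-age units in one age band."""
    if parameter not in PARAM_COLUMNS:
        raise ValueError(f"unknown parameter {parameter!r}; expected one of {PARAM_COLUMNS}")
    sub = units.loc[units["band_index"] == band_index]
    if len(sub) == 0:
        raise ValueError(f"no survey-age units in band {band_index}")
    mean, lo, hi = cluster_robust_mean_ci(
        sub[parameter].to_numpy(), sub["country_id"].to_numpy(), method=method
    )
    return AgeBandSummary(
        band_index=int(band_index),
        parameter=parameter,
        pooled_mean=mean,
        ci_low=lo,
        ci_high=hi,
        n_units=len(sub),
        n_countries=int(sub["country_id"].nunique()),
    )


def summarize_all_bands(
    units: pd.DataFrame,
    parameters: tuple[str, ...] = tuple(PARAM_COLUMNS),
    method: str = "cluster_robust",
) -> pd.DataFrame:
    """Tidy table: one row per (parameter, band) present in *units*.

    This is the data behind the age-trend figure: plotting pooled mean,
    p5 and p95 against band index shows whether the whole distribution
    shifts down with age and whether the SD narrows.
    """
    if len(units) == 0:
        raise ValueError("no survey-age units to summarise")
    rows = []
    for parameter in parameters:
        for band in sorted(units["band_index"].unique()):
            s = pool_age_band(units, parameter, band, method=method)
            rows.append(vars(s))
    return pd.DataFrame(
        rows,
        columns=["parameter", "band_index", "pooled_mean", "ci_low", "ci_high", "n_units", "n_countries"],
    )


def plot_band_trends(summaries: pd.DataFrame, path=None):
    """Render the age-trend figure (mean/p5/p95 panel and SD panel)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for param, color in [("mean", "k"), ("p5", "tab:blue"), ("p95", "tab:red")]:
        sub = summaries[summaries["parameter"] == param]
        axes[0].plot(sub["band_index"], sub["pooled_mean"], "-o", ms=3, color=color, label=param)
        axes[0].fill_between(sub["band_index"], sub["ci_low"], sub["ci_high"], color=color, alpha=0.15)
    axes[0].set(xlabel="3-month age band", ylabel="HAZ", title="Mean and tail percentiles")
    axes[0].legend()
    sub = summaries[summaries["parameter"] == "sd"]
    axes[1].plot(sub["band_index"], sub["pooled_mean"], "-o", ms=3, color="k")
    axes[1].fill_between(sub["band_index"], sub["ci_low"], sub["ci_high"], color="k", alpha=0.15)
    axes[1].set(xlabel="3-month age band", ylabel="SD of HAZ", title="Standard deviation")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
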