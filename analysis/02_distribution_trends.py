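"""Survey-age units and pooled age trends of the HAZ distribution.

Bands the generated children into 12 three-month (91.3-day) intervals,
applies the |HAZ| <= 9 plausibility filter, computes weighted
distributional parameters per survey-age unit, and pools them by age band
with country-cluster-robust CIs. With the default generator (declining
mean, declining measurement error) the pooled mean, p5 and p95 all fall
with age and the SD narrows - the pattern seen in the survey compilation.
"""

import argparse
from pathlib import Path

import pandas as pd

from hazshift.distribution_params import build_survey_age_units
from hazshift.pooled_summary import plot_band_trends, summarize_all_bands


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = pd.read_csv(args.datadir / "child_records.csv")
    meta = pd.read_csv(args.datadir / "survey_meta.csv")
    units = build_survey_age_units(records, meta)
    print(f"survey-age units: {len(units)} "
          f"({units['survey_id'].nunique()} surveys x up to {units['band_index'].nunique()} bands); "
          f"excluded {units.attrs['n_excluded_plausibility']} implausible HAZ values")

    summaries = summarize_all_bands(units)
    args.outdir.mkdir(parents=True, exist_ok=True)
    units.to_csv(args.outdir / "survey_age_units.csv", index=False, float_format="%.10g")
    summaries.to_csv(args.outdir / "band_summaries.csv", index=False, float_format="%.10g")
    plot_band_trends(summaries, args.outdir / "fig_band_trends.png")

    wide = summaries.pivot(index="band_index", columns="parameter", values="pooled_mean")
    print("\npooled parameters by age band:")
    print(wide[["mean", "median", "sd", "p5", "p95", "dp5", "dp95"]].round(3).to_string())
    drop = wide.iloc[-1] - wide.iloc[0]
    print(f"\nbirth-to-36mo change: mean {drop['mean']:+.2f}, p5 {drop['p5']:+.2f}, "
          f"p95 {drop['p95']:+.2f}, sd {drop['sd']:+.2f}")
    print("=> whole distribution shifts down with age; SD narrows rather than widens")


if __name__ == "__main__":
    main()
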