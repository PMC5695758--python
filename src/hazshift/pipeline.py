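"""End-to-end orchestration: generate -> units -> pool -> fit -> simulate.

A single PipelineConfig (loadable from YAML) drives every stage; each
stage writes tidy CSVs under an output directory and records row counts,
exclusion counts and seeds in a JSON run manifest. A single global seed
deterministically derives per-stage seeds (SeedSequence spawned on
[global_seed, stage code]), so stages are independently reproducible and
two runs with the same config produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hazshift import __version__
from hazshift.distribution_params import (
    BAND_WIDTH_1M,
    BAND_WIDTH_6M,
    BandingConfig,
    build_survey_age_units,
)
from hazshift.errors import ConfigurationError
from hazshift.faltering_simulator import SimScenario, run_scenario
from hazshift.multilevel_models import (
    fit_stratified,
    fit_three_level,
    survey_fixed_effects_slopes,
    with_derived_strata,
)
from hazshift.pooled_summary import summarize_all_bands
from hazshift.synthetic_data import GeneratorConfig, generate_multisurvey_dataset

STAGE_CODES = {"generate": 1, "units": 2, "pool": 3, "fit": 4, "simulate": 5}

SENSITIVITY_SWITCHES = ("age_lt_24m", "limit_6", "bands_1m", "bands_6m")


def stage_seed(global_seed: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage integer seed derived from the global seed."""
    code = STAGE_CODES.get(stage)
    if code is None:
        raise ConfigurationError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), code, int(extra)])
    return int(ss.generate_state(1)[0]) % (2**31)


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    banding: BandingConfig = field(default_factory=BandingConfig)
    model_outcomes: tuple[str, ...] = ("sd", "median", "dp5", "dp95")
    stratifiers: tuple[str, ...] = ()
    sensitivity_switches: tuple[str, ...] = ()
    scenarios: tuple[SimScenario, ...] = ()
    output_dir: str = "results/pipeline"
    global_seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        self.banding.validate()
        for s in self.sensitivity_switches:
            if s not in SENSITIVITY_SWITCHES:
                raise ConfigurationError(f"unknown sensitivity switch {s!r}")
        for scen in self.scenarios:
            scen.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["covariate_scheme"] = {
            k: {str(kk): vv for kk, vv in v.items()} for k, v in d["generator"]["covariate_scheme"].items()
        }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file (missing sections use defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        gen = GeneratorConfig(**raw.get("generator", {}))
        banding = BandingConfig(**raw.get("banding", {}))
        scenarios = tuple(SimScenario(**s) for s in raw.get("scenarios", []))
        cfg = PipelineConfig(
            generator=gen,
            banding=banding,
            model_outcomes=tuple(raw.get("model_outcomes", ("sd", "median", "dp5", "dp95"))),
            stratifiers=tuple(raw.get("stratifiers", ())),
            sensitivity_switches=tuple(raw.get("sensitivity_switches", ())),
            scenarios=scenarios,
            output_dir=raw.get("output_dir", "results/pipeline"),
            global_seed=int(raw.get("global_seed", 0)),
        )
    except TypeError as exc:
        raise ConfigurationError(f"invalid config: {exc}") from exc
    cfg.validate()
    return cfg


def demo_config(output_dir: str = "results/demo", global_seed: int = 0) -> PipelineConfig:
    """Small end-to-end configuration: 2 countries x 2 surveys x 500 children."""
    return PipelineConfig(
        generator=GeneratorConfig(
            n_countries=2, surveys_per_country=2, children_per_survey=500, seed=0
        ),
        scenarios=tuple(
            SimScenario(p_exposed=p, n_replications=100) for p in (0.25, 0.5, 0.75, 1.0)
        ),
        stratifiers=("region",),
        output_dir=output_dir,
        global_seed=global_seed,
    )


def _sensitivity_variants(records: pd.DataFrame, banding: BandingConfig, switch: str):
    """Apply one sensitivity switch; returns (records, banding) for refit."""
    if switch == "age_lt_24m":
        n_bands = int(np.floor(730.5 / banding.band_width_days))
        return records.loc[records["age_days"] < 730.5], dataclasses.replace(banding, n_bands=n_bands)
    if switch == "limit_6":
        return records, dataclasses.replace(banding, plausibility_limit=6.0)
    if switch == "bands_1m":
        return records, dataclasses.replace(banding, band_width_days=BAND_WIDTH_1M, n_bands=36)
    if switch == "bands_6m":
        return records, dataclasses.replace(banding, band_width_days=BAND_WIDTH_6M, n_bands=6)
    raise ConfigurationError(f"unknown sensitivity switch {switch!r}")


class PipelineRun:
    """Stage-by-stage execution with a cumulative manifest."""

    def __init__(self, config: PipelineConfig):
        config.validate()
        self.config = config
        self.outdir = Path(config.output_dir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config_hash": config.config_hash(),
            "software_version": __version__,
            "global_seed": config.global_seed,
            "seeds": {},
            "row_counts": {},
            "exclusions": {},
            "outputs": {},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def _write(self, df: pd.DataFrame, name: str, stage: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        self.manifest["outputs"][name] = stage
        self.manifest["row_counts"][name] = len(df)
        return path

    def _read(self, name: str) -> pd.DataFrame:
        path = self.outdir / name
        if not path.exists():
            raise FileNotFoundError(f"stage output {name} missing; run earlier stages first")
        return pd.read_csv(path)

    def save_manifest(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        return path

    # --- stages -------------------------------------------------------------

    def generate(self):
        seed = stage_seed(self.config.global_seed, "generate")
        self.manifest["seeds"]["generate"] = seed
        gen = dataclasses.replace(self.config.generator, seed=seed)
        records, meta = generate_multisurvey_dataset(gen)
        self._write(records, "child_records.csv", "generate")
        self._write(meta, "survey_meta.csv", "generate")
        return records, meta

    def units(self):
        records, meta = self._read("child_records.csv"), self._read("survey_meta.csv")
        units = build_survey_age_units(records, meta, self.config.banding)
        self.manifest["exclusions"]["plausibility"] = units.attrs["n_excluded_plausibility"]
        self.manifest["exclusions"]["age_range"] = units.attrs["n_excluded_age_range"]
        n_in, n_banded = units.attrs["n_records_in"], units.attrs["n_records_banded"]
        assert n_in == n_banded + units.attrs["n_excluded_plausibility"] + units.attrs["n_excluded_age_range"]
        self.manifest["row_counts"]["children_in"] = n_in
        self.manifest["row_counts"]["children_banded"] = n_banded
        self._write(units, "survey_age_units.csv", "units")
        return units

    def pool(self):
        units = self._read("survey_age_units.csv")
        summaries = summarize_all_bands(units)
        self._write(summaries, "band_summaries.csv", "pool")
        return summaries

    def fit(self):
        units = with_derived_strata(self._read("survey_age_units.csv"))
        coef_rows, strat_frames, slope_frames = [], [], []
        for outcome in self.config.model_outcomes:
            mfit = fit_three_level(units, outcome)
            coef_rows.append(mfit.summary_row())
            blups = mfit.blup_slopes.rename("blup_slope").rename_axis("survey_id").reset_index()
            blups.insert(0, "outcome", outcome)
            slope_frames.append(blups)
            for strat in self.config.stratifiers:
                st = fit_stratified(units, outcome, strat)
                st.insert(0, "stratifier", strat)
                st.insert(0, "outcome", outcome)
                strat_frames.append(st)
        self._write(pd.DataFrame(coef_rows), "model_coefficients.csv", "fit")
        if strat_frames:
            self._write(pd.concat(strat_frames, ignore_index=True), "stratified_slopes.csv", "fit")
        self._write(pd.concat(slope_frames, ignore_index=True), "blup_slopes.csv", "fit")
        per_survey = survey_fixed_effects_slopes(units, "sd")
        self._write(per_survey, "survey_slopes_sd.csv", "fit")
        # sensitivity refits on the primary outcome set
        sens_rows = []
        if self.config.sensitivity_switches:
            records, meta = self._read("child_records.csv"), self._read("survey_meta.csv")
            for switch in self.config.sensitivity_switches:
                recs, banding = _sensitivity_variants(records, self.config.banding, switch)
                sunits = with_derived_strata(build_survey_age_units(recs, meta, banding))
                for outcome in self.config.model_outcomes:
                    row = fit_three_level(sunits, outcome).summary_row()
                    row["switch"] = switch
                    sens_rows.append(row)
            self._write(pd.DataFrame(sens_rows), "sensitivity_coefficients.csv", "fit")
        return pd.DataFrame(coef_rows)

    def simulate(self):
        frames = []
        for i, scen in enumerate(self.config.scenarios):
            seed = stage_seed(self.config.global_seed, "simulate", extra=i)
            self.manifest["seeds"][f"simulate_{i}"] = seed
            traj = run_scenario(dataclasses.replace(scen, seed=seed))
            t = traj.table.copy()
            t.insert(0, "p_exposed", scen.p_exposed)
            t.insert(0, "selection_rule", scen.selection_rule)
            t.insert(0, "scenario", i)
            frames.append(t)
        if frames:
            self._write(pd.concat(frames, ignore_index=True), "scenario_trajectories.csv", "simulate")
        return frames


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the completed manifest."""
    run = PipelineRun(config)
    stage = "generate"
    try:
        run.generate()
        stage = "units"
        run.units()
        stage = "pool"
        run.pool()
        stage = "fit"
        run.fit()
        stage = "simulate"
        run.simulate()
    except Exception:
        run.manifest["failed_stage"] = stage
        run.save_manifest()
        raise
    run.save_manifest()
    return run.manifest


def render_report(output_dir) -> str:
    """Human-readable run summary assembled from the stage CSVs.

    Deterministic given the manifest; missing stage outputs are noted
    rather than fatal, but an empty run (no outputs at all) is an error.
    """
    outdir = Path(output_dir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {outdir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    if not manifest.get("outputs"):
        raise ValueError("manifest lists no outputs; nothing to report")
    lines = [
        "# HAZ distribution pipeline report",
        f"config hash: {manifest['config_hash']}  |  version: {manifest['software_version']}"
        f"  |  global seed: {manifest['global_seed']}",
        "",
    ]
    sections = [
        ("band_summaries.csv", "Pooled parameters by age band"),
        ("model_coefficients.csv", "Multilevel model coefficients (outcome vs 1-unit decline in mean HAZ)"),
        ("stratified_slopes.csv", "Stratum-specific slopes"),
        ("sensitivity_coefficients.csv", "Sensitivity analyses"),
        ("scenario_trajectories.csv", "Faltering simulation trajectories (final step per scenario)"),
    ]
    for name, title in sections:
        path = outdir / name
        if not path.exists():
            if name in manifest.get("outputs", {}):
                lines += [f"## {title}", "(output file missing)", ""]
            continue
        df = pd.read_csv(path)
        if name == "scenario_trajectories.csv":
            df = df.sort_values("step").groupby("scenario").tail(1)
        lines += [f"## {title}", df.round(4).to_string(index=False), ""]
    report = "\n".join(lines)
    (outdir / "report.md").write_text(report)
    return report
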