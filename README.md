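# hazshift

Analysis of how the height-for-age Z-score (HAZ) distribution of
children aged 0–36 months changes as its population mean declines with
age — the question of whether early-childhood linear growth faltering in
low- and middle-income countries is a *subgroup* phenomenon (some
high-risk children diverge, widening and skewing the distribution) or a
*whole-population* downward shift (everyone falters, the distribution
moves without widening).

The package is aimed at biostatisticians and nutrition epidemiologists
working with multi-survey anthropometry. It provides:

* a hierarchical **synthetic survey generator** (countries → surveys →
  children, DHS-style probability weights, configurable age curves for
  mean HAZ, biological SD and measurement-error SD), since real survey
  microdata are access-restricted;
* **survey-age units**: 3-month (91.3-day) age bands per survey with
  weighted mean, median, SD, p5, p95, and the tail distances
  Δp5 = mean − p5 and Δp95 = p95 − mean, after excluding implausible
  values (|HAZ| > 9);
* **pooled age trends** of each parameter with country-cluster-robust
  95% CIs;
* **three-level mixed models** (units in surveys in countries; REML)
  of each parameter on the sign-reversed unit mean, x = −(mean HAZ):

      y = β₀ + β₁x + u_country + a_survey + b_survey·x + ε

  with stratified (interaction) slopes, ICCs, per-survey OLS slopes for
  forest plots, and shrunken (BLUP) survey slopes;
* a **Monte Carlo faltering simulator**: 10,000 children starting at
  N(0, 1), the mean driven from 0 to −2 in 20 decrements of 0.1 carried
  by an exposed fraction p of children (whose mean decline is therefore
  0.1/p per step, with per-child SD one tenth of that), averaged over
  1000 replications — plus preferential-selection, floor-censoring and
  deficit-gradient variants, and a closed-form mixture-moments oracle.

## Worked example

```python
from hazshift.faltering_simulator import SimScenario, run_scenario, mixture_moments_oracle

scen = SimScenario(p_exposed=0.25, n_replications=200, seed=7)
traj = run_scenario(scen)
print(f"final mean {traj.table['mean'].iloc[-1]:.3f}, "
      f"final SD {traj.final_sd:.3f}, "
      f"oracle SD {mixture_moments_oracle(scen)['sd'].iloc[-1]:.3f}")
```

prints

```
final mean -2.002, final SD 3.607, oracle SD 3.607
```

With only 25% of children exposed, pushing the population mean to −2
forces the exposed group down by 8 HAZ — the SD explodes from 1 to 3.6.
Under whole-population exposure (`p_exposed=1.0`) the final SD is 1.00:
the distribution shifts without widening. Observed survey data show the
SD *narrowing* as the mean declines, which no subgroup scenario
reproduces.

The survey-analysis side, end to end on synthetic data:

```bash
python analysis/01_generate_surveys.py --seed 0   # 179 surveys, 64 countries
python analysis/02_distribution_trends.py         # units + pooled age trends
python analysis/03_multilevel_models.py           # three-level REML fits
python analysis/04_faltering_simulations.py       # simulation grid + variants
```

`03` prints, for the default generator (truth: symmetric Gaussian HAZ,
declining mean, age-declining measurement error):

```
sd     slope -0.120 (-0.126, -0.114)  intercept +1.473  pred@-2 +1.233  ICC country 0.26 survey 0.32
median slope -1.002 (-1.009, -0.995)  intercept -0.005  pred@-2 -2.009  ICC country 0.28 survey 0.35
dp5    slope -0.197 (-0.214, -0.180)  ...
dp95   slope -0.197 (-0.212, -0.182)  ...
```

i.e. the median tracks the mean one-for-one (slope ≈ −1), the SD falls
as the mean falls (positive x is a declining mean, negative slope is
narrowing), and the two tails contract symmetrically (Δp5 and Δp95
slopes equal) — the whole-population signature built into the generator
and recovered by the models.

The same stages are scriptable through one config:

```bash
hazshift all --config my_run.yaml --seed 1
hazshift simulate --output-dir results/demo      # demo config, simulation only
```

## Layout

```
src/hazshift/        library: synthetic_data, distribution_params,
                     pooled_summary, multilevel_models,
                     faltering_simulator, pipeline, cli
analysis/            numbered narrative drivers (write under results/)
scripts/acceptance.py
tests/               pytest suite (unit, property and acceptance tests)
docs/methods.md      modelling and simulation details, assumptions, limits
```
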