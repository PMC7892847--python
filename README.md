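# salmon-lcm

Climate-forced, age-structured life-cycle modelling for stream-type Chinook
salmon (*Oncorhynchus tshawytscha*) populations.

Wild spring/summer Chinook in the interior Columbia basin complete a life
cycle that crosses four environments — natal tributaries, the dammed
mainstem migration corridor, the northeast Pacific, and the upstream return
route — and climate change touches every one of them.  `salmon-lcm` is a
research pipeline for asking how correlated climate trends propagate
through that life cycle to population viability: which life stage drives
decline, how fast quasi-extinction risk accumulates under different
emissions scenarios, and how sensitive the answers are to covariate
choices.  It is aimed at population ecologists and conservation modellers,
and runs entirely on synthetic data with recorded ground truth so every
statistical component is recovery-tested.

## The model

**Environment.** Annual covariates (basin-scale and coastal SST, coastal
upwelling, summer air temperature, seasonal stream flows) follow a
mean-reverting multivariate AR(1):

    x_t ~ MVN(rho x_{t-1}, Q),    y_t ~ N(x_t, 0.001)

with scalar autocorrelation `rho` and an unstructured covariance `Q`
(0.5·n·(n−1) free correlations for n covariates), so cross-stage climate
correlation is explicit.  Climate-change scenarios add per-covariate trend
offsets extracted from GCM ensembles: baseline mean over 2005–2025,
anomalies, a centered 20-year running mean, then 25th/50th/75th quantiles
across ensemble members.

**Life cycle.** Five annual time-steps: Gompertz spawner→parr and
parr→smolt recruitment (log R = a + (1+b) log S + Σ cᵢxᵢ + ε), a binned
empirical emulator of mainstem passage (survival, arrival-day shift,
transported fraction as functions of spring temperature and flow), a
mixed-effects logistic smolt-to-adult return (SAR) model with AR(1)
day-of-entry effects and separate transported/in-river variants, and
logistic adult upstream survival.  Total SAR is partitioned into ages by
the maturation parameters:

    S_SAR = (b3 N3 + b4 N4 + N5) / N2,
    N3 = S3 N2,  N4 = (1−b3) N3 S0,  N5 = (1−b4) N4 S0

Effective spawners weight age-3 jacks 0, age-4 fish 1, and age-5 fish F5.

**Calibration.** The maturation parameters (S0, b3, b4, F5) are tuned by
rejection ABC: 500,000 candidate parameter sets (beta/normal priors, each
paired intact with a freshwater-posterior draw) are run through the life
cycle under the historical covariate record and ranked by two-sample
Kolmogorov–Smirnov deviance against the observed spawner distribution;
the top 0.2% (1000 sets) is retained.

**Risk and sensitivity.** Quasi-extinction (QET50) is the first year the
4-year running mean of spawners drops strictly below 50.  Sensitivity
designs cover covariate-model swaps (Models 1–3) and a stage-specific
forcing factorial that applies the climate trend to one life stage at a
time and reports the 2060s/2020s geometric-mean abundance ratio.

## Worked example

```python
import numpy as np
from salmon_lcm import synthdata as sd
from salmon_lcm.envsim import ClimateScenario, fit_covariance_model, simulate_detrended
from salmon_lcm.interface import build_scenario_trends
from salmon_lcm.lifecycle import run_projection
from salmon_lcm.risk import summarize_risk

world = sd.default_world(seed=1, populations=("sulphur_creek",))
pop = "sulphur_creek"
model = fit_covariance_model(world.historical_env)
print(f"AR(1) coefficient rho = {float(np.asarray(model.rho)):.3f}, "
      f"free correlations in Q = {model.n_correlation_params}")
draws = simulate_detrended(model, 75, 200, seed=2, start_year=2015)
trends = build_scenario_trends("rcp85", 50, seed=3, covariates=model.names)
for label, scen in [("detrended", ClimateScenario(draws)),
                    ("rcp85", ClimateScenario(draws, trends, label="rcp85"))]:
    trajs = run_projection(world.params[pop], scen, 200, seed=4,
                           init_spawners=world.init_spawners[pop], population=pop)
    s = summarize_risk(trajs)
    med_final = np.median([t.spawners[-10:].mean() for t in trajs])
    print(f"{label:>9}: median 2080s spawners = {med_final:7.1f}, "
          f"P(QET50 by 2089) = {s.prop_below[-1]:.2f}")
```

prints

```
AR(1) coefficient rho = 0.128, free correlations in Q = 28
detrended: median 2080s spawners =   716.3, P(QET50 by 2089) = 0.00
    rcp85: median 2080s spawners =    78.5, P(QET50 by 2089) = 0.46
```

The covariance model fitted to 16 historical years estimates a modest
year-to-year autocorrelation and all 28 pairwise covariate correlations.
Under a detrended (stationary) climate the population holds its abundance
and never crosses the quasi-extinction threshold; adding the RCP 8.5
median trend — which pushes SST upward against negative marine-survival
coefficients — collapses median spawners roughly ninefold by the 2080s and
puts nearly half of simulations past QET50 within the projection horizon.

A thin CLI wraps the same functions:

```bash
salmon-lcm synth --out data/ --seed 1          # synthetic world + truth sidecars
salmon-lcm env fit --covariates data/covariates.csv --out fit.csv
salmon-lcm calibrate --pop sulphur_creek --n 2000 --fraction 0.05 --seed 1 --out abc.csv
salmon-lcm run --out exp/ --seed 1             # full configured experiment
```

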