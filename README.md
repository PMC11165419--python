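# radassim

Predicting how glioma cell cultures respond to fractionated radiotherapy, and
sharpening those predictions every 24 hours as new time-lapse measurements
arrive.

Replicate wells with identical seeding density and fractionation scheme can
respond very differently to the same treatment. A forecast built only from
population-average parameters cannot capture that heterogeneity. `radassim`
implements a biology-based ordinary-differential-equation model of confluence
dynamics under fractionated radiation together with a Monte-Carlo data
assimilation loop that blends population knowledge with each well's own
accumulating measurements. It is aimed at quantitative radiobiologists and
modellers working with time-resolved microscopy (e.g. Incucyte confluence
courses) who want per-well forecasts with prediction intervals.

## The model

Live-cell confluence N ∈ [0, 1] of an untreated well follows Allee-logistic
growth, dN/dt = k_p N (N/θ + A)(1 − N/θ). After irradiation the population
splits into proliferating (N_p) and senescent (N_s) compartments with three
loss pathways:

    dN_p/dt = (k_p − k_ld(t)) (N/θ + A) N_p (1 − N/θ) − k_ed(t) N_p − k_ps N_0 N_p
    dN_s/dt = k_ps N_0 N_p,                N = N_p + N_s

where k_ed(t) = k_acute Σ_j f_DSB(t − t_j) is acute apoptotic death driven by
unrepaired double-strand breaks, k_ld(t) = Σ_j k_accum τ_j e^(−r τ_j) is
delayed death from accumulating misrepair (τ_j = time since fraction j), and
k_ps N_0 is the conversion rate into senescence. Population-level rates
collapse to per-well rates through k_acute = k_acute,N·N_0 and
k_accum = (α_accum,N·N_0 + 1)·k_accum,D·D.

Forecasting runs in two modes:

* **Global prediction** — one deterministic forward run from the well's
  initial confluence using the population parameter means X_pop.
* **Data assimilation** — every T = 24 h, refit the well's own parameters
  X_ind to the data so far, draw an ensemble from the interquartile range of
  N(X_pop, σ_pop/(1+ω)), mix each draw as (1−ω)·X_pop* + ω·X_ind with a
  confidence weight ω that grows (linearly or quadratically) over the course,
  and run all draws forward. The ensemble median is the forecast and its
  envelope the prediction interval.

Forecast quality is scored with Lin's concordance correlation coefficient
(CCC), and five model variants (global; {plain, time-weighted} cost ×
{linear, quadratic} ω) are compared by mean CCC with one-way ANOVA.

Because the original microscopy data are not public, the package ships a
first-class synthetic-cohort generator (`radassim.synthetic_data`) that
reproduces the study structure: six fractionation arms (16 or 20 Gy in 2–4
daily fractions), seeding densities spanning a 10× range, log-normal
between-well heterogeneity, additive measurement noise, and the 70/10/20
training/testing/validation split.

## Worked example

```python
import numpy as np
import radassim as ra

# 1. synthetic cohort: 40 treated wells of a 9L-like line, heterogeneous
#    response (CV 0.3), measurement noise sd 0.01
spec = ra.default_population_spec("9L")
rng = np.random.default_rng(7)
cohort = ra.generate_cohort(40, spec, rng, split=(0.75, 0.25, 0.0))

# 2. population-level calibration on the training wells
fit = ra.fit_global(cohort.training, spec.growth, n_starts=2, seed=7)
pop = fit.estimates

# 3. forecast one held-out well: population-only vs assimilated
well = cohort.testing[0]
cfg = ra.AssimilationConfig(n_draws=300, rng_seed=7,
                            weight_schedule="quadratic", cost_flavor="revised")
global_pred = ra.predict_global(well.confluence[0], well.schedule, pop,
                                spec.growth, cfg, n0=well.n0,
                                output_times=well.times)
assim_pred = ra.assimilate(well, pop, spec.growth, cfg)
print(ra.ccc(well.confluence, global_pred.confluence))
print(ra.ccc(well.confluence, assim_pred.median))
```

Output:

```
global fit: converged=True, cost=0.7532
  kacute_N=0.478  kaccum_D=2.66e-04  r=0.0190
well s0035 (16 Gy in 4 fractions, N0=0.142):
  CCC global prediction     : 0.410
  CCC assimilated prediction: 0.848
```

The global fit recovers population parameters close to the generator's means
(k_acute,N = 0.5, k_accum,D = 3e−4, r = 0.02). The held-out well is a
heterogeneous responder: the population-only forecast misjudges its
trajectory (CCC 0.41), while the assimilated forecast, updated every 24 h
from the well's own measurements, tracks it closely (CCC 0.85).

A command-line interface mirrors the pipeline
(`radassim simulate | fit-growth | fit-global | predict-global | assimilate |
evaluate`); run `radassim --help` for the formats.

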