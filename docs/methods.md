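# Methods

## The model

`radassim` models the live-cell confluence N(t) ∈ [0, 1] of glioma cultures
(9L-like and C6-like lines) imaged every 4–6 h for up to 330 h after the first
of 2–4 radiation fractions delivered 24 h apart (16 or 20 Gy total, split
equally).

**Untreated growth** combines an Allee effect with logistic saturation:

    dN/dt = kp · N · (N/θ + A) · (1 − N/θ)

with proliferation rate kp (1/h), carrying capacity θ (confluence fraction),
and Allee constant A (dimensionless cooperation at low density). kp, θ, A are
calibrated once per cell line from untreated control wells and then held
fixed.

**Treated dynamics** split the population into proliferating Np and senescent
Ns compartments (N = Np + Ns), with three radiation-induced loss pathways:

    dNp/dt = (kp − kld(t)) · ((Np+Ns)/θ + A) · Np · (1 − (Np+Ns)/θ)
             − ked(t) · Np − kps · N0 · Np
    dNs/dt = kps · N0 · Np

* *Early death* (acute apoptosis from unrepaired double-strand breaks):
  ked(t) = kacute · Σ_j fDSB(t − t_j), summing over delivered fractions.
  fDSB is 1 at delivery, 0 before it, and decays mono-exponentially with a
  repair half-life of 4 h by default. The half-life, and an optional
  dose-dependence hook, live in `DSBRepairSpec`; the exponential form is the
  package's own choice of repair kinetics, normalised so the rate at delivery
  equals kacute.
* *Late death* (mitotic catastrophe from accumulating misrepair):
  kld(t) = Σ_j kaccum · τ_j · exp(−r τ_j) with τ_j = max(t − t_j, 0); each
  fraction's term rises as damage accumulates and decays with radiation
  efficacy at rate r, peaking at τ = 1/r. Each fraction's clock starts at its
  own delivery time — a fraction cannot act before it is delivered. (An
  absolute-time variant is conceivable but acausal for later fractions; the
  per-fraction clock is used throughout.)
* *Senescence*: irreversible arrest converting Np to Ns at rate kps·N0, with
  kps calibrated separately per total dose (16 vs 20 Gy), and Ns(0) = 0.

At the population level the per-sample rates collapse through the dose and
seeding-density laws kacute = kacute_N·N0 and
kaccum = (α_accum,N·N0 + 1)·kaccum_D·D (D = dose per fraction, N0 = seeding
confluence). Fitting a single well uses the collapsed rates directly since D
and N0 are then fixed and known.

## Numerics

The system is integrated by explicit forward Euler with fixed step
dt = 0.01 h. Measurement times are snapped to the Euler grid (0.01 h divides
the 4–6 h imaging cadence exactly); there is no interpolation. Against an
adaptive Runge–Kutta reference at rtol 1e−10 the stepper agrees to better
than 1e−3 confluence over a full 330-h course, and halving dt changes the
endpoint by less than 1e−3 (first-order convergence).

If a large fitted death rate transiently drives a compartment negative within
a step, the state is clamped at 0 and a warning recorded; this occurs only
during optimizer exploration of extreme parameter corners.

The hot loop is numba-compiled and vectorised over an ensemble of parameter
draws. Per-fraction exponentials are advanced multiplicatively (two running
accumulators per draw for the late-death sum), so a step costs a handful of
flops regardless of the fraction count; accumulated round-off over 33,000
steps is ~1e−12 relative. `EulerPlan` caches the grid/schedule setup so
optimizers and ensembles pay one kernel call per evaluation.

## Calibration

All fits are Levenberg–Marquardt (scipy's MINPACK `lm`) on a smooth bounded
reparameterisation x = ub·z²/(1+z²), which enforces the biological lower
bound of 0 and a generous upper bound (≈10× nominal magnitude) while keeping
the inner solver unconstrained. Convergence: relative cost change < 1e−8 or
500 iterations. Multistart (default 5 starts: one heuristic plus seeded
log-uniform draws over the bounds) guards against the multimodal landscape;
the best cost wins.

* `fit_growth` pools all control wells of a line into one joint fit of
  (kp, θ, A).
* `fit_global` fits (kacute_N, α_accum,N, kaccum_D, r, kps per total dose)
  jointly to every training well, expanding per-well rates through the
  dose/density laws. Standard errors from the Jacobian-based covariance at
  the optimum form σ_pop; a rank-deficient direction carries no information
  and its σ is replaced by the prior width (a quarter of the bound range) and
  flagged.
* `fit_individual` fits the collapsed (kacute, kaccum, r, kps) of one well to
  its measurements up to a cutoff, under either the plain sum-of-squares cost
  or the *revised* cost that multiplies each squared residual by
  min(t, Ttotal), discounting early observations in favour of recent ones.

## Data assimilation

Forecasts are refined every T = 24 h. At step i (data observed on [0, iT]):

1. ω(i) sets the confidence in the individual estimate: linear
   ω = min(iT/Ttotal, 1) or quadratic ω = −0.6x² + 1.2x + 0.4 with
   x = min(iT/Ttotal, 1), Ttotal = 330 h. The quadratic coefficients solve
   ω(24/330) = 0.5, ω(1) = 1, ω′(1) = 0, rounded to the nearest tenth.
   At i = 0 no individual fit can exist (a single measurement), so ω is
   forced to 0 for both schedules and the forecast is purely population-based.
2. The individual parameters are refit to [0, iT] (warm-started from the
   previous step; cold restart from the population evaluation if the warm fit
   fails to converge, keeping the better cost).
3. Each of n_draws ensemble members samples the global parameters from
   Normal(X_pop, σ_pop/(1+ω)) truncated to that normal's interquartile range
   — density-proportional inverse-CDF sampling on [Q1, Q3], intersected with
   [0, ∞) (a uniform-on-IQR variant sits behind `iqr_mode="uniform"`) — then
   evaluates them at the sample's dose and seeding density and mixes towards
   the individual estimate: X_weighted = (1−ω)·X_pop* + ω·X_ind.
4. All draws run forward from t = 0 (Np(0) = first measured confluence,
   Ns(0) = 0) to (i+1)T. The pointwise median over draws is the prediction;
   the pointwise min/max envelope is the prediction interval (a 2.5/97.5%
   quantile variant sits behind `interval="quantile"`). Only the window
   (iT, (i+1)T] is kept, and windows are concatenated into the final
   trajectory.

One seeded random stream is consumed per (call, window) in a fixed order
(one uniform block per window), so identical configurations reproduce
bit-identical predictions. The population-only forecast ("global
prediction") is the deterministic ω ≡ 0, mean-parameters special case and is
exposed both as `predict_global` and as `force_global=True` in the loop.

## Evaluation

Agreement between prediction and measurement over a whole course is scored by
Lin's concordance correlation coefficient with population (1/n) moments:

    CCC = 2·cov(x, y) / (var x + var y + (mean x − mean y)²)

CCC penalises bias as well as imprecision and, unlike MSE, is comparable
across lines with different carrying capacities; Pearson's r is provided for
the precision-only view. The comparison is computed over all measurement
times from t = 0 (no window restriction). Five variants are compared: the
global prediction (model 1) and assimilation with cost ∈ {plain,
time-weighted} × ω ∈ {linear, quadratic} (models 2–5); a one-way ANOVA
(classical sum-of-squares table, F-distribution p-value, no multiple-testing
correction) tests whether the per-sample CCC groups differ, with two-group
ANOVAs for pairwise contrasts. The best model maximises mean CCC.

## Synthetic cohorts

The microscopy data behind this framework are not public, so cohorts are
generated with the structure the analysis assumes. Defaults (one config
block in `synthetic_data`, explicitly generator choices, not published
values):

| parameter | default | why |
|---|---|---|
| growth (9L-like) | kp 0.05 /h, θ 0.98, A 0.1 | dense-growing line; θ = 0.98 fixed by the study design |
| growth (C6-like) | kp 0.04 /h, θ 0.81, A 0.15 | lighter-growing line; θ = 0.81 fixed |
| kacute_N | 0.5 /h per confluence | early death visibly dents high-N0 wells without extinguishing them |
| α_accum,N | 2.0 per confluence | moderate density coupling of late death |
| kaccum_D | 3e−4 /(h²·Gy) | high-dose arms decline through ~50–250 h; 16 Gy arms partially recover |
| r | 0.02 /h | per-fraction late-death peak at τ = 50 h (days scale) |
| kps(16) / kps(20) | 0.05 / 0.08 /h per confluence | slow conversion; a resistant well can regrow |
| seeding range | N0 ∈ [0.02, 0.2] | the 10× range of 1,000–10,000 cells/well, on the confluence scale |
| heterogeneity | log-normal, CV 0.3 per response parameter | the heterogeneous-response regime the assimilation targets |
| noise | additive Gaussian, sd 0.01, clipped to [0, 1] | approximately additive segmentation error |
| grid | every 4 h for 330 h; fractions 24 h apart | imaging and treatment cadence |

Six fractionation arms (16 Gy as 4×4/3×5.33/2×8; 20 Gy as 4×5/3×6.67/2×10)
are assigned uniformly; cohorts are split 70/10/20 into
training/testing/validation by largest-remainder allocation; per-sample true
parameters are retained for recovery tests. The generator emulates the
statistical structure of time-lapse confluence data, not its imaging physics:
no spatial information, no segmentation artefacts, no temporally correlated
noise, no plate-edge or medium-exchange effects. Passing tests therefore
demonstrate internal consistency of the pipeline under the assumed model, not
performance on real microscopy data.

## Problem sizes and study conditions used in the checks

* Integrator checks: full 330-h courses at dt = 0.01 h against closed-form
  and adaptive-RK references.
* Parameter recovery: 50-curve homogeneous cohorts (noise-free and sd 0.01),
  fit at dt = 0.01 with the default 5-start optimizer.
* Model-selection experiment: one 100-sample cohort (CV 0.3, noise sd 0.01),
  70 training wells for the global fit, the pooled 30 testing+validation
  wells evaluated, 300 ensemble draws per window (the loop's default is
  5,000; the window median the experiment depends on is stable far below
  that), dt = 0.01.
* Fast unit tests use coarser steps (dt 0.05–0.1) and short courses where
  only structural properties, not integration accuracy, are at stake.

## Known limitations

* **Practical identifiability.** The late-death parameterisation is sloppy:
  (α_accum,N·N0 + 1) spans only ~1.04–1.4 over the study's seeding range, so
  with realistic measurement noise the likelihood barely constrains
  α_accum,N individually — the fit can trade it against kaccum_D and r while
  reproducing every observable trajectory. Noise-free recovery is exact;
  under noise sd 0.01 at 50 curves the well-identified parameters (kacute_N,
  kps) recover to within ~6% while the sloppy subspace can displace far
  further. Collapsed per-well rates, and hence predictions, remain well
  determined; users should treat the individual values of α_accum,N,
  kaccum_D and r with caution and consult σ_pop.
* The fDSB repair kinetics are a modelling choice (mono-exponential, 4-h
  half-life, dose-independent by default), not a measured curve.
* Fixed-step Euler requires re-simulation from t = 0 in every window; the
  senescent fraction is never directly observed, so the initial condition
  cannot be restarted mid-course.
* The ensemble quantifies parameter uncertainty only; measurement noise is
  not propagated into the prediction interval.
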