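"""Monte-Carlo data assimilation: sequential 24-h refinement of per-sample forecasts.

The forecast for a new well starts from the population parameters alone
("global prediction", Scenario 1).  As measurements accumulate, every T hours
(default 24 h) the sample's own parameters X_ind are refit to the data seen so
far, and the next window [iT, (i+1)T] is predicted by an ensemble: draws from
the interquartile range of the population parameter distribution
N(X_pop, sigma_pop/(1+omega)) are evaluated at the sample's dose and seeding
density, mixed towards X_ind with weight omega, and run forward from t = 0.
The pointwise ensemble median is the prediction and the envelope of all draws
the prediction interval; the final prediction concatenates the windows.

The confidence weight omega grows with the assimilation step i either linearly,
omega = min(iT/Ttotal, 1), or quadratically with the calibrated polynomial
-0.6 x^2 + 1.2 x + 0.4 in x = min(iT/Ttotal, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .core import (
    GlobalParams,
    GrowthParams,
    IndividualParams,
    Prediction,
    RadiationSchedule,
    TimeCourse,
    ValidationError,
    evaluate_pop_star,
    kps_lookup,
)
from .calibration import fit_individual
from .dynamics import DEFAULT_DSB, DSBRepairSpec, simulate, simulate_batch

__all__ = [
    "AssimilationConfig",
    "WeightedDraw",
    "weight_linear",
    "weight_quadratic",
    "quadratic_weight_coefficients",
    "QUADRATIC_COEFFS",
    "weighted_sigma",
    "sample_global_iqr",
    "evaluate_pop_star",
    "combine",
    "predict_window",
    "assimilate",
    "predict_global",
]

#: printed coefficients of the quadratic weight (rounded to the nearest tenth)
QUADRATIC_COEFFS = (-0.6, 1.2, 0.4)

@dataclass(frozen=True)
class AssimilationConfig:
    """Knobs of the assimilation loop.

    T               prediction window length (h)
    t_total         study / training-set duration Ttotal (h)
    n_draws         ensemble size per window
    weight_schedule 'linear' or 'quadratic' growth of the individual weight
    cost_flavor     'basic' (plain SSE) or 'revised' (time-weighted) refits
    rng_seed        seed of the per-call random stream
    dt              Euler step (h)
    interval        'extrema' (envelope of all draws) or 'quantile' (2.5/97.5%)
    iqr_mode        'truncated_normal' (density-proportional on [Q1,Q3]) or
                    'uniform' (flat on [Q1,Q3])
    force_global    run with omega = 0 and the population means only
                    (degenerate, deterministic Scenario-1 reduction)
    """

    T: float = 24.0
    t_total: float = 330.0
    n_draws: int = 5000
    weight_schedule: str = "linear"
    cost_flavor: str = "basic"
    rng_seed: int = 0
    dt: float = 0.01
    interval: str = "extrema"
    iqr_mode: str = "truncated_normal"
    force_global: bool = False

    def __post_init__(self):
        if self.T <= 0:
            raise ValidationError("T must be positive")
        if self.t_total < self.T:
            raise ValidationError("t_total must be at least T")
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        if self.weight_schedule not in ("linear", "quadratic"):
            raise ValidationError(f"unknown weight schedule {self.weight_schedule!r}")
        if self.cost_flavor not in ("basic", "revised"):
            raise ValidationError(f"unknown cost flavor {self.cost_flavor!r}")

    def weight(self, i: int) -> float:
        if self.force_global or i == 0:
            # no individual fit can exist at step 0 (a single measurement);
            # the weighted parameters then equal the global parameters
            return 0.0
        fn = weight_linear if self.weight_schedule == "linear" else weight_quadratic
        return fn(i, self.T, self.t_total)


@dataclass(frozen=True)
class WeightedDraw:
    """One ensemble member: mixed parameter vector and its weight."""

    values: IndividualParams
    omega: float

    def __post_init__(self):
        if not (0.0 <= self.omega <= 1.0):
            raise ValidationError("omega must lie in [0, 1]")


# --------------------------------------------------------------------------
# weight schedules
# --------------------------------------------------------------------------


def weight_linear(i: int, T: float = 24.0, t_total: float = 330.0) -> float:
    """Linear confidence weight min(iT/Ttotal, 1)."""
    if i < 0:
        raise ValidationError("step index must be non-negative")
    return min(i * T / t_total, 1.0)


def weight_quadratic(i: int, T: float = 24.0, t_total: float = 330.0) -> float:
    """Quadratic confidence weight -0.6 x^2 + 1.2 x + 0.4 in x = min(iT/Ttotal, 1).

    Calibrated so the individual weight is ~0.5 after the first window and
    exactly 1 at the end of the course; clipped at 1 as a safety net.
    """
    if i < 0:
        raise ValidationError("step index must be non-negative")
    x = min(i * T / t_total, 1.0)
    a, b, c = QUADRATIC_COEFFS
    return min(a * x * x + b * x + c, 1.0)


def quadratic_weight_coefficients(
    T: float = 24.0, t_total: float = 330.0, early_weight: float = 0.5
) -> np.ndarray:
    """Solve for the quadratic weight's coefficients (a, b, c).

    The polynomial omega(x) = a x^2 + b x + c in normalized time x = iT/Ttotal
    is pinned by three constraints: the weight after the first window equals
    ``early_weight`` (so individual parameters dominate from the start), the
    weight at the end of the course is 1, and that endpoint is the maximum
    (omega'(1) = 0).  Rounding the solution to the nearest tenth yields the
    working coefficients (-0.6, 1.2, 0.4).
    """
    x1 = T / t_total
    lhs = np.array([[x1 * x1, x1, 1.0], [1.0, 1.0, 1.0], [2.0, 1.0, 0.0]])
    rhs = np.array([early_weight, 1.0, 0.0])
    return np.linalg.solve(lhs, rhs)


# --------------------------------------------------------------------------
# sampling and mixing
# --------------------------------------------------------------------------


def weighted_sigma(sigma_pop, omega: float):
    """Shrink the population spread as confidence in the individual grows:
    sigma_weighted = sigma_pop / (1 + omega), elementwise."""
    if not (0.0 <= omega <= 1.0):
        raise ValidationError("omega must lie in [0, 1]")
    if isinstance(sigma_pop, GlobalParams):
        f = 1.0 / (1.0 + omega)
        return GlobalParams(
            kacute_n=sigma_pop.kacute_n * f,
            alpha_accum_n=sigma_pop.alpha_accum_n * f,
            kaccum_d=sigma_pop.kaccum_d * f,
            r=sigma_pop.r * f,
            kps_by_total_dose={d: v * f for d, v in sigma_pop.kps_by_total_dose.items()},
        )
    return np.asarray(sigma_pop, dtype=float) / (1.0 + omega)


def _pop_arrays(pop: GlobalParams, total_dose: float) -> Tuple[np.ndarray, np.ndarray]:
    """(means, sds) in fixed order kacute_n, alpha_accum_n, kaccum_d, r, kps(dose)."""
    means = np.array(
        [pop.kacute_n, pop.alpha_accum_n, pop.kaccum_d, pop.r, kps_lookup(pop, total_dose)]
    )
    if pop.sigma is None:
        sds = np.zeros(5)
    else:
        s = pop.sigma
        sds = np.array(
            [s.kacute_n, s.alpha_accum_n, s.kaccum_d, s.r, kps_lookup(s, total_dose)]
        )
    return means, sds


def _sample_iqr_arrays(
    means: np.ndarray,
    sds: np.ndarray,
    rng: np.random.Generator,
    size: int,
    mode: str = "truncated_normal",
) -> np.ndarray:
    """Draw ``size`` vectors from the IQR-truncated parameter distribution.

    Each component is drawn from Normal(mean, sd) restricted to its own
    interquartile range [Q1, Q3] (density-proportional via inverse-CDF
    sampling, or flat when mode='uniform'), then further truncated at zero:
    negative rates are biologically meaningless, so the admissible quantile
    band is intersected with [0, inf) before sampling.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    out = np.empty((size, means.size))
    u = rng.uniform(size=(size, means.size))  # one block per call, fixed order
    for j in range(means.size):
        if sds[j] == 0.0:
            out[:, j] = means[j]
            continue
        lo_q, hi_q = 0.25, 0.75
        q_zero = norm.cdf((0.0 - means[j]) / sds[j])
        lo_q = max(lo_q, q_zero)
        if lo_q >= hi_q:
            # the whole IQR sits below zero; the zero-truncated mass vanishes
            out[:, j] = 0.0
            continue
        if mode == "uniform":
            lo_x = means[j] + sds[j] * norm.ppf(lo_q)
            hi_x = means[j] + sds[j] * norm.ppf(hi_q)
            out[:, j] = lo_x + u[:, j] * (hi_x - lo_x)
        else:
            out[:, j] = means[j] + sds[j] * norm.ppf(lo_q + u[:, j] * (hi_q - lo_q))
    return np.maximum(out, 0.0)


def sample_global_iqr(
    pop: GlobalParams,
    omega: float,
    rng: np.random.Generator,
    size: int = 1,
    total_dose: Optional[float] = None,
    mode: str = "truncated_normal",
) -> List[GlobalParams]:
    """Draw global-parameter vectors from the IQR of N(X_pop, sigma_weighted)."""
    if total_dose is None:
        doses = sorted(pop.kps_by_total_dose)
    else:
        doses = [total_dose]
    samples = {}
    for d in doses:
        means, sds = _pop_arrays(pop, d)
        samples[d] = _sample_iqr_arrays(means, weighted_sigma(sds, omega), rng, size, mode)
    out = []
    for k in range(size):
        first = samples[doses[0]][k]
        out.append(
            GlobalParams(
                kacute_n=first[0],
                alpha_accum_n=first[1],
                kaccum_d=first[2],
                r=first[3],
                kps_by_total_dose={d: samples[d][k, 4] for d in doses},
            )
        )
    return out


def combine(pop_star: IndividualParams, ind: IndividualParams, omega: float) -> WeightedDraw:
    """Mix a population draw towards the individual estimate:
    X_weighted = (1 - omega) X_pop* + omega X_ind."""
    if not (0.0 <= omega <= 1.0):
        raise ValidationError("omega must lie in [0, 1]")
    values = (1.0 - omega) * pop_star.as_array() + omega * ind.as_array()
    return WeightedDraw(values=IndividualParams.from_array(values), omega=omega)


# --------------------------------------------------------------------------
# forward predictions
# --------------------------------------------------------------------------


def predict_global(
    sample_init: float,
    schedule: RadiationSchedule,
    pop: GlobalParams,
    g: GrowthParams,
    cfg: AssimilationConfig,
    spec: DSBRepairSpec = DEFAULT_DSB,
    n0: Optional[float] = None,
    output_times: Optional[Sequence[float]] = None,
) -> TimeCourse:
    """Scenario-1 forecast: one deterministic forward run with X_pop means.

    Individualised only through the initial confluence, seeding density and
    schedule — two samples sharing those yield identical predictions.
    """
    n0 = sample_init if n0 is None else n0
    ind = evaluate_pop_star(pop, n0, schedule)
    if output_times is None:
        output_times = np.arange(0.0, cfg.t_total + 1e-9, 4.0)
    return simulate(
        initial_np=sample_init,
        g=g,
        ind=ind,
        schedule=schedule,
        n0=n0,
        spec=spec,
        t_end=float(np.max(output_times)),
        dt=cfg.dt,
        output_times=output_times,
        sample_id="global-prediction",
    )


def _window_rng(cfg: AssimilationConfig, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.rng_seed), int(i)]))


def _window_times(sample: TimeCourse, i: int, T: float) -> np.ndarray:
    lo, hi = i * T, (i + 1) * T
    mask = (sample.times > lo + 1e-9) & (sample.times <= hi + 1e-9)
    if i == 0:
        mask |= sample.times == 0.0
    return sample.times[mask]


def predict_window(
    sample: TimeCourse,
    i: int,
    pop: GlobalParams,
    ind_i: Optional[IndividualParams],
    g: GrowthParams,
    cfg: AssimilationConfig,
    spec: DSBRepairSpec = DEFAULT_DSB,
    rng: Optional[np.random.Generator] = None,
) -> Prediction:
    """Ensemble forecast of the window [iT, (i+1)T] at the sample's grid.

    Every draw is run forward from t = 0 with Np(0) equal to the first
    measured confluence and Ns(0) = 0; only the window segment is returned.
    """
    if sample.schedule is None:
        raise ValidationError("predict_window requires a treated sample")
    if sample.times[-1] + 1e-9 < i * cfg.T and i > 0:
        raise ValidationError("sample does not cover the assimilation window start")
    omega = cfg.weight(i)
    if omega > 0 and ind_i is None:
        raise ValidationError("an individual estimate is required once omega > 0")
    times = _window_times(sample, i, cfg.T)
    if times.size == 0:
        return Prediction(times=times, median=times, lower=times, upper=times,
                          window_index=np.empty(0, dtype=int))
    if rng is None:
        rng = _window_rng(cfg, i)

    d = sample.schedule.dose
    if cfg.force_global:
        draws = np.array([[pop.kacute_n, pop.alpha_accum_n, pop.kaccum_d, pop.r,
                           kps_lookup(pop, sample.schedule.total_dose)]])
    else:
        means, sds = _pop_arrays(pop, sample.schedule.total_dose)
        draws = _sample_iqr_arrays(means, weighted_sigma(sds, omega), rng,
                                   cfg.n_draws, cfg.iqr_mode)
    # evaluate X_pop* at this sample's dose and seeding density
    kacute = draws[:, 0] * sample.n0
    kaccum = (draws[:, 1] * sample.n0 + 1.0) * draws[:, 2] * d
    r = draws[:, 3]
    kps = draws[:, 4]
    if omega > 0:
        ia = ind_i.as_array()
        kacute = (1.0 - omega) * kacute + omega * ia[0]
        kaccum = (1.0 - omega) * kaccum + omega * ia[1]
        r = (1.0 - omega) * r + omega * ia[2]
        kps = (1.0 - omega) * kps + omega * ia[3]
    curves = simulate_batch(
        initial_np=sample.confluence[0],
        g=g,
        kacute=kacute, kaccum=kaccum, r=r, kps=kps,
        schedule=sample.schedule,
        n0=sample.n0,
        spec=spec,
        t_end=(i + 1) * cfg.T,
        dt=cfg.dt,
        output_times=times,
    )
    median = np.median(curves, axis=1)
    if cfg.interval == "quantile":
        lower = np.percentile(curves, 2.5, axis=1)
        upper = np.percentile(curves, 97.5, axis=1)
    else:
        lower = curves.min(axis=1)
        upper = curves.max(axis=1)
    return Prediction(times=times, median=median, lower=lower, upper=upper,
                      window_index=np.full(times.size, i, dtype=int))


def assimilate(
    sample: TimeCourse,
    pop: GlobalParams,
    g: GrowthParams,
    cfg: AssimilationConfig,
    spec: DSBRepairSpec = DEFAULT_DSB,
) -> Prediction:
    """Full sequential forecast of one well, refined every T hours.

    Step i refits the individual parameters to the data observed in [0, iT]
    (warm-started from the previous step, with a cold restart from the
    population evaluation as fallback), forecasts the window [iT, (i+1)T] with
    the Monte-Carlo ensemble, and concatenates the windows.  The random stream
    is derived from ``cfg.rng_seed`` (one sub-stream per window), so the same
    configuration reproduces the same Prediction exactly.
    """
    if sample.schedule is None:
        raise ValidationError("assimilate requires a treated sample")
    if sample.times[0] != 0.0:
        raise ValidationError("sample must be measured at t = 0")
    t_last = sample.times[-1]
    n_windows = max(int(math.ceil(t_last / cfg.T - 1e-9)), 1)
    pop_star = evaluate_pop_star(pop, sample.n0, sample.schedule)
    ind: Optional[IndividualParams] = None
    segments: List[Prediction] = []
    for i in range(n_windows):
        omega = cfg.weight(i)
        if omega > 0.0 and not cfg.force_global:
            start = ind if ind is not None else pop_star
            fit = fit_individual(
                sample, up_to=i * cfg.T, g=g, cost_flavor=cfg.cost_flavor,
                start=start, t_total=cfg.t_total, dt=cfg.dt, n_starts=1,
                seed=cfg.rng_seed, spec=spec,
            )
            if not fit.converged and start is not pop_star:
                cold = fit_individual(
                    sample, up_to=i * cfg.T, g=g, cost_flavor=cfg.cost_flavor,
                    start=pop_star, t_total=cfg.t_total, dt=cfg.dt, n_starts=1,
                    seed=cfg.rng_seed, spec=spec,
                )
                if cold.cost < fit.cost:
                    fit = cold
            ind = fit.estimates
        segments.append(predict_window(sample, i, pop, ind, g, cfg, spec))
    segments = [s for s in segments if len(s) > 0]
    return Prediction(
        times=np.concatenate([s.times for s in segments]),
        median=np.concatenate([s.median for s in segments]),
        lower=np.concatenate([s.lower for s in segments]),
        upper=np.concatenate([s.upper for s in segments]),
        window_index=np.concatenate([s.window_index for s in segments]),
    )
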