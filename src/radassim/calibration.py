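"""Nonlinear least-squares calibration of growth, global, and per-sample parameters.

All fits run Levenberg–Marquardt (scipy ``least_squares(method="lm")``) on a
smooth reparameterisation that enforces biological bounds: every rate x is
expressed as x = ub * z^2 / (1 + z^2), which maps the unconstrained internal
coordinate z onto [0, ub).  The lower bound at zero reflects the biological
definitions (a negative death rate is meaningless); the upper bounds are
generous — roughly ten times a nominal magnitude — and exist only to keep the
solver in a numerically sane region.

Three estimation problems are covered:

* ``fit_growth``   — (kp, theta, A) from pooled control wells;
* ``fit_global``   — the population parameters (kacute_n, alpha_accum_n,
  kaccum_d, r, and one kps per total dose) jointly from every training well,
  with standard errors forming sigma_pop;
* ``fit_individual`` — (kacute, kaccum, r, kps) from a single well's
  measurements up to a cutoff time, under either the plain sum-of-squares
  cost or the time-weighted ("revised") cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .core import (
    GlobalParams,
    GrowthParams,
    IndividualParams,
    TimeCourse,
    ValidationError,
    evaluate_pop_star,
)
from .dynamics import DEFAULT_DSB, DSBRepairSpec, EulerPlan, simulate_batch

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "cost_basic",
    "cost_revised",
    "fit_growth",
    "fit_global",
    "fit_individual",
]

ParamSet = Union[GrowthParams, GlobalParams, IndividualParams]

# generous upper bounds (~10x nominal magnitudes) for the bounded transform
_UB_GROWTH = {"kp": 0.5, "theta": 1.0, "allee": 5.0}
_UB_GLOBAL = {"kacute_n": 20.0, "alpha_accum_n": 50.0, "kaccum_d": 0.01, "r": 0.5, "kps": 1.0}
_UB_IND = {"kacute": 10.0, "kaccum": 1.0, "r": 0.5, "kps": 1.0}

_FTOL = 1e-8          # relative cost-change convergence tolerance
_MAX_ITER = 500


@dataclass
class FitResult:
    """Outcome of one least-squares calibration."""

    estimates: ParamSet
    standard_errors: Optional[ParamSet]
    cost: float
    converged: bool
    n_residuals: int
    message: str = ""
    multistart_costs: List[float] = field(default_factory=list)


# --------------------------------------------------------------------------
# bounded reparameterisation
# --------------------------------------------------------------------------


def _to_internal(x: np.ndarray, ub: np.ndarray) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=float), 1e-12, ub * (1 - 1e-9))
    return np.sqrt(x / (ub - x))


def _from_internal(z: np.ndarray, ub: np.ndarray) -> np.ndarray:
    z2 = z * z
    return ub * z2 / (1.0 + z2)


def _jac_scale(z: np.ndarray, ub: np.ndarray) -> np.ndarray:
    # |dx/dz| for the delta-method standard errors
    return ub * 2.0 * np.abs(z) / (1.0 + z * z) ** 2


# --------------------------------------------------------------------------
# model evaluation and cost functions
# --------------------------------------------------------------------------


def _curve_params(params: ParamSet, tc: TimeCourse) -> Optional[IndividualParams]:
    """Collapse whatever parameter set was supplied to this curve's rates."""
    if isinstance(params, GrowthParams) or tc.schedule is None:
        return None
    if isinstance(params, GlobalParams):
        return evaluate_pop_star(params, tc.n0, tc.schedule)
    return params


def _residuals_one(
    tc: TimeCourse,
    params: ParamSet,
    g: GrowthParams,
    up_to: Optional[float],
    spec: DSBRepairSpec,
    dt: float,
) -> np.ndarray:
    mask = np.ones(len(tc), dtype=bool) if up_to is None else tc.times <= up_to + 1e-9
    times = tc.times[mask]
    obs = tc.confluence[mask]
    ind = _curve_params(params, tc)
    if isinstance(params, GrowthParams):
        g = params
    if ind is None:
        rates = np.zeros(4)
        schedule = None
    else:
        rates = ind.as_array()
        schedule = tc.schedule
    sim = simulate_batch(
        tc.confluence[0], g, rates[0:1], rates[1:2], rates[2:3], rates[3:4],
        schedule, tc.n0, spec, t_end=times[-1], dt=dt, output_times=times,
    )
    return obs - sim[:, 0]


def _group_key(tc: TimeCourse) -> tuple:
    return (tc.schedule, tuple(tc.times))


def _check_cost_inputs(data: Sequence[TimeCourse], up_to: Optional[float]):
    if len(data) == 0:
        raise ValidationError("cost requires at least one time course")
    for tc in data:
        n = len(tc) if up_to is None else int(np.sum(tc.times <= up_to + 1e-9))
        if n < 2:
            raise ValidationError(
                f"time course {tc.sample_id!r} has fewer than 2 points at or before the cutoff"
            )


def cost_basic(
    data: Sequence[TimeCourse],
    params: ParamSet,
    g: Optional[GrowthParams] = None,
    up_to: Optional[float] = None,
    spec: DSBRepairSpec = DEFAULT_DSB,
    dt: float = 0.01,
) -> float:
    """Plain sum of squared residuals over all curves and times <= up_to."""
    _check_cost_inputs(data, up_to)
    if g is None:
        if not isinstance(params, GrowthParams):
            raise ValidationError("growth parameters g are required for treated-model costs")
        g = params
    total = 0.0
    for tc in data:
        res = _residuals_one(tc, params, g, up_to, spec, dt)
        total += float(np.sum(res * res))
    return total


def cost_revised(
    data: Sequence[TimeCourse],
    params: ParamSet,
    g: Optional[GrowthParams] = None,
    up_to: Optional[float] = None,
    t_total: float = 330.0,
    spec: DSBRepairSpec = DEFAULT_DSB,
    dt: float = 0.01,
) -> float:
    """Time-weighted cost: each squared residual is multiplied by min(t, Ttotal).

    Recent observations matter more for forecasting the next window than the
    earliest ones, so the weight grows linearly with measurement time and
    saturates at the training-set duration Ttotal.
    """
    _check_cost_inputs(data, up_to)
    if g is None:
        if not isinstance(params, GrowthParams):
            raise ValidationError("growth parameters g are required for treated-model costs")
        g = params
    total = 0.0
    for tc in data:
        mask = np.ones(len(tc), dtype=bool) if up_to is None else tc.times <= up_to + 1e-9
        res = _residuals_one(tc, params, g, up_to, spec, dt)
        total += float(np.sum(res * res * np.minimum(tc.times[mask], t_total)))
    return total


# --------------------------------------------------------------------------
# Levenberg-Marquardt driver
# --------------------------------------------------------------------------


def _run_lm(residual_fn, z0: np.ndarray, n_res: int):
    max_nfev = _MAX_ITER * (z0.size + 1)
    if n_res < z0.size:
        # LM needs at least as many residuals as parameters; pad with zeros so
        # early, under-determined individual fits still return a result.
        def padded(z):
            r = residual_fn(z)
            return np.concatenate([r, np.zeros(z0.size - r.size)]) if r.size < z0.size else r
        fn = padded
    else:
        fn = residual_fn
    return least_squares(fn, z0, method="lm", ftol=_FTOL, xtol=1e-10, gtol=1e-10, max_nfev=max_nfev)


def _standard_errors(res, z: np.ndarray, ub: np.ndarray):
    """Delta-method standard errors from the Jacobian at the optimum.

    Returns (sd_in_natural_units, rank_deficient_mask)."""
    jac = np.atleast_2d(res.jac)
    n, p = jac.shape
    dof = max(n - p, 1)
    s2 = 2.0 * res.cost / dof
    jtj = jac.T @ jac
    rank = np.linalg.matrix_rank(jtj, tol=1e-12 * max(np.trace(jtj), 1e-300))
    deficient = np.zeros(p, dtype=bool)
    if rank < p:
        # flag parameters whose column is (numerically) in the null space
        _, s, vt = np.linalg.svd(jtj)
        null = vt[rank:]
        deficient = np.any(np.abs(null) > 1e-6, axis=0)
    cov = np.linalg.pinv(jtj) * s2
    sd_z = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    sd_x = _jac_scale(z, ub) * sd_z
    # a rank-deficient direction carries no information: report the prior width
    sd_x[deficient] = ub[deficient] / 4.0
    return sd_x, bool(deficient.any())


def _multistart(residual_fn, starts: List[np.ndarray], ub: np.ndarray, n_res: int):
    best = None
    costs = []
    for x0 in starts:
        z0 = _to_internal(np.asarray(x0, dtype=float), ub)
        try:
            res = _run_lm(residual_fn, z0, n_res)
        except Exception as exc:  # LM can fail on pathological starts
            logger.debug("LM start failed: %s", exc)
            continue
        costs.append(2.0 * res.cost)
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ValidationError("all optimizer starts failed")
    return best, costs


def _random_starts(rng: np.random.Generator, ub: np.ndarray, n: int) -> List[np.ndarray]:
    """Log-uniform draws over (ub/1e4, ub*0.9) — the optimiser's search prior."""
    lo = ub * 1e-4
    hi = ub * 0.9
    return [np.exp(rng.uniform(np.log(lo), np.log(hi))) for _ in range(n)]


# --------------------------------------------------------------------------
# public fits
# --------------------------------------------------------------------------


def fit_growth(
    controls: Sequence[TimeCourse],
    dt: float = 0.01,
    n_starts: int = 5,
    seed: int = 0,
    start: Optional[GrowthParams] = None,
) -> FitResult:
    """Estimate (kp, theta, A) by a joint fit to all pooled control wells."""
    if len(controls) == 0:
        raise ValidationError("fit_growth requires at least one control time course")
    _check_cost_inputs(controls, None)
    ub = np.array([_UB_GROWTH["kp"], _UB_GROWTH["theta"], _UB_GROWTH["allee"]])
    zero = np.zeros(1)
    plans = [
        (EulerPlan(GrowthParams(0.05, 0.9, 0.1), None, tc.n0, DEFAULT_DSB,
                   tc.times[-1], dt, tc.times),
         tc.confluence[0], tc.confluence)
        for tc in controls
    ]

    def residual_fn(z):
        kp, theta, allee = _from_internal(z, ub)
        try:
            g = GrowthParams(kp=max(kp, 1e-12), theta=min(max(theta, 1e-9), 1.0), allee=allee)
        except ValidationError:
            return np.full(n_res, 1e3)
        return np.concatenate(
            [obs - plan.run(c0, zero, zero, zero, zero, g=g)[:, 0] for plan, c0, obs in plans]
        )

    n_res = sum(len(tc) for tc in controls)
    rng = np.random.default_rng(seed)
    heuristic = np.array([0.05, min(max(max(tc.confluence.max() for tc in controls), 0.3), 0.999), 0.2])
    starts = [heuristic] + _random_starts(rng, ub, max(n_starts - 1, 0))
    if start is not None:
        starts.insert(0, np.array([start.kp, start.theta, start.allee]))
    best, costs = _multistart(residual_fn, starts, ub, n_res)
    x = _from_internal(best.x, ub)
    estimates = GrowthParams(kp=x[0], theta=min(x[1], 1.0), allee=x[2])
    sd, deficient = _standard_errors(best, best.x, ub)
    return FitResult(
        estimates=estimates,
        standard_errors=_growth_sd(sd),
        cost=2.0 * best.cost,
        converged=best.status > 0,
        n_residuals=n_res,
        message="rank-deficient Jacobian" if deficient else best.message,
        multistart_costs=costs,
    )


def _growth_sd(sd: np.ndarray) -> GrowthParams:
    # bypass validation: standard errors share the shape, not the invariants
    g = GrowthParams.__new__(GrowthParams)
    object.__setattr__(g, "kp", float(sd[0]))
    object.__setattr__(g, "theta", float(sd[1]))
    object.__setattr__(g, "allee", float(sd[2]))
    return g


def fit_global(
    training: Sequence[TimeCourse],
    g: GrowthParams,
    dt: float = 0.01,
    n_starts: int = 5,
    seed: int = 0,
    spec: DSBRepairSpec = DEFAULT_DSB,
) -> FitResult:
    """Joint fit of the population parameters to every training well at once.

    One parameter vector (kacute_n, alpha_accum_n, kaccum_d, r, kps per total
    dose) must explain all curves regardless of dose or seeding density; the
    per-curve rates are expanded through the dose/density laws.  Jacobian-based
    standard errors at the optimum populate sigma_pop.
    """
    treated = [tc for tc in training if tc.schedule is not None]
    if len(treated) == 0:
        raise ValidationError("fit_global requires at least one treated time course")
    _check_cost_inputs(treated, None)
    doses = sorted({tc.schedule.total_dose for tc in treated})
    if len({round(tc.n0, 12) for tc in treated}) == 1:
        logger.warning(
            "all training wells share one seeding density; alpha_accum_n and "
            "kaccum_d are not separately identifiable"
        )
    if len(doses) == 1:
        logger.warning("training set spans a single total dose; only one kps is estimable")

    names = ["kacute_n", "alpha_accum_n", "kaccum_d", "r"] + [f"kps_{d:g}" for d in doses]
    ub = np.array(
        [_UB_GLOBAL["kacute_n"], _UB_GLOBAL["alpha_accum_n"], _UB_GLOBAL["kaccum_d"], _UB_GLOBAL["r"]]
        + [_UB_GLOBAL["kps"]] * len(doses)
    )

    def unpack(x: np.ndarray) -> GlobalParams:
        return GlobalParams(
            kacute_n=x[0],
            alpha_accum_n=x[1],
            kaccum_d=x[2],
            r=x[3],
            kps_by_total_dose={d: x[4 + i] for i, d in enumerate(doses)},
        )

    # one kernel call per (schedule, grid) group and eval: everything constant
    # across optimizer iterations is precomputed here
    grouped: Dict[tuple, list] = {}
    for tc in treated:
        grouped.setdefault(_group_key(tc), []).append(tc)
    dose_index = {d: i for i, d in enumerate(doses)}
    groups = []
    for (schedule, times), members in grouped.items():
        times_arr = np.asarray(times)
        n0s = np.array([tc.n0 for tc in members])
        plan = EulerPlan(g, schedule, n0s, spec, times_arr[-1], dt, times_arr)
        groups.append(
            (
                plan,
                n0s,
                schedule.dose,
                dose_index[schedule.total_dose],
                np.array([tc.confluence[0] for tc in members]),
                np.column_stack([tc.confluence for tc in members]),
            )
        )

    def residual_fn(z):
        x = _from_internal(z, ub)
        chunks = []
        for plan, n0s, dose, di, init0, obs in groups:
            kacute = x[0] * n0s
            kaccum = (x[1] * n0s + 1.0) * x[2] * dose
            sim = plan.run(init0, kacute, kaccum,
                           np.full_like(n0s, x[3]), np.full_like(n0s, x[4 + di]))
            chunks.append((obs - sim).ravel(order="F"))
        return np.concatenate(chunks)

    n_res = sum(len(tc) for tc in treated)
    rng = np.random.default_rng(seed)
    starts = [ub * 0.05] + _random_starts(rng, ub, max(n_starts - 1, 0))
    best, costs = _multistart(residual_fn, starts, ub, n_res)
    x = _from_internal(best.x, ub)
    sd, deficient = _standard_errors(best, best.x, ub)
    sigma = GlobalParams(
        kacute_n=sd[0],
        alpha_accum_n=sd[1],
        kaccum_d=sd[2],
        r=sd[3],
        kps_by_total_dose={d: sd[4 + i] for i, d in enumerate(doses)},
    )
    estimates = GlobalParams(
        kacute_n=x[0],
        alpha_accum_n=x[1],
        kaccum_d=x[2],
        r=x[3],
        kps_by_total_dose=dict(zip(doses, x[4:])),
        sigma=sigma,
    )
    return FitResult(
        estimates=estimates,
        standard_errors=sigma,
        cost=2.0 * best.cost,
        converged=best.status > 0,
        n_residuals=n_res,
        message="rank-deficient Jacobian" if deficient else best.message,
        multistart_costs=costs,
    )


def fit_individual(
    sample: TimeCourse,
    up_to: float,
    g: GrowthParams,
    cost_flavor: str = "basic",
    start: Optional[IndividualParams] = None,
    t_total: float = 330.0,
    dt: float = 0.01,
    n_starts: int = 5,
    seed: int = 0,
    spec: DSBRepairSpec = DEFAULT_DSB,
) -> FitResult:
    """Fit one well's (kacute, kaccum, r, kps) to its measurements in [0, up_to].

    Dose per fraction and seeding density are fixed and known for a single
    well, so the collapsed per-sample rates are estimated directly.  With only
    a handful of early measurements the problem is under-determined; the fit
    still returns, flagged unconverged when LM could not make progress.
    """
    if sample.schedule is None:
        raise ValidationError("fit_individual requires a treated time course")
    if cost_flavor not in ("basic", "revised"):
        raise ValidationError(f"unknown cost flavor {cost_flavor!r}")
    n_obs = int(np.sum(sample.times <= up_to + 1e-9))
    if n_obs < 2:
        raise ValidationError("up_to must include at least the first two measurements")
    ub = np.array([_UB_IND["kacute"], _UB_IND["kaccum"], _UB_IND["r"], _UB_IND["kps"]])
    mask = sample.times <= up_to + 1e-9
    times = sample.times[mask]
    obs = sample.confluence[mask]
    weights = np.sqrt(np.minimum(times, t_total)) if cost_flavor == "revised" else None
    plan = EulerPlan(g, sample.schedule, sample.n0, spec, times[-1], dt, times)
    c0 = sample.confluence[0]

    def residual_fn(z):
        x = _from_internal(z, ub)
        res = obs - plan.run(c0, x[0:1], x[1:2], x[2:3], x[3:4])[:, 0]
        return res * weights if weights is not None else res

    rng = np.random.default_rng(seed)
    if start is not None:
        starts = [np.maximum(start.as_array(), 1e-10)]
        starts += _random_starts(rng, ub, max(n_starts - 1, 0))
    else:
        starts = [ub * 0.02] + _random_starts(rng, ub, max(n_starts - 1, 0))
    best, costs = _multistart(residual_fn, starts, ub, n_obs)
    x = _from_internal(best.x, ub)
    sd, deficient = _standard_errors(best, best.x, ub)
    return FitResult(
        estimates=IndividualParams.from_array(x),
        standard_errors=IndividualParams.from_array(np.abs(sd)),
        cost=2.0 * best.cost,
        converged=best.status > 0 and not deficient,
        n_residuals=n_obs,
        message="rank-deficient Jacobian" if deficient else best.message,
        multistart_costs=costs,
    )
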