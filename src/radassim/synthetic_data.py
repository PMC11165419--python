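"""Synthetic cohorts of confluence time courses with realistic study structure.

The raw time-lapse microscopy data behind this framework are not public, so
the generator emulates their statistical structure: cell-line-specific
Allee-logistic growth to a carrying capacity, six fractionation schemes
(16 Gy as 4x4 / 3x5.33 / 2x8; 20 Gy as 4x5 / 3x6.67 / 2x10, 24 h apart),
per-sample heterogeneity of the radiobiological response (log-normal around
population means), additive Gaussian measurement noise on confluence, and the
70/10/20 training/testing/validation split.

Every sample's generating ("true") parameters are retained so calibration and
assimilation can be validated by parameter- and trajectory-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    GlobalParams,
    GrowthParams,
    IndividualParams,
    RadiationSchedule,
    TimeCourse,
    ValidationError,
    build_schedule,
    evaluate_pop_star,
)
from .dynamics import DEFAULT_DSB, DSBRepairSpec, simulate

__all__ = [
    "PopulationSpec",
    "Cohort",
    "default_growth",
    "default_response_means",
    "default_population_spec",
    "draw_sample_params",
    "generate_time_course",
    "generate_controls",
    "generate_cohort",
    "split_counts",
]

#: the six fractionation arms: (total dose Gy, number of fractions)
DEFAULT_SCHEMES: Tuple[Tuple[float, int], ...] = (
    (16.0, 4), (16.0, 3), (16.0, 2), (20.0, 4), (20.0, 3), (20.0, 2),
)


def default_growth(line: str = "9L") -> GrowthParams:
    """Growth parameters for the two emulated glioma lines.

    The carrying capacities (0.98 for the dense-growing 9L-like line, 0.81 for
    the C6-like line) are the two values the study design fixes; kp and the
    Allee constant are generator choices of realistic magnitude.
    """
    if line.upper().startswith("9L"):
        return GrowthParams(kp=0.05, theta=0.98, allee=0.1)
    if line.upper().startswith("C6"):
        return GrowthParams(kp=0.04, theta=0.81, allee=0.15)
    raise ValidationError(f"unknown cell line {line!r}")


def default_response_means() -> GlobalParams:
    """Nominal population-mean response parameters.

    Order-of-magnitude generator choices (the fitted values of the original
    study are unpublished): early death visibly dents high-density wells,
    high-dose two-fraction arms decline between ~100 and ~250 h (per-fraction
    late death peaks at tau = 1/r = 50 h), and senescent conversion is slow
    enough that a radioresistant draw can regrow late in the course.
    """
    return GlobalParams(
        kacute_n=0.5,          # 1/h per unit seeding confluence
        alpha_accum_n=2.0,     # per unit seeding confluence
        kaccum_d=3e-4,         # 1/(h^2 Gy)
        r=0.02,                # 1/h
        kps_by_total_dose={16.0: 0.05, 20.0: 0.08},  # 1/h per unit confluence
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions of one synthetic cohort."""

    growth: GrowthParams = field(default_factory=default_growth)
    response_means: GlobalParams = field(default_factory=default_response_means)
    response_cv: float = 0.3          # per-sample log-normal heterogeneity
    noise_sd: float = 0.01            # additive Gaussian noise, confluence units
    sampling_interval: float = 4.0    # h between images
    duration: float = 330.0           # h of imaging
    seeding_range: Tuple[float, float] = (0.02, 0.2)  # initial confluence N0
    schemes: Tuple[Tuple[float, int], ...] = DEFAULT_SCHEMES
    fraction_interval: float = 24.0   # h between fractions
    dt: float = 0.01                  # Euler step of the forward simulation
    dsb: DSBRepairSpec = DEFAULT_DSB

    def __post_init__(self):
        if self.response_cv < 0:
            raise ValidationError("response_cv must be non-negative")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.duration < self.sampling_interval:
            raise ValidationError("duration must be at least one sampling interval")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 1e-9, self.sampling_interval)


def default_population_spec(line: str = "9L", **overrides) -> PopulationSpec:
    return replace(PopulationSpec(growth=default_growth(line)), **overrides)


@dataclass
class Cohort:
    """Split cohort with per-sample generating truth (for recovery tests)."""

    training: List[TimeCourse]
    testing: List[TimeCourse]
    validation: List[TimeCourse]
    truth: Dict[str, IndividualParams]
    spec: PopulationSpec

    @property
    def all_samples(self) -> List[TimeCourse]:
        return self.training + self.testing + self.validation


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Log-normal with the requested arithmetic mean and coefficient of variation."""
    if cv == 0.0 or mean == 0.0:
        return np.full(size, mean) if size is not None else mean
    s2 = np.log1p(cv * cv)
    mu = np.log(mean) - 0.5 * s2
    return rng.lognormal(mean=mu, sigma=np.sqrt(s2), size=size)


def draw_sample_params(
    spec: PopulationSpec, rng: np.random.Generator
) -> Tuple[IndividualParams, float, RadiationSchedule]:
    """Draw one sample's true response, seeding density and treatment arm.

    Heterogeneity between replicate wells (passage number, cell-cycle state,
    phenotype) is emulated by log-normal variation of each population-level
    response parameter; the collapsed per-sample rates are then evaluated at
    the drawn seeding density and dose.
    """
    n0 = float(rng.uniform(*spec.seeding_range))
    total_dose, n_frac = spec.schemes[rng.integers(len(spec.schemes))]
    schedule = build_schedule(total_dose, n_frac, spec.fraction_interval)
    m = spec.response_means
    draw = GlobalParams(
        kacute_n=float(_lognormal(rng, m.kacute_n, spec.response_cv)),
        alpha_accum_n=float(_lognormal(rng, m.alpha_accum_n, spec.response_cv)),
        kaccum_d=float(_lognormal(rng, m.kaccum_d, spec.response_cv)),
        r=float(_lognormal(rng, m.r, spec.response_cv)),
        kps_by_total_dose={
            d: float(_lognormal(rng, v, spec.response_cv))
            for d, v in m.kps_by_total_dose.items()
        },
    )
    return evaluate_pop_star(draw, n0, schedule), n0, schedule


def generate_time_course(
    params: Optional[IndividualParams],
    n0: float,
    schedule: Optional[RadiationSchedule],
    spec: PopulationSpec,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
) -> TimeCourse:
    """Forward-simulate one well on the imaging grid and add measurement noise."""
    clean = simulate(
        initial_np=n0,
        g=spec.growth,
        ind=params,
        schedule=schedule,
        n0=n0,
        spec=spec.dsb,
        t_end=spec.duration,
        dt=spec.dt,
        output_times=spec.grid,
        sample_id=sample_id,
    )
    conf = clean.confluence
    if spec.noise_sd > 0:
        conf = np.clip(conf + rng.normal(0.0, spec.noise_sd, size=conf.size), 0.0, 1.0)
    return TimeCourse(
        sample_id=sample_id,
        times=clean.times,
        confluence=conf,
        seeding_density_n0=n0,
        schedule=schedule,
    )


def generate_controls(
    n: int, spec: PopulationSpec, rng: np.random.Generator
) -> List[TimeCourse]:
    """Untreated wells for growth-parameter calibration."""
    out = []
    for k in range(n):
        n0 = float(rng.uniform(*spec.seeding_range))
        out.append(generate_time_course(None, n0, None, spec, rng, sample_id=f"ctrl{k:04d}"))
    return out


def split_counts(n: int, split: Sequence[float]) -> List[int]:
    """Largest-remainder allocation of n samples to split fractions."""
    split = np.asarray(split, dtype=float)
    if split.size == 0 or np.any(split < 0) or abs(split.sum() - 1.0) > 1e-9:
        raise ValidationError("split fractions must be non-negative and sum to 1")
    exact = n * split
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    return counts.tolist()


def generate_cohort(
    n: int,
    spec: PopulationSpec,
    rng: np.random.Generator,
    split: Sequence[float] = (0.7, 0.1, 0.2),
) -> Cohort:
    """Generate n treated wells and partition them at random by ``split``."""
    truth: Dict[str, IndividualParams] = {}
    samples: List[TimeCourse] = []
    for k in range(n):
        params, n0, schedule = draw_sample_params(spec, rng)
        sid = f"s{k:04d}"
        samples.append(generate_time_course(params, n0, schedule, spec, rng, sample_id=sid))
        truth[sid] = params
    counts = split_counts(n, split)
    order = rng.permutation(n)
    bounds = np.cumsum([0] + counts)
    groups = [
        [samples[i] for i in order[bounds[j]:bounds[j + 1]]] for j in range(len(counts))
    ]
    while len(groups) < 3:
        groups.append([])
    return Cohort(
        training=groups[0], testing=groups[1], validation=groups[2],
        truth=truth, spec=spec,
    )
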