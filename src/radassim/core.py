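"""Shared domain types for modelling glioma-cell response to fractionated radiotherapy.

The model state variable is live-cell *confluence*: the fraction of well area
covered by live cells, a dimensionless number in [0, 1]. Time is measured in
hours since the first radiation fraction (t = 0 at first dose), doses in Gy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "RadiationSchedule",
    "TimeCourse",
    "GrowthParams",
    "GlobalParams",
    "IndividualParams",
    "ModelState",
    "Prediction",
    "build_schedule",
    "kps_lookup",
    "evaluate_pop_star",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


# --------------------------------------------------------------------------
# treatment schedules
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RadiationSchedule:
    """One fractionation arm: when each fraction is delivered and at what dose.

    ``fraction_times`` are hours since the first fraction (so the first entry
    is 0); ``dose_per_fraction`` is in Gy.  The sum of per-fraction doses must
    match ``total_dose`` to within 0.5 Gy, which tolerates the conventional
    rounding of an equal split (e.g. 16 Gy in three fractions of "5.3 Gy").
    """

    fraction_times: tuple
    dose_per_fraction: tuple
    total_dose: float

    def __post_init__(self):
        ft = tuple(float(t) for t in self.fraction_times)
        dpf = tuple(float(d) for d in self.dose_per_fraction)
        object.__setattr__(self, "fraction_times", ft)
        object.__setattr__(self, "dose_per_fraction", dpf)
        if len(ft) == 0 or len(ft) != len(dpf):
            raise ValidationError("fraction_times and dose_per_fraction must be equal, non-zero length")
        if ft[0] != 0.0:
            raise ValidationError("first fraction must be at t = 0")
        if any(b <= a for a, b in zip(ft, ft[1:])):
            raise ValidationError("fraction_times must be strictly increasing")
        if any(d <= 0 for d in dpf):
            raise ValidationError("all doses must be positive")
        if abs(sum(dpf) - self.total_dose) > 0.5:
            raise ValidationError(
                f"sum of per-fraction doses {sum(dpf):g} Gy does not match total dose "
                f"{self.total_dose:g} Gy within 0.5 Gy"
            )

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_times)

    @property
    def dose(self) -> float:
        """Dose per fraction (Gy) for equal-split schedules."""
        return self.dose_per_fraction[0]


def build_schedule(total_dose: float, n_fractions: int, interval: float = 24.0) -> RadiationSchedule:
    """Equal-split schedule: ``n_fractions`` fractions of ``total_dose / n_fractions``
    Gy, delivered every ``interval`` hours starting at t = 0."""
    if total_dose <= 0:
        raise ValidationError("total_dose must be positive")
    if n_fractions < 1:
        raise ValidationError("n_fractions must be >= 1")
    if interval <= 0:
        raise ValidationError("interval must be positive")
    d = float(total_dose) / int(n_fractions)
    return RadiationSchedule(
        fraction_times=tuple(i * float(interval) for i in range(int(n_fractions))),
        dose_per_fraction=(d,) * int(n_fractions),
        total_dose=float(total_dose),
    )


# --------------------------------------------------------------------------
# measurements
# --------------------------------------------------------------------------


@dataclass
class TimeCourse:
    """Confluence measurements for one culture well.

    ``seeding_density_n0`` is the initial confluence implied by the seeding
    density (dimensionless, same scale as the measurements); it enters the
    radiobiological rate laws, while the first *measured* confluence is used
    as the model's initial condition.  ``schedule`` is None for control wells.
    """

    sample_id: str
    times: np.ndarray
    confluence: np.ndarray
    seeding_density_n0: float
    schedule: Optional[RadiationSchedule] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.confluence = np.asarray(self.confluence, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.confluence.shape:
            raise ValidationError("times and confluence must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValidationError("time course must contain at least one measurement")
        if self.times[0] != 0.0:
            raise ValidationError("first measurement must be at t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.confluence < 0) or np.any(self.confluence > 1):
            raise ValidationError("confluence values must lie in [0, 1]")

    @property
    def n0(self) -> float:
        return self.seeding_density_n0

    def __len__(self) -> int:
        return self.times.size


# --------------------------------------------------------------------------
# parameter sets
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Untreated Allee-logistic growth: dN/dt = kp N (N/theta + A)(1 - N/theta).

    kp    proliferation rate (1/h)
    theta carrying capacity (confluence fraction, in (0, 1])
    allee Allee constant A (dimensionless cooperation at low confluence)
    """

    kp: float
    theta: float
    allee: float

    def __post_init__(self):
        if self.kp <= 0:
            raise ValidationError("kp must be positive")
        if not (0 < self.theta <= 1):
            raise ValidationError("theta must lie in (0, 1]")
        if self.allee < 0:
            raise ValidationError("Allee constant must be non-negative")


@dataclass(frozen=True)
class GlobalParams:
    """Population-level radiobiological parameters (the global fit, X_pop).

    kacute_n          early-death coefficient per unit seeding confluence (1/h per confluence)
    alpha_accum_n     seeding-density coefficient of late death (per confluence)
    kaccum_d          dose coefficient of late death (1/(h^2 Gy))
    r                 decay rate of radiation efficacy (1/h)
    kps_by_total_dose senescence conversion rate (1/h per confluence), one entry
                      per total dose calibrated in the training set
    sigma             per-parameter standard deviations (sigma_pop), same shape,
                      or None when unknown
    """

    kacute_n: float
    alpha_accum_n: float
    kaccum_d: float
    r: float
    kps_by_total_dose: Mapping[float, float]
    sigma: Optional["GlobalParams"] = None

    def __post_init__(self):
        object.__setattr__(
            self,
            "kps_by_total_dose",
            {float(k): float(v) for k, v in dict(self.kps_by_total_dose).items()},
        )
        vals = [self.kacute_n, self.alpha_accum_n, self.kaccum_d, self.r]
        vals += list(self.kps_by_total_dose.values())
        if any(v < 0 for v in vals):
            raise ValidationError("all rates must be non-negative")

    def kps(self, total_dose: float) -> float:
        return kps_lookup(self, total_dose)


def kps_lookup(params: GlobalParams, total_dose: float) -> float:
    """Exact-match lookup of the senescence rate for one total dose.

    The conversion rate is calibrated separately per total dose; there is no
    interpolation between dose levels.
    """
    for dose, value in params.kps_by_total_dose.items():
        if abs(dose - total_dose) < 1e-9:
            return value
    raise ValidationError(f"no kps calibrated for total dose {total_dose:g} Gy")


@dataclass(frozen=True)
class IndividualParams:
    """Sample-specific response parameters (X_ind), with dose and seeding
    density absorbed: kacute (1/h), kaccum (1/h^2), r (1/h), kps (1/h per
    unit confluence)."""

    kacute: float
    kaccum: float
    r: float
    kps: float

    def __post_init__(self):
        if min(self.kacute, self.kaccum, self.r, self.kps) < 0:
            raise ValidationError("all individual rates must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.kacute, self.kaccum, self.r, self.kps], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "IndividualParams":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


def evaluate_pop_star(params: GlobalParams, n0: float, schedule: RadiationSchedule) -> IndividualParams:
    """Evaluate global parameters at one sample's seeding density and schedule.

    The global fit estimates dose- and density-independent coefficients; a
    single sample with known dose per fraction D and seeding confluence N0 is
    governed by the collapsed rates
        kacute = kacute_n * N0
        kaccum = (alpha_accum_n * N0 + 1) * kaccum_d * D
    with r passed through and kps looked up at the schedule's total dose.
    """
    return IndividualParams(
        kacute=params.kacute_n * n0,
        kaccum=(params.alpha_accum_n * n0 + 1.0) * params.kaccum_d * schedule.dose,
        r=params.r,
        kps=kps_lookup(params, schedule.total_dose),
    )


# --------------------------------------------------------------------------
# model state and predictions
# --------------------------------------------------------------------------


@dataclass
class ModelState:
    """Proliferating (Np) and senescent (Ns) confluence compartments."""

    proliferating: float
    senescent: float

    def __post_init__(self):
        if self.proliferating < 0 or self.senescent < 0:
            raise ValidationError("compartment confluences must be non-negative")

    @property
    def total(self) -> float:
        return self.proliferating + self.senescent


@dataclass
class Prediction:
    """Concatenated per-window ensemble prediction.

    ``median`` is the pointwise ensemble median, ``lower``/``upper`` the
    prediction-interval envelope, and ``window_index`` the assimilation step
    that produced each time point.
    """

    times: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    window_index: np.ndarray = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.median = np.asarray(self.median, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.window_index is None:
            self.window_index = np.zeros(self.times.size, dtype=int)
        self.window_index = np.asarray(self.window_index, dtype=int)
        n = self.times.size
        for arr in (self.median, self.lower, self.upper, self.window_index):
            if arr.size != n:
                raise ValidationError("prediction arrays must share one length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("prediction times must be strictly increasing")
        if np.any(self.lower > self.median + 1e-12) or np.any(self.median > self.upper + 1e-12):
            raise ValidationError("prediction interval must bracket the median")

    def __len__(self) -> int:
        return self.times.size
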