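import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import radassim as ra

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def growth_9l() -> ra.GrowthParams:
    return ra.GrowthParams(kp=0.05, theta=0.98, allee=0.1)


@pytest.fixture(scope="session")
def pop_means() -> ra.GlobalParams:
    """Population response means matching the generator defaults."""
    return ra.GlobalParams(
        kacute_n=0.5, alpha_accum_n=2.0, kaccum_d=3e-4, r=0.02,
        kps_by_total_dose={16.0: 0.05, 20.0: 0.08},
    )


@pytest.fixture(scope="session")
def pop_with_sigma(pop_means) -> ra.GlobalParams:
    sigma = ra.GlobalParams(
        kacute_n=0.05, alpha_accum_n=0.5, kaccum_d=3e-5, r=0.002,
        kps_by_total_dose={16.0: 0.005, 20.0: 0.008},
    )
    return ra.GlobalParams(
        kacute_n=pop_means.kacute_n, alpha_accum_n=pop_means.alpha_accum_n,
        kaccum_d=pop_means.kaccum_d, r=pop_means.r,
        kps_by_total_dose=pop_means.kps_by_total_dose, sigma=sigma,
    )


@pytest.fixture(scope="session")
def coarse_spec() -> ra.PopulationSpec:
    """Noise-free, homogeneous, coarse-stepped study spec for fast tests."""
    return ra.default_population_spec("9L", noise_sd=0.0, response_cv=0.0, dt=0.05)


@pytest.fixture(scope="session")
def schedule_16x4() -> ra.RadiationSchedule:
    return ra.build_schedule(16.0, 4, 24.0)


@pytest.fixture(scope="session")
def treated_sample(coarse_spec, pop_means, schedule_16x4) -> ra.TimeCourse:
    """One noise-free treated well generated from the population means."""
    n0 = 0.08
    ind = ra.evaluate_pop_star(pop_means, n0, schedule_16x4)
    rng = np.random.default_rng(11)
    return ra.generate_time_course(ind, n0, schedule_16x4, coarse_spec, rng, sample_id="well")
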