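import numpy as np
import pytest

import radassim as ra
from radassim.core import ValidationError


def _perturbed(tc: ra.TimeCourse, at: float, delta: float) -> ra.TimeCourse:
    conf = tc.confluence.copy()
    conf[np.argmin(np.abs(tc.times - at))] += delta
    return ra.TimeCourse(tc.sample_id, tc.times, conf, tc.seeding_density_n0, tc.schedule)


@pytest.fixture(scope="module")
def exact_fit_inputs(treated_sample, pop_means, growth_9l, schedule_16x4):
    ind = ra.evaluate_pop_star(pop_means, treated_sample.n0, schedule_16x4)
    return treated_sample, ind, growth_9l


class TestCosts:
    def test_zero_residual_data(self, exact_fit_inputs):
        tc, ind, g = exact_fit_inputs
        assert ra.cost_basic([tc], ind, g, dt=0.05) == pytest.approx(0.0, abs=1e-24)
        assert ra.cost_revised([tc], ind, g, dt=0.05) == pytest.approx(0.0, abs=1e-22)

    def test_sum_of_squares_and_additivity(self, exact_fit_inputs):
        tc, ind, g = exact_fit_inputs
        bumped = _perturbed(_perturbed(tc, 100.0, 0.1), 200.0, 0.2)
        one = ra.cost_basic([bumped], ind, g, dt=0.05)
        assert one == pytest.approx(0.1**2 + 0.2**2, rel=1e-9)
        assert ra.cost_basic([bumped, bumped], ind, g, dt=0.05) == pytest.approx(2 * one)

    def test_revised_weight_grows_with_time(self, exact_fit_inputs):
        tc, ind, g = exact_fit_inputs
        bumped = _perturbed(tc, 100.0, 0.1)
        assert ra.cost_revised([bumped], ind, g, dt=0.05) == pytest.approx(
            0.1**2 * 100.0, rel=1e-9
        )

    def test_revised_weight_saturates_at_t_total(self, exact_fit_inputs):
        tc, ind, g = exact_fit_inputs
        bumped = _perturbed(tc, tc.times[-1], 0.1)  # 328 h on the 4-h grid
        assert ra.cost_revised([bumped], ind, g, t_total=200.0, dt=0.05) == pytest.approx(
            0.1**2 * 200.0, rel=1e-9
        )

    def test_empty_data_rejected(self, exact_fit_inputs):
        _, ind, g = exact_fit_inputs
        with pytest.raises(ValidationError):
            ra.cost_basic([], ind, g)

    def test_cutoff_restricts_residuals(self, exact_fit_inputs):
        tc, ind, g = exact_fit_inputs
        bumped = _perturbed(tc, 200.0, 0.1)
        assert ra.cost_basic([bumped], ind, g, up_to=100.0, dt=0.05) == pytest.approx(
            0.0, abs=1e-22
        )


class TestFitGrowth:
    def test_recovers_known_parameters(self, coarse_spec):
        rng = np.random.default_rng(5)
        controls = ra.generate_controls(3, coarse_spec, rng)
        res = ra.fit_growth(controls, dt=coarse_spec.dt, n_starts=3, seed=0)
        true = coarse_spec.growth
        assert res.converged
        assert res.estimates.kp == pytest.approx(true.kp, rel=0.01)
        assert res.estimates.theta == pytest.approx(true.theta, rel=0.01)
        assert res.estimates.allee == pytest.approx(true.allee, rel=0.01)

    def test_truth_start_is_a_fixed_point(self, coarse_spec):
        rng = np.random.default_rng(6)
        controls = ra.generate_controls(2, coarse_spec, rng)
        res = ra.fit_growth(controls, dt=coarse_spec.dt, n_starts=1, seed=0,
                            start=coarse_spec.growth)
        assert res.cost == pytest.approx(0.0, abs=1e-16)
        assert res.estimates.theta == pytest.approx(coarse_spec.growth.theta, rel=1e-4)

    @pytest.mark.parametrize("line,theta", [("9L", 0.98), ("C6", 0.81)])
    def test_recovers_line_specific_carrying_capacity(self, line, theta):
        spec = ra.default_population_spec(line, noise_sd=0.0, response_cv=0.0, dt=0.1)
        rng = np.random.default_rng(7)
        controls = ra.generate_controls(3, spec, rng)
        res = ra.fit_growth(controls, dt=spec.dt, n_starts=2, seed=0)
        assert res.estimates.theta == pytest.approx(theta, rel=0.01)

    def test_requires_controls(self):
        with pytest.raises(ValidationError):
            ra.fit_growth([])


class TestFitIndividual:
    def test_recovers_generating_parameters(self, treated_sample, growth_9l, pop_means):
        true = ra.evaluate_pop_star(pop_means, treated_sample.n0, treated_sample.schedule)
        res = ra.fit_individual(treated_sample, up_to=330.0, g=growth_9l,
                                dt=0.05, n_starts=5, seed=0)
        for name in ("kacute", "kaccum", "r", "kps"):
            assert getattr(res.estimates, name) == pytest.approx(
                getattr(true, name), rel=0.05
            ), name

    def test_early_underdetermined_fit_still_returns(self, treated_sample, growth_9l):
        res = ra.fit_individual(treated_sample, up_to=24.0, g=growth_9l, dt=0.05,
                                n_starts=1, seed=0)
        assert isinstance(res.estimates, ra.IndividualParams)
        assert res.n_residuals == 7  # 4-h grid up to 24 h

    def test_cutoff_before_second_measurement_rejected(self, treated_sample, growth_9l):
        with pytest.raises(ValidationError):
            ra.fit_individual(treated_sample, up_to=2.0, g=growth_9l)

    def test_revised_cost_tracks_late_structure_better(self, coarse_spec, growth_9l,
                                                       pop_means, schedule_16x4):
        # early-time systematic deviation: the plain cost compromises the late
        # fit to absorb it, the time-weighted cost discounts it
        n0 = 0.08
        ind = ra.evaluate_pop_star(pop_means, n0, schedule_16x4)
        rng = np.random.default_rng(3)
        tc = ra.generate_time_course(ind, n0, schedule_16x4, coarse_spec, rng)
        conf = tc.confluence + np.where(tc.times < 150.0, 0.02 * (1 - tc.times / 150.0), 0.0)
        tc = ra.TimeCourse(tc.sample_id, tc.times, np.clip(conf, 0, 1), n0, schedule_16x4)
        late = tc.times >= tc.times[-1] - 48.0

        def late_sse(flavor):
            res = ra.fit_individual(tc, up_to=330.0, g=growth_9l, cost_flavor=flavor,
                                    dt=0.05, n_starts=2, seed=2, start=ind)
            pred = ra.simulate(tc.confluence[0], growth_9l, res.estimates, schedule_16x4,
                               n0=n0, t_end=330.0, dt=0.05, output_times=tc.times)
            return np.sum((tc.confluence[late] - pred.confluence[late]) ** 2)

        assert late_sse("revised") < late_sse("basic")


class TestFitGlobal:
    def test_recovers_shared_parameters(self):
        spec = ra.default_population_spec("9L", noise_sd=0.0, response_cv=0.0, dt=0.05)
        rng = np.random.default_rng(9)
        cohort = ra.generate_cohort(10, spec, rng, split=(1.0, 0.0, 0.0))
        res = ra.fit_global(cohort.training, spec.growth, dt=spec.dt, n_starts=2, seed=0)
        true = spec.response_means
        assert res.converged
        assert res.estimates.kacute_n == pytest.approx(true.kacute_n, rel=0.02)
        assert res.estimates.kaccum_d == pytest.approx(true.kaccum_d, rel=0.02)
        assert res.estimates.r == pytest.approx(true.r, rel=0.02)
        for d in (16.0, 20.0):
            assert res.estimates.kps_by_total_dose[d] == pytest.approx(
                true.kps_by_total_dose[d], rel=0.02
            )
        sig = res.estimates.sigma
        assert sig is not None and sig.kacute_n >= 0.0

    def test_zero_response_cohort_pins_rates_at_zero(self):
        spec = ra.default_population_spec(
            "9L", noise_sd=0.0, response_cv=0.0, dt=0.1,
            response_means=ra.GlobalParams(0.0, 0.0, 0.0, 0.0, {16.0: 0.0, 20.0: 0.0}),
        )
        rng = np.random.default_rng(10)
        cohort = ra.generate_cohort(5, spec, rng, split=(1.0, 0.0, 0.0))
        res = ra.fit_global(cohort.training, spec.growth, dt=spec.dt, n_starts=2, seed=0)
        assert res.estimates.kacute_n < 1e-3
        assert res.estimates.kaccum_d < 1e-6
        for v in res.estimates.kps_by_total_dose.values():
            assert v < 1e-3

    def test_requires_treated_curves(self, growth_9l):
        with pytest.raises(ValidationError):
            ra.fit_global([], growth_9l)
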