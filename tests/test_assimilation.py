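import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

import radassim as ra
from radassim.assimilation import _pop_arrays, _sample_iqr_arrays
from radassim.core import ValidationError


class TestWeightSchedules:
    def test_linear_values(self):
        assert ra.weight_linear(0) == 0.0
        assert ra.weight_linear(5, 24.0, 330.0) == pytest.approx(120.0 / 330.0)
        assert ra.weight_linear(20, 24.0, 330.0) == 1.0  # saturation

    def test_quadratic_values(self):
        assert ra.weight_quadratic(0) == pytest.approx(0.4)
        assert ra.weight_quadratic(1, 24.0, 330.0) == pytest.approx(0.484099173553719)
        assert ra.weight_quadratic(14, 24.0, 330.0) == 1.0  # x = 1

    def test_printed_coefficients_solve_the_constraint_system(self):
        # value 0.5 one window in, maximum of 1 at the end of the course
        coeffs = ra.quadratic_weight_coefficients(T=24.0, t_total=330.0)
        assert tuple(np.round(coeffs, 1)) == ra.QUADRATIC_COEFFS
        a, b, c = coeffs
        x1 = 24.0 / 330.0
        assert a * x1**2 + b * x1 + c == pytest.approx(0.5)
        assert a + b + c == pytest.approx(1.0)
        assert 2 * a + b == pytest.approx(0.0)

    @pytest.mark.parametrize("fn", [ra.weight_linear, ra.weight_quadratic])
    def test_schedule_properties(self, fn):
        vals = [fn(i, 24.0, 330.0) for i in range(0, 40)]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(b >= a for a, b in zip(vals, vals[1:]))  # non-decreasing
        assert vals[-1] == 1.0

    def test_quadratic_dominates_linear(self):
        for i in range(0, 40):
            assert ra.weight_quadratic(i) >= ra.weight_linear(i)

    def test_step_zero_weight_is_forced_global(self):
        for schedule in ("linear", "quadratic"):
            cfg = ra.AssimilationConfig(weight_schedule=schedule)
            assert cfg.weight(0) == 0.0


class TestWeightedSigma:
    def test_limits_and_monotonicity(self):
        s = np.array([1.0, 0.5])
        assert np.array_equal(ra.weighted_sigma(s, 0.0), s)
        assert np.array_equal(ra.weighted_sigma(s, 1.0), s / 2.0)
        widths = [ra.weighted_sigma(s, w)[0] for w in np.linspace(0, 1, 11)]
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_global_params_structure(self, pop_with_sigma):
        shrunk = ra.weighted_sigma(pop_with_sigma.sigma, 1.0)
        assert shrunk.kacute_n == pop_with_sigma.sigma.kacute_n / 2
        assert shrunk.kps_by_total_dose[16.0] == pop_with_sigma.sigma.kps_by_total_dose[16.0] / 2


class TestIqrSampling:
    def test_degenerate_spread_returns_means(self, pop_means):
        rng = np.random.default_rng(0)
        draws = ra.sample_global_iqr(pop_means, 0.3, rng, size=5)
        assert all(d.kacute_n == pop_means.kacute_n for d in draws)
        assert all(d.r == pop_means.r for d in draws)

    def test_draws_confined_to_interquartile_range(self):
        rng = np.random.default_rng(1)
        means = np.array([1.0, 0.02])
        sds = np.array([0.3, 0.004])
        draws = _sample_iqr_arrays(means, sds, rng, size=100_000)
        q1 = means + sds * norm.ppf(0.25)
        q3 = means + sds * norm.ppf(0.75)
        assert np.all(draws >= q1 - 1e-12) and np.all(draws <= q3 + 1e-12)
        # symmetric truncation: the sample median sits at the parent mean
        med = np.median(draws, axis=0)
        assert np.allclose(med, means, rtol=5e-3)

    def test_zero_truncation_applies_after_iqr(self):
        # mean close to zero: the admissible band is the IQR intersected with
        # the non-negative axis
        rng = np.random.default_rng(2)
        draws = _sample_iqr_arrays(np.array([0.001]), np.array([0.1]), rng, size=10_000)
        assert np.all(draws >= 0.0)
        assert np.all(draws <= 0.001 + 0.1 * norm.ppf(0.75) + 1e-12)

    def test_uniform_mode_spans_the_same_band(self):
        rng = np.random.default_rng(3)
        means, sds = np.array([1.0]), np.array([0.3])
        draws = _sample_iqr_arrays(means, sds, rng, size=50_000, mode="uniform")
        assert draws.min() >= (means + sds * norm.ppf(0.25))[0] - 1e-12
        assert draws.max() <= (means + sds * norm.ppf(0.75))[0] + 1e-12


class TestCombine:
    def test_endpoints_and_midpoint(self):
        a = ra.IndividualParams(0.2, 0.002, 0.02, 0.04)
        b = ra.IndividualParams(0.4, 0.004, 0.04, 0.08)
        assert ra.combine(a, b, 0.0).values == a
        assert ra.combine(a, b, 1.0).values == b
        mid = ra.combine(a, b, 0.5).values
        assert mid.kacute == pytest.approx(0.3)

    @given(
        omega=st.floats(0.0, 1.0),
        pa=st.floats(0.0, 1.0),
        pb=st.floats(0.0, 1.0),
    )
    def test_mixture_stays_on_the_segment(self, omega, pa, pb):
        a = ra.IndividualParams(pa, 0.001, 0.01, 0.01)
        b = ra.IndividualParams(pb, 0.001, 0.01, 0.01)
        mixed = ra.combine(a, b, omega).values.kacute
        assert min(pa, pb) - 1e-12 <= mixed <= max(pa, pb) + 1e-12


@pytest.fixture(scope="module")
def fast_cfg():
    return ra.AssimilationConfig(n_draws=30, rng_seed=42, dt=0.05)


class TestPredictions:
    def test_global_prediction_is_shared_across_identical_samples(
        self, pop_means, growth_9l, schedule_16x4, fast_cfg
    ):
        a = ra.predict_global(0.08, schedule_16x4, pop_means, growth_9l, fast_cfg)
        b = ra.predict_global(0.08, schedule_16x4, pop_means, growth_9l, fast_cfg)
        assert np.array_equal(a.confluence, b.confluence)

    def test_degenerate_ensemble_equals_global_prediction(
        self, treated_sample, pop_means, growth_9l, fast_cfg
    ):
        cfg = replace(fast_cfg, n_draws=1)
        win = ra.predict_window(treated_sample, 0, pop_means, None, growth_9l, cfg)
        ref = ra.predict_global(
            treated_sample.confluence[0], treated_sample.schedule, pop_means,
            growth_9l, cfg, n0=treated_sample.n0, output_times=win.times,
        )
        assert np.array_equal(win.median, ref.confluence)

    def test_interval_brackets_median(self, treated_sample, pop_with_sigma, growth_9l, fast_cfg):
        win = ra.predict_window(treated_sample, 0, pop_with_sigma, None, growth_9l, fast_cfg)
        assert np.all(win.lower <= win.median) and np.all(win.median <= win.upper)
        # spread is non-degenerate once the draws diverge from the shared
        # initial condition
        assert np.all(win.upper[1:] > win.lower[1:])

    def test_ensemble_contracts_as_confidence_grows(
        self, treated_sample, pop_with_sigma, growth_9l, fast_cfg
    ):
        ind = ra.evaluate_pop_star(pop_with_sigma, treated_sample.n0, treated_sample.schedule)
        cfg = replace(fast_cfg, n_draws=200)
        early = ra.predict_window(treated_sample, 2, pop_with_sigma, ind, growth_9l, cfg)
        late = ra.predict_window(treated_sample, 12, pop_with_sigma, ind, growth_9l, cfg)
        assert (late.upper - late.lower)[0] < (early.upper - early.lower)[0]

    def test_forced_global_weights_reduce_to_scenario_one(
        self, treated_sample, pop_with_sigma, growth_9l, fast_cfg
    ):
        cfg = replace(fast_cfg, force_global=True)
        pred = ra.assimilate(treated_sample, pop_with_sigma, growth_9l, cfg)
        ref = ra.predict_global(
            treated_sample.confluence[0], treated_sample.schedule, pop_with_sigma,
            growth_9l, cfg, n0=treated_sample.n0, output_times=treated_sample.times,
        )
        assert np.array_equal(pred.times, treated_sample.times)
        assert np.array_equal(pred.median, ref.confluence)

    def test_same_seed_reproduces_bit_identical_prediction(
        self, treated_sample, pop_with_sigma, growth_9l, fast_cfg
    ):
        cfg = replace(fast_cfg, weight_schedule="quadratic", cost_flavor="revised")
        a = ra.assimilate(treated_sample, pop_with_sigma, growth_9l, cfg)
        b = ra.assimilate(treated_sample, pop_with_sigma, growth_9l, cfg)
        assert np.array_equal(a.median, b.median)
        assert np.array_equal(a.lower, b.lower)
        assert np.array_equal(a.upper, b.upper)

    def test_concatenation_covers_the_course_without_gaps(
        self, treated_sample, pop_with_sigma, growth_9l, fast_cfg
    ):
        pred = ra.assimilate(treated_sample, pop_with_sigma, growth_9l, fast_cfg)
        assert np.array_equal(pred.times, treated_sample.times)
        assert np.all(np.diff(pred.times) > 0)
        assert np.all(np.diff(pred.window_index) >= 0)
        assert pred.window_index[0] == 0 and pred.window_index[-1] == 13

    def test_assimilation_captures_regrowth_missed_by_global_mean(
        self, pop_with_sigma, growth_9l, schedule_16x4, coarse_spec
    ):
        # a radioresistant well regrows late; the population mean predicts
        # sustained suppression, so only the assimilated forecast tracks it
        n0 = 0.1
        star = ra.evaluate_pop_star(pop_with_sigma, n0, schedule_16x4)
        weak = ra.IndividualParams(star.kacute * 0.3, star.kaccum * 0.3, star.r, star.kps * 0.3)
        rng = np.random.default_rng(8)
        tc = ra.generate_time_course(weak, n0, schedule_16x4, coarse_spec, rng, "resistant")
        cfg = ra.AssimilationConfig(n_draws=50, rng_seed=5, dt=0.05,
                                    weight_schedule="quadratic", cost_flavor="revised")
        global_pred = ra.predict_global(tc.confluence[0], schedule_16x4, pop_with_sigma,
                                        growth_9l, cfg, n0=n0, output_times=tc.times)
        assim_pred = ra.assimilate(tc, pop_with_sigma, growth_9l, cfg)
        ccc_global = ra.ccc(tc.confluence, global_pred.confluence)
        ccc_assim = ra.ccc(tc.confluence, assim_pred.median)
        assert ccc_assim > ccc_global

    def test_requires_measurement_at_time_zero(self, pop_means, growth_9l, fast_cfg,
                                               schedule_16x4):
        with pytest.raises(ValidationError):
            tc = ra.TimeCourse("x", [4.0, 8.0], [0.1, 0.1], 0.1, schedule_16x4)

    def test_window_needs_individual_estimate_once_weighted(
        self, treated_sample, pop_with_sigma, growth_9l, fast_cfg
    ):
        with pytest.raises(ValidationError):
            ra.predict_window(treated_sample, 3, pop_with_sigma, None, growth_9l, fast_cfg)
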