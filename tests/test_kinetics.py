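import numpy as np
import pytest

from vo2energetics import (KineticsParams, PhaseMarks, accumulated_vo2,
                           bootstrap_fit, epoc, fit_transient, fit_vo2_curve,
                           model_value)

from conftest import series_from_arrays

COHORT_MEAN = KineticsParams(a0=6.8, ap=42.0, tdp=4.3, tau_p=14.2)


class TestModelValue:
    def test_before_delay_is_baseline(self):
        assert model_value(2.0, COHORT_MEAN) == 6.8
        assert model_value(0.0, COHORT_MEAN) == 6.8

    def test_one_time_constant_after_delay(self):
        t = COHORT_MEAN.tdp + COHORT_MEAN.tau_p
        expected = 6.8 + 42.0 * (1 - np.exp(-1))
        assert model_value(t, COHORT_MEAN) == pytest.approx(expected)
        assert model_value(t, COHORT_MEAN) == pytest.approx(6.8 + 0.6321 * 42,
                                                           abs=1e-2)

    def test_off_transient_asymptote(self):
        p = KineticsParams(a0=50.0, ap=40.0, tdp=2.0, tau_p=10.0,
                           asc=5.0, tdsc=20.0, tau_sc=30.0, direction="off")
        assert model_value(5000.0, p) == pytest.approx(5.0, abs=1e-6)

    def test_continuity_at_delays(self):
        p = KineticsParams(a0=6.8, ap=42.0, tdp=4.3, tau_p=14.2,
                           asc=6.0, tdsc=60.0, tau_sc=30.0)
        for td in (p.tdp, p.tdsc):
            eps = 1e-9
            lo, mid, hi = model_value([td - eps, td, td + eps], p)
            assert abs(hi - lo) < 1e-6
            assert mid == pytest.approx(lo, abs=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KineticsParams(a0=5, ap=40, tdp=4, tau_p=0.0)
        with pytest.raises(ValueError):
            KineticsParams(a0=5, ap=40, tdp=10, tau_p=10,
                           asc=1, tdsc=5, tau_sc=10)  # tdsc < tdp


class TestFitting:
    def test_noiseless_on_transient_recovered_exactly(self):
        t = np.arange(0.0, 117.0, 1.0)
        y = model_value(t, COHORT_MEAN)
        fit = fit_vo2_curve(t, y)
        assert fit.converged
        for name in ("a0", "ap", "tdp", "tau_p"):
            est = getattr(fit.params, name)
            true = getattr(COHORT_MEAN, name)
            assert abs(est - true) / true < 1e-4, name

    def test_nested_models_agree_on_mono_data(self):
        t = np.arange(0.0, 117.0, 1.0)
        y = model_value(t, COHORT_MEAN)
        mono = fit_vo2_curve(t, y, model="mono")
        bi = fit_vo2_curve(t, y, model="bi")
        assert bi.rss <= mono.rss + 1e-9
        assert bi.params.asc == pytest.approx(0.0, abs=0.5)
        np.testing.assert_allclose(bi.fitted, mono.fitted, atol=0.2)

    def test_noiseless_off_transient_recovered(self):
        true = KineticsParams(a0=48.0, ap=30.0, tdp=5.0, tau_p=45.0,
                              direction="off")
        t = np.arange(0.0, 300.0, 1.0)
        y = model_value(t, true)
        fit = fit_vo2_curve(t, y, direction="off")
        for name in ("a0", "ap", "tdp", "tau_p"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(true, name), rel=1e-3)

    def test_median_bias_small_under_noise(self):
        """50 noisy replicates: median relative bias < 5% per parameter."""
        rng = np.random.default_rng(101)
        t = np.arange(0.0, 117.0, 1.0)
        mu = model_value(t, COHORT_MEAN)
        a = np.sqrt(3.0) * 2.0
        est = {k: [] for k in ("ap", "tdp", "tau_p")}
        for _ in range(50):
            fit = fit_vo2_curve(t, mu + rng.uniform(-a, a, len(t)))
            for k in est:
                est[k].append(getattr(fit.params, k))
        for k, values in est.items():
            true = getattr(COHORT_MEAN, k)
            bias = abs(np.median(values) - true) / true
            assert bias < 0.05, (k, bias)

    def test_fit_transient_exclusion_and_direction(self):
        marks = PhaseMarks(0.0, 180.0, 297.0, 600.0)
        t = np.arange(0.5, 600.0, 1.0)
        mass = 80.0
        vo2 = np.where(t < 180.0, 6.8 * mass,
                       model_value(t - 180.0, COHORT_MEAN) * mass)
        vo2 = np.where(t >= 297.0, 48.0 * mass, vo2)
        s = series_from_arrays(t, vo2, marks, mass=mass)
        fit = fit_transient(s, "exercise", exclude_s=30.0)
        assert fit.t.min() >= 30.0
        assert fit.params.direction == "on"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            fit_vo2_curve([0.0, 1.0, 2.0], [5.0, 6.0, 7.0])

    def test_deterministic_given_identical_input(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 117.0, 1.0)
        y = model_value(t, COHORT_MEAN) + rng.normal(0, 2, len(t))
        f1 = fit_vo2_curve(t, y)
        f2 = fit_vo2_curve(t, y)
        assert f1.params == f2.params


class TestBootstrap:
    def _noisy_fit(self, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(0.0, 117.0, 1.0)
        y = model_value(t, COHORT_MEAN) + rng.uniform(-3.46, 3.46, len(t))
        return fit_vo2_curve(t, y)

    def test_zero_residuals_collapse_to_point(self):
        t = np.arange(0.0, 117.0, 1.0)
        fit = fit_vo2_curve(t, model_value(t, COHORT_MEAN))
        bf = bootstrap_fit(fit, b=50, seed=0)
        for name, (lo, hi) in bf.ci95.items():
            assert hi - lo == pytest.approx(0.0, abs=1e-4), name

    def test_fixed_seed_bit_identical(self):
        fit = self._noisy_fit()
        b1 = bootstrap_fit(fit, b=100, seed=42)
        b2 = bootstrap_fit(fit, b=100, seed=42)
        for name in b1.bootstrap:
            np.testing.assert_array_equal(b1.bootstrap[name],
                                          b2.bootstrap[name])
        assert b1.ci95 == b2.ci95

    def test_ci_brackets_point_estimate_and_counts_b(self):
        fit = self._noisy_fit(seed=5)
        bf = bootstrap_fit(fit, b=150, seed=7)
        for name in ("ap", "tau_p"):
            lo, hi = bf.ci95[name]
            assert len(bf.bootstrap[name]) == 150
            assert lo <= getattr(bf.params, name) <= hi

    def test_requires_converged_fit(self):
        fit = self._noisy_fit()
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            bootstrap_fit(fit, b=10, seed=0)


class TestIntegrals:
    def _series(self, vo2_l_min, marks=PhaseMarks(0.0, 60.0, 177.0, 600.0),
                mass=80.0):
        t = np.arange(0.25, 600.0, 0.5)
        v = np.broadcast_to(vo2_l_min(t) * 1000.0, t.shape)
        return series_from_arrays(t, v, marks, mass=mass)

    def test_constant_net_rate_rectangle(self):
        s = self._series(lambda t: np.where((t >= 60) & (t < 177), 4.8, 0.6))
        vol, rate = accumulated_vo2(s, baseline_rate_l_min=0.6)
        assert vol == pytest.approx(4.2 * 117 / 60, rel=1e-3)
        assert rate == pytest.approx(4.2, rel=1e-3)

    def test_vo2_at_baseline_gives_zero(self):
        s = self._series(lambda t: np.full_like(t, 0.6))
        vol, rate = accumulated_vo2(s, 0.6)
        assert vol == 0.0 and rate == 0.0

    def test_trapezoid_matches_closed_form_antiderivative(self):
        """Net integral of a0 + ap(1-exp(-(t-td)/tau)) above a0, at 1 Hz,
        agrees with tau*exp(-u/tau) + u - tau within 0.1%."""
        mass, tau, td, ap = 80.0, 14.2, 4.3, 42.0
        marks = PhaseMarks(0.0, 60.0, 177.0, 600.0)
        t = np.arange(60.0, 177.0, 1.0)
        u = t - 60.0
        curve = model_value(u, COHORT_MEAN) * mass
        full = np.concatenate([[30.0], t, [400.0]])
        vo2 = np.concatenate([[6.8 * mass], curve, [6.8 * mass]])
        s = series_from_arrays(full, vo2, marks, mass=mass)
        vol, _ = accumulated_vo2(s, baseline_rate_l_min=6.8 * mass / 1000)
        dur = u[-1]
        exact_ml_kg = ap * (dur - td + tau * np.exp(-(dur - td) / tau) - tau) / 60.0
        # the last sampled value is held over the final second of the phase
        exact_ml_kg += ap * (1 - np.exp(-(dur - td) / tau)) / 60.0
        exact_l = exact_ml_kg * mass / 1000.0
        assert vol == pytest.approx(exact_l, rel=1e-3)

    def test_epoc_zero_when_recovery_at_baseline(self):
        s = self._series(lambda t: np.full_like(t, 0.6))
        assert epoc(s, 0.6) == 0.0

    def test_epoc_matches_closed_form_off_integral(self):
        mass = 80.0
        off = KineticsParams(a0=48.0, ap=41.2, tdp=0.0, tau_p=45.0,
                             direction="off")
        marks = PhaseMarks(0.0, 60.0, 177.0, 600.0)
        t = np.arange(177.0, 600.0, 1.0)
        u = t - 177.0
        vo2 = model_value(u, off) * mass
        s = series_from_arrays(np.concatenate([[30.0], t]),
                               np.concatenate([[6.8 * mass], vo2]),
                               marks, mass=mass)
        w = 300.0
        got = epoc(s, baseline_rate_l_min=6.8 * mass / 1000, window_s=w)
        # integral of (a0 - base) - ap(1-exp(-u/tau)) from 0..w (all > 0 here)
        exact_ml_kg = ((off.a0 - 6.8) * w
                       - off.ap * (w + off.tau_p * np.exp(-w / off.tau_p)
                                   - off.tau_p)) / 60.0
        assert got == pytest.approx(exact_ml_kg * mass / 1000.0, rel=1e-3)

    def test_epoc_monotone_in_window(self, default_profile):
        from vo2energetics import generate_breaths
        s = generate_breaths(default_profile)
        base = default_profile.baseline_vo2_l_min
        values = [epoc(s, base, w) for w in (60.0, 120.0, 300.0, 420.0)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_nonpositive_baseline_rejected(self):
        s = self._series(lambda t: np.full_like(t, 0.6))
        with pytest.raises(ValueError):
            accumulated_vo2(s, 0.0)
        with pytest.raises(ValueError):
            epoc(s, -1.0)
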