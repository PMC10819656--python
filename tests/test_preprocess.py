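import numpy as np
import pandas as pd
import pytest

from vo2energetics import (CohortSpec, NoiseSpec, PhaseMarks, clean,
                           drop_flagged, fit_vo2_curve, generate_breaths,
                           make_subject, model_value, moving_average,
                           sd3_filter, slice_phase, time_bin)

from conftest import series_from_arrays


def flat_noisy_series(marks, n=100, mean=2000.0, seed=0, spike=None):
    rng = np.random.default_rng(seed)
    t = np.arange(0.5, 0.5 + n, 1.0)
    v = np.full(n, mean) + rng.uniform(-50, 50, n)
    if spike is not None:
        v[n // 2] = spike
    return series_from_arrays(t, v, marks)


class TestDropFlagged:
    def test_unflagged_series_unchanged(self, flat_series):
        out, rep = drop_flagged(flat_series)
        assert out.equals(flat_series)
        assert rep.n_artifact_removed == 0

    def test_counts(self, marks):
        t = np.arange(0.5, 100.5, 1.0)
        flags = np.zeros(100, bool)
        flags[[3, 20, 50, 90]] = True
        s = series_from_arrays(t, np.full(100, 2000.0), marks,
                               artifact=flags)
        out, rep = drop_flagged(s)
        assert len(out) == 96
        assert rep.n_artifact_removed == 4
        assert rep.n_input == rep.n_artifact_removed + rep.n_sd_removed + len(out)

    def test_simulator_injection_log_recovered_exactly(self):
        profile = make_subject(CohortSpec(master_seed=21), 1)
        series = generate_breaths(profile)
        injected = set(series.times[series.df["artifact"]])
        out, rep = drop_flagged(series)
        removed = set(series.times) - set(out.times)
        assert removed == injected
        assert rep.n_artifact_removed == len(injected)


class TestSd3Filter:
    def test_constant_series_unchanged_both_modes(self, flat_series):
        for mode in ("band", "local"):
            out, rep = sd3_filter(flat_series, mode=mode)
            assert out.equals(flat_series)
            assert rep.n_sd_removed == 0

    def test_band_mode_matches_bruteforce_band(self, marks):
        """One +5 SD spike (SD of the contaminated set): only breaths the
        recomputed mean +- 3 SD band excludes are removed."""
        base = flat_noisy_series(PhaseMarks(0, 200, 300, 400), n=100)
        v = base.channel("vo2").copy()
        mu0, sd0 = v.mean(), v.std(ddof=1)
        # place the spike so it sits 5 contaminated-SDs above the mean
        for _ in range(50):  # fixed-point iteration on the contaminated SD
            v_spiked = v.copy()
            v_spiked[50] = mu0 + 5 * sd0
            mu0, sd0 = v_spiked.mean(), v_spiked.std(ddof=1)
        s = base.replace_df(base.df.assign(vo2=v_spiked))
        out, rep = sd3_filter(s, mode="band")
        # brute-force oracle
        mu, sd = v_spiked.mean(), v_spiked.std(ddof=1)
        expected = np.flatnonzero(np.abs(v_spiked - mu) > 3 * sd)
        assert list(expected) == [50]
        assert rep.n_sd_removed == 1
        assert s.times[50] not in out.times

    def test_local_mode_removes_unflagged_spike_only(self):
        marks = PhaseMarks(0, 200, 300, 400)
        s = flat_noisy_series(marks, n=150, spike=2600.0)
        out, rep = sd3_filter(s, mode="local")
        assert rep.n_sd_removed == 1
        assert s.times[75] not in out.times

    def test_local_mode_keeps_transient_onset(self, default_profile):
        """A phase-wide band would delete the exercise onset; the
        trend-aware mode must not."""
        profile = default_profile
        series = generate_breaths(profile)
        series, _ = drop_flagged(series)
        out, rep = sd3_filter(series, mode="local")
        ex = slice_phase(out, "exercise", rezero=True)
        assert rep.n_sd_removed == 0
        assert ex.times.min() < 5.0  # earliest breaths survive

    def test_refilter_removes_no_more(self, marks):
        s = flat_noisy_series(PhaseMarks(0, 200, 300, 400), n=100,
                              spike=3000.0)
        once, rep1 = sd3_filter(s, mode="band")
        twice, rep2 = sd3_filter(once, mode="band")
        assert rep2.n_sd_removed <= rep1.n_sd_removed
        assert set(twice.times).issubset(set(once.times))


class TestMovingAverage:
    def test_constant_series_unchanged(self, flat_series):
        assert moving_average(flat_series).equals(flat_series)

    def test_centered_shrinking_window_hand_case(self):
        marks = PhaseMarks(0, 100, 200, 300)
        s = series_from_arrays([1.0, 2.0, 3.0], [0.0, 3.0, 6.0], marks)
        out = moving_average(s, 3)
        np.testing.assert_allclose(out.channel("vo2"), [1.5, 3.0, 4.5])
        np.testing.assert_allclose(out.times, s.times)

    def test_length_preserved(self, default_profile):
        series = generate_breaths(default_profile)
        assert len(moving_average(series)) == len(series)

    def test_does_not_smear_across_phase_boundary(self, marks):
        t = np.array([58.0, 59.0, 61.0, 62.0])  # two baseline, two exercise
        s = series_from_arrays(t, [100.0, 100.0, 4000.0, 4000.0], marks)
        out = moving_average(s, 3)
        np.testing.assert_allclose(out.channel("vo2"),
                                   [100.0, 100.0, 4000.0, 4000.0])


class TestTimeBin:
    def test_hand_case_1hz_ramp(self):
        marks = PhaseMarks(0.0, 100.0, 200.0, 300.0)
        t = np.arange(1.0, 21.0)  # breaths at 1..20 s in baseline
        s = series_from_arrays(t, t, marks)
        out = time_bin(s, 10.0)
        # members 1-9 and 10-19; the breath at t=20 opens a third bin
        np.testing.assert_allclose(out.channel("vo2")[:2], [5.0, 14.5])
        np.testing.assert_allclose(out.times[:2], [5.0, 15.0])
        assert len(out) == 3 and out.channel("vo2")[2] == 20.0

    def test_single_breath_single_bin(self, marks):
        s = series_from_arrays([70.0], [1234.0], marks)
        out = time_bin(s, 10.0)
        assert len(out) == 1
        assert out.channel("vo2")[0] == 1234.0

    def test_mean_rate_conserved_on_uniform_grid(self, marks):
        # binning a linear ramp conserves the VO2.time mass per unit time
        t = np.arange(60.25, 180.0, 0.5)
        v = 1000.0 + 20.0 * (t - 60.0)
        s = series_from_arrays(t, v, marks)
        out = time_bin(s, 10.0)
        raw_mean = np.trapezoid(v, t) / (t[-1] - t[0])
        tb, vb = out.times, out.channel("vo2")
        binned_mean = np.trapezoid(vb, tb) / (tb[-1] - tb[0])
        assert binned_mean == pytest.approx(raw_mean, rel=1e-3)


class TestChain:
    def test_chain_never_grows_or_reorders(self, default_profile):
        series = generate_breaths(default_profile)
        out, rep = clean(series)
        assert len(out) <= len(series)
        assert np.all(np.diff(out.times) > 0)
        assert rep.n_input == len(series)

    def test_chain_preserves_kinetics_on_low_noise_data(self):
        """The editing chain is denoising, not distorting: fitted primary
        parameters move < 5% relative to a raw-data fit."""
        spec = CohortSpec(master_seed=9, noise=NoiseSpec(
            vo2_sd=0.2, artifact_rate=0.0))
        profile = make_subject(spec, 0)
        series = generate_breaths(profile)

        def fit_params(s):
            ex = slice_phase(s, "exercise", rezero=True)
            f = fit_vo2_curve(ex.times, ex.channel("vo2") / s.body_mass)
            return f.params

        raw = fit_params(series)
        # the fitting path of the chain: editing + smoothing, breath-level
        cleaned, _ = clean(series, bin_s=None)
        chained = fit_params(cleaned)
        for name in ("ap", "tau_p"):
            a, b = getattr(raw, name), getattr(chained, name)
            assert abs(b - a) / a < 0.05, name
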