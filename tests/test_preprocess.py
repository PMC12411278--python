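import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import welch
from scipy.special import i0, i1

from voltfield.io_model import OdorDelayAxis
from voltfield.preprocess import (
    ThetaSignal,
    bin_rates,
    bin_spike_counts,
    burst_index,
    despike,
    moving_average,
    odor_score,
    power_spectrum,
    segment_motion,
    speed_score,
    spectrogram_flattened,
    spike_phase_stats,
    theta_extract,
)
from voltfield.synthgen import SynthConfig, generate_cell_session

from conftest import make_session, make_trial, regular_spikes


class TestSegmentMotion:
    def test_all_zeros(self):
        assert segment_motion(np.zeros(5000)).segments == []

    def test_rectangular_bout(self):
        x = np.zeros(5000)
        x[2000:2100] = 0.05
        segs = segment_motion(x)
        assert len(segs.segments) == 1
        s0, s1 = segs.segments[0]
        # filter smears edges by up to half the smoothing window
        assert abs(s0 - 2000) <= 25 and abs(s1 - 2100) <= 25

    def test_merge_close_bouts(self):
        x = np.zeros(5000)
        x[1000:1030] = 0.05
        x[1045:1075] = 0.05  # 15-ms gap -> merged
        segs = segment_motion(x)
        assert len(segs.segments) == 1

    def test_empty_signal_error(self):
        with pytest.raises(ValueError):
            segment_motion(np.array([]))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_invariants_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        x = np.abs(rng.standard_normal(3000)) * 0.02
        segs = segment_motion(x)
        prev_end = None
        for s0, s1 in segs.segments:
            assert s1 - s0 >= 10
            if prev_end is not None:
                assert s0 - prev_end >= 20
                assert s0 >= prev_end
            prev_end = s1


class TestBinRates:
    def test_three_spikes_one_bin(self):
        sess = make_session([make_trial([1010, 1050, 1090])])
        rm = bin_rates(sess, OdorDelayAxis())
        assert rm.rates[0, 0] == 30.0
        assert rm.rates[0, 1:].sum() == 0

    def test_zero_spikes(self):
        sess = make_session([make_trial([]), make_trial([])])
        assert not bin_rates(sess, OdorDelayAxis()).rates.any()

    def test_impulse_smoothing_spreads_fifth(self):
        sess = make_session([make_trial([4010])])  # interior bin 30
        rm = bin_rates(sess, OdorDelayAxis(), smooth_points=5)
        np.testing.assert_allclose(rm.rates[0, 28:33], 2.0)
        assert rm.rates[0, 27] == 0.0

    def test_conservation_unsmoothed(self, synth_session):
        sess, _ = synth_session
        axis = OdorDelayAxis()
        rm = bin_rates(sess, axis)
        counts = bin_spike_counts(sess, axis)
        np.testing.assert_allclose(rm.rates.sum(axis=1) * 0.1, counts.sum(axis=1))

    def test_zscore(self):
        sess = make_session([make_trial([1010, 1020, 1030, 3050])])
        rm = bin_rates(sess, OdorDelayAxis(), zscore=True)
        assert abs(rm.rates[0].mean()) < 1e-12
        assert abs(rm.rates[0].std() - 1.0) < 1e-12

    def test_axis_beyond_trial_errors(self):
        sess = make_session([make_trial([], n=5000)])
        with pytest.raises(ValueError, match="axis"):
            bin_rates(sess, OdorDelayAxis())


class TestBurstIndex:
    def test_example(self):
        assert burst_index(np.array([0, 5, 200, 400])) == pytest.approx(0.25)

    def test_no_bursts(self):
        assert burst_index(np.array([0, 20, 40, 60])) == 0.0

    def test_regular_fast_train(self):
        n = 10
        assert burst_index(np.arange(0, 5 * n, 5)) == pytest.approx((n - 1) / n)

    def test_undefined_below_two_spikes(self):
        assert burst_index(np.array([5])) is None
        assert burst_index(np.array([])) is None


class TestScores:
    def test_speed_score_proportional(self):
        trials = []
        rng = np.random.default_rng(0)
        for _ in range(3):
            counts = rng.integers(0, 5, size=110)
            spikes = np.concatenate(
                [b * 100 + np.arange(c) for b, c in enumerate(counts)]
            ).astype(int)
            loco = np.repeat(counts.astype(float), 100)
            trials.append(make_trial(np.sort(spikes), locomotion=loco))
        score, band = speed_score(make_session(trials), smooth_points=1, n_surrogates=50)
        assert score == pytest.approx(1.0)

    def test_odor_score_boxcar_exact(self):
        # one spike per 100-ms bin during both odor deliveries only
        spikes = np.concatenate(
            [np.arange(1000, 2000, 100), np.arange(7000, 8000, 100)]
        )
        sess = make_session([make_trial(spikes), make_trial(spikes)])
        score, _ = odor_score(sess, smooth_points=1, n_surrogates=50)
        assert score == pytest.approx(1.0)

    def test_flat_rate_excluded(self):
        sess = make_session([make_trial([]), make_trial([])])
        with pytest.warns(UserWarning, match="constant"):
            score, _ = odor_score(sess, n_surrogates=10)
        assert np.isnan(score)


class TestDespike:
    def test_no_spikes_identity(self):
        x = np.random.default_rng(0).standard_normal(2000)
        assert np.array_equal(despike(x, np.array([])), x)

    def test_outside_windows_untouched_and_merge(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        spikes = np.array([1000, 1010])  # windows merge into [995, 1030)
        y = despike(x, spikes)
        changed = np.nonzero(y != x)[0]
        assert changed.min() >= 995 and changed.max() < 1030
        assert np.array_equal(y[:995], x[:995])
        assert np.array_equal(y[1030:], x[1030:])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        x = np.sin(2 * np.pi * 7 * np.arange(3000) / 1000) + 0.1 * rng.standard_normal(3000)
        spikes = np.array([500, 1200, 1210, 2500])
        once = despike(x, spikes)
        twice = despike(once, spikes)
        assert np.array_equal(once, twice)

    def test_band_power_preserved(self):
        cfg = SynthConfig(seed=21, n_trials=5, baseline_rate_hz=10, theta_amp=0.01,
                          noise_sd=0.004)
        sess, gt = generate_cell_session(cfg)

        def band_power(x):
            f, p = welch(x, fs=1000, nperseg=2048)
            sel = (f >= 4) & (f <= 10)
            return np.trapezoid(p[sel], f[sel])

        total_clean = sum(band_power(s) for s in gt.subthreshold)
        total_despiked = sum(
            band_power(despike(t.dff, t.spike_times)) for t in sess.trials
        )
        assert 0.9 < total_despiked / total_clean < 1.1


class TestSpectra:
    def test_sinusoid_peak(self):
        t = np.arange(10000) / 1000.0
        freqs, power = power_spectrum([np.sin(2 * np.pi * 7 * t)])
        assert abs(freqs[np.argmax(power)] - 7.0) <= 0.5

    def test_zero_signal(self):
        freqs, power = power_spectrum([np.zeros(4000)])
        assert np.allclose(power, 0.0)

    def test_concatenates_segments(self):
        t = np.arange(3000) / 1000.0
        seg = np.sin(2 * np.pi * 7 * t)
        f1, p1 = power_spectrum([seg, seg])
        assert abs(f1[np.argmax(p1)] - 7.0) <= 0.5

    def test_flattened_spectrogram_white_noise(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30000)
        times, freqs, sxx = spectrogram_flattened(x)
        mean_spec = sxx.mean(axis=1)
        band = (freqs >= 1) & (freqs <= 100)
        slope = np.polyfit(np.log10(freqs[band]), np.log10(mean_spec[band]), 1)[0]
        assert abs(slope) < 0.3  # no residual 1/f trend

    def test_short_trace_error(self):
        with pytest.raises(ValueError, match="window"):
            spectrogram_flattened(np.zeros(100))


class TestTheta:
    def test_spikes_at_peaks(self):
        t = np.arange(6000)
        x = 0.01 * np.sin(2 * np.pi * 7 * t / 1000.0)
        theta = theta_extract(x)
        spikes = np.round((0.25 + np.arange(30)) / 7 * 1000).astype(int)
        stats = spike_phase_stats(theta, spikes)
        assert stats.vector_length > 0.98
        # analytic-signal convention: oscillation peaks sit at phase 0
        assert abs(stats.preferred_phase) < 0.15

    def test_uniform_phases_low_vector_length(self):
        rng = np.random.default_rng(4)
        theta = ThetaSignal(
            phase=rng.uniform(-np.pi, np.pi, 20000), amplitude=np.ones(20000)
        )
        stats = spike_phase_stats(theta, np.arange(0, 20000, 2))
        assert stats.vector_length < 0.05

    def test_von_mises_closed_form(self):
        rng = np.random.default_rng(5)
        phases = rng.vonmises(0.0, 2.0, size=20000)
        theta = ThetaSignal(phase=phases, amplitude=np.ones_like(phases))
        stats = spike_phase_stats(theta, np.arange(len(phases)))
        assert abs(stats.vector_length - i1(2.0) / i0(2.0)) < 0.02

    def test_no_spikes_undefined(self):
        theta = ThetaSignal(phase=np.zeros(6000), amplitude=np.ones(6000))
        assert spike_phase_stats(theta, np.array([])) is None

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6), st.integers(1, 200))
    def test_phasor_sum_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        phases = rng.uniform(-np.pi, np.pi, n)
        theta = ThetaSignal(phase=phases, amplitude=np.ones(n))
        stats = spike_phase_stats(theta, np.arange(n))
        # brute-force phasor sum
        sx = sum(np.cos(p) for p in phases) / n
        sy = sum(np.sin(p) for p in phases) / n
        assert stats.vector_length == pytest.approx(np.hypot(sx, sy))
        assert stats.preferred_phase == pytest.approx(np.arctan2(sy, sx))


def test_moving_average_mean_preserving_interior():
    x = np.ones(20)
    assert np.allclose(moving_average(x, 5), 1.0)  # edge-normalized
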