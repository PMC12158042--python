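"""Filtering, resampling, normalization, RMSSD and categorical encodings."""

import numpy as np
import pytest
from scipy import signal as sps

from cogfuse.preprocess import (
    NormalizationSpec,
    butter_lowpass,
    compute_rmssd,
    encode_difficulty,
    encode_gaze_event,
    encode_humidity,
    encode_noise,
    gaze_events_to_signal,
    normalize_baseline,
    normalize_task_counts,
    notch_filter,
    resample_uniform,
)


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


def _steady(x, frac=0.25):
    n = len(x)
    return x[int(n * frac) : int(n * (1 - frac))]


class TestNotch:
    def test_dc_preserved(self):
        x = np.ones(4096)
        assert np.allclose(notch_filter(x, 1024.0, 50.0), 1.0, atol=1e-6)

    def test_mains_attenuated_20db(self):
        fs, f0 = 1024.0, 50.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = notch_filter(x, fs, f0)
        att_db = 20 * np.log10(_rms(_steady(y)) / _rms(_steady(x)))
        assert att_db <= -20.0
        # frequency-response oracle: designed notch at f0 is a deep null
        b, a = sps.iirnotch(f0, 30.0, fs=fs)
        _, h = sps.freqz(b, a, worN=[f0], fs=fs)
        assert 20 * np.log10(np.abs(h[0])) <= -20.0

    def test_passband_within_1db(self):
        fs = 1024.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        y = notch_filter(x, fs, 50.0)
        att_db = 20 * np.log10(_rms(_steady(y)) / _rms(_steady(x)))
        assert abs(att_db) < 1.0

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="notch above Nyquist"):
            notch_filter(np.ones(100), 80.0, 50.0)


class TestButterworth:
    def test_dc_gain_unity(self):
        x = np.full(4096, 2.5)
        assert np.allclose(butter_lowpass(x, 1024.0, 1.0), 2.5, atol=1e-6)

    def test_minus_3db_at_cutoff(self):
        # magnitude response of the designed (single-pass) filter
        for fs, cutoff in ((1024.0, 110.0), (32.0, 1.0), (1024.0, 0.05)):
            sos = sps.butter(2, cutoff, btype="low", fs=fs, output="sos")
            _, h = sps.sosfreqz(sos, worN=[cutoff], fs=fs)
            assert 20 * np.log10(np.abs(h[0])) == pytest.approx(-3.01, abs=0.1)

    def test_stopband_at_10x_cutoff(self):
        fs, cutoff = 1024.0, 5.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * cutoff * t)
        y = butter_lowpass(x, fs, cutoff)
        att_db = 20 * np.log10(_rms(_steady(y)) / _rms(_steady(x)))
        assert att_db <= -35.0
        sos = sps.butter(2, cutoff, btype="low", fs=fs, output="sos")
        _, h = sps.sosfreqz(sos, worN=[10 * cutoff], fs=fs)
        assert 20 * np.log10(np.abs(h[0])) <= -35.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            butter_lowpass(np.ones(100), 32.0, 16.0)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=2048), rng.normal(size=2048)
        a, b = 1.7, -0.4
        lhs = butter_lowpass(a * x + b * y, 256.0, 3.0)
        rhs = a * butter_lowpass(x, 256.0, 3.0) + b * butter_lowpass(y, 256.0, 3.0)
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestResample:
    def test_constant_preserved(self):
        out = resample_uniform(np.full(1000, 1.3), 100.0, 32.0)
        assert np.allclose(out, 1.3)

    def test_identity_rate(self):
        x = np.arange(10.0)
        assert np.array_equal(resample_uniform(x, 32.0, 32.0), x)

    def test_ramp_upsampling_exact(self):
        # 1 Hz ramp 0..1 over 10 s upsampled to 1024 Hz matches the line
        x = np.linspace(0, 1, 11)
        out = resample_uniform(x, 1.0, 1024.0)
        t = np.arange(out.size) / 1024.0
        assert np.max(np.abs(out - t / 10.0)) < 1e-9

    def test_duration_preserved(self):
        out = resample_uniform(np.zeros(100), 100.0, 32.0)
        assert abs((out.size - 1) / 32.0 - 99 / 100.0) <= 1 / 32.0

    def test_band_limited_round_trip(self):
        t = np.arange(0, 600, 1 / 32.0)
        x = 1 + 0.3 * np.sin(2 * np.pi * 0.03 * t)
        back = resample_uniform(resample_uniform(x, 32.0, 1024.0), 1024.0, 32.0)
        n = min(back.size, x.size)
        rel = np.max(np.abs(back[:n] - x[:n])) / np.max(np.abs(x))
        assert rel < 1e-3

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="cannot resample"):
            resample_uniform(np.array([1.0]), 1.0, 10.0)


class TestNormalization:
    def test_self_normalization_is_one(self):
        spec = NormalizationSpec(72.0, (0.0, 2.0))
        assert normalize_baseline(np.array([72.0]), spec)[0] == pytest.approx(1.0)

    def test_clipping_bounds(self):
        spec02 = NormalizationSpec(1.0, (0.0, 2.0))
        assert normalize_baseline(np.array([3.0]), spec02)[0] == 2.0
        spec12 = NormalizationSpec(1.0, (1.0, 2.0))
        assert normalize_baseline(np.array([0.5]), spec12)[0] == 1.0

    def test_baseline_mean_property(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.8, 1.2, 500) * 63.0
        spec = NormalizationSpec(float(x.mean()), (0.0, 2.0))
        out = normalize_baseline(x, spec)
        assert out.mean() == pytest.approx(1.0, abs=1e-9)
        assert out.min() >= 0.0 and out.max() <= 2.0

    def test_invalid_baseline(self):
        with pytest.raises(ValueError, match="invalid baseline"):
            NormalizationSpec(0.0, (0.0, 2.0))
        with pytest.raises(ValueError, match="invalid baseline"):
            NormalizationSpec(float("nan"), (1.0, 2.0))

    def test_only_protocol_ranges_allowed(self):
        with pytest.raises(ValueError):
            NormalizationSpec(1.0, (0.0, 1.0))


class TestRmssd:
    def test_constant_series_zero(self):
        _, v = compute_rmssd([800.0, 800.0, 800.0])
        assert v[0] == pytest.approx(0.0)

    def test_single_difference(self):
        _, v = compute_rmssd([800.0, 810.0])
        assert v[0] == pytest.approx(10.0)

    def test_hand_computed_value(self):
        # successive diffs 40, -30, 15 -> sqrt(mean of squares) = sqrt(2725/3)
        _, v = compute_rmssd([780.0, 820.0, 790.0, 805.0])
        assert v[0] == pytest.approx(np.sqrt(2725.0 / 3.0), abs=1e-9)

    def test_shift_invariance(self):
        # one window spanning the whole series: the interval set is identical,
        # so a constant offset leaves the successive differences unchanged
        rng = np.random.default_rng(8)
        rr = rng.uniform(700, 900, 120)
        _, a = compute_rmssd(rr, window=1e6)
        _, b = compute_rmssd(rr + 150.0, window=1e6)
        assert a[0] == pytest.approx(b[0])

    def test_sparse_window_marked_missing(self):
        # one interval onsets inside [60, 90): not enough for a difference
        _, v = compute_rmssd([800.0] * 10 + [62000.0, 800.0], window=30.0, step=30.0)
        assert np.isnan(v).any()


class TestEncodings:
    @pytest.mark.parametrize(
        "fn,label,expected",
        [
            (encode_noise, "low", 0.0),
            (encode_noise, "medium", 0.5),
            (encode_noise, "high", 1.0),
            (encode_difficulty, "medium", 0.5),
            (encode_gaze_event, "fixation", 2.0),
            (encode_gaze_event, "saccade", 1.0),
        ],
    )
    def test_exact_codes(self, fn, label, expected):
        assert fn(label) == expected

    def test_unknown_label_lists_vocabulary(self):
        with pytest.raises(ValueError, match="fixation"):
            encode_gaze_event("blink")

    def test_humidity_scaling(self):
        assert encode_humidity(45.0) == pytest.approx(0.45)
        with pytest.raises(ValueError):
            encode_humidity(150.0)


class TestTaskCounts:
    def test_test1_items_column(self):
        items = [3, 1, 1, 1, 1, 4, 3, 0, 6, 0, 1, 1]  # max is task 9's 6
        out = normalize_task_counts(items)
        assert out[8] == pytest.approx(1.0)
        assert out[0] == pytest.approx(0.5)

    def test_singleton(self):
        assert normalize_task_counts([2])[0] == pytest.approx(1.0)

    def test_test2_operations_column(self):
        ops = [8, 4, 8, 12, 8, 2, 2, 5, 1, 2, 6]  # max is task 4's 12
        out = normalize_task_counts(ops)
        assert out[3] == pytest.approx(1.0)
        assert out[8] == pytest.approx(1.0 / 12.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="degenerate task table"):
            normalize_task_counts([0, 0, 0])


class TestGazeStepSignal:
    def test_codes_and_hold(self):
        events = [(0.0, "fixation"), (1.0, "saccade"), (1.5, "unclassified"), (2.0, "fixation")]
        out = gaze_events_to_signal(events, fs=4.0, duration=3.0)
        # unclassified at 1.5 holds the previous saccade code
        assert out[0] == 2.0 and out[4] == 1.0 and out[6] == 1.0 and out[8] == 2.0

    def test_before_first_event_holds_first_code(self):
        out = gaze_events_to_signal([(1.0, "saccade")], fs=2.0, duration=2.0)
        assert np.all(out == 1.0)
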