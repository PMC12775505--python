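import numpy as np
import pytest

from fidgetlab import (align_streams, frame_labels, generate_cohort,
                       resample_linear, segment_windows)
from fidgetlab.config import CohortConfig, PreprocessConfig
from fidgetlab.preprocessing import (FM_MINUS, FM_PLUS, INVALID,
                                     AlignmentError)
from fidgetlab.synthetic import AnnotationInterval

from conftest import make_recording


def brute_force_offset(a, b, fs, max_lag_s):
    """Naive correlation scan oracle for stream alignment."""
    best, best_lag = -np.inf, 0
    L = int(round(max_lag_s * fs))
    for lag in range(-L, L + 1):
        if lag >= 0:
            xa, xb = a[:len(a) - lag or None], b[lag:]
        else:
            xa, xb = a[-lag:], b[:len(b) + lag]
        n = min(len(xa), len(xb))
        xa, xb = xa[:n], xb[:n]
        if np.std(xa) == 0 or np.std(xb) == 0:
            continue
        c = np.corrcoef(xa, xb)[0, 1]
        if c > best + 1e-12 or (abs(c - best) <= 1e-12 and
                                abs(lag) < abs(best_lag)):
            best, best_lag = c, lag
    return best_lag / fs


class TestAlignStreams:
    def test_identical_series_zero_offset(self):
        rng = np.random.default_rng(0)
        a = np.cumsum(rng.normal(size=500))
        assert align_streams(a, a, 100.0, 1.0) == 0.0

    def test_constructed_two_second_delay(self):
        rng = np.random.default_rng(1)
        base = np.convolve(rng.normal(size=2000), np.ones(25) / 25, "same")
        fs = 100.0
        delay = int(2.0 * fs)
        b = np.concatenate([np.zeros(delay), base])[: base.size]
        assert align_streams(base, b, fs, 3.0) == pytest.approx(2.0)

    def test_fractional_shift_recovered_within_one_sample(self):
        fs = 30.0
        rng = np.random.default_rng(2)
        t_hi = np.arange(0, 40, 1 / 300)
        smooth = np.interp(t_hi, np.arange(0, 41), rng.normal(size=41))
        t = np.arange(0, 35, 1 / fs)
        a = np.interp(t, t_hi, smooth)
        b = np.interp(t + 0.37, t_hi, smooth)  # b leads; delayed by -0.37
        est = align_streams(a, b, fs, 1.0)
        assert abs(est - (-0.37)) <= 1 / fs
        assert est == pytest.approx(brute_force_offset(a, b, fs, 1.0))

    def test_oracle_equivalence_random_series(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a = np.convolve(rng.normal(size=400), np.ones(9) / 9, "same")
            shift = rng.integers(-20, 21)
            b = np.roll(a, shift)
            assert align_streams(a, b, 50.0, 0.5) == pytest.approx(
                brute_force_offset(a, b, 50.0, 0.5))

    def test_constant_series_rejected(self):
        with pytest.raises(AlignmentError):
            align_streams(np.ones(100), np.arange(100.0), 10.0, 1.0)


class TestResampleLinear:
    def test_linear_ramp_is_fixed_point(self):
        t = np.arange(0, 2, 1 / 200)
        out = resample_linear(t, 200.0, 100.0)
        expected = np.arange(out.size) / 100.0
        assert np.allclose(out, expected, atol=1e-12)

    def test_identity_when_rates_match(self):
        x = np.random.default_rng(0).normal(size=300)
        assert np.array_equal(resample_linear(x, 100.0, 100.0), x)

    def test_sine_downsample_accuracy(self):
        t = np.arange(0, 1, 1 / 200)
        x = np.sin(2 * np.pi * 7 * t)
        out = resample_linear(x, 200.0, 100.0)
        t_out = np.arange(out.size) / 100.0
        assert np.max(np.abs(out - np.sin(2 * np.pi * 7 * t_out))) < 0.01

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            resample_linear(np.array([1.0]), 100.0, 50.0)

    def test_multichannel_shape(self):
        x = np.random.default_rng(1).normal(size=(201, 3))
        out = resample_linear(x, 200.0, 100.0)
        assert out.shape == (101, 3)


class TestFrameLabels:
    def test_no_annotations_all_negative(self):
        labels = frame_labels([], 2.0, 100.0)
        assert labels.size == 201
        assert np.all(labels == FM_MINUS)

    def test_half_open_boundary(self):
        labels = frame_labels([AnnotationInterval(1.0, 2.0, "FM")], 3.0, 100.0)
        assert labels[99] == FM_MINUS
        assert labels[100] == FM_PLUS
        assert labels[199] == FM_PLUS
        assert labels[200] == FM_MINUS

    def test_invalid_takes_precedence(self):
        labels = frame_labels([AnnotationInterval(0.0, 3.0, "FM"),
                               AnnotationInterval(2.0, 4.0, "INVALID")],
                              5.0, 100.0)
        assert np.all(labels[200:300] == INVALID)
        assert np.all(labels[:200] == FM_PLUS)

    def test_interval_beyond_duration_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipping"):
            labels = frame_labels([AnnotationInterval(0.0, 9.0, "FM")],
                                  2.0, 100.0)
        assert np.all(labels == FM_PLUS)


class TestSegmentWindows:
    def test_all_fm_recording_yields_all_fm_windows(self):
        rec = make_recording(10.0, [(0.0, 10.0, "FM")])
        w = segment_windows(rec)
        assert len(w) == 10
        assert np.all(w.labels == 1)
        assert w.imu.shape == (10, 4, 100, 6)
        assert w.pose.shape == (10, 30, 99)

    def test_55_percent_majority_excluded(self):
        rec = make_recording(1.0, [(0.0, 0.55, "FM")])
        w = segment_windows(rec)
        assert len(w) == 0
        assert w.n_excluded == 1

    def test_61_percent_majority_kept(self):
        rec = make_recording(1.0, [(0.0, 0.61, "FM")])
        w = segment_windows(rec)
        assert len(w) == 1 and w.labels[0] == 1

    def test_invalid_majority_discarded(self):
        rec = make_recording(2.0, [(0.0, 1.0, "INVALID")])
        w = segment_windows(rec)
        assert w.n_invalid_discarded == 1
        assert len(w) == 1  # the second, clean window survives

    def test_short_recording_warns_empty(self):
        rec = make_recording(0.8)
        with pytest.warns(UserWarning):
            w = segment_windows(rec)
        assert len(w) == 0

    def test_label_conservation_and_oracle(self):
        """Naive per-window majority recount matches segment_windows."""
        cfg = CohortConfig(duration_fixed_s=25.0)
        recs, _ = generate_cohort(8, cfg, 31)
        for rec in recs:
            w = segment_windows(rec)
            labels = frame_labels(rec.annotations, rec.duration_s, 100.0)
            n_windows = int(rec.duration_s)
            kept = {}
            n_excl = n_inv = 0
            for i in range(n_windows):
                chunk = labels[i * 100:(i + 1) * 100]
                counts = [(chunk == c).sum() for c in (0, 1, 2)]
                top = max(counts)
                if counts.count(top) > 1 or top < 60:
                    n_excl += 1
                elif counts.index(top) == 2:
                    n_inv += 1
                else:
                    kept[i] = counts.index(top)
            assert w.n_total_windows == n_windows
            assert w.n_excluded == n_excl
            assert w.n_invalid_discarded == n_inv
            assert list(w.window_start_s.astype(int)) == sorted(kept)
            assert [int(l) for l in w.labels] == [kept[i] for i in
                                                  sorted(kept)]

    def test_windows_do_not_overlap_and_cover_span(self):
        rec = make_recording(8.0, [(0.0, 8.0, "FM")])
        w = segment_windows(rec)
        starts = np.sort(w.window_start_s)
        assert np.all(np.diff(starts) >= 1.0)
        assert starts[0] >= 0 and starts[-1] + 1.0 <= rec.duration_s + 1e-9

    def test_clock_offset_recovered_by_alignment(self):
        """An IMU stream on a shifted clock realigns to the reference."""
        import copy
        rec0 = make_recording(30.0, [(0.0, 30.0, "FM")], freq_hz=0.4,
                              noise=0.002)
        rec = copy.deepcopy(rec0)
        shift = 0.8
        t = rec.imu_t[0]
        rec.imu[0] = np.stack([np.interp(t + shift, t, rec.imu[0][:, ch])
                               for ch in range(6)], axis=1)
        truth = segment_windows(rec0, config=PreprocessConfig(align=False))
        aligned = segment_windows(rec)
        plain = segment_windows(rec, config=PreprocessConfig(align=False))
        sl = slice(2, len(truth) - 2)
        err_aligned = np.abs(aligned.imu[sl, 0, :, 0] -
                             truth.imu[sl, 0, :, 0]).mean()
        err_plain = np.abs(plain.imu[sl, 0, :, 0] -
                           truth.imu[sl, 0, :, 0]).mean()
        assert err_aligned < 0.25 * err_plain
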