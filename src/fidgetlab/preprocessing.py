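"""Stream alignment, resampling, and majority-label windowing.

A recording enters as four 200 Hz IMU streams on their own device clocks, a
30 Hz pose track on the reference clock, and interval annotations. It
leaves as non-overlapping 1-second windows — per-IMU frames of shape
100 x 6 at the 100 Hz target rate and pose frames of shape 30 x 99 — each
carrying a single FM+/FM- label decided by a 60% majority of the 100 Hz
frame labels, with ambiguous windows excluded and invalid-majority windows
discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .config import PreprocessConfig
from .synthetic import (LABEL_FM, LABEL_INVALID, N_IMU_CHANNELS, N_SENSORS,
                        N_POSE_CHANNELS, AnnotationInterval, Recording)

# Frame label codes on the resampled grid.
FM_MINUS, FM_PLUS, INVALID = 0, 1, 2

POSE_HZ = 30.0


class AlignmentError(ValueError):
    """Raised when stream alignment is ill-posed (e.g. constant input)."""


# ---------------------------------------------------------------------------
# Alignment and resampling
# ---------------------------------------------------------------------------

def align_streams(series_a: np.ndarray, series_b: np.ndarray, fs_hz: float,
                  max_lag_s: float) -> float:
    """Offset (s) of ``series_b`` relative to ``series_a``.

    Scans integer lags in [-max_lag_s, +max_lag_s] and returns the lag
    maximizing the normalized cross-correlation of the overlapping parts.
    A positive result means ``series_b`` is delayed: subtracting the offset
    from b's timestamps aligns it to a. Ties are broken toward the smallest
    absolute offset.
    """
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if max_lag_s <= 0:
        raise ValueError("max_lag_s must be positive")
    if np.std(a) == 0 or np.std(b) == 0:
        raise AlignmentError(
            "constant input series: correlation is undefined")
    max_lag = int(round(max_lag_s * fs_hz))
    best_corr, best_lag = -np.inf, 0
    # Visit lags by increasing |lag| so ties resolve to the smallest offset.
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda l: (abs(l), l)):
        if lag >= 0:
            xa, xb = a[: a.size - lag or None], b[lag:]
        else:
            xa, xb = a[-lag:], b[: b.size + lag]
        n = min(xa.size, xb.size)
        if n < 2:
            continue
        xa, xb = xa[:n], xb[:n]
        sa, sb = np.std(xa), np.std(xb)
        if sa == 0 or sb == 0:
            continue
        corr = np.mean((xa - xa.mean()) * (xb - xb.mean())) / (sa * sb)
        if corr > best_corr + 1e-12:
            best_corr, best_lag = corr, lag
    return best_lag / fs_hz


def resample_linear(series: np.ndarray, native_hz: float,
                    target_hz: float = 100.0) -> np.ndarray:
    """Linear-interpolation resampling on a uniform grid.

    The output covers the same time range as the input; a trailing partial
    target interval is truncated.
    """
    x = np.asarray(series, dtype=float)
    if native_hz <= 0 or target_hz <= 0:
        raise ValueError("sampling rates must be positive")
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise ValueError("resampling needs at least 2 samples")
    t_in = np.arange(n) / native_hz
    n_out = int(np.floor(t_in[-1] * target_hz)) + 1
    t_out = np.arange(n_out) / target_hz
    out = np.stack([np.interp(t_out, t_in, x[:, c])
                    for c in range(x.shape[1])], axis=1)
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Frame labels
# ---------------------------------------------------------------------------

def frame_labels(annotations: Sequence[AnnotationInterval], duration_s: float,
                 grid_hz: float = 100.0) -> np.ndarray:
    """Per-frame label codes on the target grid.

    Frames sit at t_i = i / grid_hz for t_i in [0, duration]. Membership in
    an interval uses the half-open convention [start_s, end_s). Invalid
    intervals take precedence over fidgety ones.
    """
    n = int(np.floor(duration_s * grid_hz)) + 1
    labels = np.full(n, FM_MINUS, dtype=np.int8)

    def _span(iv: AnnotationInterval):
        if iv.end_s > duration_s + 1e-9:
            warnings.warn(
                f"interval [{iv.start_s}, {iv.end_s}) extends beyond the "
                f"{duration_s} s recording; clipping", stacklevel=3)
        i0 = max(int(np.ceil(iv.start_s * grid_hz - 1e-9)), 0)
        i1 = min(int(np.ceil(iv.end_s * grid_hz - 1e-9)), n)
        return i0, i1

    for iv in annotations:
        if iv.label == LABEL_FM:
            i0, i1 = _span(iv)
            labels[i0:i1] = FM_PLUS
    for iv in annotations:
        if iv.label == LABEL_INVALID:
            i0, i1 = _span(iv)
            labels[i0:i1] = INVALID
    return labels


# ---------------------------------------------------------------------------
# Window container
# ---------------------------------------------------------------------------

@dataclass
class WindowDataset:
    """Labelled 1-second frames from one or more recordings.

    ``labels`` uses 1 for FM+ and 0 for FM-. The exclusion counters keep
    the label-conservation identity: kept + excluded + invalid_discarded
    equals the total number of raw windows.
    """

    imu: np.ndarray            # (n, 4, win*target_hz, 6)
    pose: np.ndarray           # (n, win*30, 99)
    labels: np.ndarray         # (n,) int8, 1 = FM+, 0 = FM-
    subject_ids: np.ndarray    # (n,) str
    window_start_s: np.ndarray  # (n,)
    majority_fraction: np.ndarray  # (n,) in [majority_threshold, 1]
    n_excluded: int = 0
    n_invalid_discarded: int = 0

    def __len__(self) -> int:
        return self.labels.size

    @property
    def n_total_windows(self) -> int:
        return len(self) + self.n_excluded + self.n_invalid_discarded

    @property
    def subjects(self) -> List[str]:
        seen: dict = {}
        for s in self.subject_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "WindowDataset":
        return WindowDataset(self.imu[mask], self.pose[mask],
                             self.labels[mask], self.subject_ids[mask],
                             self.window_start_s[mask],
                             self.majority_fraction[mask])

    def for_subjects(self, subject_ids: Sequence[str]) -> "WindowDataset":
        wanted = set(map(str, subject_ids))
        mask = np.array([str(s) in wanted for s in self.subject_ids])
        return self.subset(mask)

    @staticmethod
    def concatenate(parts: Sequence["WindowDataset"]) -> "WindowDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        return WindowDataset(
            imu=np.concatenate([p.imu for p in parts]),
            pose=np.concatenate([p.pose for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            window_start_s=np.concatenate([p.window_start_s for p in parts]),
            majority_fraction=np.concatenate(
                [p.majority_fraction for p in parts]),
            n_excluded=sum(p.n_excluded for p in parts),
            n_invalid_discarded=sum(p.n_invalid_discarded for p in parts),
        )

    def fm_plus_share(self) -> float:
        """Share of FM+ among surviving windows, in percent."""
        if len(self) == 0:
            return float("nan")
        return 100.0 * float(np.mean(self.labels == 1))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _movement_trace(x: np.ndarray) -> np.ndarray:
    """Mean-removed RMS across channels; the alignment feature."""
    centered = x - x.mean(axis=0, keepdims=True)
    return np.sqrt(np.mean(centered**2, axis=1))


def segment_windows(recording: Recording, window_s: float = 1.0,
                    majority_threshold: float = 0.6,
                    config: Optional[PreprocessConfig] = None
                    ) -> WindowDataset:
    """Align, resample and segment one recording into labelled windows.

    Pipeline: (1) each IMU stream is aligned to the pose reference clock by
    maximum cross-correlation of movement-intensity traces; (2) IMU streams
    are linearly resampled to the target rate (default 100 Hz) on the
    reference timeline while the pose stays at its native 30 Hz; (3) the
    annotation intervals become per-frame labels on the target grid;
    (4) consecutive non-overlapping windows of ``window_s`` seconds receive
    the modal frame label if it reaches the majority threshold — otherwise
    the window is excluded — and invalid-majority windows are discarded.
    """
    cfg = config or PreprocessConfig()
    cfg = PreprocessConfig(target_hz=cfg.target_hz, window_s=window_s,
                           majority_threshold=majority_threshold,
                           max_lag_s=cfg.max_lag_s, align=cfg.align).validate()
    rec = recording.validate()
    target_hz = cfg.target_hz
    win_frames = int(round(cfg.window_s * target_hz))
    if not np.isclose(win_frames, cfg.window_s * target_hz):
        raise ValueError("window_s times target_hz must be integral")
    pose_per_win = int(round(cfg.window_s * POSE_HZ))

    if rec.duration_s < cfg.window_s:
        warnings.warn("recording shorter than one window; empty dataset",
                      stacklevel=2)
        return WindowDataset(
            imu=np.empty((0, N_SENSORS, win_frames, N_IMU_CHANNELS),
                         dtype=np.float32),
            pose=np.empty((0, pose_per_win, N_POSE_CHANNELS),
                          dtype=np.float32),
            labels=np.empty(0, dtype=np.int8),
            subject_ids=np.empty(0, dtype=object),
            window_start_s=np.empty(0), majority_fraction=np.empty(0))

    # Reference trace from the pose stream, brought to the target rate.
    pose_native_hz = 1.0 / float(np.median(np.diff(rec.pose_t)))
    ref = resample_linear(_movement_trace(rec.pose), pose_native_hz, target_hz)

    imu_aligned = []
    for s in range(N_SENSORS):
        native_hz = 1.0 / float(np.median(np.diff(rec.imu_t[s])))
        t_dev = rec.imu_t[s]
        if cfg.align:
            trace = resample_linear(_movement_trace(rec.imu[s][:, :3]),
                                    native_hz, target_hz)
            n = min(ref.size, trace.size)
            offset = align_streams(ref[:n], trace[:n], target_hz,
                                   cfg.max_lag_s)
        else:
            offset = 0.0
        # A positive offset means the IMU trace lags the reference; shifting
        # its timestamps by -offset places the samples on the reference clock.
        t_ref = t_dev - offset
        n_out = int(np.floor(rec.duration_s * target_hz)) + 1
        t_out = np.arange(n_out) / target_hz
        vals = np.stack([np.interp(t_out, t_ref, rec.imu[s][:, ch])
                         for ch in range(N_IMU_CHANNELS)], axis=1)
        imu_aligned.append(vals)
    imu_aligned = np.stack(imu_aligned)          # (4, T, 6)

    labels = frame_labels(rec.annotations, rec.duration_s, target_hz)

    n_windows = min((imu_aligned.shape[1]) // win_frames,
                    rec.pose.shape[0] // pose_per_win,
                    labels.size // win_frames)

    kept_imu, kept_pose, kept_lab, kept_start, kept_frac = [], [], [], [], []
    n_excluded = n_invalid = 0
    frame_mat = labels[:n_windows * win_frames].reshape(n_windows, win_frames)
    counts = np.stack([(frame_mat == code).sum(axis=1)
                       for code in (FM_MINUS, FM_PLUS, INVALID)], axis=1)
    for w in range(n_windows):
        top = counts[w].max()
        modal_candidates = np.flatnonzero(counts[w] == top)
        frac = top / win_frames
        if modal_candidates.size > 1 or frac < cfg.majority_threshold:
            n_excluded += 1
            continue
        modal = int(modal_candidates[0])
        if modal == INVALID:
            n_invalid += 1
            continue
        kept_imu.append(imu_aligned[:, w * win_frames:(w + 1) * win_frames, :])
        kept_pose.append(rec.pose[w * pose_per_win:(w + 1) * pose_per_win])
        kept_lab.append(modal)
        kept_start.append(w * cfg.window_s)
        kept_frac.append(frac)

    n_kept = len(kept_lab)
    return WindowDataset(
        imu=np.asarray(kept_imu, dtype=np.float32).reshape(
            n_kept, N_SENSORS, win_frames, N_IMU_CHANNELS),
        pose=np.asarray(kept_pose, dtype=np.float32).reshape(
            n_kept, pose_per_win, N_POSE_CHANNELS),
        labels=np.asarray(kept_lab, dtype=np.int8),
        subject_ids=np.array([rec.subject_id] * n_kept, dtype=object),
        window_start_s=np.asarray(kept_start, dtype=float),
        majority_fraction=np.asarray(kept_frac, dtype=float),
        n_excluded=n_excluded,
        n_invalid_discarded=n_invalid,
    )


def segment_cohort(recordings: Sequence[Recording],
                   config: Optional[PreprocessConfig] = None) -> WindowDataset:
    cfg = (config or PreprocessConfig()).validate()
    parts = [segment_windows(rec, cfg.window_s, cfg.majority_threshold, cfg)
             for rec in recordings]
    return WindowDataset.concatenate(parts)
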