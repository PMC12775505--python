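"""Synthetic multimodal infant-movement cohorts.

Generates, per subject, four 6-channel limb IMU streams (3-axis acceleration
and angular velocity at a native 200 Hz), one 33-keypoint x 3-coordinate pose
stream at 30 Hz, and interval annotations (fidgety onset/offset plus invalid
periods), with the statistical structure the downstream analysis assumes:

* fidgety movements appear as band-limited (default 2-6 Hz) small-amplitude
  oscillation bursts superimposed on large, slow gross movement;
* subject identity leaks into the movement channels through placement
  rotations, baseline offsets, body/vigor scaling and subject-specific
  oscillation bands, with an overall ``confound_strength`` dial in [0, 1];
* when confounded, non-fidgety periods also contain subject-keyed
  "distractor" oscillations, so no population-level spectral rule separates
  the classes on an unseen subject — the mechanism by which shortcut
  learning is made observable at desk scale.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from .config import CohortConfig, ConfigError, derive_seed

# Sensor order is part of the on-disk schema: left arm, left thigh,
# right arm, right thigh.
SENSOR_NAMES = ("LA", "LT", "RA", "RT")
N_SENSORS = 4
N_IMU_CHANNELS = 6
N_KEYPOINTS = 33
N_POSE_CHANNELS = 99

# 33-keypoint body layout (face 0-10, shoulders 11-12, arms, hips 23-24, legs).
LIMB_KEYPOINTS: Dict[str, List[int]] = {
    "LA": [13, 15, 17, 19, 21],
    "RA": [14, 16, 18, 20, 22],
    "LT": [25, 27, 29, 31],
    "RT": [26, 28, 30, 32],
}
CORE_KEYPOINTS: List[int] = [k for k in range(N_KEYPOINTS)
                             if not any(k in v for v in LIMB_KEYPOINTS.values())]

LABEL_FM = "FM"
LABEL_INVALID = "INVALID"

# Canonical (subject-independent) mixing constants, fixed once for the
# package so that the unconfounded cohort shares a single movement "dialect".
_CANON_RNG = np.random.default_rng(20240901)
_CANON_MIX_ACC = _CANON_RNG.normal(size=(N_SENSORS, 3, 3))
_CANON_MIX_GYR = _CANON_RNG.normal(size=(N_SENSORS, 3, 3))
_CANON_DIR_ACC = _CANON_RNG.normal(size=(N_SENSORS, 3))
_CANON_DIR_GYR = _CANON_RNG.normal(size=(N_SENSORS, 3))
_CANON_DIR_POSE = _CANON_RNG.normal(size=(N_KEYPOINTS, 3))
_CANON_MIX_ACC /= np.linalg.norm(_CANON_MIX_ACC, axis=2, keepdims=True)
_CANON_MIX_GYR /= np.linalg.norm(_CANON_MIX_GYR, axis=2, keepdims=True)
_CANON_DIR_ACC /= np.linalg.norm(_CANON_DIR_ACC, axis=1, keepdims=True)
_CANON_DIR_GYR /= np.linalg.norm(_CANON_DIR_GYR, axis=1, keepdims=True)
_CANON_DIR_POSE /= np.linalg.norm(_CANON_DIR_POSE, axis=1, keepdims=True)
# A rough supine skeleton (metres), only used as static keypoint rest points.
_REST_POSE = _CANON_RNG.uniform(-0.25, 0.25, size=(N_KEYPOINTS, 3))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AnnotationInterval:
    """A labelled time interval, half-open [start_s, end_s)."""

    start_s: float
    end_s: float
    label: str  # LABEL_FM or LABEL_INVALID
    regions: List[str] = field(default_factory=list)

    def validate(self, duration_s: Optional[float] = None) -> "AnnotationInterval":
        if not 0.0 <= self.start_s < self.end_s:
            raise ValueError(
                f"invalid interval [{self.start_s}, {self.end_s}): "
                "need 0 <= start_s < end_s")
        if duration_s is not None and self.end_s > duration_s + 1e-9:
            raise ValueError(
                f"interval end {self.end_s} exceeds duration {duration_s}")
        if self.label not in (LABEL_FM, LABEL_INVALID):
            raise ValueError(f"unknown interval label {self.label!r}")
        return self


@dataclass
class SubjectProfile:
    """Per-subject generative parameters.

    Identity fields (rotations, offsets, scales, subject bands) leak into the
    movement channels with strength ``confound_strength``; the remaining
    fields shape the movement itself.
    """

    subject_id: str
    risk_flag: bool
    body_scale: float
    rotation_axes: np.ndarray       # (4, 3) unit axes, one per IMU
    rotation_angles_rad: np.ndarray  # (4,) placement-jitter angles
    baseline_offset: np.ndarray     # (4, 6) per-channel constants
    amplitude_scale: float
    noise_sd: Dict[str, float]      # {"imu": ..., "pose": ...}
    fm_burst_rate: float            # bursts / minute during FM+ intervals
    confound_strength: float
    # Subject-specific oscillation bands (identity leakage into spectra).
    fm_freq_hz: float
    distractor_freq_hz: float
    # Subject-specific channel patterns, blended with the canonical ones.
    dir_acc: np.ndarray             # (4, 3)
    dir_gyr: np.ndarray             # (4, 3)
    dir_pose: np.ndarray            # (33, 3)
    pose_offset: np.ndarray         # (3,) position of the infant on the mat
    config: CohortConfig = field(default_factory=CohortConfig, repr=False)

    @property
    def placement_rotations(self) -> np.ndarray:
        """Full-strength placement rotation matrices, shape (4, 3, 3)."""
        return np.stack([
            Rotation.from_rotvec(self.rotation_axes[s] *
                                 self.rotation_angles_rad[s]).as_matrix()
            for s in range(N_SENSORS)])

    def validate(self) -> "SubjectProfile":
        if self.body_scale <= 0:
            raise ValueError("body_scale must be positive")
        if not 0.0 <= self.confound_strength <= 1.0:
            raise ValueError("confound_strength must lie in [0, 1]")
        R = self.placement_rotations
        err = np.abs(R @ np.swapaxes(R, 1, 2) - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError("placement rotations are not orthonormal")
        return self


@dataclass
class Recording:
    """One subject's synchronized IMU + pose streams with annotations."""

    subject_id: str
    imu_t: List[np.ndarray]      # 4 timestamp vectors (sensor clocks)
    imu: List[np.ndarray]        # 4 arrays (n_s, 6): ax ay az gx gy gz
    pose_t: np.ndarray           # (n_p,) reference clock
    pose: np.ndarray             # (n_p, 99)
    annotations: List[AnnotationInterval]
    duration_s: float

    def validate(self) -> "Recording":
        if len(self.imu) != N_SENSORS or len(self.imu_t) != N_SENSORS:
            raise ValueError("a recording must carry exactly 4 IMU streams")
        for s, arr in enumerate(self.imu):
            if arr.ndim != 2 or arr.shape[1] != N_IMU_CHANNELS:
                raise ValueError(f"IMU stream {s} must have 6 channels")
            if np.any(np.diff(self.imu_t[s]) <= 0):
                raise ValueError(f"IMU stream {s} timestamps not increasing")
        if self.pose.ndim != 2 or self.pose.shape[1] != N_POSE_CHANNELS:
            raise ValueError("pose stream must have 99 coordinate channels")
        if np.any(np.diff(self.pose_t) <= 0):
            raise ValueError("pose timestamps not increasing")
        for iv in self.annotations:
            iv.validate(self.duration_s)
        return self


def normalize_intervals(intervals: Sequence[AnnotationInterval]
                        ) -> List[AnnotationInterval]:
    """Sort and merge overlapping intervals of the same label."""
    out: List[AnnotationInterval] = []
    for label in (LABEL_FM, LABEL_INVALID):
        group = sorted((iv for iv in intervals if iv.label == label),
                       key=lambda iv: iv.start_s)
        for iv in group:
            if out and out[-1].label == label and iv.start_s <= out[-1].end_s:
                out[-1].end_s = max(out[-1].end_s, iv.end_s)
                out[-1].regions = sorted(set(out[-1].regions) | set(iv.regions))
            else:
                out.append(AnnotationInterval(iv.start_s, iv.end_s, label,
                                              list(iv.regions)))
    return sorted(out, key=lambda iv: (iv.start_s, iv.label))


# ---------------------------------------------------------------------------
# Profile sampling
# ---------------------------------------------------------------------------

def sample_subject_profile(cohort_config: CohortConfig, rng_seed: int,
                           subject_id: Optional[str] = None) -> SubjectProfile:
    """Draw one subject's generative parameters from the cohort distributions."""
    cfg = cohort_config.validate()
    rng = np.random.default_rng(rng_seed)
    sid = subject_id if subject_id is not None else f"S{rng_seed % 10**6:06d}"

    risk = bool(rng.random() < cfg.risk_prevalence)
    body_scale = float(np.exp(rng.normal(0.0, cfg.body_scale_sd)))
    amplitude_scale = float(np.exp(rng.normal(0.0, cfg.amplitude_scale_sd)))

    axes = rng.normal(size=(N_SENSORS, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = rng.normal(0.0, np.deg2rad(cfg.rotation_jitter_deg_sd), N_SENSORS)

    offsets = np.empty((N_SENSORS, N_IMU_CHANNELS))
    offsets[:, :3] = rng.normal(0.0, cfg.accel_offset_sd, (N_SENSORS, 3))
    offsets[:, 3:] = rng.normal(0.0, cfg.gyro_offset_sd, (N_SENSORS, 3))

    lo, hi = cfg.fm_band_hz
    margin = 0.1 * (hi - lo)
    fm_freq = float(rng.uniform(lo + margin, hi - margin))
    for _ in range(200):
        distractor = float(rng.uniform(lo + margin, hi - margin))
        if abs(distractor - fm_freq) >= 0.2 * (hi - lo):
            break
    rate_lo, rate_hi = cfg.fm_burst_rate_range
    burst_rate = float(rng.uniform(rate_lo, rate_hi))

    def _unit(shape):
        v = rng.normal(size=shape)
        return v / np.linalg.norm(v, axis=-1, keepdims=True)

    return SubjectProfile(
        subject_id=sid,
        risk_flag=risk,
        body_scale=body_scale,
        rotation_axes=axes,
        rotation_angles_rad=angles,
        baseline_offset=offsets,
        amplitude_scale=amplitude_scale,
        noise_sd={"imu": cfg.imu_noise_sd, "pose": cfg.pose_noise_sd},
        fm_burst_rate=burst_rate,
        confound_strength=cfg.confound_strength,
        fm_freq_hz=fm_freq,
        distractor_freq_hz=distractor,
        dir_acc=_unit((N_SENSORS, 3)),
        dir_gyr=_unit((N_SENSORS, 3)),
        dir_pose=_unit((N_KEYPOINTS, 3)),
        pose_offset=rng.normal(0.0, cfg.pose_offset_sd, 3),
        config=cfg,
    ).validate()


def draw_duration(cfg: CohortConfig, rng: np.random.Generator) -> float:
    """Recording duration: truncated normal, or the configured fixed value."""
    if cfg.duration_fixed_s is not None:
        return float(cfg.duration_fixed_s)
    while True:
        d = rng.normal(cfg.duration_mean_s, cfg.duration_sd_s)
        if cfg.duration_min_s <= d <= cfg.duration_max_s:
            return float(d)


# ---------------------------------------------------------------------------
# Annotation process
# ---------------------------------------------------------------------------

def _draw_annotations(cfg: CohortConfig, duration_s: float,
                      rng: np.random.Generator) -> List[AnnotationInterval]:
    """Alternating FM+/FM- segments plus Poisson-placed invalid periods."""
    intervals: List[AnnotationInterval] = []
    f = cfg.fm_fraction
    mean_fm = cfg.fm_segment_mean_s
    mean_non = mean_fm * (1.0 - f) / f
    t = 0.0
    state_fm = bool(rng.random() < f)
    while t < duration_s:
        seg = float(rng.exponential(mean_fm if state_fm else mean_non))
        seg = max(seg, 0.25)
        end = min(t + seg, duration_s)
        if state_fm and end > t:
            n_regions = 1 + int(rng.random() < 0.6) + int(rng.random() < 0.3)
            regions = list(rng.choice(SENSOR_NAMES, size=min(n_regions, 4),
                                      replace=False))
            intervals.append(AnnotationInterval(t, end, LABEL_FM, regions))
        t = end
        state_fm = not state_fm

    if cfg.invalid_fraction > 0:
        n_invalid = rng.poisson(cfg.invalid_fraction * duration_s
                                / cfg.invalid_mean_s)
        for _ in range(n_invalid):
            d = float(np.clip(rng.exponential(cfg.invalid_mean_s),
                              0.5, 3.0 * cfg.invalid_mean_s))
            if d >= duration_s:
                continue
            start = float(rng.uniform(0.0, duration_s - d))
            intervals.append(AnnotationInterval(start, start + d, LABEL_INVALID))
    return normalize_intervals(intervals)


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _gross_latent(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS slow gross-movement latent, shape (n, 3) per limb call.

    Sum of <=1 Hz sinusoids with random phase plus smoothed noise, the
    large motor background the fidgety bursts ride on.
    """
    t = np.arange(n) / fs
    out = np.zeros((n, 3))
    for c in range(3):
        sig = np.zeros(n)
        for _ in range(4):
            f = rng.uniform(0.1, 0.7)
            a = rng.uniform(0.3, 1.0)
            sig += a * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        noise = gaussian_filter1d(rng.normal(size=n), sigma=0.4 * fs)
        nrms = np.sqrt(np.mean(noise**2))
        if nrms > 0:
            sig += 0.4 * noise / nrms
        rms = np.sqrt(np.mean(sig**2))
        out[:, c] = sig / rms if rms > 0 else sig
    return out


def _place_bursts(spans: Sequence[Tuple[float, float]], rate_per_min: float,
                  dur_range: Tuple[float, float], rng: np.random.Generator
                  ) -> List[Tuple[float, float]]:
    """Renewal-process burst placement inside the given time spans.

    The gap distribution is chosen so the long-run burst rate matches
    ``rate_per_min``; short exponential gaps give near-continuous coverage,
    mirroring how fidgety oscillations pervade a fidgety period.
    """
    if rate_per_min <= 0:
        return []
    mean_dur = 0.5 * (dur_range[0] + dur_range[1])
    mean_gap = max(60.0 / rate_per_min - mean_dur, 0.05)
    bursts = []
    for start, end in spans:
        pos = start + float(rng.exponential(0.5 * mean_gap))
        while pos < end:
            d = float(rng.uniform(*dur_range))
            bursts.append((pos, min(pos + d, end)))
            pos += d + float(rng.exponential(mean_gap))
    return bursts


def _render_bursts(t: np.ndarray, fs: float,
                   bursts: Sequence[Tuple[float, float]],
                   freqs: np.ndarray, phases: np.ndarray, amps: np.ndarray,
                   regions: np.ndarray, t0: float) -> np.ndarray:
    """Sum Hann-enveloped sinusoid bursts into per-limb tracks (n, 4)."""
    out = np.zeros((t.size, N_SENSORS))
    for (b0, b1), f, ph, a, r in zip(bursts, freqs, phases, amps, regions):
        i0 = max(int(np.floor((b0 - t0) * fs)), 0)
        i1 = min(int(np.ceil((b1 - t0) * fs)) + 1, t.size)
        if i1 <= i0 + 1:
            continue
        tt = t[i0:i1]
        # Flat-topped (Tukey) envelope: cosine tapers over the outer 30%.
        u = np.clip((tt - b0) / max(b1 - b0, 1e-9), 0, 1)
        edge = np.minimum(u, 1 - u) / 0.15
        env = np.where(edge < 1, np.sin(0.5 * np.pi * np.clip(edge, 0, 1))**2,
                       1.0)
        wave = a * env * np.sin(2 * np.pi * f * (tt - b0) + ph)
        w = np.full(N_SENSORS, 0.5)
        w[r] = 1.0
        out[i0:i1] += wave[:, None] * w[None, :]
    return out


def generate_recording(profile: SubjectProfile, duration_s: Optional[float],
                       rng_seed: int,
                       config: Optional[CohortConfig] = None) -> Recording:
    """Synthesize one subject's multimodal recording.

    ``duration_s=None`` draws the duration from the cohort's truncated
    normal. The identity confound (placement rotation, baseline offset,
    body/vigor scale, subject-specific bands and channel patterns) is
    applied with strength ``profile.confound_strength``; at strength 0 the
    movement content depends only on (config, seed), not on who the
    subject is.
    """
    cfg = (config or profile.config).validate()
    rng = np.random.default_rng(rng_seed)
    c = float(profile.confound_strength)

    if duration_s is None:
        duration_s = draw_duration(cfg, rng)
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if duration_s < 1.0:
        warnings.warn(f"recording shorter than one window ({duration_s:.2f} s); "
                      "emitting it anyway", stacklevel=2)

    annotations = _draw_annotations(cfg, duration_s, rng)
    fm_spans = [(iv.start_s, iv.end_s) for iv in annotations
                if iv.label == LABEL_FM]
    region_lookup = {span: [SENSOR_NAMES.index(r) for r in iv.regions] or
                     list(range(N_SENSORS))
                     for span, iv in zip(fm_spans,
                                         (iv for iv in annotations
                                          if iv.label == LABEL_FM))}
    # Complement of FM spans: where confounded distractor bursts may live.
    nonfm_spans = []
    prev = 0.0
    for s0, s1 in fm_spans:
        if s0 > prev:
            nonfm_spans.append((prev, s0))
        prev = s1
    if prev < duration_s:
        nonfm_spans.append((prev, duration_s))

    # Master grid at the IMU rate, padded so clock-shifted resampling and
    # alignment have support outside [0, duration].
    fs = cfg.imu_hz
    pad = 1.0
    t0 = -pad
    n_master = int(round((duration_s + 2 * pad) * fs)) + 1
    t_master = t0 + np.arange(n_master) / fs

    gross = np.stack([_gross_latent(n_master, fs, rng)
                      for _ in range(N_SENSORS)])        # (4, n, 3)

    # Fidgety bursts. Burst frequency blends a canonical draw from the FM
    # band with the subject's own band; both draws always happen so the RNG
    # stream is identical across confound strengths.
    lo, hi = cfg.fm_band_hz
    fm_bursts = _place_bursts(fm_spans, profile.fm_burst_rate,
                              cfg.fm_burst_duration_s, rng)
    nb = len(fm_bursts)
    canon_f = rng.uniform(lo, hi, nb)
    subj_f = rng.normal(profile.fm_freq_hz, cfg.subject_band_sd_hz, nb)
    fm_freqs = np.clip((1 - c) * canon_f + c * subj_f, 0.5, fs / 2 - 1)
    fm_phases = rng.uniform(0, 2 * np.pi, nb)
    fm_amps = rng.uniform(0.8, 1.2, nb)
    fm_regions = np.empty(nb, dtype=int)
    span_of = []
    for b0, b1 in fm_bursts:
        for span in fm_spans:
            if span[0] - 1e-9 <= b0 <= span[1] + 1e-9:
                span_of.append(span)
                break
        else:
            span_of.append(fm_spans[0])
    for i, span in enumerate(span_of):
        fm_regions[i] = rng.choice(region_lookup[span])
    fm_track = _render_bursts(t_master, fs, fm_bursts, fm_freqs, fm_phases,
                              fm_amps, fm_regions, t0)       # (n, 4)

    # Distractor bursts: only materialize with confounding (rate scales
    # with c), in the subject's other band, slightly weaker.
    d_bursts = _place_bursts(nonfm_spans, 0.8 * c * profile.fm_burst_rate,
                             cfg.fm_burst_duration_s, rng)
    nd = len(d_bursts)
    d_freqs = np.clip(rng.normal(profile.distractor_freq_hz,
                                 cfg.subject_band_sd_hz, nd), 0.5, fs / 2 - 1)
    d_track = _render_bursts(t_master, fs, d_bursts, d_freqs,
                             rng.uniform(0, 2 * np.pi, nd),
                             cfg.distractor_rel_amplitude *
                             rng.uniform(0.8, 1.2, nd),
                             rng.integers(0, N_SENSORS, nd), t0)
    osc_track = fm_track + d_track                           # (n, 4)

    amp = profile.amplitude_scale ** c
    scale = profile.body_scale ** c
    dir_acc = (1 - c) * _CANON_DIR_ACC + c * profile.dir_acc
    dir_gyr = (1 - c) * _CANON_DIR_GYR + c * profile.dir_gyr
    dir_pose = (1 - c) * _CANON_DIR_POSE + c * profile.dir_pose
    dir_acc /= np.linalg.norm(dir_acc, axis=1, keepdims=True)
    dir_gyr /= np.linalg.norm(dir_gyr, axis=1, keepdims=True)
    dir_pose /= np.linalg.norm(dir_pose, axis=1, keepdims=True)

    # Per-sensor clock offsets are synchronization artifacts, not identity;
    # they are drawn from the recording stream regardless of confounding.
    clock_offsets = rng.normal(0.0, cfg.imu_clock_offset_sd_s, N_SENSORS)

    fm_amp_acc = cfg.fm_rel_amplitude * cfg.gross_accel_amplitude
    fm_amp_gyr = cfg.fm_rel_amplitude * cfg.gross_gyro_amplitude

    imu_t: List[np.ndarray] = []
    imu: List[np.ndarray] = []
    rot = Rotation.from_rotvec(profile.rotation_axes *
                               (c * profile.rotation_angles_rad)[:, None])
    rot_mats = rot.as_matrix()                               # (4, 3, 3)
    for s in range(N_SENSORS):
        acc = (cfg.gross_accel_amplitude * amp *
               gross[s] @ _CANON_MIX_ACC[s].T)
        acc += fm_amp_acc * amp * osc_track[:, s:s + 1] * dir_acc[s]
        gyr_latent = np.gradient(gross[s], axis=0) * fs
        grms = np.sqrt(np.mean(gyr_latent**2, axis=0, keepdims=True))
        gyr_latent = gyr_latent / np.where(grms > 0, grms, 1.0)
        gyr = (cfg.gross_gyro_amplitude * amp *
               gyr_latent @ _CANON_MIX_GYR[s].T)
        gyr += fm_amp_gyr * amp * osc_track[:, s:s + 1] * dir_gyr[s]

        acc = acc @ rot_mats[s].T
        gyr = gyr @ rot_mats[s].T
        sig = np.concatenate([acc, gyr], axis=1)             # (n, 6)
        sig += c * profile.baseline_offset[s]
        sig += rng.normal(0.0, profile.noise_sd["imu"], sig.shape)

        # Sample onto this sensor's (offset) clock; timestamps as emitted by
        # the device start at 0 on its own clock.
        n_s = int(np.floor(duration_s * fs)) + 1
        t_dev = np.arange(n_s) / fs
        t_true = t_dev + clock_offsets[s]
        vals = np.stack([np.interp(t_true, t_master, sig[:, ch])
                         for ch in range(N_IMU_CHANNELS)], axis=1)
        imu_t.append(t_dev)
        imu.append(vals)

    # Pose: rest skeleton + gross limb motion + fidgety bursts on the limb
    # keypoints, then body scaling, mat offset and tracking noise.
    n_p = int(np.floor(duration_s * cfg.pose_hz)) + 1
    t_pose = np.arange(n_p) / cfg.pose_hz
    gross_p = np.stack([np.stack([np.interp(t_pose, t_master, gross[s][:, d])
                                  for d in range(3)], axis=1)
                        for s in range(N_SENSORS)])          # (4, n_p, 3)
    osc_p = np.stack([np.interp(t_pose, t_master, osc_track[:, s])
                      for s in range(N_SENSORS)], axis=1)    # (n_p, 4)
    fm_amp_pose = cfg.fm_rel_amplitude * cfg.gross_pose_amplitude

    pose = np.empty((n_p, N_KEYPOINTS, 3))
    core_motion = gross_p.mean(axis=0) * 0.3
    for k in range(N_KEYPOINTS):
        limb = next((name for name, kps in LIMB_KEYPOINTS.items() if k in kps),
                    None)
        if limb is None:
            motion = core_motion
        else:
            s = SENSOR_NAMES.index(limb)
            motion = (gross_p[s] +
                      (fm_amp_pose / cfg.gross_pose_amplitude) *
                      osc_p[:, s:s + 1] * dir_pose[k])
        pose[:, k, :] = _REST_POSE[k] + cfg.gross_pose_amplitude * amp * motion
    pose = scale * pose + c * profile.pose_offset
    noise_sd = profile.noise_sd["pose"]
    pose += rng.normal(0.0, noise_sd, pose.shape)
    if cfg.pose_unstable_tracking:
        # Mimic tracker instability in quiet periods: extra jitter where
        # overall movement is weak.
        speed = np.linalg.norm(np.gradient(pose, axis=0), axis=(1, 2))
        quiet = speed < np.median(speed)
        pose[quiet] += rng.normal(0.0, 4.0 * noise_sd, pose[quiet].shape)

    return Recording(
        subject_id=profile.subject_id,
        imu_t=imu_t,
        imu=imu,
        pose_t=t_pose,
        pose=pose.reshape(n_p, N_POSE_CHANNELS),
        annotations=annotations,
        duration_s=float(duration_s),
    ).validate()


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(n_subjects: int, cohort_config: CohortConfig,
                    rng_seed: int,
                    duration_s: Optional[float] = None
                    ) -> Tuple[List[Recording], dict]:
    """Generate one recording per subject plus a cohort manifest.

    Fully seeded: per-subject profile and recording seeds are derived from
    ``rng_seed`` with documented labels, so any single subject can be
    regenerated in isolation.
    """
    if n_subjects < 5:
        raise ConfigError(
            "n_subjects must be >= 5: the downstream subject-independent "
            "5-fold cross-validation needs at least one subject per fold")
    cfg = cohort_config.validate()
    recordings: List[Recording] = []
    entries = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        profile = sample_subject_profile(
            cfg, derive_seed(rng_seed, f"profile:{i}"), subject_id=sid)
        rec = generate_recording(
            profile, duration_s, derive_seed(rng_seed, f"recording:{sid}"))
        recordings.append(rec)
        entries.append({
            "subject_id": sid,
            "risk_flag": profile.risk_flag,
            "duration_s": round(rec.duration_s, 6),
            "files": None,
        })
    manifest = {
        "n_subjects": n_subjects,
        "seed": int(rng_seed),
        "subjects": entries,
    }
    return recordings, manifest


def manifest_json(manifest: dict) -> str:
    return json.dumps(manifest, indent=2, sort_keys=True)
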