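"""Hand-crafted time/frequency features and the random-forest baseline.

Each sensor channel of a 1-second window is summarized by 29 descriptors —
23 time-domain statistics and 6 spectral ones — computed channel-wise and
concatenated, giving 696 (IMU, 24 channels), 2871 (pose, 99 channels) or
3567 (both) dimensions per window. A random forest trained on these vectors
is the classical baseline against which the learned representations are
compared.

Definitional choices (the descriptor names admit several conventions):
percentiles use linear interpolation; zero crossings count strict sign
changes of the mean-removed signal; autocorrelation is the lag-1 Pearson
correlation; jerk is the first difference divided by the sampling interval,
summarized by its absolute mean, absolute max and L2 norm; sample entropy
uses m=2, r=0.2*SD, Chebyshev distance, is 0 for constant signals and is
capped at log(n) when no template matches; permutation entropy uses order 3,
delay 1, normalized to [0, 1]; spectra are magnitude-squared one-sided FFTs
of the un-windowed, mean-removed segment normalized so spectral energy
equals the time-domain energy of the mean-removed signal; spectral entropy
is in bits; rolloff is at 85% cumulative energy; flatness is the geometric
over arithmetic PSD mean (DC bin excluded); the high-frequency ratio is the
energy strictly above fs/4 over the total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupShuffleSplit

from .config import derive_seed
from .preprocessing import WindowDataset

FEATURE_NAMES: List[str] = [
    "max", "min", "mean", "std",
    "p20", "p50", "p80", "iqr",
    "skewness", "kurtosis", "zero_crossings", "autocorr_lag1",
    "diff1_mean", "diff1_l2", "diff2_mean", "diff2_l2",
    "rms", "energy",
    "jerk_mean", "jerk_max", "jerk_l2",
    "sample_entropy", "permutation_entropy",
    "spectral_energy", "spectral_entropy", "spectral_centroid",
    "spectral_rolloff", "spectral_flatness", "hf_energy_ratio",
]
N_FEATURES = len(FEATURE_NAMES)  # 29

IMU_CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")

_CHUNK = 256  # row-block size for the O(T^2) entropy computations


def _sample_entropy(X: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """SampEn(m=2, r=0.2*SD, Chebyshev) per row of X."""
    n, T = X.shape
    m = 2
    r = 0.2 * sd
    out = np.zeros(n)
    cap = np.log(T)
    for i0 in range(0, n, _CHUNK):
        xb = X[i0:i0 + _CHUNK]
        rb = r[i0:i0 + _CHUNK][:, None, None]
        D = np.abs(xb[:, :, None] - xb[:, None, :])
        nt = T - m  # templates of length m and m+1 share these start points
        d2 = np.maximum(D[:, :nt, :nt], D[:, 1:nt + 1, 1:nt + 1])
        d3 = np.maximum(d2, D[:, 2:nt + 2, 2:nt + 2])
        B = (d2 <= rb).sum(axis=(1, 2)) - nt  # exclude self-matches
        A = (d3 <= rb).sum(axis=(1, 2)) - nt
        with np.errstate(divide="ignore", invalid="ignore"):
            val = -np.log(A / B)
        val = np.where((A > 0) & (B > 0), val, cap)
        out[i0:i0 + _CHUNK] = val
    return np.where(sd > 0, out, 0.0)


def _permutation_entropy(X: np.ndarray) -> np.ndarray:
    """Order-3, delay-1 permutation entropy, normalized to [0, 1]."""
    triples = sliding_window_view(X, 3, axis=1)          # (n, T-2, 3)
    order = np.argsort(triples, axis=2, kind="stable")
    code = order[..., 0] * 9 + order[..., 1] * 3 + order[..., 2]
    n, nt = code.shape
    H = np.zeros(n)
    for i0 in range(0, n, _CHUNK):
        cb = code[i0:i0 + _CHUNK]
        counts = np.zeros((cb.shape[0], 27))
        for cid in range(27):
            counts[:, cid] = (cb == cid).sum(axis=1)
        p = counts / nt
        lg = np.log2(np.where(p > 0, p, 1.0))
        H[i0:i0 + _CHUNK] = -(p * lg).sum(axis=1)
    return H / np.log2(6.0)


def _features_block(X: np.ndarray, fs: float) -> np.ndarray:
    """All 29 features for a block of signals, shape (n, T) -> (n, 29)."""
    X = np.asarray(X, dtype=float)
    n, T = X.shape
    if T < 4:
        raise ValueError("signals must have length >= 4")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in input signal")
    out = np.empty((n, N_FEATURES))
    mean = X.mean(axis=1)
    sd = X.std(axis=1)
    xc = X - mean[:, None]

    out[:, 0] = X.max(axis=1)
    out[:, 1] = X.min(axis=1)
    out[:, 2] = mean
    out[:, 3] = sd
    p = np.percentile(X, [20, 50, 80, 25, 75], axis=1)
    out[:, 4], out[:, 5], out[:, 6] = p[0], p[1], p[2]
    out[:, 7] = p[4] - p[3]

    m2 = (xc**2).mean(axis=1)
    m3 = (xc**3).mean(axis=1)
    m4 = (xc**4).mean(axis=1)
    m2safe = np.where(m2 > 0, m2, 1.0)
    out[:, 8] = np.where(m2 > 0, m3 / m2safe**1.5, 0.0)
    out[:, 9] = np.where(m2 > 0, m4 / m2safe**2.0 - 3.0, 0.0)

    s = np.sign(xc)
    out[:, 10] = (s[:, :-1] * s[:, 1:] == -1).sum(axis=1)

    a, b = X[:, :-1], X[:, 1:]
    am, bm = a.mean(axis=1), b.mean(axis=1)
    cov = ((a - am[:, None]) * (b - bm[:, None])).mean(axis=1)
    den = a.std(axis=1) * b.std(axis=1)
    out[:, 11] = np.where(den > 0, cov / np.where(den > 0, den, 1.0), 0.0)

    d1 = np.diff(X, axis=1)
    d2 = np.diff(X, n=2, axis=1)
    out[:, 12] = d1.mean(axis=1)
    out[:, 13] = np.sqrt((d1**2).sum(axis=1))
    out[:, 14] = d2.mean(axis=1)
    out[:, 15] = np.sqrt((d2**2).sum(axis=1))

    out[:, 16] = np.sqrt((X**2).mean(axis=1))
    out[:, 17] = (X**2).sum(axis=1)

    jerk = d1 * fs
    out[:, 18] = np.abs(jerk).mean(axis=1)
    out[:, 19] = np.abs(jerk).max(axis=1)
    out[:, 20] = np.sqrt((jerk**2).sum(axis=1))

    out[:, 21] = _sample_entropy(X, sd)
    out[:, 22] = _permutation_entropy(X)

    # One-sided PSD of the mean-removed segment, scaled so that the total
    # equals sum((x - mean)^2): Parseval at the documented normalization.
    F = np.fft.rfft(xc, axis=1)
    psd = np.abs(F)**2
    psd[:, 1:] *= 2.0
    if T % 2 == 0:
        psd[:, -1] /= 2.0
    psd /= T
    freqs = np.fft.rfftfreq(T, d=1.0 / fs)
    ptot = psd.sum(axis=1)
    safe = np.where(ptot > 0, ptot, 1.0)
    q = psd / safe[:, None]

    out[:, 23] = ptot
    lg = np.log2(np.where(q > 0, q, 1.0))
    out[:, 24] = np.where(ptot > 0, -(q * lg).sum(axis=1), 0.0)
    out[:, 25] = np.where(ptot > 0, q @ freqs, 0.0)

    cum = np.cumsum(q, axis=1)
    roll_idx = np.argmax(cum >= 0.85 - 1e-12, axis=1)
    out[:, 26] = np.where(ptot > 0, freqs[roll_idx], 0.0)

    pb = psd[:, 1:] + 1e-300
    geo = np.exp(np.log(pb).mean(axis=1))
    out[:, 27] = np.where(ptot > 0, geo / pb.mean(axis=1), 0.0)

    hf = q[:, freqs > fs / 4.0].sum(axis=1)
    out[:, 28] = np.where(ptot > 0, hf, 0.0)
    return out


def channel_features(signal: np.ndarray, fs: float) -> np.ndarray:
    """The 29 descriptors of one channel of one window, in documented order."""
    x = np.asarray(signal, dtype=float).ravel()
    if x.size < 4:
        raise ValueError("signal length must be >= 4")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return _features_block(x[None, :], fs)[0]


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    values: np.ndarray          # (n_windows, D)
    feature_names: List[str]
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self):
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match columns")


MODALITIES = ("imu", "pose", "both")


def build_feature_matrix(windows: WindowDataset, modality: str
                         ) -> FeatureMatrix:
    """Channel-wise features for every window of the selected modality.

    Channel order is stable: IMU sensors 0..3 each with channels
    ax..gz (fs = 100 Hz), then pose coordinates kp00_x..kp32_z (fs = 30 Hz).
    """
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    if len(windows) == 0:
        raise ValueError("empty window dataset")
    cols: List[np.ndarray] = []
    names: List[str] = []
    if modality in ("imu", "both"):
        n, n_sensors, t_imu, n_ch = windows.imu.shape
        fs = float(t_imu)  # samples per 1-s window = rate in Hz
        for s in range(n_sensors):
            for ch in range(n_ch):
                try:
                    cols.append(_features_block(windows.imu[:, s, :, ch], fs))
                except ValueError as exc:
                    raise ValueError(
                        f"channel imu{s}.{IMU_CHANNEL_NAMES[ch]}: {exc}"
                    ) from exc
                names += [f"imu{s}.{IMU_CHANNEL_NAMES[ch]}.{f}"
                          for f in FEATURE_NAMES]
    if modality in ("pose", "both"):
        n, t_pose, n_pc = windows.pose.shape
        fs = float(t_pose)
        for pc in range(n_pc):
            kp, coord = divmod(pc, 3)
            cname = f"kp{kp:02d}_{'xyz'[coord]}"
            try:
                cols.append(_features_block(windows.pose[:, :, pc], fs))
            except ValueError as exc:
                raise ValueError(f"channel pose.{cname}: {exc}") from exc
            names += [f"pose.{cname}.{f}" for f in FEATURE_NAMES]
    values = np.concatenate(cols, axis=1)
    if not np.all(np.isfinite(values)):
        bad = np.flatnonzero(~np.isfinite(values).all(axis=0))[0]
        raise ValueError(f"non-finite feature column {names[bad]}")
    return FeatureMatrix(values=values, feature_names=names,
                         labels=np.asarray(windows.labels).copy(),
                         subject_ids=np.asarray(windows.subject_ids).copy())


# ---------------------------------------------------------------------------
# Random forest with random hyperparameter search
# ---------------------------------------------------------------------------

# The search space is a documented stand-in covering the usual knobs.
RF_SEARCH_SPACE: Dict[str, list] = {
    "n_estimators": [100, 200, 300],
    "max_depth": [None, 5, 10, 15, 20, 30],
    "min_samples_leaf": [1, 2, 4, 8],
    "max_features": ["sqrt", "log2", 0.1, 0.3],
}


def fit_rf(features: FeatureMatrix, search_budget: int = 10,
           rng_seed: int = 0) -> Tuple[RandomForestClassifier, dict]:
    """Random-search a forest with subject-grouped inner validation.

    Candidate configurations are scored on a held-out subject group so
    the search itself cannot exploit subject identity; the best one is
    refit on the full training set.
    """
    if search_budget < 1:
        raise ValueError("search_budget must be >= 1")
    y = np.asarray(features.labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    X = features.values
    groups = np.asarray([str(s) for s in features.subject_ids])
    rng = np.random.default_rng(derive_seed(rng_seed, "rf-search"))

    candidates = []
    for _ in range(search_budget):
        params = {k: v[rng.integers(len(v))] for k, v in RF_SEARCH_SPACE.items()}
        candidates.append(params)

    def _score(params: dict) -> float:
        if np.unique(groups).size < 2:
            return 0.0  # no grouped validation possible; order = sampling order
        splitter = GroupShuffleSplit(
            n_splits=2, test_size=0.25,
            random_state=derive_seed(rng_seed, "rf-inner") % (2**32))
        accs = []
        for tr, va in splitter.split(X, y, groups):
            if np.unique(y[tr]).size < 2:
                continue
            clf = RandomForestClassifier(
                random_state=derive_seed(rng_seed, "rf-cand") % (2**32),
                n_jobs=1, **params)
            clf.fit(X[tr], y[tr])
            accs.append(clf.score(X[va], y[va]))
        return float(np.mean(accs)) if accs else 0.0

    if len(candidates) == 1:
        best = candidates[0]
    else:
        scores = [_score(p) for p in candidates]
        best = candidates[int(np.argmax(scores))]
    model = RandomForestClassifier(
        random_state=derive_seed(rng_seed, "rf-final") % (2**32),
        n_jobs=1, **best)
    model.fit(X, y)
    return model, best
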