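"""Multi-branch 1-D CNN for fidgety-movement classification.

One convolutional branch per sensor stream — four IMU branches (left arm,
left thigh, right arm, right thigh), one pose branch, or all five — whose
outputs are concatenated and passed to a two-layer MLP head with l2
regularization, dropout and a softmax output. Trained with cross-entropy
under a strictly subject-independent protocol: any attempt to evaluate on
a training subject raises.

The published architecture search is not available; the per-branch layout
here (two conv layers of 32 and 64 filters, kernel 5, max-pool 2, then a
128-64-2 head) is a configurable default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from ._nn import (Adam, Conv1D, Dense, Tensor, concat, dropout, l2_penalty,
                  maxpool1d, relu, reshape, softmax, softmax_cross_entropy,
                  tmean)
from .config import ConfigError, derive_rng, derive_seed
from .preprocessing import WindowDataset


class ProtocolError(RuntimeError):
    """Subject-independence violation: a subject appears in both splits."""


def check_subject_disjoint(train: WindowDataset, eval_: WindowDataset):
    overlap = set(train.subjects) & set(eval_.subjects)
    if overlap:
        raise ProtocolError(
            f"subjects present in both train and eval splits: "
            f"{sorted(overlap)}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class MBCNNConfig:
    modality: str = "imu"                  # imu | pose | both
    conv_filters: Tuple[int, int] = (32, 64)
    kernel: int = 5
    pool: int = 2
    dense: Tuple[int, int] = (128, 64)
    n_classes: int = 2
    dropout: float = 0.3
    l2: float = 1e-4
    pooling: str = "flatten"               # flatten | average (global)
    input_diff: bool = False               # feed temporal first differences
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 64

    def validate(self) -> "MBCNNConfig":
        if self.modality not in ("imu", "pose", "both"):
            raise ConfigError("modality must be imu, pose or both")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must lie in [0, 1)")
        if self.pooling not in ("flatten", "average"):
            raise ConfigError("pooling must be 'flatten' or 'average'")
        if self.l2 < 0:
            raise ConfigError("l2 must be non-negative")
        if self.kernel < 1 or self.pool < 1:
            raise ConfigError("kernel and pool must be >= 1")
        return self

    def n_branches(self) -> int:
        return {"imu": 4, "pose": 1, "both": 5}[self.modality]


def branch_inputs(windows: WindowDataset, modality: str) -> List[np.ndarray]:
    """Split a window dataset into per-branch arrays (B, T, C)."""
    parts: List[np.ndarray] = []
    if modality in ("imu", "both"):
        parts += [np.asarray(windows.imu[:, s], dtype=float)
                  for s in range(windows.imu.shape[1])]
    if modality in ("pose", "both"):
        parts.append(np.asarray(windows.pose, dtype=float))
    if not parts:
        raise ConfigError(f"modality {modality!r} selects no channels")
    return parts


@dataclass
class TrainingHistory:
    """Per-epoch metrics; accuracies as fractions in [0, 1]."""

    train_acc: List[float] = field(default_factory=list)
    eval_acc: List[float] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    eval_loss: List[float] = field(default_factory=list)
    selected_epoch: int = -1

    def __len__(self) -> int:
        return len(self.train_acc)


def select_epoch(history: TrainingHistory) -> int:
    """Epoch maximizing the mean of train and eval accuracy; ties earliest.

    Deliberately mirrors the study protocol, which selects the epoch on a
    criterion that includes the test fold — a form of test-set peeking that
    the documentation flags rather than hides.
    """
    if len(history) == 0:
        raise ValueError("empty history")
    means = (np.asarray(history.train_acc) + np.asarray(history.eval_acc)) / 2
    return int(np.argmax(means))  # argmax returns the first maximum


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class _Branch:
    def __init__(self, t_in: int, c_in: int, cfg: MBCNNConfig,
                 rng: np.random.Generator):
        f1, f2 = cfg.conv_filters
        self.conv1 = Conv1D(cfg.kernel, c_in, f1, rng)
        self.conv2 = Conv1D(cfg.kernel, f1, f2, rng)
        self.pool = cfg.pool
        self.pooling = cfg.pooling
        t = (t_in - cfg.kernel + 1) // cfg.pool
        t = (t - cfg.kernel + 1) // cfg.pool
        if t < 1:
            raise ConfigError(
                f"branch input length {t_in} too short for the conv stack")
        self.out_width = f2 if cfg.pooling == "average" else t * f2

    def __call__(self, x: Tensor) -> Tensor:
        h = maxpool1d(relu(self.conv1(x)), self.pool)
        h = maxpool1d(relu(self.conv2(h)), self.pool)
        if self.pooling == "average":
            return tmean(h, axis=1)
        return reshape(h, (x.shape[0], self.out_width))

    @property
    def params(self):
        return self.conv1.params + self.conv2.params


class MBCNN:
    """Multi-branch CNN handle: branches + dense head, with train-set
    per-channel standardization stored on the model."""

    def __init__(self, config: MBCNNConfig, input_shapes: Sequence[Tuple[int, int]],
                 seed: int = 0):
        cfg = config.validate()
        if len(input_shapes) != cfg.n_branches():
            raise ConfigError(
                f"modality {cfg.modality!r} expects {cfg.n_branches()} "
                f"branches, got {len(input_shapes)} input shapes")
        self.config = cfg
        rng = derive_rng(seed, "mbcnn-init")
        self.branches = [_Branch(t, c, cfg, rng) for t, c in input_shapes]
        self.embedding_width = sum(b.out_width for b in self.branches)
        d1, d2 = cfg.dense
        self.fc1 = Dense(self.embedding_width, d1, rng)
        self.fc2 = Dense(d1, d2, rng)
        self.out = Dense(d2, cfg.n_classes, rng)
        self.norm_mean: Optional[List[np.ndarray]] = None
        self.norm_sd: Optional[List[np.ndarray]] = None

    # -- parameters --------------------------------------------------------

    @property
    def params(self):
        ps = []
        for b in self.branches:
            ps += b.params
        return ps + self.fc1.params + self.fc2.params + self.out.params

    def state(self) -> List[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def load_state(self, state: Sequence[np.ndarray]):
        for p, s in zip(self.params, state):
            p.data = s.copy()

    # -- normalization -----------------------------------------------------

    def _encode(self, inputs: Sequence[np.ndarray]) -> List[np.ndarray]:
        """Optional jerk encoding: per-sample first differences over time."""
        if not self.config.input_diff:
            return list(inputs)
        return [np.diff(x, axis=1, prepend=x[:, :1, :]) for x in inputs]

    def fit_normalization(self, inputs: Sequence[np.ndarray]):
        inputs = self._encode(inputs)
        self.norm_mean = [x.mean(axis=(0, 1)) for x in inputs]
        self.norm_sd = [np.where(x.std(axis=(0, 1)) > 0, x.std(axis=(0, 1)), 1.0)
                        for x in inputs]

    def _normalize(self, inputs: Sequence[np.ndarray]) -> List[np.ndarray]:
        inputs = self._encode(inputs)
        if self.norm_mean is None:
            return list(inputs)
        return [(x - m) / s for x, m, s in
                zip(inputs, self.norm_mean, self.norm_sd)]

    # -- forward -----------------------------------------------------------

    def features(self, inputs: Sequence[np.ndarray], train: bool = False,
                 rng: Optional[np.random.Generator] = None) -> Tensor:
        """Concatenated pre-head branch representation."""
        if len(inputs) != len(self.branches):
            raise ConfigError(
                f"expected {len(self.branches)} branch inputs, got "
                f"{len(inputs)}")
        inputs = self._normalize(inputs)
        outs = []
        for i, (branch, x) in enumerate(zip(self.branches, inputs)):
            if x.ndim != 3 or x.shape[2] != branch.conv1.w.data.shape[1]:
                raise ConfigError(
                    f"branch {i}: expected (batch, time, "
                    f"{branch.conv1.w.data.shape[1]}) input, got {x.shape}")
            outs.append(branch(Tensor(x)))
        return concat(outs, axis=1)

    def logits(self, inputs: Sequence[np.ndarray], train: bool = False,
               rng: Optional[np.random.Generator] = None) -> Tensor:
        emb = self.features(inputs, train, rng)
        return self.head(emb, train, rng)

    def head(self, emb: Tensor, train: bool = False,
             rng: Optional[np.random.Generator] = None) -> Tensor:
        cfg = self.config
        rng = rng or np.random.default_rng(0)
        h = relu(self.fc1(emb))
        h = dropout(h, cfg.dropout, rng, train)
        h = relu(self.fc2(h))
        h = dropout(h, cfg.dropout, rng, train)
        return self.out(h)

    def predict_proba(self, windows: WindowDataset,
                      batch: int = 256) -> np.ndarray:
        inputs = branch_inputs(windows, self.config.modality)
        probs = []
        for i0 in range(0, len(windows), batch):
            xs = [x[i0:i0 + batch] for x in inputs]
            probs.append(softmax(self.logits(xs).data))
        return np.concatenate(probs)

    def head_l2_params(self):
        # l2 regularization applies to the dense-head weights only.
        return [self.fc1.w, self.fc2.w, self.out.w]


def build_mbcnn(config: MBCNNConfig, windows: WindowDataset,
                seed: int = 0) -> MBCNN:
    """Instantiate an MBCNN whose branch shapes match a window dataset."""
    shapes = [(x.shape[1], x.shape[2])
              for x in branch_inputs(windows, config.modality)]
    return MBCNN(config, shapes, seed=seed)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _accuracy_and_loss(model: MBCNN, inputs: List[np.ndarray],
                       y: np.ndarray, batch: int = 256) -> Tuple[float, float]:
    correct, total_loss, n = 0, 0.0, y.size
    for i0 in range(0, n, batch):
        xs = [x[i0:i0 + batch] for x in inputs]
        logits = model.logits(xs)
        probs = softmax(logits.data)
        yb = y[i0:i0 + batch]
        correct += int((probs.argmax(axis=1) == yb).sum())
        eps = 1e-12
        total_loss += -np.log(probs[np.arange(yb.size), yb] + eps).sum()
    return correct / n, total_loss / n


def train_mbcnn(model: MBCNN, train_windows: WindowDataset,
                eval_windows: WindowDataset, seed: int = 0
                ) -> TrainingHistory:
    """Adam training with per-epoch metrics and best-epoch restoration.

    The restored weights correspond to ``select_epoch``'s choice (highest
    mean of train and eval accuracy, earliest on ties). Deterministic for
    a given seed.
    """
    check_subject_disjoint(train_windows, eval_windows)
    cfg = model.config
    x_train = branch_inputs(train_windows, cfg.modality)
    x_eval = branch_inputs(eval_windows, cfg.modality)
    y_train = (np.asarray(train_windows.labels) == 1).astype(int)
    y_eval = (np.asarray(eval_windows.labels) == 1).astype(int)

    model.fit_normalization(x_train)
    opt = Adam(model.params, lr=cfg.learning_rate)
    shuffle_rng = derive_rng(seed, "mbcnn-shuffle")
    drop_rng = derive_rng(seed, "mbcnn-dropout")
    history = TrainingHistory()
    best_score, best_state = -np.inf, None

    n = y_train.size
    for _ in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        for i0 in range(0, n, cfg.batch_size):
            idx = order[i0:i0 + cfg.batch_size]
            xs = [x[idx] for x in x_train]
            logits = model.logits(xs, train=True, rng=drop_rng)
            loss = softmax_cross_entropy(logits, y_train[idx])
            loss = _nn.add(loss, l2_penalty(model.head_l2_params(), cfg.l2))
            opt.zero_grad()
            loss.backward()
            opt.step()
        tr_acc, tr_loss = _accuracy_and_loss(model, x_train, y_train)
        ev_acc, ev_loss = _accuracy_and_loss(model, x_eval, y_eval)
        history.train_acc.append(tr_acc)
        history.eval_acc.append(ev_acc)
        history.train_loss.append(tr_loss)
        history.eval_loss.append(ev_loss)
        score = (tr_acc + ev_acc) / 2
        if score > best_score:
            best_score, best_state = score, model.state()

    if len(history):
        history.selected_epoch = select_epoch(history)
        model.load_state(best_state)
    return history


def embed(model: MBCNN, windows: WindowDataset, batch: int = 256
          ) -> np.ndarray:
    """Concatenated pre-head representation for each window."""
    inputs = branch_inputs(windows, model.config.modality)
    outs = []
    for i0 in range(0, len(windows), batch):
        xs = [x[i0:i0 + batch] for x in inputs]
        outs.append(model.features(xs).data)
    return np.concatenate(outs)
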