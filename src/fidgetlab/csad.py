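"""Cross-Subject Adversarial Disentanglement (CSAD).

A multi-branch CNN backbone feeds two beta-variational autoencoders that
split each window's representation into a movement code ``z_m`` and a
subject code ``z_s``. A movement MLP classifies fidgety presence from
``z_m`` and, adversarially, from ``z_s``; a subject MLP classifies subject
identity from ``z_s`` and, adversarially, from ``z_m``. A joint decoder
reconstructs the backbone feature vector from the concatenated codes
(scored by RMSE) so the codes keep the information the adversaries strip
away from the wrong side.

Optimization alternates per batch: (1) the two adversarial classifier
heads are fit by ordinary cross-entropy against frozen codes; (2) the
backbone, encoders, task heads and decoder minimize

    task CE(FM | z_m) + task CE(subject | z_s)
    + beta_m KL_m + beta_s KL_s + lambda_rec RMSE
    - lambda_adv (CE_adv(FM | z_s) + CE_adv(subject | z_m)),

so the encoders are driven to make the adversaries fail. At equilibrium a
concurrently-trained adversary predicting subject identity from ``z_m``
can do no better than chance — the quantity ``subject_probe_accuracy``
reports.

Subject classification heads cover training-fold subjects only; unseen
test subjects are never subject-classified. Downstream representations use
the posterior mean of ``z_m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from ._nn import (Adam, Dense, Tensor, add, clip, concat, exp, mul, relu,
                  softmax, softmax_cross_entropy, softmax_cross_entropy_soft,
                  sqrt, tmean, tsum)
from .config import ConfigError, derive_rng
from .mbcnn import (MBCNN, MBCNNConfig, branch_inputs, check_subject_disjoint)
from .preprocessing import WindowDataset

LOGVAR_CLIP = 10.0


@dataclass
class CSADConfig:
    backbone: MBCNNConfig = field(default_factory=MBCNNConfig)
    latent_dim_m: int = 64
    latent_dim_s: int = 64
    enc_hidden: int = 128
    mlp_hidden: int = 64
    beta_m: float = 1.0
    beta_s: float = 1.0
    lambda_adv: float = 0.5
    lambda_rec: float = 1.0
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    adv_steps: int = 1        # adversary updates per main update
    adv_lr_scale: float = 1.0  # adversary lr relative to the main lr
    adv_warmup_frac: float = 0.0  # fraction of epochs to ramp lambda_adv
    rec_detach_movement: bool = False  # reconstruction gradient only via z_s
    # Encoder-side adversarial objective: "negative_ce" subtracts the
    # adversary's true-label cross-entropy; "confusion" minimizes its
    # cross-entropy toward a uniform prediction (equilibrium: the codes
    # carry no decodable information, instead of anti-predictive codes).
    adv_objective: str = "negative_ce"
    adv_on_means: bool = False  # adversaries see posterior means, not samples
    task_weight_movement: float = 1.0  # extra weight on the FM head CE

    def validate(self) -> "CSADConfig":
        self.backbone.validate()
        if self.latent_dim_m < 1 or self.latent_dim_s < 1:
            raise ConfigError("latent dims must be >= 1")
        if self.latent_dim_m != self.latent_dim_s:
            raise ConfigError(
                "latent dims must match: the movement and subject MLP trunks "
                "each process both codes")
        for name in ("beta_m", "beta_s", "lambda_adv", "lambda_rec"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.adv_objective not in ("negative_ce", "confusion"):
            raise ConfigError(
                "adv_objective must be 'negative_ce' or 'confusion'")
        return self


@dataclass
class CSADLossReport:
    """Itemized loss components; ``total`` is their exact weighted sum.

    ``adv_movement_from_zs`` and ``adv_subject_from_zm`` are the
    adversaries' true-label cross-entropies. ``adv_encoder_term`` is the
    signed quantity the encoder objective adds: minus their sum under the
    default negative-CE objective, or the uniform-target confusion
    cross-entropy under the confusion objective.
    """

    movement_bce: float
    subject_cce: float
    adv_movement_from_zs: float
    adv_subject_from_zm: float
    adv_encoder_term: float
    kl_movement: float
    kl_subject: float
    reconstruction_rmse: float
    weights: Dict[str, float]
    total: float

    def recompute_total(self) -> float:
        w = self.weights
        return (w.get("task_weight_movement", 1.0) * self.movement_bce
                + self.subject_cce
                + w["beta_m"] * self.kl_movement
                + w["beta_s"] * self.kl_subject
                + w["lambda_rec"] * self.reconstruction_rmse
                + w["lambda_adv"] * self.adv_encoder_term)


@dataclass
class LatentRepresentation:
    z_m: np.ndarray          # posterior means, (n, latent_dim_m)
    z_s: np.ndarray
    logvar_m: np.ndarray
    logvar_s: np.ndarray


@dataclass
class CSADHistory:
    train_movement_acc: List[float] = field(default_factory=list)
    eval_movement_acc: List[float] = field(default_factory=list)
    train_subject_acc: List[float] = field(default_factory=list)
    total_loss: List[float] = field(default_factory=list)
    subject_probe_accuracy: float = float("nan")

    def __len__(self):
        return len(self.train_movement_acc)


class _VAEEncoder:
    def __init__(self, d_in: int, hidden: int, d_lat: int, rng):
        self.h = Dense(d_in, hidden, rng)
        self.mu = Dense(hidden, d_lat, rng)
        self.logvar = Dense(hidden, d_lat, rng)
        # Start with a tight posterior (sd ~ 0.14) so early training is not
        # drowned in reparameterization noise.
        self.logvar.b.data[:] = -4.0

    def __call__(self, x: Tensor) -> Tuple[Tensor, Tensor]:
        h = relu(self.h(x))
        return self.mu(h), clip(self.logvar(h), -LOGVAR_CLIP, LOGVAR_CLIP)

    @property
    def params(self):
        return self.h.params + self.mu.params + self.logvar.params


class CSAD:
    """Model handle holding backbone, dual VAE, heads and decoder."""

    def __init__(self, config: CSADConfig,
                 input_shapes: Sequence[Tuple[int, int]],
                 subject_ids: Sequence[str], seed: int = 0):
        cfg = config.validate()
        self.config = cfg
        self.subjects = sorted(set(map(str, subject_ids)))
        self.subject_index = {s: i for i, s in enumerate(self.subjects)}
        n_subj = len(self.subjects)
        if n_subj < 2:
            raise ConfigError("CSAD needs at least 2 training subjects")

        self.backbone = MBCNN(cfg.backbone, input_shapes, seed=seed)
        d_feat = self.backbone.embedding_width
        rng = derive_rng(seed, "csad-init")
        self.enc_m = _VAEEncoder(d_feat, cfg.enc_hidden, cfg.latent_dim_m, rng)
        self.enc_s = _VAEEncoder(d_feat, cfg.enc_hidden, cfg.latent_dim_s, rng)
        # Shared MLP trunks; each processes both its own code (task head)
        # and the other code (adversarial head).
        self.trunk_m = Dense(cfg.latent_dim_m, cfg.mlp_hidden, rng)
        self.trunk_s = Dense(cfg.latent_dim_s, cfg.mlp_hidden, rng)
        self.head_fm = Dense(cfg.mlp_hidden, 2, rng)
        self.head_subject = Dense(cfg.mlp_hidden, n_subj, rng)
        # Adversarial classifiers own their full MLPs (hidden layer included)
        # so they can keep tracking the moving codes; a linear probe on a
        # trunk the encoder controls is too easy to fool.
        self.adv_fm_hidden = Dense(cfg.latent_dim_s, cfg.mlp_hidden, rng)
        self.adv_fm_from_zs = Dense(cfg.mlp_hidden, 2, rng)
        self.adv_subj_hidden = Dense(cfg.latent_dim_m, cfg.mlp_hidden, rng)
        self.adv_subject_from_zm = Dense(cfg.mlp_hidden, n_subj, rng)
        self.dec1 = Dense(cfg.latent_dim_m + cfg.latent_dim_s,
                          cfg.enc_hidden, rng)
        self.dec2 = Dense(cfg.enc_hidden, d_feat, rng)

    # -- parameter groups --------------------------------------------------

    @property
    def main_params(self):
        return (self.backbone.params + self.enc_m.params + self.enc_s.params
                + self.trunk_m.params + self.trunk_s.params
                + self.head_fm.params + self.head_subject.params
                + self.dec1.params + self.dec2.params)

    @property
    def adversary_params(self):
        return (self.adv_fm_hidden.params + self.adv_fm_from_zs.params
                + self.adv_subj_hidden.params
                + self.adv_subject_from_zm.params)

    # -- forward pieces ----------------------------------------------------

    def encode(self, inputs: Sequence[np.ndarray]
               ) -> Tuple[Tensor, Tensor, Tensor, Tensor, Tensor]:
        feat = self.backbone.features(inputs)
        mu_m, lv_m = self.enc_m(feat)
        mu_s, lv_s = self.enc_s(feat)
        return feat, mu_m, lv_m, mu_s, lv_s

    @staticmethod
    def reparameterize(mu: Tensor, logvar: Tensor,
                       eps: Optional[np.ndarray]) -> Tensor:
        if eps is None:
            return mu
        std = exp(mul(logvar, Tensor(0.5)))
        return add(mu, mul(std, Tensor(eps)))

    def decode(self, z_m: Tensor, z_s: Tensor) -> Tensor:
        if self.config.rec_detach_movement:
            z_m = z_m.detach()
        return self.dec2(relu(self.dec1(concat([z_m, z_s], axis=1))))

    def movement_logits(self, z_m: Tensor) -> Tensor:
        return self.head_fm(relu(self.trunk_m(z_m)))

    def subject_logits(self, z_s: Tensor) -> Tensor:
        return self.head_subject(relu(self.trunk_s(z_s)))

    def adv_movement_logits(self, z_s: Tensor) -> Tensor:
        return self.adv_fm_from_zs(relu(self.adv_fm_hidden(z_s)))

    def adv_subject_logits(self, z_m: Tensor) -> Tensor:
        return self.adv_subject_from_zm(relu(self.adv_subj_hidden(z_m)))

    def subject_targets(self, subject_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.subject_index[str(s)] for s in subject_ids])
        except KeyError as exc:
            raise ConfigError(
                f"subject {exc.args[0]!r} not among the training subjects "
                "the subject head was built for") from exc


def _kl_gaussian(mu: Tensor, logvar: Tensor) -> Tensor:
    """Mean over the batch of KL(N(mu, diag exp(logvar)) || N(0, I))."""
    per_sample = tsum(add(add(mul(mu, mu), exp(logvar)),
                          add(mul(logvar, Tensor(-1.0)), Tensor(-1.0))),
                      axis=1)
    return mul(tmean(per_sample), Tensor(0.5))


def build_csad(config: CSADConfig, windows: WindowDataset,
               seed: int = 0) -> CSAD:
    shapes = [(x.shape[1], x.shape[2])
              for x in branch_inputs(windows, config.backbone.modality)]
    return CSAD(config, shapes, windows.subject_ids, seed=seed)


def csad_losses(model: CSAD, inputs: Sequence[np.ndarray],
                fm_labels: np.ndarray, subject_ids: Sequence[str],
                eps_m: Optional[np.ndarray] = None,
                eps_s: Optional[np.ndarray] = None
                ) -> Tuple[CSADLossReport, Tensor]:
    """All loss components for one batch, plus the differentiable total.

    With ``eps_m``/``eps_s`` omitted the posterior mean is used, making the
    report deterministic; training passes sampled noise (reparameterization).
    """
    cfg = model.config
    y_fm = (np.asarray(fm_labels) == 1).astype(int)
    y_subj = model.subject_targets(subject_ids)

    feat, mu_m, lv_m, mu_s, lv_s = model.encode(inputs)
    z_m = model.reparameterize(mu_m, lv_m, eps_m)
    z_s = model.reparameterize(mu_s, lv_s, eps_s)

    ce_fm = softmax_cross_entropy(model.movement_logits(z_m), y_fm)
    ce_subj = softmax_cross_entropy(model.subject_logits(z_s), y_subj)
    # Optionally the adversaries act on the posterior means — the
    # representation exported downstream — so the independence pressure
    # targets that geometry rather than the sampling-blurred codes.
    if cfg.adv_on_means:
        adv_m_logits = model.adv_movement_logits(mu_s)
        adv_s_logits = model.adv_subject_logits(mu_m)
    else:
        adv_m_logits = model.adv_movement_logits(z_s)
        adv_s_logits = model.adv_subject_logits(z_m)
    ce_adv_fm = softmax_cross_entropy(adv_m_logits, y_fm)
    ce_adv_subj = softmax_cross_entropy(adv_s_logits, y_subj)
    if cfg.adv_objective == "confusion":
        n_subj = len(model.subjects)
        unif2 = np.full((y_fm.size, 2), 0.5)
        unifk = np.full((y_fm.size, n_subj), 1.0 / n_subj)
        adv_term = add(softmax_cross_entropy_soft(adv_m_logits, unif2),
                       softmax_cross_entropy_soft(adv_s_logits, unifk))
    else:
        adv_term = mul(add(ce_adv_fm, ce_adv_subj), Tensor(-1.0))
    kl_m = _kl_gaussian(mu_m, lv_m)
    kl_s = _kl_gaussian(mu_s, lv_s)
    recon = model.decode(z_m, z_s)
    diff = add(recon, mul(feat.detach(), Tensor(-1.0)))
    rmse = sqrt(tmean(mul(diff, diff)))

    total = mul(ce_fm, Tensor(cfg.task_weight_movement))
    total = add(total, ce_subj)
    total = add(total, mul(kl_m, Tensor(cfg.beta_m)))
    total = add(total, mul(kl_s, Tensor(cfg.beta_s)))
    total = add(total, mul(rmse, Tensor(cfg.lambda_rec)))
    total = add(total, mul(adv_term, Tensor(cfg.lambda_adv)))

    report = CSADLossReport(
        movement_bce=float(ce_fm.data),
        subject_cce=float(ce_subj.data),
        adv_movement_from_zs=float(ce_adv_fm.data),
        adv_subject_from_zm=float(ce_adv_subj.data),
        adv_encoder_term=float(adv_term.data),
        kl_movement=float(kl_m.data),
        kl_subject=float(kl_s.data),
        reconstruction_rmse=float(rmse.data),
        weights={"beta_m": cfg.beta_m, "beta_s": cfg.beta_s,
                 "lambda_adv": cfg.lambda_adv, "lambda_rec": cfg.lambda_rec,
                 "task_weight_movement": cfg.task_weight_movement},
        total=float(total.data),
    )
    return report, total


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def latent_means(model: CSAD, windows: WindowDataset,
                 batch: int = 256) -> LatentRepresentation:
    inputs = branch_inputs(windows, model.config.backbone.modality)
    zs, zm, lvm, lvs = [], [], [], []
    for i0 in range(0, len(windows), batch):
        xs = [x[i0:i0 + batch] for x in inputs]
        _, mu_m, lv_m, mu_s, lv_s = model.encode(xs)
        zm.append(mu_m.data)
        zs.append(mu_s.data)
        lvm.append(lv_m.data)
        lvs.append(lv_s.data)
    return LatentRepresentation(z_m=np.concatenate(zm),
                                z_s=np.concatenate(zs),
                                logvar_m=np.concatenate(lvm),
                                logvar_s=np.concatenate(lvs))


def _movement_accuracy(model: CSAD, inputs, y: np.ndarray,
                       batch: int = 256) -> float:
    correct = 0
    for i0 in range(0, y.size, batch):
        xs = [x[i0:i0 + batch] for x in inputs]
        _, mu_m, _, _, _ = model.encode(xs)
        probs = softmax(model.movement_logits(mu_m).data)
        correct += int((probs.argmax(axis=1) == y[i0:i0 + batch]).sum())
    return correct / y.size


def _subject_accuracy(model: CSAD, inputs, y_subj: np.ndarray,
                      adversarial: bool, batch: int = 256) -> float:
    correct = 0
    for i0 in range(0, y_subj.size, batch):
        xs = [x[i0:i0 + batch] for x in inputs]
        _, mu_m, _, mu_s, _ = model.encode(xs)
        if adversarial:
            logits = model.adv_subject_logits(mu_m)
        else:
            logits = model.subject_logits(mu_s)
        probs = softmax(logits.data)
        correct += int((probs.argmax(axis=1) == y_subj[i0:i0 + batch]).sum())
    return correct / y_subj.size


def train_csad(model: CSAD, train_windows: WindowDataset,
               eval_windows: WindowDataset, seed: int = 0
               ) -> Tuple[CSADHistory, LatentRepresentation,
                          LatentRepresentation]:
    """Alternating adversarial training; returns history and latent codes.

    Per batch, the adversarial heads take one gradient step on frozen codes
    (their cross-entropy minimized), then the main parameters take one step
    on the full objective with the adversary cross-entropies subtracted.
    Returns the history plus posterior-mean latents for the train and eval
    windows at the final epoch.
    """
    check_subject_disjoint(train_windows, eval_windows)
    cfg = model.config
    modality = cfg.backbone.modality
    x_train = branch_inputs(train_windows, modality)
    x_eval = branch_inputs(eval_windows, modality)
    y_train = (np.asarray(train_windows.labels) == 1).astype(int)
    y_eval = (np.asarray(eval_windows.labels) == 1).astype(int)
    y_subj = model.subject_targets(train_windows.subject_ids)
    sid_train = np.asarray(train_windows.subject_ids)

    model.backbone.fit_normalization(x_train)
    opt_main = Adam(model.main_params, lr=cfg.learning_rate)
    opt_adv = Adam(model.adversary_params,
                   lr=cfg.adv_lr_scale * cfg.learning_rate)
    shuffle_rng = derive_rng(seed, "csad-shuffle")
    eps_rng = derive_rng(seed, "csad-eps")
    history = CSADHistory()

    n = y_train.size
    lambda_base = cfg.lambda_adv
    warmup = max(int(round(cfg.adv_warmup_frac * cfg.epochs)), 0)
    for epoch in range(cfg.epochs):
        # Ramp the adversarial weight so task features form before the
        # identity-scrubbing pressure peaks.
        if warmup:
            cfg.lambda_adv = lambda_base * min(1.0, (epoch + 1) / warmup)
        order = shuffle_rng.permutation(n)
        epoch_total = 0.0
        n_batches = 0
        for i0 in range(0, n, cfg.batch_size):
            idx = order[i0:i0 + cfg.batch_size]
            xs = [x[idx] for x in x_train]
            nb = idx.size
            eps_m = eps_rng.standard_normal((nb, cfg.latent_dim_m))
            eps_s = eps_rng.standard_normal((nb, cfg.latent_dim_s))

            # (1) adversary step(s) against frozen codes
            _, mu_m, lv_m, mu_s, lv_s = model.encode(xs)
            if cfg.adv_on_means:
                z_m = Tensor(mu_m.data)
                z_s = Tensor(mu_s.data)
            else:
                z_m = Tensor(mu_m.data + np.exp(0.5 * lv_m.data) * eps_m)
                z_s = Tensor(mu_s.data + np.exp(0.5 * lv_s.data) * eps_s)
            for _ in range(max(cfg.adv_steps, 0)):
                adv_loss = add(
                    softmax_cross_entropy(model.adv_movement_logits(z_s),
                                          y_train[idx]),
                    softmax_cross_entropy(model.adv_subject_logits(z_m),
                                          y_subj[idx]))
                opt_adv.zero_grad()
                adv_loss.backward()
                opt_adv.step()

            # (2) main step on the full objective
            _, total = csad_losses(model, xs, y_train[idx],
                                   sid_train[idx], eps_m, eps_s)
            opt_main.zero_grad()
            total.backward()
            opt_main.step()
            epoch_total += float(total.data)
            n_batches += 1

        history.train_movement_acc.append(
            _movement_accuracy(model, x_train, y_train))
        history.eval_movement_acc.append(
            _movement_accuracy(model, x_eval, y_eval))
        history.train_subject_acc.append(
            _subject_accuracy(model, x_train, y_subj, adversarial=False))
        history.total_loss.append(epoch_total / max(n_batches, 1))

    cfg.lambda_adv = lambda_base
    history.subject_probe_accuracy = _subject_accuracy(
        model, x_train, y_subj, adversarial=True)
    return history, latent_means(model, train_windows), latent_means(
        model, eval_windows)
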