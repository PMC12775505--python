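"""Subject-independent evaluation protocol and cross-method statistics.

Folds partition subjects (never windows): each infant's data lands in
exactly one fold, with at-risk subjects spread evenly, so every test fold
contains only subjects unseen in training. Classification quality is
summarized per fold by accuracy, macro-averaged F1 (AF1), sensitivity
(recall of FM+), specificity and precision, all in percent; methods are
compared across repeated runs with a Friedman rank test and Nemenyi
post-hoc under a Bonferroni-corrected significance level.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._nn import Tensor, softmax
from .config import CohortConfig, StudyConfig, derive_seed
from .csad import CSAD, CSADConfig, build_csad, train_csad
from .disentanglement import ane
from .hcf import build_feature_matrix, fit_rf
from .mbcnn import (MBCNN, MBCNNConfig, build_mbcnn, check_subject_disjoint,
                    embed, train_mbcnn)
from .preprocessing import WindowDataset, segment_cohort
from .synthetic import generate_cohort

APPROACHES = ("hcf", "mbcnn", "csad")
MODALITIES = ("imu", "pose", "both")


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    n_folds: int
    assignment: Dict[str, int]       # subject_id -> fold index
    risk_flags: Dict[str, bool]
    seed: int

    def fold_subjects(self, fold: int) -> List[str]:
        return [s for s, f in self.assignment.items() if f == fold]

    def train_test_subjects(self, fold: int) -> Tuple[List[str], List[str]]:
        test = self.fold_subjects(fold)
        train = [s for s, f in self.assignment.items() if f != fold]
        return train, test


def make_folds(subjects: Sequence[str], risk_flags: Dict[str, bool],
               n_folds: int = 5, seed: int = 0) -> FoldSplit:
    """Stratified subject-level folds.

    At-risk subjects are shuffled and dealt round-robin across folds first;
    the remaining subjects are then dealt to keep fold sizes within one of
    each other.
    """
    subjects = [str(s) for s in subjects]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if len(subjects) < n_folds:
        raise ValueError("need at least one subject per fold")
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    rng = np.random.default_rng(derive_seed(seed, "folds"))
    at_risk = sorted(s for s in subjects if risk_flags.get(s, False))
    healthy = sorted(s for s in subjects if not risk_flags.get(s, False))
    rng.shuffle(at_risk)
    rng.shuffle(healthy)

    assignment: Dict[str, int] = {}
    for i, s in enumerate(at_risk):
        assignment[s] = i % n_folds
    counts = np.bincount(list(assignment.values()), minlength=n_folds)
    for s in healthy:
        fold = int(np.argmin(counts))
        assignment[s] = fold
        counts[fold] += 1
    return FoldSplit(n_folds=n_folds, assignment=assignment,
                     risk_flags={s: bool(risk_flags.get(s, False))
                                 for s in subjects},
                     seed=seed)


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsRow:
    """One fold's metrics, in percent; positive class is FM+."""

    accuracy: float
    af1: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> Dict[str, float]:
        return {"accuracy": self.accuracy, "af1": self.af1,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision}


def classification_metrics(y_true: Sequence[int],
                           y_pred: Sequence[int]) -> MetricsRow:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    acc = (tp + tn) / y_true.size
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    spec = tn / (tn + fp) if (tn + fp) else 0.0
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision defined as 0",
                      stacklevel=2)
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    prec_neg = tn / (tn + fn) if (tn + fn) else 0.0
    f1_pos = (2 * prec * sens / (prec + sens)) if (prec + sens) else 0.0
    f1_neg = (2 * prec_neg * spec / (prec_neg + spec)) \
        if (prec_neg + spec) else 0.0
    af1 = (f1_pos + f1_neg) / 2
    return MetricsRow(accuracy=100 * acc, af1=100 * af1,
                      sensitivity=100 * sens, specificity=100 * spec,
                      precision=100 * prec)


def aggregate_metrics(rows: Sequence[MetricsRow]) -> Dict[str, Tuple[float, float]]:
    """Mean and SD across folds, per metric."""
    out = {}
    for key in ("accuracy", "af1", "sensitivity", "specificity", "precision"):
        vals = np.array([getattr(r, key) for r in rows])
        out[key] = (float(vals.mean()), float(vals.std(ddof=1))
                    if vals.size > 1 else 0.0)
    return out


# ---------------------------------------------------------------------------
# Friedman + Nemenyi with Bonferroni correction
# ---------------------------------------------------------------------------

@dataclass
class StatTestReport:
    metric_name: str
    friedman_statistic: float
    friedman_p: float
    method_names: List[str]
    nemenyi_p: np.ndarray          # (k, k) pairwise p-values
    alpha: float
    n_tests: int
    corrected_alpha: float
    significant: np.ndarray        # (k, k) boolean flags


def friedman_statistic(table: np.ndarray) -> float:
    """Textbook Friedman chi-square with average ranks for ties.

    ``table`` is methods x runs; ranking happens within each run.
    """
    k, n = table.shape
    ranks = np.stack([stats.rankdata(table[:, j]) for j in range(n)], axis=1)
    rbar = ranks.mean(axis=1)
    chi = 12.0 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2.0) ** 2)
    # Tie correction (reduces the statistic when runs contain tied values).
    correction = 0.0
    for j in range(n):
        _, counts = np.unique(table[:, j], return_counts=True)
        correction += float(np.sum(counts**3 - counts))
    denom = 1.0 - correction / (n * k * (k**2 - 1))
    if denom <= 0:
        return 0.0
    return float(chi / denom)


def friedman_nemenyi(table: np.ndarray, method_names: Sequence[str],
                     metric_name: str = "", alpha: float = 0.05,
                     n_tests: int = 9) -> StatTestReport:
    """Friedman rank test with Nemenyi post-hoc pairwise comparisons.

    ``table`` has one row per method and one column per repeated run. The
    Bonferroni-corrected level alpha / n_tests is reported to 4 decimals
    (0.05 over 9 approach-modality configurations gives 0.0056).
    """
    table = np.asarray(table, dtype=float)
    k, n = table.shape
    if k < 3:
        raise ValueError("Friedman test needs at least 3 methods")
    if n < 2:
        raise ValueError("Friedman test needs at least 2 runs")
    if len(method_names) != k:
        raise ValueError("method_names length must match rows")

    chi = friedman_statistic(table)
    p = float(stats.chi2.sf(chi, k - 1)) if chi > 0 else 1.0

    ranks = np.stack([stats.rankdata(table[:, j]) for j in range(n)], axis=1)
    rbar = ranks.mean(axis=1)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    nemenyi = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(rbar[i] - rbar[j]) / se
            pval = float(stats.studentized_range.sf(q * np.sqrt(2.0), k,
                                                    np.inf))
            pval = float(np.clip(pval, 0.0, 1.0))
            nemenyi[i, j] = nemenyi[j, i] = pval

    corrected = round(alpha / n_tests, 4)
    return StatTestReport(
        metric_name=metric_name,
        friedman_statistic=chi,
        friedman_p=p,
        method_names=list(method_names),
        nemenyi_p=nemenyi,
        alpha=alpha,
        n_tests=n_tests,
        corrected_alpha=corrected,
        significant=nemenyi < corrected,
    )


# ---------------------------------------------------------------------------
# Method runners (shared by the orchestrator and the recovery study)
# ---------------------------------------------------------------------------

def _split_windows(windows: WindowDataset, fold: "FoldSplit", fold_idx: int
                   ) -> Tuple[WindowDataset, WindowDataset]:
    train_subj, test_subj = fold.train_test_subjects(fold_idx)
    train = windows.for_subjects(train_subj)
    test = windows.for_subjects(test_subj)
    check_subject_disjoint(train, test)
    return train, test


def run_hcf(train: WindowDataset, test: WindowDataset, modality: str,
            seed: int, search_budget: int = 10) -> Dict:
    feats_train = build_feature_matrix(train, modality)
    feats_test = build_feature_matrix(test, modality)
    model, params = fit_rf(feats_train, search_budget=search_budget,
                           rng_seed=seed)
    pred_train = model.predict(feats_train.values)
    pred_test = model.predict(feats_test.values)
    return {
        "train_metrics": classification_metrics(feats_train.labels, pred_train),
        "test_metrics": classification_metrics(feats_test.labels, pred_test),
        "train_features": feats_train,
        "test_features": feats_test,
        "params": params,
    }


def run_mbcnn(train: WindowDataset, test: WindowDataset, modality: str,
              seed: int, train_config: Optional[MBCNNConfig] = None) -> Dict:
    cfg = train_config or MBCNNConfig()
    cfg.modality = modality
    model = build_mbcnn(cfg, train, seed=seed)
    history = train_mbcnn(model, train, test, seed=seed)
    sel = history.selected_epoch
    pred_train = model.predict_proba(train).argmax(axis=1)
    pred_test = model.predict_proba(test).argmax(axis=1)
    return {
        "history": history,
        "selected_epoch": sel,
        "train_acc_pct": 100 * history.train_acc[sel] if len(history) else None,
        "test_acc_pct": 100 * history.eval_acc[sel] if len(history) else None,
        "train_metrics": classification_metrics(
            (np.asarray(train.labels) == 1).astype(int), pred_train),
        "test_metrics": classification_metrics(
            (np.asarray(test.labels) == 1).astype(int), pred_test),
        "model": model,
        "train_embedding": embed(model, train),
        "test_embedding": embed(model, test),
    }


def run_csad(train: WindowDataset, test: WindowDataset, modality: str,
             seed: int, csad_config: Optional[CSADConfig] = None) -> Dict:
    cfg = csad_config or CSADConfig()
    cfg.backbone.modality = modality
    model = build_csad(cfg, train, seed=seed)
    history, lat_train, lat_test = train_csad(model, train, test, seed=seed)
    pm_train = softmax(
        model.movement_logits(Tensor(lat_train.z_m)).data).argmax(axis=1)
    pm_test = softmax(
        model.movement_logits(Tensor(lat_test.z_m)).data).argmax(axis=1)
    return {
        "history": history,
        "train_metrics": classification_metrics(
            (np.asarray(train.labels) == 1).astype(int), pm_train),
        "test_metrics": classification_metrics(
            (np.asarray(test.labels) == 1).astype(int), pm_test),
        "subject_probe_accuracy_pct": 100 * history.subject_probe_accuracy,
        "chance_accuracy_pct": 100.0 / len(model.subjects),
        "model": model,
        "latents_train": lat_train,
        "latents_test": lat_test,
    }


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def run_experiment(config: StudyConfig, dry_run: bool = False,
                   approaches: Sequence[str] = APPROACHES,
                   modalities: Sequence[str] = MODALITIES,
                   log=lambda msg: None) -> Dict:
    """Full protocol: simulate -> preprocess -> train x evaluate -> compare.

    ``dry_run`` returns the job plan without computing anything. The report
    contains per-fold metric tables per (approach, modality), subject-label
    ANE values for the learned representations, and the cross-method
    Friedman/Nemenyi comparison on the test AF1.
    """
    config = config.validate()
    n_folds = config.evaluation.n_folds
    plan = [{"approach": a, "modality": m, "folds": n_folds}
            for a in approaches for m in modalities]
    if dry_run:
        return {"plan": plan, "n_jobs": len(plan),
                "n_trainings": len(plan) * n_folds}

    t0 = time.time()
    log(f"simulating cohort of {config.cohort.n_subjects} subjects")
    recordings, manifest = generate_cohort(
        config.cohort.n_subjects, config.cohort,
        derive_seed(config.seed, "cohort"))
    log(f"segmenting ({time.time() - t0:.1f}s)")
    windows = segment_cohort(recordings, config.preprocess)
    risk = {e["subject_id"]: e["risk_flag"] for e in manifest["subjects"]}
    folds = make_folds(windows.subjects, risk, n_folds=n_folds,
                       seed=derive_seed(config.seed, "folds"))

    mbcnn_cfg = MBCNNConfig(
        learning_rate=config.mbcnn.learning_rate,
        epochs=config.mbcnn.epochs, batch_size=config.mbcnn.batch_size)
    csad_cfg = CSADConfig(
        learning_rate=config.csad.learning_rate,
        epochs=config.csad.epochs, batch_size=config.csad.batch_size)

    results: Dict = {"plan": plan, "tables": {}, "ane": {}, "stats": {}}
    k_ane = config.evaluation.ane_k
    for a in approaches:
        for m in modalities:
            rows_train, rows_test, ane_pairs = [], [], []
            for f in range(n_folds):
                train, test = _split_windows(windows, folds, f)
                seed_f = derive_seed(config.seed, f"{a}:{m}:fold{f}")
                log(f"{a}/{m} fold {f} ({time.time() - t0:.1f}s)")
                if a == "hcf":
                    res = run_hcf(train, test, m, seed_f,
                                  config.hcf.search_budget)
                    rep_train = res["train_features"].values
                    rep_test = res["test_features"].values
                elif a == "mbcnn":
                    res = run_mbcnn(train, test, m, seed_f, mbcnn_cfg)
                    rep_train = res["train_embedding"]
                    rep_test = res["test_embedding"]
                else:
                    res = run_csad(train, test, m, seed_f, csad_cfg)
                    rep_train = res["latents_train"].z_m
                    rep_test = res["latents_test"].z_m
                rows_train.append(res["train_metrics"])
                rows_test.append(res["test_metrics"])
                pair = {}
                for split_name, rep, ds in (("train", rep_train, train),
                                            ("test", rep_test, test)):
                    if len(ds) > k_ane:
                        pair[split_name] = ane(
                            rep, ds.subject_ids, k=k_ane).ane
                ane_pairs.append(pair)
            results["tables"][(a, m)] = {
                "train": rows_train, "test": rows_test,
                "train_aggregate": aggregate_metrics(rows_train),
                "test_aggregate": aggregate_metrics(rows_test),
            }
            results["ane"][(a, m)] = ane_pairs

    # Cross-method comparison on test AF1 (per-fold values as repeated runs).
    names, table = [], []
    for a in approaches:
        for m in modalities:
            names.append(f"{a}-{m}")
            table.append([r.af1 for r in results["tables"][(a, m)]["test"]])
    if len(names) >= 3:
        results["stats"]["test_af1"] = friedman_nemenyi(
            np.asarray(table), names, metric_name="test_af1",
            alpha=config.evaluation.alpha,
            n_tests=len(names))
    results["n_windows"] = len(windows)
    results["fm_plus_share_pct"] = windows.fm_plus_share()
    return results


# ---------------------------------------------------------------------------
# Scaled-down disentanglement recovery study
# ---------------------------------------------------------------------------

def recovery_study(seed: int, n_subjects: int = 10, duration_s: float = 60.0,
                   modality: str = "imu", search_budget: int = 3) -> Dict:
    """Shortcut-learning reproduction at desk scale.

    Trains all three approaches on a small confounded cohort and its
    unconfounded twin. With identity confounds on, all methods should show
    a large train-test gap, the CNN embedding should cluster by subject
    (low subject-ANE), and the adversarially disentangled movement code
    should not (high subject-ANE, subject probe near chance); with
    confounds off, test accuracy should track train accuracy.

    Problem sizes and training schedules here are the package's scaled-down
    defaults for this experiment (10 subjects of 60 s; compact conv
    branches with a jerk input encoding; learning rate 1e-3 and batch 32
    over 30 CNN / 70 CSAD epochs); the cohort generator itself keeps its
    study-condition defaults.
    """
    out: Dict = {"seed": seed, "n_subjects": n_subjects,
                 "duration_s": duration_s}
    branch = dict(modality=modality, conv_filters=(16, 32), dense=(64, 32),
                  kernel=9, pooling="flatten", input_diff=True)
    mb_cfg = MBCNNConfig(learning_rate=1e-3, epochs=30, batch_size=32,
                         **branch)
    cs_cfg = CSADConfig(backbone=MBCNNConfig(**branch),
                        latent_dim_m=8, latent_dim_s=8,
                        beta_m=0.05, beta_s=0.05, lambda_adv=3.0,
                        adv_steps=2, adv_lr_scale=1.0, adv_warmup_frac=0.5,
                        rec_detach_movement=True, adv_objective="confusion",
                        task_weight_movement=2.0,
                        learning_rate=1e-3, epochs=70, batch_size=32)

    for cond, strength in (("confounded", 1.0), ("clean", 0.0)):
        cfg = CohortConfig(confound_strength=strength,
                           duration_fixed_s=duration_s)
        recordings, manifest = generate_cohort(
            n_subjects, cfg, derive_seed(seed, f"recovery:{cond}"))
        windows = segment_cohort(recordings)
        risk = {e["subject_id"]: e["risk_flag"] for e in manifest["subjects"]}
        folds = make_folds(windows.subjects, risk, n_folds=5,
                           seed=derive_seed(seed, "recovery-folds"))
        train, test = _split_windows(windows, folds, 0)

        block: Dict = {"n_windows": len(windows),
                       "fm_plus_share_pct": windows.fm_plus_share()}
        res_h = run_hcf(train, test, modality, derive_seed(seed, f"h:{cond}"),
                        search_budget=search_budget)
        block["hcf"] = {
            "train_acc_pct": res_h["train_metrics"].accuracy,
            "test_acc_pct": res_h["test_metrics"].accuracy}

        res_m = run_mbcnn(train, test, modality,
                          derive_seed(seed, f"m:{cond}"), mb_cfg)
        block["mbcnn"] = {
            "train_acc_pct": res_m["train_acc_pct"],
            "test_acc_pct": res_m["test_acc_pct"]}

        res_c = run_csad(train, test, modality,
                         derive_seed(seed, f"c:{cond}"), cs_cfg)
        sel_hist = res_c["history"]
        block["csad"] = {
            "train_acc_pct": 100 * sel_hist.train_movement_acc[-1],
            "test_acc_pct": 100 * sel_hist.eval_movement_acc[-1],
            "subject_probe_accuracy_pct": res_c["subject_probe_accuracy_pct"],
            "chance_accuracy_pct": res_c["chance_accuracy_pct"]}

        if cond == "confounded":
            block["ane_mbcnn_train"] = ane(
                res_m["train_embedding"], train.subject_ids, k=10).ane
            block["ane_csad_zm_train"] = ane(
                res_c["latents_train"].z_m, train.subject_ids, k=10).ane
            block["ane_ceiling_bits"] = float(
                np.log2(min(10, len(set(map(str, train.subject_ids))))))
        out[cond] = block
    return out
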