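"""Cross-validated ROC evaluation and paired AUC comparison.

The evaluation protocol mirrors the reference design: subjects are randomly
split into five class-stratified folds; in each fold the classifier is
trained ``n_trials`` times (10 by default) on the other four folds and the
best trial is kept; validation scores of the kept models are pooled across
folds so that every subject is scored exactly once, and the pooled scores
feed ROC analysis.  AUCs are Mann-Whitney statistics with ties counted 0.5;
variances, confidence intervals and the paired two-sided test for comparing
matrix types use DeLong's placement-value estimator.  Sensitivity,
specificity and accuracy are computed at a patient-probability cutoff of 0.5.

Note on trial selection: picking the trial with the highest *validation* AUC
reuses the validation fold for selection and optimistically biases the pooled
estimate.  This circularity is preserved deliberately for fidelity to the
reference protocol; ``selection="train_loss"`` gives an unbiased alternative
that selects on final training loss instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortDataset
from .core import preprocess_matrix
from .errors import ConfigurationError, DataError
from .network import (ArchitectureSpec, TrainConfig, TrainedClassifier,
                      build_classifier, predict_batch, train)
from .seeds import derive_seed

SELECTION_RULES = ("val_auc", "train_loss")


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 5
    n_trials: int = 10
    selection: str = "val_auc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.selection not in SELECTION_RULES:
            raise ConfigurationError(f"selection must be one of {SELECTION_RULES}")


@dataclass
class ConfusionMetrics:
    """Threshold metrics with explicit numerators and denominators."""

    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fn: int
    tn: int
    fp: int
    cutoff: float = 0.5

    def percents(self) -> dict[str, int]:
        """Integer-percent rendering, e.g. sensitivity 89/115 -> 77."""
        return {k: round(100 * getattr(self, k))
                for k in ("sensitivity", "specificity", "accuracy")}


@dataclass
class PooledResult:
    """Scores and metrics pooled across cross-validation folds."""

    per_subject: list[tuple[str, str, float]]
    per_fold_auc: list[float]
    pooled_auc: float
    pooled_ci: tuple[float, float]
    confusion: ConfusionMetrics
    fold_models: list[TrainedClassifier] = field(default_factory=list)
    fold_validation_ids: list[list[str]] = field(default_factory=list)

    def scores_and_labels(self) -> tuple[np.ndarray, np.ndarray]:
        scores = np.array([s for _, _, s in self.per_subject])
        labels = np.array([1 if g == "patient" else 0 for _, g, _ in self.per_subject])
        return scores, labels


# ---------------------------------------------------------------------------
# ROC / DeLong machinery
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos, neg = labels == 1, labels == 0
    if not pos.any() or not neg.any():
        raise DataError("AUC undefined: both classes must be present")
    return pos, neg


def _placements(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    sp, sn = scores[pos], scores[neg]
    cmp = (sp[:, None] > sn[None, :]) + 0.5 * (sp[:, None] == sn[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def compute_auc(scores, labels, alpha: float = 0.05):
    """Mann-Whitney AUC (ties 0.5) with a DeLong-variance confidence interval.

    Returns ``(auc, (lo, hi))`` with the interval truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    v10, v01 = _placements(scores, pos, neg)
    auc = float(v10.mean())
    m, n = len(v10), len(v01)
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, (max(0.0, auc - half), min(1.0, auc + half))


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    z: float
    p_value: float


def delong_paired_test(scores_a, scores_b, labels) -> DeLongResult:
    """Two-sided paired DeLong test for correlated AUCs on the same subjects."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("paired score vectors must have the same length")
    pos, neg = _check_two_classes(labels)
    va10, va01 = _placements(a, pos, neg)
    vb10, vb01 = _placements(b, pos, neg)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    diff = auc_a - auc_b
    m, n = len(va10), len(va01)
    var = 0.0
    if m > 1:
        var += (va10 - vb10).var(ddof=1) / m
    if n > 1:
        var += (va01 - vb01).var(ddof=1) / n
    if var <= 0:
        # Degenerate: identical placements -> no evidence of a difference.
        return DeLongResult(auc_a, auc_b, diff, 0.0, 1.0 if diff == 0 else 0.0)
    z = diff / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return DeLongResult(auc_a, auc_b, diff, float(z), float(p))


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Corrected per-test significance level alpha / n (e.g. 0.05/10 = 0.005)."""
    if n_comparisons < 1:
        raise ConfigurationError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def confusion_metrics(scores, labels, cutoff: float = 0.5) -> ConfusionMetrics:
    """Sensitivity/specificity/accuracy with patient (label 1) as positive.

    A score >= cutoff predicts patient.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(labels)
    pred = scores >= cutoff
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & neg))
    fp = int(np.sum(pred & neg))
    return ConfusionMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / (tp + fn + tn + fp),
        tp=tp, fn=fn, tn=tn, fp=fp, cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_folds(dataset: CohortDataset, cfg: CVConfig) -> list[np.ndarray]:
    """Class-stratified random partition; element f holds fold f's subject indices."""
    labels = dataset.labels()
    if len(labels) < cfg.n_folds:
        raise DataError("fewer subjects than folds")
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                          random_state=cfg.seed % (2**32 - 1))
    return [val for _, val in skf.split(np.zeros(len(labels)), labels)]


@dataclass
class TrialRecord:
    trial: int
    model: TrainedClassifier
    val_scores: np.ndarray
    val_auc: float
    final_loss: float


def select_best_trial(trials: list[TrialRecord], rule: str) -> TrialRecord:
    """Pick one trial per fold: highest validation AUC, or lowest final
    training loss in the unbiased mode.  Ties go to the earliest trial."""
    if rule == "val_auc":
        return max(trials, key=lambda t: (t.val_auc, -t.trial))
    return min(trials, key=lambda t: (t.final_loss, t.trial))


def run_cross_validation(dataset: CohortDataset, metric: str,
                         arch: ArchitectureSpec, train_cfg: TrainConfig,
                         cv_cfg: CVConfig) -> PooledResult:
    """Full repeated-trial cross-validation of one matrix type."""
    if metric not in dataset.matrices:
        raise DataError(f"cohort has no {metric!r} matrices")
    ids = dataset.subject_ids
    inputs = [preprocess_matrix(dataset.matrices[metric][sid]) for sid in ids]
    teachers = dataset.teacher_vectors()
    labels = dataset.labels()

    folds = make_folds(dataset, cv_cfg)
    per_subject: dict[str, tuple[str, float]] = {}
    per_fold_auc: list[float] = []
    fold_models: list[TrainedClassifier] = []
    fold_validation_ids: list[list[str]] = []

    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(ids)), val_idx)
        train_samples = [(inputs[i], teachers[i]) for i in train_idx]
        val_inputs = [inputs[i] for i in val_idx]
        val_labels = labels[val_idx]
        trials = []
        for t in range(cv_cfg.n_trials):
            seed_t = derive_seed(cv_cfg.seed, metric, "fold", f, "trial", t)
            model = build_classifier(arch, seed=seed_t)
            cfg_t = replace(train_cfg, seed=derive_seed(seed_t, "train"))
            try:
                train(model, train_samples, cfg_t)
            except Exception as exc:  # pragma: no cover - context for rare failures
                raise DataError(f"training failed in fold {f}, trial {t}: {exc}") from exc
            scores = predict_batch(model, val_inputs)[:, 1]
            auc, _ = compute_auc(scores, val_labels)
            trials.append(TrialRecord(t, model, scores, auc, model.training_log[-1]))
        best = select_best_trial(trials, cv_cfg.selection)
        per_fold_auc.append(best.val_auc)
        fold_models.append(best.model)
        fold_validation_ids.append([ids[i] for i in val_idx])
        for i, s in zip(val_idx, best.val_scores):
            per_subject[ids[i]] = (dataset.subjects[i].group, float(s))

    per_subject_rows = [(sid, per_subject[sid][0], per_subject[sid][1]) for sid in ids]
    scores = np.array([per_subject[sid][1] for sid in ids])
    pooled_auc, ci = compute_auc(scores, labels)
    conf = confusion_metrics(scores, labels)
    return PooledResult(per_subject_rows, per_fold_auc, pooled_auc, ci, conf,
                        fold_models, fold_validation_ids)
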