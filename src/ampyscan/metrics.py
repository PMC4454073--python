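"""Confusion-matrix statistics and the 5-fold cross-validation harness.

Per-class statistics are one-vs-rest collapses of the multiclass confusion
matrix: sensitivity SN = TP/(TP+FN), specificity SP = TN/(TN+FP) (the
true-negative rate), accuracy, the Matthews correlation coefficient and
F1.  The aggregate "percent better than random" score normalises overall
accuracy against the uniform random baseline for k classes:
``S = 100 * (ACC% - 100/k) / (100 - 100/k)``.

Predictions may be "unclassified" (a profile scan with no passing hit);
such predictions are tracked in a dedicated column and count as an error
for the true class — a false negative in its one-vs-rest table and a false
positive for no class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .seqio import SequenceRecord

UNCLASSIFIED = "unclassified"


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray  # (k, k+1): predicted column k is "unclassified"

    @classmethod
    def empty(cls, classes: Sequence[str]) -> "ConfusionMatrix":
        k = len(classes)
        return cls(classes=list(classes), counts=np.zeros((k, k + 1), dtype=int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls_name: str) -> tuple[int, int, int, int]:
        """Collapse to (TP, FP, TN, FN) for one class."""
        i = self.classes.index(cls_name)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fp, tn, fn


def confusion_matrix(true: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix:
    """Tally a confusion matrix; unknown true labels are an error."""
    if len(true) != len(predicted):
        raise ValueError("true and predicted must have equal length")
    classes = sorted(set(true))
    cm = ConfusionMatrix.empty(classes)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true, predicted):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        j = index.get(p, len(classes))  # unknown/unclassified -> last column
        cm.counts[index[t], j] += 1
    return cm


@dataclass
class ClassMetrics:
    sn: float
    sp: float
    acc: float
    mcc: float
    f1: float


@dataclass
class MetricsReport:
    per_class: dict[str, ClassMetrics]
    overall_acc: float  # fraction in [0, 1]
    s_score: float  # percent better than random, in [-inf, 100]
    fold: int | None = None

    @property
    def macro(self) -> ClassMetrics:
        vals = list(self.per_class.values())
        return ClassMetrics(
            sn=float(np.mean([v.sn for v in vals])),
            sp=float(np.mean([v.sp for v in vals])),
            acc=float(np.mean([v.acc for v in vals])),
            mcc=float(np.mean([v.mcc for v in vals])),
            f1=float(np.mean([v.f1 for v in vals])),
        )


def binary_mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when the denominator vanishes."""
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def compute_metrics(cm: ConfusionMatrix, fold: int | None = None) -> MetricsReport:
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    per_class: dict[str, ClassMetrics] = {}
    n = cm.total
    for c in cm.classes:
        tp, fp, tn, fn = cm.one_vs_rest(c)
        per_class[c] = ClassMetrics(
            sn=tp / (tp + fn) if tp + fn else 0.0,
            sp=tn / (tn + fp) if tn + fp else 0.0,
            acc=(tp + tn) / n,
            mcc=binary_mcc(tp, fp, tn, fn),
            f1=2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
        )
    overall_acc = float(np.trace(cm.counts[:, : len(cm.classes)])) / n
    k = len(cm.classes)
    random_pct = 100.0 / k
    s = 100.0 * (overall_acc * 100.0 - random_pct) / (100.0 - random_pct) if k > 1 else 100.0
    return MetricsReport(per_class=per_class, overall_acc=overall_acc, s_score=s, fold=fold)


def kfold_split(
    labels: Sequence[str], folds: int = 5, seed: int = 0, stratified: bool = True
) -> np.ndarray:
    """Fold assignment (0..folds-1) per example, reproducible given seed."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    labels = list(labels)
    n = len(labels)
    assignment = np.full(n, -1, dtype=int)
    if stratified:
        counts = {c: labels.count(c) for c in set(labels)}
        small = [c for c, v in counts.items() if v < folds]
        if small:
            raise ValueError(f"classes smaller than fold count: {sorted(small)}")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
            assignment[test_idx] = fold
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, folds)):
            assignment[chunk] = fold
    return assignment


class Trainer(Protocol):
    """A classifier builder used by the cross-validation harness."""

    def fit(self, records: Sequence[SequenceRecord], labels: Sequence[str]) -> "Predictor": ...


class Predictor(Protocol):
    def predict(self, records: Sequence[SequenceRecord]) -> list[str]: ...


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    fold_matrices: list[ConfusionMatrix]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.overall_acc for r in self.fold_reports]))

    @property
    def mean_s(self) -> float:
        return float(np.mean([r.s_score for r in self.fold_reports]))

    @property
    def mean_macro_mcc(self) -> float:
        return float(np.mean([r.macro.mcc for r in self.fold_reports]))

    @property
    def mean_macro_f1(self) -> float:
        return float(np.mean([r.macro.f1 for r in self.fold_reports]))


def crossvalidate(
    records: Sequence[SequenceRecord],
    labels: Sequence[str],
    trainer: Trainer,
    folds: int = 5,
    seed: int = 0,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of a sequence classifier.

    For each fold the trainer is fit on the remaining folds and applied to
    the held-out sequences; per-fold metric reports are returned together
    with their confusion matrices.  Trainer failures propagate annotated
    with the fold id.
    """
    if len(records) != len(labels):
        raise ValueError("records and labels must have equal length")
    assignment = kfold_split(labels, folds=folds, seed=seed, stratified=True)
    reports: list[MetricsReport] = []
    matrices: list[ConfusionMatrix] = []
    for fold in range(folds):
        train_idx = [i for i in range(len(records)) if assignment[i] != fold]
        test_idx = [i for i in range(len(records)) if assignment[i] == fold]
        try:
            predictor = trainer.fit(
                [records[i] for i in train_idx], [labels[i] for i in train_idx]
            )
            predicted = predictor.predict([records[i] for i in test_idx])
        except Exception as exc:
            raise RuntimeError(f"trainer failed on fold {fold}: {exc}") from exc
        cm = confusion_matrix([labels[i] for i in test_idx], predicted)
        matrices.append(cm)
        reports.append(compute_metrics(cm, fold=fold))
    return CrossValidationResult(fold_reports=reports, fold_matrices=matrices)


# --- trainers --------------------------------------------------------------

@dataclass
class SVMTrainer:
    """Hybrid k-mer composition SVM trainer for the CV harness."""

    ks: tuple[int, ...] = (1, 2, 4)
    C: float = 0.01
    degree: int = 3
    seed: int = 0

    def fit(self, records: Sequence[SequenceRecord], labels: Sequence[str]):
        from .features import feature_matrix
        from .svm import train_multiclass

        X = feature_matrix(records, self.ks)
        model = train_multiclass(X, labels, C=self.C, degree=self.degree, ks=self.ks, seed=self.seed)
        ks = self.ks

        class _Predictor:
            def predict(self, recs: Sequence[SequenceRecord]) -> list[str]:
                return model.predict(feature_matrix(recs, ks))

        return _Predictor()


@dataclass
class HMMTrainer:
    """Per-class profile-HMM trainer for the CV harness.

    Training members of each class are re-aligned with a progressive star
    alignment around the longest member, a profile is built per class and
    calibrated on background samples; held-out sequences are classified by
    E-value competition.  Sequences with no hit at the cutoff come back
    "unclassified".
    """

    pseudocount_weight: float = 1.0
    e_cutoff: float = 1e-3
    n_calibration: int = 100
    seed: int = 0

    def fit(self, records: Sequence[SequenceRecord], labels: Sequence[str]):
        from .phmm import build_profile, calibrate_evalue, classify_family, scan
        from .seqio import star_align

        profiles = []
        for i, cls_name in enumerate(sorted(set(labels))):
            members = [r for r, l in zip(records, labels) if l == cls_name]
            msa = star_align(members)
            profile = build_profile(msa, pseudocount_weight=self.pseudocount_weight, name=cls_name)
            calibrate_evalue(profile, n_random=self.n_calibration, seed=self.seed + i)
            profiles.append(profile)
        e_cutoff = self.e_cutoff

        class _Predictor:
            def predict(self, recs: Sequence[SequenceRecord]) -> list[str]:
                hits = scan(recs, profiles, e_cutoff=e_cutoff, align=False)
                by_seq: dict[str, list] = {}
                for h in hits:
                    by_seq.setdefault(h.seq_id, []).append(h)
                return [
                    classify_family(by_seq[r.id]).label if r.id in by_seq else UNCLASSIFIED
                    for r in recs
                ]

        return _Predictor()
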