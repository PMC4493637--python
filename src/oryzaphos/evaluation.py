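"""Cross-validated evaluation: confusion metrics, ROC/AUC, per-residue reports.

Metrics follow the standard two-class definitions:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is set to 0 by convention when its denominator vanishes.  ROC curves
are sensitivity versus (1 - specificity) over all distinct decision-score
thresholds, with AUC by the trapezoidal rule; tied scores collapse into a
single operating point.

Cross-validation is stratified 10-fold with every fitted component
(scaler, relief-F selection, KNN references) confined to the training
folds; fold confusion counts are pooled (micro-averaged) for the headline
metrics, with per-fold metrics also reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from oryzaphos.dataset import Fragment
from oryzaphos.encodings import EncodingSpec
from oryzaphos.errors import DataError
from oryzaphos.featsel import SelectionSpec
from oryzaphos.models import ClassifierSpec, TrainedPredictor, decision_scores, train

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float


@dataclass
class MetricsReport:
    """Confusion counts, scalar metrics, ROC points/AUC and per-residue breakdown."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    roc: np.ndarray | None = None  # columns: (1 - specificity, sensitivity)
    auc: float | None = None
    per_residue: dict[str, "MetricsReport"] = field(default_factory=dict)
    fold_metrics: list[Metrics] = field(default_factory=list)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sn/Sp/ACC/MCC from confusion counts; MCC = 0 on a zero denominator."""
    if counts.total == 0:
        raise DataError("cannot compute metrics from empty confusion counts")
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        logger.info("MCC denominator zero; reporting MCC = 0 by convention")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def confusion_from_labels(
    true_labels: Sequence[str], predicted_labels: Sequence[str]
) -> ConfusionCounts:
    t = np.array([lab == "positive" for lab in true_labels])
    p = np.array([lab == "positive" for lab in predicted_labels])
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> tuple[np.ndarray, float]:
    """ROC operating points and trapezoidal AUC.

    Returns an array of (1 - specificity, sensitivity) rows running from
    (0, 0) to (1, 1), one point per distinct score, and the AUC.
    """
    y = np.array([lab == "positive" for lab in labels], dtype=int)
    if y.min() == y.max():
        raise DataError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(_sk_auc(fpr, tpr))


def _report(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    scores: Sequence[float] | None = None,
    with_roc: bool = True,
) -> MetricsReport:
    counts = confusion_from_labels(true_labels, pred_labels)
    m = compute_metrics(counts)
    report = MetricsReport(counts=counts, sn=m.sn, sp=m.sp, acc=m.acc, mcc=m.mcc)
    if with_roc and scores is not None:
        y = {lab == "positive" for lab in true_labels}
        if len(y) == 2:
            report.roc, report.auc = roc_curve(scores, true_labels)
    return report


def _per_residue(
    fragments: Sequence[Fragment],
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    scores: Sequence[float],
) -> dict[str, MetricsReport]:
    out: dict[str, MetricsReport] = {}
    for residue in "STY":
        idx = [i for i, f in enumerate(fragments) if f.center_residue == residue]
        if not idx:
            continue
        out[residue] = _report(
            [true_labels[i] for i in idx],
            [pred_labels[i] for i in idx],
            [scores[i] for i in idx],
        )
    return out


def cross_validate(
    fragments: Sequence[Fragment],
    encoding_spec: EncodingSpec | None = None,
    selection_spec: SelectionSpec | None = None,
    classifier_spec: ClassifierSpec | None = None,
    folds: int = 10,
    seed: int = 0,
    threshold: float | None = None,
) -> MetricsReport:
    """Stratified k-fold cross-validation of the full training pipeline.

    All fitting (scaling, relief-F, classifier, KNN references) is confined
    to the training folds; held-out fragments are scored against
    fold-training references only.  Confusion counts are pooled across
    folds; per-fold metrics are kept in ``fold_metrics``.
    """
    fragments = list(fragments)
    encoding_spec = encoding_spec or EncodingSpec()
    selection_spec = selection_spec or SelectionSpec()
    classifier_spec = classifier_spec or ClassifierSpec()

    y = np.array([1 if f.label == "positive" else 0 for f in fragments])
    if min(np.bincount(y, minlength=2)) < folds:
        raise DataError(f"need at least {folds} fragments per class for {folds}-fold CV")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n = len(fragments)
    all_scores = np.empty(n)
    pred_labels: list[str | None] = [None] * n
    fold_metrics: list[Metrics] = []
    for train_idx, test_idx in skf.split(np.zeros(n), y):
        train_frags = [fragments[i] for i in train_idx]
        test_frags = [fragments[i] for i in test_idx]
        predictor = train(
            train_frags, encoding_spec, selection_spec, classifier_spec, exclude_self=True
        )
        thr = predictor.threshold if threshold is None else threshold
        scores = decision_scores(predictor, test_frags)
        for j, i in enumerate(test_idx):
            all_scores[i] = scores[j]
            pred_labels[i] = "positive" if scores[j] >= thr else "negative"
        fold_counts = confusion_from_labels(
            [f.label for f in test_frags],
            [pred_labels[i] for i in test_idx],
        )
        fold_metrics.append(compute_metrics(fold_counts))

    true_labels = [f.label for f in fragments]
    report = _report(true_labels, pred_labels, all_scores)
    report.fold_metrics = fold_metrics
    report.per_residue = _per_residue(fragments, true_labels, pred_labels, all_scores)
    return report


def evaluate_independent(
    predictor: TrainedPredictor,
    test_fragments: Sequence[Fragment],
    threshold: float | None = None,
) -> MetricsReport:
    """Score a held-out set and report metrics, ROC and per-residue breakdown.

    Raises if any test fragment shares a (protein_id, position) key with
    the predictor's training set.
    """
    test_fragments = list(test_fragments)
    overlap = sorted({f.key for f in test_fragments} & predictor.train_keys)
    if overlap:
        shown = ", ".join(f"{p}:{pos}" for p, pos in overlap[:10])
        raise DataError(
            f"{len(overlap)} test fragments overlap the training set: {shown}"
            + ("..." if len(overlap) > 10 else "")
        )
    thr = predictor.threshold if threshold is None else threshold
    scores = decision_scores(predictor, test_fragments)
    pred = ["positive" if s >= thr else "negative" for s in scores]
    true = [f.label for f in test_fragments]
    report = _report(true, pred, scores)
    report.per_residue = _per_residue(test_fragments, true, pred, list(scores))
    return report
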