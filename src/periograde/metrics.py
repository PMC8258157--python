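"""Segmentation and classification metrics, and the repeated-split protocol.

Dice(all) is the overall mask overlap 2|X n Y|/(|X|+|Y|); Dice(single)
averages per-tooth Dice over the ground-truth teeth, matching prediction to
ground truth by FDI label (0 when a tooth is unpredicted). mAP follows the
standard detection protocol: per class, score-ranked predictions are TP iff
their IoU with a not-yet-matched ground truth exceeds the threshold, and AP
is the area under the all-point-interpolated precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

from .types import DetectionSet, SeverityGrade


@dataclass
class MetricsReport:
    dice_all: Optional[float] = None
    dice_single: Optional[float] = None
    map_score: Optional[float] = None
    per_class_ap: dict = field(default_factory=dict)
    macro_f1: Optional[float] = None
    accuracy: Optional[float] = None
    per_class_precision: Optional[np.ndarray] = None
    per_class_recall: Optional[np.ndarray] = None
    n: Optional[int] = None
    per_repeat: list = field(default_factory=list)

    def as_dict(self) -> dict:
        out = {}
        for k in ("dice_all", "dice_single", "map_score", "macro_f1", "accuracy", "n"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        if self.per_class_ap:
            out["per_class_ap"] = dict(self.per_class_ap)
        if self.per_repeat:
            out["per_repeat"] = list(self.per_repeat)
        return out


def dice_overall(X: np.ndarray, Y: np.ndarray) -> float:
    """2|X n Y| / (|X| + |Y|) over boolean masks; 1.0 when both are empty."""
    X = np.asarray(X, dtype=bool)
    Y = np.asarray(Y, dtype=bool)
    if X.shape != Y.shape:
        raise ValueError(f"mask shapes differ: {X.shape} vs {Y.shape}")
    denom = int(X.sum()) + int(Y.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((X & Y).sum()) / denom


def _pair_dice(a: Polygon, b: Polygon) -> float:
    denom = a.area + b.area
    if denom == 0:
        return 1.0
    return 2.0 * a.intersection(b).area / denom


def dice_per_tooth(pred: DetectionSet, gt: DetectionSet) -> float:
    """Mean Dice over the n ground-truth teeth, matched by FDI label."""
    gts = gt.labeled()
    if not gts:
        raise ValueError("ground truth has no labeled teeth")
    for ds in (pred, gt):
        codes = [t.label.code for t in ds.labeled()]
        if len(codes) != len(set(codes)):
            raise ValueError(f"duplicate FDI labels in {ds.source} set")
    by_code = {t.label.code: t for t in pred.labeled()}
    total = 0.0
    for g in gts:
        p = by_code.get(g.label.code)
        total += _pair_dice(p.polygon, g.polygon) if p is not None else 0.0
    return total / len(gts)


def _polygon_iou(a: Polygon, b: Polygon) -> float:
    inter = a.intersection(b).area
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def average_precision(
    scores: Sequence[float], is_tp: Sequence[bool], n_gt: int
) -> float:
    """All-point-interpolated area under the precision-recall curve."""
    if n_gt == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    tp = np.asarray(is_tp, dtype=float)[order]
    fp = 1.0 - tp
    cum_tp, cum_fp = np.cumsum(tp), np.cumsum(fp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # envelope: interpolated precision at recall >= r
    mrec = np.concatenate([[0.0], recall, [1.0]])
    mpre = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    idx = np.nonzero(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_average_precision(
    preds: DetectionSet,
    gts: DetectionSet,
    iou_threshold: float = 0.5,
) -> tuple[float, dict[int, float]]:
    """(mAP, per-class AP) over the FDI classes present in the ground truth.

    Predictions must carry confidence scores. Within a class, predictions
    are processed in descending score order; each is a TP iff its best-IoU
    unmatched ground truth exceeds the threshold, else an FP.
    """
    if any(t.score is None for t in preds):
        raise ValueError("predictions must carry confidence scores")
    gt_classes = sorted({t.label.code for t in gts.labeled()})
    per_class: dict[int, float] = {}
    for code in gt_classes:
        gt_teeth = [t for t in gts.labeled() if t.label.code == code]
        cand = sorted(
            (t for t in preds.labeled() if t.label.code == code),
            key=lambda t: -t.score,
        )
        matched: set[str] = set()
        scores, flags = [], []
        for p in cand:
            ious = [
                (_polygon_iou(p.polygon, g.polygon), g.instance_id) for g in gt_teeth
            ]
            ious = [x for x in ious if x[1] not in matched]
            best = max(ious, default=(0.0, None))
            if best[0] > iou_threshold:
                matched.add(best[1])
                flags.append(True)
            else:
                flags.append(False)
            scores.append(p.score)
        per_class[code] = average_precision(scores, flags, len(gt_teeth))
    mAP = float(np.mean(list(per_class.values()))) if per_class else 0.0
    return mAP, per_class


def confusion_matrix(
    y_true: Sequence[SeverityGrade], y_pred: Sequence[SeverityGrade], n_classes: int = 4
) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def classification_metrics(
    cm: np.ndarray,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """(macro F1, accuracy, per-class precision, per-class recall).

    Rows of ``cm`` are true grades, columns predicted. Precision/recall of
    a class with a zero denominator count as 0, as does the F1 term of an
    empty class, so an absent or never-predicted grade drags macro F1 down
    rather than being silently skipped.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    macro_f1 = float(f1.mean())
    accuracy = float(tp.sum() / total)
    return macro_f1, accuracy, precision, recall


def repeated_split_evaluate(
    X: np.ndarray,
    y: Sequence[SeverityGrade],
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray],
    fraction: float = 0.8,
    repeats: int = 3,
    seed: int = 0,
) -> MetricsReport:
    """Repeat a stratified train/test split, average the metrics.

    ``fit_predict(X_train, y_train, X_test, seed)`` returns predicted
    grades for the test set; oversampling, if any, must happen inside it on
    the training fold only. A split that drops a class from the training
    fold is resampled with the next seed (logged).
    """
    from sklearn.model_selection import StratifiedShuffleSplit
    import logging

    X = np.asarray(X, dtype=float)
    y = np.asarray([int(g) for g in y])
    if len(X) < 2 * repeats:
        raise ValueError("too few samples for the repeated-split protocol")
    report = MetricsReport()
    n_classes = len(np.unique(y))
    rep_seed = seed
    for rep in range(repeats):
        for _attempt in range(10):
            splitter = StratifiedShuffleSplit(
                n_splits=1, train_size=fraction, random_state=rep_seed
            )
            (train_idx, test_idx), = splitter.split(X, y)
            rep_seed += 1
            if len(np.unique(y[train_idx])) == n_classes:
                break
            logging.getLogger(__name__).warning(
                "repeat %d: class missing from training split; resampling", rep
            )
        y_pred = fit_predict(X[train_idx], y[train_idx], X[test_idx], rep_seed)
        cm = confusion_matrix(y[test_idx], y_pred)
        macro_f1, acc, _, _ = classification_metrics(cm)
        report.per_repeat.append({"macro_f1": macro_f1, "accuracy": acc})
    report.macro_f1 = float(np.mean([r["macro_f1"] for r in report.per_repeat]))
    report.accuracy = float(np.mean([r["accuracy"] for r in report.per_repeat]))
    report.n = len(y)
    return report
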