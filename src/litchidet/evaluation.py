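"""Detection metrics: IoU-0.5 matching, P/R/F1, AP, mAP, fruit counts.

The matching protocol is the de-facto VOC convention: detections are
visited in descending confidence; each one claims the unmatched
same-class ground-truth box of highest IoU when that IoU clears the
threshold (0.5 in all reported experiments), otherwise it is a false
positive.  AP integrates the monotone precision envelope over recall
(all-point interpolation); mAP averages the per-class APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CLASSES

__all__ = [
    "MatchResult", "EvalReport", "match", "precision_recall_f1",
    "average_precision", "mean_ap", "evaluate", "count_fruits",
    "density_stratum", "yield_regression",
]


@dataclass
class MatchResult:
    det_is_tp: list            # per detection, confidence-descending order
    det_order: list            # indices into the input detection list
    gt_matched: list           # per ground-truth box
    match_ious: list           # IoU for each TP detection (0.0 for FP)

    @property
    def tp(self):
        return int(sum(self.det_is_tp))

    @property
    def fp(self):
        return len(self.det_is_tp) - self.tp

    @property
    def fn(self):
        return len(self.gt_matched) - int(sum(self.gt_matched))


def match(detections, gts, iou_thr=0.5) -> MatchResult:
    """Greedy confidence-ordered matching of detections to ground truth."""
    order = sorted(range(len(detections)), key=lambda i: -detections[i].confidence)
    gt_matched = [False] * len(gts)
    det_is_tp, match_ious = [], []
    for i in order:
        det = detections[i]
        best_iou, best_j = 0.0, -1
        for j, gt in enumerate(gts):
            if gt_matched[j] or gt.label != det.label:
                continue
            v = det.box.iou(gt)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_thr:
            gt_matched[best_j] = True
            det_is_tp.append(True)
            match_ious.append(best_iou)
        else:
            det_is_tp.append(False)
            match_ious.append(0.0)
    return MatchResult(det_is_tp, order, gt_matched, match_ious)


def precision_recall_f1(tp, fp, fn):
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0 on empty denominators."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def _pr_curve(confidences, is_tp, n_gt):
    order = np.argsort(-np.asarray(confidences, dtype=np.float64), kind="stable")
    tp_cum = np.cumsum(np.asarray(is_tp, dtype=np.float64)[order])
    fp_cum = np.cumsum(1.0 - np.asarray(is_tp, dtype=np.float64)[order])
    recall = tp_cum / max(n_gt, 1)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    return recall, precision


def average_precision(confidences, is_tp, n_gt, interpolation="all"):
    """Area under the PR curve swept over detection confidences.

    ``all``: continuous monotone-envelope integration;
    ``101``: COCO-style 101-point recall sampling (cross-check only).
    """
    if n_gt == 0:
        return 0.0
    if len(confidences) == 0:
        return 0.0
    recall, precision = _pr_curve(confidences, is_tp, n_gt)
    r = np.concatenate([[0.0], recall, [1.0]])
    p = np.concatenate([[1.0], precision, [0.0]])
    p = np.flip(np.maximum.accumulate(np.flip(p)))  # monotone envelope
    if interpolation == "all":
        idx = np.where(r[1:] != r[:-1])[0]
        return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
    if interpolation == "101":
        grid = np.linspace(0, 1, 101)
        return float(np.mean(np.interp(grid, r, p)))
    raise ValueError("interpolation must be 'all' or '101'")


def mean_ap(per_class_aps):
    """Arithmetic mean of per-class AP values."""
    aps = list(per_class_aps.values()) if isinstance(per_class_aps, dict) \
        else list(per_class_aps)
    if not aps:
        raise ValueError("need at least one class AP")
    return float(np.mean(aps))


@dataclass
class EvalReport:
    per_class: dict = field(default_factory=dict)  # label -> metrics dict
    map50: float = 0.0
    precision: float = 0.0    # micro-averaged over all classes
    recall: float = 0.0
    f1: float = 0.0
    per_image_counts: list = field(default_factory=list)
    iou_thr: float = 0.5

    def as_dict(self):
        return {"per_class": self.per_class, "mAP@0.5": self.map50,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1, "iou_thr": self.iou_thr,
                "per_image_counts": self.per_image_counts}

    def table(self):
        rows = [f"{'class':<12}{'P%':>8}{'R%':>8}{'AP%':>8}"]
        for name, m in self.per_class.items():
            rows.append(f"{name:<12}{100 * m['precision']:>8.1f}"
                        f"{100 * m['recall']:>8.1f}{100 * m['ap']:>8.1f}")
        rows.append(f"{'all':<12}{100 * self.precision:>8.1f}"
                    f"{100 * self.recall:>8.1f}{100 * self.map50:>8.1f}")
        rows.append(f"F1-score: {self.f1:.2f}")
        return "\n".join(rows)


def evaluate(detections_per_image, gts_per_image, iou_thr=0.5,
             interpolation="all") -> EvalReport:
    """Dataset-level evaluation.

    ``detections_per_image`` and ``gts_per_image`` are parallel lists;
    ground truth entries are Box lists, detections are Detection lists
    (already thresholded and NMS-suppressed).
    """
    if len(detections_per_image) != len(gts_per_image):
        raise ValueError("detections and ground truth lists differ in length")
    per_class = {}
    counts = []
    scores = {c: [] for c in CLASSES}
    flags = {c: [] for c in CLASSES}
    totals = {c: 0 for c in CLASSES}
    for dets, gts in zip(detections_per_image, gts_per_image):
        res = match(dets, gts, iou_thr)
        for rank, i in enumerate(res.det_order):
            d = dets[i]
            scores[d.label].append(d.confidence)
            flags[d.label].append(res.det_is_tp[rank])
        for c in CLASSES:
            totals[c] += sum(1 for g in gts if g.label == c)
        counts.append(count_fruits(dets, gt_count=len(gts)))
    tp_all = fp_all = fn_all = 0
    for c in CLASSES:
        tp = int(sum(flags[c]))
        fp = len(flags[c]) - tp
        fn = totals[c] - tp
        p, r, f1 = precision_recall_f1(tp, fp, fn)
        ap = average_precision(scores[c], flags[c], totals[c], interpolation)
        per_class[c] = {"precision": p, "recall": r, "f1": f1, "ap": ap,
                        "tp": tp, "fp": fp, "fn": fn, "n_gt": totals[c]}
        tp_all, fp_all, fn_all = tp_all + tp, fp_all + fp, fn_all + fn
    p, r, f1 = precision_recall_f1(tp_all, fp_all, fn_all)
    return EvalReport(per_class, mean_ap({c: per_class[c]["ap"] for c in CLASSES}),
                      p, r, f1, counts, iou_thr)


# ---------------------------------------------------------------------------
# yield counting
# ---------------------------------------------------------------------------

def density_stratum(n: int) -> str:
    """Scene density by fruit count: <40 light, 40-80 moderate, >80 heavy."""
    if n < 40:
        return "light"
    if n <= 80:
        return "moderate"
    return "heavy"


def count_fruits(detections, gt_count=None) -> dict:
    """Per-class and total counts for one image, plus its density stratum."""
    per_class = {c: 0 for c in CLASSES}
    for d in detections:
        per_class[d.label] += 1
    total = sum(per_class.values())
    basis = gt_count if gt_count is not None else total
    return {"per_class": per_class, "total": total,
            "stratum": density_stratum(basis)}


def yield_regression(predicted, actual) -> dict:
    """OLS fit of predicted counts on actual counts, with R-squared."""
    predicted = np.asarray(predicted, dtype=np.float64)
    actual = np.asarray(actual, dtype=np.float64)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be 1-D arrays of equal length")
    if len(actual) < 3:
        raise ValueError("need at least 3 paired counts")
    if np.ptp(actual) == 0:
        return {"slope": np.nan, "intercept": np.nan, "r2": np.nan,
                "defined": False}
    a = np.stack([actual, np.ones_like(actual)], axis=1)
    (slope, intercept), *_ = np.linalg.lstsq(a, predicted, rcond=None)
    fitted = slope * actual + intercept
    ss_res = float(((predicted - fitted) ** 2).sum())
    ss_tot = float(((predicted - predicted.mean()) ** 2).sum())
    # a constant prediction carries no information about the counts
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {"slope": float(slope), "intercept": float(intercept),
            "r2": r2, "defined": True}
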