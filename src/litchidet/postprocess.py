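"""Letterboxing, anchor estimation, prediction decoding and NMS."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import CLASSES, Box, Detection

__all__ = [
    "LetterboxTransform", "letterbox", "AnchorSet", "kmeans_anchors",
    "wh_iou", "iou", "decode", "nms",
]

PAD_VALUE = 114  # neutral gray


@dataclass(frozen=True)
class LetterboxTransform:
    """Aspect-preserving resize + symmetric padding, and its inverse."""

    scale: float
    pad_x: float
    pad_y: float
    orig_size: tuple    # (w, h)
    target_size: tuple  # (w, h)

    def apply_points(self, pts):
        return np.asarray(pts, dtype=np.float64) * self.scale + [self.pad_x, self.pad_y]

    def invert_points(self, pts):
        return (np.asarray(pts, dtype=np.float64) - [self.pad_x, self.pad_y]) / self.scale

    def invert_box(self, box: Box) -> Box:
        (x0, y0), (x1, y1) = self.invert_points([[box.x_min, box.y_min],
                                                 [box.x_max, box.y_max]])
        w, h = self.orig_size
        return Box(x0, y0, x1, y1, box.label).clip(w, h)


def letterbox(image, target=1280):
    """Scale the longer side to ``target`` and pad the rest with gray."""
    from PIL import Image

    h, w = image.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    scale = target / max(h, w)
    new_w, new_h = round(w * scale), round(h * scale)
    resized = np.asarray(Image.fromarray(image).resize((new_w, new_h), Image.BILINEAR))
    pad_x = (target - new_w) // 2
    pad_y = (target - new_h) // 2
    canvas = np.full((target, target) + image.shape[2:], PAD_VALUE, dtype=image.dtype)
    canvas[pad_y:pad_y + new_h, pad_x:pad_x + new_w] = resized
    return canvas, LetterboxTransform(scale, pad_x, pad_y, (w, h), (target, target))


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnchorSet:
    """k prior boxes grouped 3 per detection scale, ascending by area."""

    anchors: tuple  # ((w,h), ...) per scale
    strides: tuple

    def __post_init__(self):
        if len(self.anchors) != len(self.strides):
            raise ValueError("one anchor group per stride required")
        for group in self.anchors:
            for w, h in group:
                if w <= 0 or h <= 0:
                    raise ValueError("anchor dimensions must be positive")

    @property
    def flat(self):
        return np.array([wh for group in self.anchors for wh in group], dtype=np.float64)


def wh_iou(wh1, wh2):
    """IoU of width-height pairs anchored at the origin, pairwise matrix."""
    wh1 = np.asarray(wh1, dtype=np.float64)[:, None]
    wh2 = np.asarray(wh2, dtype=np.float64)[None]
    inter = np.minimum(wh1, wh2).prod(axis=2)
    return inter / (wh1.prod(axis=2) + wh2.prod(axis=2) - inter)


def kmeans_wh(wh, k, seed=0, distance="iou", max_iter=300, max_restarts=10):
    """K-means on width-height pairs under 1-IoU (or Euclidean) distance.

    Iterates to an assignment fixpoint; restarts with a fresh draw if
    clusters collapse below k.  Returns (centroids sorted by area,
    per-iteration mean best-IoU history).
    """
    wh = np.asarray(wh, dtype=np.float64).reshape(-1, 2)
    if len(wh) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(wh)}")
    rng = np.random.default_rng(seed)
    history = []
    for _ in range(max_restarts):
        centroids = wh[rng.choice(len(wh), k, replace=False)].copy()
        assign = np.full(len(wh), -1)
        history = []
        for _ in range(max_iter):
            if distance == "iou":
                sim = wh_iou(wh, centroids)
                d = 1.0 - sim
            else:
                d = ((wh[:, None] - centroids[None]) ** 2).sum(axis=2)
                sim = wh_iou(wh, centroids)
            history.append(float(sim.max(axis=1).mean()))
            new_assign = d.argmin(axis=1)
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for j in range(k):
                members = wh[assign == j]
                if len(members):
                    centroids[j] = members.mean(axis=0)
        if len(np.unique(assign)) == k:
            break
    return centroids[np.argsort(centroids.prod(axis=1))], history


def kmeans_anchors(wh, k=9, seed=0, strides=None, distance="iou",
                   max_iter=300, max_restarts=10):
    """Estimate an AnchorSet: k centroids grouped 3 per detection scale."""
    if k % 3:
        raise ValueError("k must be a multiple of 3 (3 anchors per scale)")
    if strides is None:
        strides = (8, 16, 32)[: k // 3]
    centroids, _ = kmeans_wh(wh, k, seed, distance, max_iter, max_restarts)
    groups = tuple(tuple(map(tuple, centroids[3 * i:3 * i + 3]))
                   for i in range(k // 3))
    return AnchorSet(groups, tuple(strides))


def mean_best_iou(wh, anchor_set: AnchorSet) -> float:
    """Mean over boxes of the best IoU against any anchor (fit diagnostic)."""
    return float(wh_iou(wh, anchor_set.flat).max(axis=1).mean())


# ---------------------------------------------------------------------------
# decoding and suppression
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def decode(head_outputs, anchor_set: AnchorSet, conf_threshold=0.5, nc=2):
    """YOLOv5-style decode of raw head maps into detections.

    Center: ``(2*sigmoid(t_xy) - 0.5 + cell) * stride``; size:
    ``(2*sigmoid(t_wh))**2 * anchor``; confidence = objectness x class
    probability.  Accepts maps of shape (na*(5+nc), H, W) or with a
    leading batch axis of 1.
    """
    if len(head_outputs) != len(anchor_set.anchors):
        raise ValueError(f"{len(head_outputs)} head maps for "
                         f"{len(anchor_set.anchors)} anchor scales")
    detections = []
    for si, (raw, group, stride) in enumerate(
            zip(head_outputs, anchor_set.anchors, anchor_set.strides)):
        arr = np.asarray(raw.data if hasattr(raw, "data") else raw, dtype=np.float64)
        if arr.ndim == 4:
            if arr.shape[0] != 1:
                raise ValueError("decode expects a single image per call")
            arr = arr[0]
        na = len(group)
        no = 5 + nc
        if arr.shape[0] != na * no:
            raise ValueError(f"scale {si} (stride {stride}): expected "
                             f"{na * no} channels, got {arr.shape[0]}")
        h, w = arr.shape[1:]
        p = _sigmoid(arr.reshape(na, no, h, w))
        gy, gx = np.mgrid[0:h, 0:w]
        cx = (2 * p[:, 0] - 0.5 + gx) * stride
        cy = (2 * p[:, 1] - 0.5 + gy) * stride
        anchors = np.array(group, dtype=np.float64)
        bw = (2 * p[:, 2]) ** 2 * anchors[:, 0, None, None]
        bh = (2 * p[:, 3]) ** 2 * anchors[:, 1, None, None]
        cls_prob = p[:, 5:]
        best_cls = cls_prob.argmax(axis=1)
        best_prob = np.take_along_axis(cls_prob, best_cls[:, None], axis=1)[:, 0]
        conf = p[:, 4] * best_prob
        keep = np.argwhere(conf >= conf_threshold)
        for a, i, j in keep:
            detections.append(Detection(
                Box(cx[a, i, j] - bw[a, i, j] / 2, cy[a, i, j] - bh[a, i, j] / 2,
                    cx[a, i, j] + bw[a, i, j] / 2, cy[a, i, j] + bh[a, i, j] / 2,
                    CLASSES[best_cls[a, i, j]]),
                float(conf[a, i, j])))
    detections.sort(key=lambda d: -d.confidence)
    return detections


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes."""
    return a.iou(b)


def nms(detections, iou_threshold=0.45, class_aware=True):
    """Greedy non-maximum suppression, descending confidence order."""
    dets = sorted(detections, key=lambda d: -d.confidence)
    kept = []
    for d in dets:
        suppressed = False
        for k in kept:
            if class_aware and k.label != d.label:
                continue
            if k.box.iou(d.box) > iou_threshold:
                suppressed = True
                break
        if not suppressed:
            kept.append(d)
    return kept
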