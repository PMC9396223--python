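"""Scikit-learn style estimator facade over the detector pipeline.

``LitchiDetector`` bundles variant construction, anchor estimation,
training and post-processing behind the familiar ``fit`` / ``predict``
/ ``score`` surface, so it slots into sklearn model selection and
pipelines.  ``X`` is a list of HxWx3 uint8 RGB images; ``y`` is a
parallel list of ground truth — either ``ImageRecord`` objects or
plain lists of ``Box``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .architecture import build_variant
from .postprocess import AnchorSet, decode, kmeans_anchors, letterbox, nms
from .records import Box, ImageRecord

__all__ = ["LitchiDetector", "predict_images"]


def predict_images(model, images, anchor_set, conf_threshold=0.25,
                   nms_iou=0.45, input_size=None):
    """Letterbox, forward, decode and suppress; boxes in original pixels."""
    size = input_size or model.spec.input_size
    model.eval()
    out = []
    for image in images:
        boxed, tf = letterbox(image, size)
        x = boxed.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
        preds = model(x)
        dets = decode(preds, anchor_set, conf_threshold, model.spec.nc)
        dets = nms(dets, nms_iou)
        out.append([d.__class__(tf.invert_box(d.box), d.confidence)
                    for d in dets])
    return out


class LitchiDetector(BaseEstimator):
    """Two-class litchi detector with a fit/predict interface.

    Parameters mirror the published training configuration; epochs and
    input size are the desk-scale dials.  Fitted attributes:
    ``model_`` (the network), ``anchors_`` (estimated AnchorSet),
    ``history_`` (per-epoch losses / validation mAP) and ``classes_``.
    """

    def __init__(self, variant="full_cut", input_size=None, epochs=5,
                 batch_size=8, lr0=0.01, eta_min=2e-3, momentum=0.937,
                 weight_decay=5e-3, t_max=None, mosaic_prob=0.0,
                 conf_threshold=0.25, nms_iou=0.45, anchors="kmeans",
                 seed=0):
        self.variant = variant
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.eta_min = eta_min
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.t_max = t_max
        self.mosaic_prob = mosaic_prob
        self.conf_threshold = conf_threshold
        self.nms_iou = nms_iou
        self.anchors = anchors
        self.seed = seed

    # -- plumbing ------------------------------------------------------------
    def _records(self, X, y):
        records = []
        for image, truth in zip(X, y):
            if isinstance(truth, ImageRecord):
                records.append(truth)
            else:
                h, w = image.shape[:2]
                records.append(ImageRecord("in-memory.jpg", w, h, list(truth)))
        return records

    def _estimate_anchors(self, records, size):
        from .training import _prepare  # letterboxed geometry
        k = 6 if "cut" in str(self.variant) or getattr(self.variant, "head_cut", False) else 9
        wh = []
        for image_size, rec in records:
            for b in rec.boxes:
                if b.is_valid():
                    wh.append([b.width, b.height])
        wh = np.asarray(wh, dtype=np.float64)
        strides = (8, 16) if k == 6 else (8, 16, 32)
        if self.anchors == "kmeans" and len(wh) >= k:
            return kmeans_anchors(wh, k=k, seed=self.seed, strides=strides)
        spec_anchors = self._spec_for().resolved_anchors()
        return AnchorSet(spec_anchors, strides)

    def _spec_for(self):
        from .architecture import VARIANTS, VariantSpec
        spec = VARIANTS[self.variant] if isinstance(self.variant, str) else self.variant
        if self.input_size:
            from dataclasses import replace
            spec = replace(spec, input_size=self.input_size)
        return spec

    # -- estimator API -------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        from .records import CLASSES
        from .training import TrainConfig, train, _prepare

        records = self._records(X, y)
        size = self.input_size or self._spec_for().input_size
        pairs = list(zip(X, records))
        # anchors estimated on letterboxed geometry (what the heads see)
        prepared = [_prepare(img, rec, size) for img, rec in pairs]
        self.anchors_ = self._estimate_anchors(
            [(size, rec) for _, rec in prepared], size)
        spec = self._spec_for()
        from dataclasses import replace
        spec = replace(spec, anchors=self.anchors_.anchors, input_size=size)
        self.model_ = build_variant(spec, seed=self.seed)
        cfg = TrainConfig(lr0=self.lr0, eta_min=self.eta_min,
                          momentum=self.momentum, weight_decay=self.weight_decay,
                          batch_size=self.batch_size,
                          t_max=self.t_max or self.epochs, epochs=self.epochs,
                          mosaic_prob=self.mosaic_prob, seed=self.seed)
        val = None
        if X_val is not None:
            val = list(zip(X_val, self._records(X_val, y_val)))
        self.history_ = train(self.model_, pairs, cfg, val_data=val,
                              input_size=size)
        self.classes_ = np.array(CLASSES)
        return self

    def predict(self, X):
        """Per-image lists of Detection (post-NMS, original pixel frame)."""
        self._check_fitted()
        return predict_images(self.model_, X, self.anchors_,
                              self.conf_threshold, self.nms_iou,
                              self.input_size)

    def score(self, X, y):
        """mAP@0.5 against ground truth (higher is better)."""
        from .evaluation import evaluate

        self._check_fitted()
        dets = predict_images(self.model_, X, self.anchors_,
                              conf_threshold=0.05, nms_iou=self.nms_iou,
                              input_size=self.input_size)
        gts = [rec.boxes for rec in self._records(X, y)]
        return evaluate(dets, gts).map50

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("LitchiDetector is not fitted; call fit() first")
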