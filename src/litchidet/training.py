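"""Loss, learning-rate schedule and the desk-scale training loop.

The loss follows the unaltered YOLOv5 recipe: CIoU box regression on
positive cells, binary cross-entropy objectness on all cells with
IoU-scaled positive targets and per-scale balance weights, and BCE
classification on positives.  Targets use the cross-grid assignment:
an anchor matches a box when the width/height ratio stays below 4, and
the centre cell plus its two nearest neighbour cells all become
positive.

The published training configuration is the default: AdamW (momentum
0.937 mapped to beta1), initial learning rate 0.01 annealed by cosine
to eta_min = 2e-3 over T_max = 250 epochs, weight decay 5e-3, batch
size 8.  Desk-scale runs shrink epochs and image size, not the recipe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .nn import AdamW, Tensor
from .records import CLASS_TO_INDEX

__all__ = ["TrainConfig", "LossBreakdown", "cosine_lr", "assign_targets",
           "bce_with_logits", "compute_loss", "train", "records_to_targets"]


@dataclass
class TrainConfig:
    lr0: float = 0.01
    eta_min: float = 2e-3
    momentum: float = 0.937        # AdamW beta1 (or SGD-style momentum)
    weight_decay: float = 5e-3
    batch_size: int = 8
    t_max: int = 250
    epochs: int = 250
    optimizer: str = "adamw"
    momentum_as_beta1: bool = True
    mosaic_prob: float = 1.0
    workers: int = 8               # kept for config parity; loop is serial
    seed: int = 0

    def __post_init__(self):
        if self.eta_min >= self.lr0:
            raise ValueError("eta_min must be below the initial learning rate")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")


@dataclass
class LossBreakdown:
    box: float
    objectness: float
    classification: float
    total: object = None  # Tensor during training, float after .item()

    def as_floats(self):
        t = self.total.data.item() if isinstance(self.total, Tensor) else self.total
        return {"box": self.box, "objectness": self.objectness,
                "classification": self.classification, "total": float(t)}


def cosine_lr(t, cfg: TrainConfig) -> float:
    """lr(t) = eta_min + (lr0 - eta_min) * (1 + cos(pi t / T_max)) / 2."""
    if not 0 <= t <= cfg.t_max:
        raise ValueError(f"epoch {t} outside [0, {cfg.t_max}]")
    return cfg.eta_min + (cfg.lr0 - cfg.eta_min) * (1 + math.cos(math.pi * t / cfg.t_max)) / 2


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

ANCHOR_T = 4.0  # anchor match threshold on max wh ratio


def assign_targets(targets, anchor_set, grids):
    """Cross-grid positive assignment per scale.

    ``targets``: (m, 6) array of (image_index, class, cx, cy, w, h)
    normalised to [0, 1].  ``grids``: (h, w) per scale.  Returns, per
    scale, a dict of index arrays (b, a, gj, gi), cell-relative box
    targets (m, 4) in grid units and class indices.
    """
    targets = np.asarray(targets, dtype=np.float64).reshape(-1, 6)
    out = []
    for (gh, gw), group, stride in zip(grids, anchor_set.anchors, anchor_set.strides):
        anchors = np.array(group, dtype=np.float64) / stride  # grid units
        if len(targets) == 0:
            out.append({"b": np.zeros(0, int), "a": np.zeros(0, int),
                        "gj": np.zeros(0, int), "gi": np.zeros(0, int),
                        "box": np.zeros((0, 4)), "cls": np.zeros(0, int),
                        "anchors": anchors})
            continue
        gxy = targets[:, 2:4] * [gw, gh]
        gwh = targets[:, 4:6] * [gw, gh]
        ratio = gwh[:, None] / anchors[None]  # (m, na, 2)
        matched = np.maximum(ratio, 1.0 / ratio).max(axis=2) < ANCHOR_T
        t_idx, a_idx = np.nonzero(matched)
        if len(t_idx) == 0:
            out.append({"b": np.zeros(0, int), "a": np.zeros(0, int),
                        "gj": np.zeros(0, int), "gi": np.zeros(0, int),
                        "box": np.zeros((0, 4)), "cls": np.zeros(0, int),
                        "anchors": anchors})
            continue
        xy = gxy[t_idx]
        offs = [np.zeros_like(xy)]
        frac = xy % 1.0
        offs.append(np.where((frac[:, [0]] < 0.5) & (xy[:, [0]] > 1), [-1, 0], np.nan))
        offs.append(np.where((frac[:, [1]] < 0.5) & (xy[:, [1]] > 1), [0, -1], np.nan))
        offs.append(np.where((frac[:, [0]] >= 0.5) & (xy[:, [0]] < gw - 1), [1, 0], np.nan))
        offs.append(np.where((frac[:, [1]] >= 0.5) & (xy[:, [1]] < gh - 1), [0, 1], np.nan))
        bs, as_, gjs, gis, boxes, clss = [], [], [], [], [], []
        for off in offs:
            valid = ~np.isnan(off[:, 0])
            cell = np.floor(xy[valid] + off[valid]).astype(int)
            gi = np.clip(cell[:, 0], 0, gw - 1)
            gj = np.clip(cell[:, 1], 0, gh - 1)
            sel = t_idx[valid]
            bs.append(targets[sel, 0].astype(int))
            as_.append(a_idx[valid])
            gjs.append(gj)
            gis.append(gi)
            boxes.append(np.concatenate([xy[valid] - cell, gwh[sel]], axis=1))
            clss.append(targets[sel, 1].astype(int))
        out.append({"b": np.concatenate(bs), "a": np.concatenate(as_),
                    "gj": np.concatenate(gjs), "gi": np.concatenate(gis),
                    "box": np.concatenate(boxes), "cls": np.concatenate(clss),
                    "anchors": anchors})
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def bce_with_logits(z: Tensor, t) -> Tensor:
    """Elementwise binary cross-entropy on logits (numerically stable)."""
    t = np.asarray(t, dtype=np.float32)
    absz = z.maximum(-z)
    return z.clamp(lo=0.0) - z * t + ((-absz).exp() + 1.0).log()


def ciou(pred: Tensor, target) -> Tensor:
    """Complete IoU between (m, 4) cxcywh tensors (target is a plain array)."""
    t = np.asarray(target, dtype=np.float32)
    px, py, pw, ph = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx, ty, tw, th = t[:, 0], t[:, 1], t[:, 2], t[:, 3]
    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    tx1, tx2 = tx - tw * 0.5, tx + tw * 0.5
    ty1, ty2 = ty - th * 0.5, ty + th * 0.5
    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.clamp(lo=0.0) * ih.clamp(lo=0.0)
    union = pw * ph + tw * th - inter + 1e-7
    iou = inter / union
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw ** 2 + ch ** 2 + 1e-7
    rho2 = (px - tx) ** 2 + (py - ty) ** 2
    v = (4.0 / math.pi ** 2) * ((Tensor(tw / np.maximum(th, 1e-7)).arctan()
                                 - (pw / (ph + 1e-7)).arctan()) ** 2)
    alpha = Tensor(v.data / np.maximum(1.0 - iou.data + v.data, 1e-7))  # detached
    return iou - rho2 / c2 - alpha * v


BOX_GAIN, OBJ_GAIN, CLS_GAIN = 0.05, 1.0, 0.5


def objectness_balance(n_heads):
    return (4.0, 1.0) if n_heads == 2 else (4.0, 1.0, 0.4)


def compute_loss(predictions, targets, anchor_set, nc=2) -> LossBreakdown:
    """YOLOv5 composite loss over per-scale raw head maps."""
    no = 5 + nc
    grids = [(p.shape[2], p.shape[3]) for p in predictions]
    assigned = assign_targets(targets, anchor_set, grids)
    balance = objectness_balance(len(predictions))
    box_l = obj_l = cls_l = None
    n_batch = predictions[0].shape[0]
    for pred, asg, bal in zip(predictions, assigned, balance):
        n, _, h, w = pred.shape
        na = len(asg["anchors"])
        p = pred.reshape(n, na, no, h, w).transpose(0, 1, 3, 4, 2)  # (n,na,h,w,no)
        tobj = np.zeros((n, na, h, w), dtype=np.float32)
        m = len(asg["b"])
        if m:
            ps = p[asg["b"], asg["a"], asg["gj"], asg["gi"]]  # (m, no)
            pxy = ps[:, 0:2].sigmoid() * 2.0 - 0.5
            pwh = (ps[:, 2:4].sigmoid() * 2.0) ** 2 * asg["anchors"][asg["a"]]
            pbox = Tensor.concat([pxy, pwh], axis=1)
            iou_t = ciou(pbox, asg["box"])
            box_term = (1.0 - iou_t).mean()
            box_l = box_term if box_l is None else box_l + box_term
            tobj[asg["b"], asg["a"], asg["gj"], asg["gi"]] = \
                np.clip(iou_t.data, 0.0, None)
            if nc > 1:
                tcls = np.zeros((m, nc), dtype=np.float32)
                tcls[np.arange(m), asg["cls"]] = 1.0
                cls_term = bce_with_logits(ps[:, 5:], tcls).mean()
                cls_l = cls_term if cls_l is None else cls_l + cls_term
        obj_term = bce_with_logits(p[..., 4], tobj).mean() * bal
        obj_l = obj_term if obj_l is None else obj_l + obj_term
    zero = Tensor(np.zeros(()))
    box_l = box_l if box_l is not None else zero
    cls_l = cls_l if cls_l is not None else zero
    total = (box_l * BOX_GAIN + obj_l * OBJ_GAIN + cls_l * CLS_GAIN) * float(n_batch)
    return LossBreakdown(float(box_l.data), float(obj_l.data),
                         float(cls_l.data), total)


# ---------------------------------------------------------------------------
# data plumbing + loop
# ---------------------------------------------------------------------------

def records_to_targets(records, image_index_offset=0):
    """Stack normalised (img, cls, cx, cy, w, h) rows from ImageRecords."""
    rows = []
    for bi, rec in enumerate(records):
        for b in rec.boxes:
            if not b.is_valid():
                continue
            cx, cy = b.center
            rows.append([bi + image_index_offset, CLASS_TO_INDEX[b.label],
                         cx / rec.width, cy / rec.height,
                         b.width / rec.width, b.height / rec.height])
    return np.array(rows, dtype=np.float64).reshape(-1, 6)


def _prepare(image, record, size):
    from .postprocess import letterbox
    from .records import Box, ImageRecord

    boxed, tf = letterbox(image, size)
    boxes = []
    for b in record.boxes:
        (x0, y0), (x1, y1) = tf.apply_points([[b.x_min, b.y_min], [b.x_max, b.y_max]])
        boxes.append(Box(x0, y0, x1, y1, b.label))
    return boxed, ImageRecord(record.image_path, size, size, boxes)


def recalibrate_bn(model, batches):
    """Re-estimate BatchNorm running statistics from data.

    Desk-scale runs take far fewer optimiser steps than the BN
    momentum assumes, leaving running means/variances near their
    initial values; a post-training pass over the data replaces them
    with the observed batch statistics.
    """
    from .nn import BatchNorm2d

    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 1.0  # each forward captures that batch's stats exactly
    model.train()
    acc = None
    n_batches = 0
    for batch in batches:
        model(batch)
        current = [(bn.running_mean.copy(), bn.running_var.copy()) for bn in bns]
        acc = current if acc is None else [
            (a + m, b + v) for (a, b), (m, v) in zip(acc, current)]
        n_batches += 1
    if n_batches:
        for bn, (m_sum, v_sum) in zip(bns, acc):
            bn.running_mean[...] = m_sum / n_batches
            bn.running_var[...] = v_sum / n_batches
    for bn, mom in zip(bns, saved):
        bn.momentum = mom
    model.eval()


def train(model, train_data, cfg: TrainConfig, val_data=None, input_size=None,
          progress=None):
    """Run the training loop on (image, ImageRecord) pairs.

    Returns a history dict with per-epoch loss components, learning
    rates and (when ``val_data`` is given) validation mAP@0.5.  The
    epoch count may be below ``t_max``; the schedule still anneals on
    the ``t_max`` horizon, exactly as configured.
    """
    from .augment import mosaic as make_mosaic
    from .detector import predict_images
    from .evaluation import evaluate
    from .postprocess import AnchorSet

    if not train_data:
        raise ValueError("empty training dataset")
    size = input_size or model.spec.input_size
    anchor_set = AnchorSet(model.spec.resolved_anchors(), model.spec.strides)
    rng = np.random.default_rng(cfg.seed)
    prepared = [_prepare(img, rec, size) for img, rec in train_data]

    no_decay = [p for name, p in model.named_parameters()
                if name.endswith("bias") or ".bn." in name]
    if cfg.optimizer != "adamw":
        raise ValueError("only the AdamW optimiser is implemented")
    beta1 = cfg.momentum if cfg.momentum_as_beta1 else 0.9
    opt = AdamW(model.parameters(), lr=cfg.lr0, beta1=beta1,
                weight_decay=cfg.weight_decay, no_decay=no_decay)

    history = {"loss": [], "box": [], "obj": [], "cls": [], "lr": [], "val_map": []}
    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(epoch, cfg)
        order = rng.permutation(len(prepared))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            images, recs = [], []
            for i in idx:
                if cfg.mosaic_prob > 0 and len(prepared) >= 4 and \
                        rng.uniform() < cfg.mosaic_prob:
                    picks = [int(i)] + list(rng.integers(0, len(prepared), 3))
                    quad_i = [prepared[q][0] for q in picks]
                    quad_r = [prepared[q][1] for q in picks]
                    img_m, rec_m = make_mosaic(quad_i, quad_r, size, rng=rng)
                    images.append(img_m)
                    recs.append(rec_m)
                else:
                    images.append(prepared[i][0])
                    recs.append(prepared[i][1])
            batch = np.stack(images).astype(np.float32).transpose(0, 3, 1, 2) / 255.0
            targets = records_to_targets(recs)
            preds = model(batch)
            loss = compute_loss(preds, targets, anchor_set, model.spec.nc)
            if not np.isfinite(loss.total.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.total.backward()
            opt.step()
            epoch_losses.append(loss.as_floats())
        means = {k: float(np.mean([e[k] for e in epoch_losses]))
                 for k in ("box", "objectness", "classification", "total")}
        history["loss"].append(means["total"])
        history["box"].append(means["box"])
        history["obj"].append(means["objectness"])
        history["cls"].append(means["classification"])
        history["lr"].append(opt.lr)
        if val_data is not None:
            recalibrate_bn(model, _stat_batches(prepared, cfg.batch_size))
            dets = predict_images(model, [img for img, _ in val_data],
                                  anchor_set, conf_threshold=0.05,
                                  input_size=size)
            report = evaluate(dets, [rec.boxes for _, rec in val_data])
            history["val_map"].append(report.map50)
            model.train()
        if progress:
            progress(epoch, history)
    recalibrate_bn(model, _stat_batches(prepared, cfg.batch_size))
    return history


def save_checkpoint(model, cfg: TrainConfig, epoch: int, path):
    """Serialise weights, the training config and the schedule position."""
    import json
    from dataclasses import asdict

    state = model.state_dict()
    np.savez_compressed(
        path, __meta=np.frombuffer(json.dumps(
            {"epoch": epoch, "cfg": asdict(cfg),
             "spec": _spec_dict(model.spec)}).encode(), dtype=np.uint8),
        **state)


def load_checkpoint(path):
    """Rebuild the model and return (model, cfg, epoch)."""
    import json

    from .architecture import VariantSpec, build_variant

    data = np.load(path)
    meta = json.loads(bytes(data["__meta"].tobytes()).decode())
    spec_d = meta["spec"]
    spec_d["anchors"] = tuple(tuple(tuple(a) for a in g)
                              for g in spec_d["anchors"]) \
        if spec_d["anchors"] else None
    spec = VariantSpec(**spec_d)
    model = build_variant(spec)
    state = {k: data[k] for k in data.files if k != "__meta"}
    model.load_state_dict(state)
    model.eval()
    return model, TrainConfig(**meta["cfg"]), meta["epoch"]


def _spec_dict(spec):
    from dataclasses import asdict

    d = asdict(spec)
    return d


def _stat_batches(prepared, batch_size):
    for start in range(0, len(prepared), batch_size):
        chunk = prepared[start:start + batch_size]
        yield np.stack([img for img, _ in chunk]).astype(
            np.float32).transpose(0, 3, 1, 2) / 255.0
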