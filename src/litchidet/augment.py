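"""Offline augmentation combos with box coordinate transforms.

Five fixed combinations enlarge a training set exactly six-fold (the
originals plus one output per combo):

1. horizontal flip (p=0.25) + vertical flip (p=0.25) + random crop of
   0-20% of width/height;
2. histogram equalisation + salt-and-pepper noise on 2% of pixels;
3. rotation by 10 degrees about the image centre;
4. random brightness 50-150% + additive Gaussian noise;
5. random scaling 70-95% + random translation of -15% to 15%.

Every geometric transform maps a box to the axis-aligned hull of its
transformed corners, clips it to the canvas and drops boxes whose
clipped area falls below ``MIN_VISIBILITY`` of the transformed area.
Mosaic (train-time 2x2 collage) lives here as well.
"""

from __future__ import annotations

import zlib
from dataclasses import replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .records import Box, ImageRecord

__all__ = [
    "MIN_VISIBILITY", "hflip", "vflip", "random_crop", "rotate",
    "equalize_hist", "salt_pepper", "brightness", "gaussian_noise",
    "scale_translate", "AugmentCombo", "COMBOS", "augment_pair",
    "augment_training_set", "mosaic", "load_image", "save_image",
]

MIN_VISIBILITY = 0.25  # keep a clipped box if >= 25% of its area survives


# ---------------------------------------------------------------------------
# box mapping
# ---------------------------------------------------------------------------

def _map_boxes(boxes, point_fn, width, height, min_visibility=MIN_VISIBILITY):
    """Axis-aligned hull of transformed corners, clipped + visibility-filtered."""
    out = []
    for b in boxes:
        corners = np.array([[b.x_min, b.y_min], [b.x_max, b.y_min],
                            [b.x_min, b.y_max], [b.x_max, b.y_max]], dtype=np.float64)
        mapped = point_fn(corners)
        hull = Box(float(mapped[:, 0].min()), float(mapped[:, 1].min()),
                   float(mapped[:, 0].max()), float(mapped[:, 1].max()), b.label)
        clipped = hull.clip(width, height)
        if hull.area > 0 and clipped.area / hull.area >= min_visibility and clipped.is_valid():
            out.append(clipped)
    return out


# ---------------------------------------------------------------------------
# geometric transforms
# ---------------------------------------------------------------------------

def hflip(image, boxes):
    h, w = image.shape[:2]
    return image[:, ::-1].copy(), [replace(b, x_min=w - b.x_max, x_max=w - b.x_min)
                                   for b in boxes]


def vflip(image, boxes):
    h, w = image.shape[:2]
    return image[::-1].copy(), [replace(b, y_min=h - b.y_max, y_max=h - b.y_min)
                                for b in boxes]


def random_crop(image, boxes, rng, frac_range=(0.0, 0.20), min_visibility=MIN_VISIBILITY):
    """Remove up to ``frac_range[1]`` of each dimension at a random offset."""
    h, w = image.shape[:2]
    fx = rng.uniform(*frac_range)
    fy = rng.uniform(*frac_range)
    cw = max(int(round(w * (1 - fx))), 1)
    ch = max(int(round(h * (1 - fy))), 1)
    x0 = int(rng.integers(0, w - cw + 1))
    y0 = int(rng.integers(0, h - ch + 1))
    out = image[y0:y0 + ch, x0:x0 + cw].copy()
    mapped = _map_boxes(boxes, lambda p: p - [x0, y0], cw, ch, min_visibility)
    return out, mapped


def rotate(image, boxes, angle_deg=10.0, min_visibility=MIN_VISIBILITY):
    """Rotate about the image centre; canvas size kept, border edge-replicated."""
    h, w = image.shape[:2]
    out = ndimage.rotate(image, angle_deg, reshape=False, order=1,
                         mode="nearest")
    theta = np.deg2rad(angle_deg)
    c, s = np.cos(theta), np.sin(theta)
    # ndimage rotates about the centre pixel; positive angle moves the
    # +x axis toward -y in image coordinates
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    rot = np.array([[c, s], [-s, c]])

    def point_fn(p):
        return (p - center) @ rot.T + center

    return out, _map_boxes(boxes, point_fn, w, h, min_visibility)


def scale_translate(image, boxes, scale, shift_x, shift_y,
                    min_visibility=MIN_VISIBILITY):
    """Scale about the centre then translate by a fraction of the canvas."""
    h, w = image.shape[:2]
    center = np.array([w / 2.0, h / 2.0])
    t = np.array([shift_x * w, shift_y * h])

    def point_fn(p):
        return (p - center) * scale + center + t

    # inverse map for the image resample: out(x) = in((x - c - t)/s + c)
    matrix = np.array([1.0 / scale, 1.0 / scale])
    offset = (center + t) * -1.0 / scale + center
    out = np.stack([ndimage.affine_transform(
        image[..., ch].astype(np.float32), matrix, offset[::-1], order=1,
        mode="constant", cval=114.0) for ch in range(image.shape[2])], axis=-1)
    out = np.clip(out, 0, 255).astype(np.uint8)
    return out, _map_boxes(boxes, point_fn, w, h, min_visibility)


# ---------------------------------------------------------------------------
# photometric transforms (boxes untouched)
# ---------------------------------------------------------------------------

def equalize_hist(image):
    out = np.empty_like(image)
    for ch in range(image.shape[2]):
        hist = np.bincount(image[..., ch].ravel(), minlength=256)
        cdf = hist.cumsum()
        nonzero = cdf[cdf > 0]
        if nonzero.size == 0:
            out[..., ch] = image[..., ch]
            continue
        lut = np.round((cdf - nonzero[0]) / max(cdf[-1] - nonzero[0], 1) * 255)
        out[..., ch] = lut.astype(np.uint8)[image[..., ch]]
    return out


def salt_pepper(image, rng, fraction=0.02):
    """Corrupt ``fraction`` of pixels, half to black and half to white."""
    h, w = image.shape[:2]
    n = int(round(h * w * fraction))
    idx = rng.choice(h * w, size=n, replace=False)
    out = image.reshape(-1, image.shape[2]).copy()
    half = n // 2
    out[idx[:half]] = 0
    out[idx[half:]] = 255
    return out.reshape(image.shape)


def brightness(image, factor):
    return np.clip(image.astype(np.float32) * factor, 0, 255).astype(np.uint8)


def gaussian_noise(image, rng, sigma):
    noisy = image.astype(np.float32) + rng.normal(0.0, sigma, image.shape)
    return np.clip(noisy, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# the five combos
# ---------------------------------------------------------------------------

class AugmentCombo:
    """One of the five offline augmentation recipes (transform-shaped)."""

    def __init__(self, combo_id: int):
        if combo_id not in (1, 2, 3, 4, 5):
            raise ValueError("combo_id must be 1..5")
        self.combo_id = combo_id

    def transform(self, image, boxes, rng):
        cid = self.combo_id
        if cid == 1:
            if rng.uniform() < 0.25:
                image, boxes = hflip(image, boxes)
            if rng.uniform() < 0.25:
                image, boxes = vflip(image, boxes)
            image, boxes = random_crop(image, boxes, rng)
        elif cid == 2:
            image = salt_pepper(equalize_hist(image), rng)
        elif cid == 3:
            image, boxes = rotate(image, boxes, 10.0)
        elif cid == 4:
            image = gaussian_noise(brightness(image, rng.uniform(0.5, 1.5)),
                                   rng, rng.uniform(5.0, 15.0))
        else:
            image, boxes = scale_translate(image, boxes, rng.uniform(0.70, 0.95),
                                           rng.uniform(-0.15, 0.15),
                                           rng.uniform(-0.15, 0.15))
        return image, boxes

    __call__ = transform


COMBOS = tuple(AugmentCombo(i) for i in range(1, 6))


def _substream(seed, key: str):
    """Per-image RNG keyed by file name, independent of processing order."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(key.encode())]))


def augment_pair(image, record: ImageRecord, combo: AugmentCombo, rng):
    out_img, out_boxes = combo.transform(image, list(record.boxes), rng)
    h, w = out_img.shape[:2]
    return out_img, ImageRecord(record.image_path, w, h, out_boxes)


def augment_training_set(records, out_dir, seed=0, image_format="jpg",
                         loader=None):
    """Write originals plus one image per (record, combo): a 6x enlargement.

    Returns the list of output ImageRecords (originals first).  Each
    output image gets a YOLO label file next to it; a manifest of the
    applied combos is written as ``augmentation_manifest.txt``.
    """
    from .data_io import write_yolo

    if not records:
        raise ValueError("no records to augment")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    loader = loader or load_image
    outputs, manifest = [], []
    for rec in records:
        image = loader(rec.image_path)
        stem = rec.image_path.stem
        copies = [(image, rec, f"{stem}.{image_format}", "original")]
        for combo in COMBOS:
            rng = _substream(seed, f"{stem}/c{combo.combo_id}")
            img_a, rec_a = augment_pair(image, rec, combo, rng)
            copies.append((img_a, rec_a, f"{stem}_c{combo.combo_id}.{image_format}",
                           f"combo{combo.combo_id}"))
        for img, r, name, tag in copies:
            path = out_dir / name
            save_image(img, path)
            out_rec = ImageRecord(path, r.width, r.height, list(r.boxes))
            write_yolo(out_rec, path.with_suffix(".txt"))
            outputs.append(out_rec)
            manifest.append(f"{name}\t{tag}")
    (out_dir / "augmentation_manifest.txt").write_text("\n".join(manifest) + "\n")
    return outputs


# ---------------------------------------------------------------------------
# mosaic (train-time only)
# ---------------------------------------------------------------------------

def mosaic(images, records, canvas_size, rng=None, center=None,
           min_visibility=MIN_VISIBILITY):
    """2x2 collage of four records around a (random) centre point.

    Each source image is resized to fill its quadrant exactly; boxes
    are remapped by the per-quadrant affine and clipped to the canvas.
    """
    if len(images) != 4 or len(records) != 4:
        raise ValueError("mosaic needs exactly 4 images and records")
    s = int(canvas_size)
    if center is None:
        if rng is None:
            center = (s // 2, s // 2)
        else:
            center = (int(rng.integers(s // 4, 3 * s // 4 + 1)),
                      int(rng.integers(s // 4, 3 * s // 4 + 1)))
    cx, cy = center
    canvas = np.full((s, s, 3), 114, dtype=np.uint8)
    quads = [(0, 0, cx, cy), (cx, 0, s - cx, cy),
             (0, cy, cx, s - cy), (cx, cy, s - cx, s - cy)]
    boxes = []
    for (x0, y0, qw, qh), img, rec in zip(quads, images, records):
        if qw < 1 or qh < 1:
            continue
        h, w = img.shape[:2]
        ys = (np.arange(qh) * (h / qh)).astype(int).clip(0, h - 1)
        xs = (np.arange(qw) * (w / qw)).astype(int).clip(0, w - 1)
        canvas[y0:y0 + qh, x0:x0 + qw] = img[np.ix_(ys, xs)]
        sx, sy = qw / w, qh / h
        boxes.extend(_map_boxes(rec.boxes,
                                lambda p, sx=sx, sy=sy, x0=x0, y0=y0:
                                p * [sx, sy] + [x0, y0],
                                s, s, min_visibility))
    return canvas, ImageRecord(Path("mosaic"), s, s, boxes)


# ---------------------------------------------------------------------------
# image file helpers
# ---------------------------------------------------------------------------

def load_image(path):
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(image, path):
    from PIL import Image

    path = Path(path)
    kwargs = {"quality": 92} if path.suffix.lower() in (".jpg", ".jpeg") else {}
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path, **kwargs)
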