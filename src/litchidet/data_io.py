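"""Annotation I/O, dataset splitting and label statistics.

Supported formats: Pascal-VOC XML in the LabelImg dialect (1-based
inclusive pixel corners) and YOLO txt labels (one ``class cx cy w h``
line per box, normalised to [0, 1]).  The 7:1:2 split reproduces the
usual bookkeeping: floor for train, round-half-up for validation, the
remainder to test.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .records import CLASSES, CLASS_TO_INDEX, Box, DatasetSplit, ImageRecord

__all__ = [
    "VocFormatError", "UnknownClassError", "read_voc", "write_voc",
    "yolo_lines", "write_yolo", "read_yolo", "split_dataset", "label_stats",
    "write_split_manifest", "read_split_manifest",
]


class VocFormatError(ValueError):
    pass


class UnknownClassError(ValueError):
    def __init__(self, name, path=None):
        self.class_name = name
        where = f" in {path}" if path else ""
        super().__init__(f"unknown class name {name!r}{where}; expected one of {CLASSES}")


def read_voc(xml_path) -> ImageRecord:
    """Parse a LabelImg Pascal-VOC file into an ImageRecord.

    VOC corners are 1-based inclusive; they become 0-based half-open
    here, so ``(xmin=1, ymin=1, xmax=10, ymax=10)`` maps to
    ``Box(0, 0, 10, 10)``.
    """
    xml_path = Path(xml_path)
    root = ET.parse(xml_path).getroot()
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise VocFormatError(f"{xml_path}: missing <size> element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    fname = root.findtext("filename") or xml_path.with_suffix(".jpg").name
    boxes = []
    for obj in root.iter("object"):
        name = obj.findtext("name")
        if name not in CLASS_TO_INDEX:
            raise UnknownClassError(name, xml_path)
        bb = obj.find("bndbox")
        if bb is None:
            raise VocFormatError(f"{xml_path}: <object> without <bndbox>")
        boxes.append(Box(float(bb.findtext("xmin")) - 1.0,
                         float(bb.findtext("ymin")) - 1.0,
                         float(bb.findtext("xmax")),
                         float(bb.findtext("ymax")),
                         name))
    return ImageRecord(xml_path.parent / fname, width, height, boxes).validate()


def write_voc(record: ImageRecord, xml_path) -> Path:
    """Write an ImageRecord as LabelImg-dialect VOC XML (inverse of read_voc)."""
    xml_path = Path(xml_path)
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(record.image_path.parent.name)
    ET.SubElement(root, "filename").text = record.image_path.name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(record.width)
    ET.SubElement(size, "height").text = str(record.height)
    ET.SubElement(size, "depth").text = "3"
    for b in record.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = b.label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = _fmt(b.x_min + 1.0)
        ET.SubElement(bb, "ymin").text = _fmt(b.y_min + 1.0)
        ET.SubElement(bb, "xmax").text = _fmt(b.x_max)
        ET.SubElement(bb, "ymax").text = _fmt(b.y_max)
    ET.indent(tree := ET.ElementTree(root))
    tree.write(xml_path, encoding="unicode")
    return xml_path


def _fmt(v: float) -> str:
    # shortest lossless float repr keeps read/write round-trips exact
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def yolo_lines(record: ImageRecord) -> list:
    """Render boxes as YOLO label lines: ``class cx cy w h`` normalised."""
    lines = []
    for i, b in enumerate(record.boxes):
        if not b.is_valid():
            raise ValueError(f"degenerate box at index {i}: {b}")
        cx, cy = b.center
        lines.append(f"{b.class_index} "
                     f"{cx / record.width:.6f} {cy / record.height:.6f} "
                     f"{b.width / record.width:.6f} {b.height / record.height:.6f}")
    return lines


def write_yolo(record: ImageRecord, txt_path) -> Path:
    txt_path = Path(txt_path)
    txt_path.write_text("\n".join(yolo_lines(record)) + ("\n" if record.boxes else ""))
    return txt_path


def read_yolo(txt_path, width, height, image_path=None) -> ImageRecord:
    txt_path = Path(txt_path)
    boxes = []
    for ln, line in enumerate(txt_path.read_text().splitlines()):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{txt_path}:{ln + 1}: expected 5 fields, got {len(parts)}")
        ci = int(parts[0])
        if not 0 <= ci < len(CLASSES):
            raise UnknownClassError(str(ci), txt_path)
        cx, cy, w, h = (float(p) for p in parts[1:])
        boxes.append(Box((cx - w / 2) * width, (cy - h / 2) * height,
                         (cx + w / 2) * width, (cy + h / 2) * height,
                         CLASSES[ci]))
    return ImageRecord(image_path or txt_path.with_suffix(".jpg"), width, height, boxes)


def split_dataset(records, ratios=(0.7, 0.1, 0.2), seed=0) -> DatasetSplit:
    """Random 7:1:2 partition.

    Sizes: train = floor(n * r_train), val = round-half-up(n * r_val),
    test = remainder.  For n = 1375 at 7:1:2 this yields 962/138/275.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(records)
    if n < 3:
        raise ValueError(f"need at least 3 records to split, got {n}")
    n_train = int(math.floor(n * ratios[0]))
    n_val = int(math.floor(n * ratios[1] + 0.5))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n} records leaves an empty part")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [records[i] for i in order]
    return DatasetSplit(shuffled[:n_train],
                        shuffled[n_train:n_train + n_val],
                        shuffled[n_train + n_val:],
                        tuple(ratios))


def label_stats(records) -> dict:
    """Total labels, per-class counts and the mature/immature class ratio."""
    counts = {name: 0 for name in CLASSES}
    for rec in records:
        for b in rec.boxes:
            counts[b.label] += 1
    total = sum(counts.values())
    immature = counts["raw_litchi"]
    ratio = counts["litchi"] / immature if immature else None
    return {"total": total, "per_class": counts,
            "ratio": ratio, "ratio_defined": immature > 0}


def write_split_manifest(split: DatasetSplit, out_dir) -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, records in split:
        p = out_dir / f"{name}.txt"
        p.write_text("".join(f"{r.image_path}\n" for r in records))
        paths[name] = p
    return paths


def read_split_manifest(out_dir) -> dict:
    out_dir = Path(out_dir)
    return {name: [Path(line) for line in (out_dir / f"{name}.txt").read_text().splitlines()]
            for name in ("train", "val", "test")}
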