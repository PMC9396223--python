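"""Core annotation types.

Coordinates are 0-based, half-open pixel intervals everywhere inside
the package; the Pascal-VOC 1-based inclusive convention is converted
once at the file boundary (see :mod:`litchidet.data_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

CLASSES = ("litchi", "raw_litchi")  # mature (red) / immature (turquoise)
CLASS_TO_INDEX = {name: i for i, name in enumerate(CLASSES)}

__all__ = ["CLASSES", "CLASS_TO_INDEX", "Box", "ImageRecord", "DatasetSplit",
           "Detection"]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    label: str = "litchi"

    def __post_init__(self):
        if self.label not in CLASS_TO_INDEX:
            raise ValueError(f"unknown class {self.label!r}; known: {CLASSES}")

    @property
    def width(self):
        return self.x_max - self.x_min

    @property
    def height(self):
        return self.y_max - self.y_min

    @property
    def area(self):
        return max(self.width, 0.0) * max(self.height, 0.0)

    @property
    def center(self):
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    @property
    def class_index(self):
        return CLASS_TO_INDEX[self.label]

    def is_valid(self):
        return self.x_min < self.x_max and self.y_min < self.y_max

    def clip(self, width, height):
        return replace(self, x_min=min(max(self.x_min, 0.0), width),
                       y_min=min(max(self.y_min, 0.0), height),
                       x_max=min(max(self.x_max, 0.0), width),
                       y_max=min(max(self.y_max, 0.0), height))

    def iou(self, other: "Box") -> float:
        ix = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        iy = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        union = self.area + other.area - inter
        return inter / union if union > 0 else 0.0


@dataclass
class ImageRecord:
    """One annotated image: path, size and its ground-truth boxes."""

    image_path: Path
    width: int
    height: int
    boxes: list = field(default_factory=list)

    def __post_init__(self):
        self.image_path = Path(self.image_path)
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")

    def validate(self):
        for i, b in enumerate(self.boxes):
            if not b.is_valid():
                raise ValueError(f"degenerate box at index {i}: {b}")
            clipped = b.clip(self.width, self.height)
            if clipped.area <= 0:
                raise ValueError(f"box {i} lies outside the image: {b}")
        return self


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    ratios: tuple = (0.7, 0.1, 0.2)

    def __iter__(self):
        yield from (("train", self.train), ("val", self.val), ("test", self.test))

    @property
    def sizes(self):
        return (len(self.train), len(self.val), len(self.test))


@dataclass(frozen=True)
class Detection:
    """Post-NMS prediction: a box, its confidence and class."""

    box: Box
    confidence: float

    @property
    def label(self):
        return self.box.label
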