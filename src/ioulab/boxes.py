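"""Axis-aligned boxes in continuous feature-map coordinates.

Boxes are stored as center/size ``(x_c, y_c, w, h)`` — the variables the
box-regression simulator optimizes — and corners are always derived, never
stored. Coordinates are continuous reals in feature-map cell units; nothing in
the loss/simulator path rounds to pixels.

:class:`FeatureMapGeometry` describes the detection-map frame (its width and
height in cells plus the reference network-input size in pixels) from which
the downsampling ratio and the S-MPDIoU scale factor derive.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "FeatureMapGeometry",
    "corners",
    "iou",
    "enclosing",
    "center_offsets",
    "corner_distances",
    "boxes_to_array",
    "boxes_from_array",
    "save_boxes_json",
    "load_boxes_json",
    "save_boxes_csv",
    "load_boxes_csv",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned box given by center ``(x_c, y_c)`` and size ``(w, h)``.

    Degenerate boxes (non-positive width or height) are rejected at
    construction; the simulator instead clamps sizes after each update so its
    iterates always remain valid boxes.
    """

    x_c: float
    y_c: float
    w: float
    h: float

    def __post_init__(self):
        for name in ("x_c", "y_c", "w", "h"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"Box.{name} must be finite, got {v!r}")
        if self.w <= 0 or self.h <= 0:
            raise ValueError(
                f"Box requires w > 0 and h > 0, got w={self.w}, h={self.h}"
            )

    @property
    def area(self) -> float:
        return self.w * self.h

    def as_array(self) -> np.ndarray:
        return np.array([self.x_c, self.y_c, self.w, self.h], dtype=float)

    def to_dict(self) -> dict:
        return {"x": self.x_c, "y": self.y_c, "w": self.w, "h": self.h}

    @classmethod
    def from_dict(cls, d: dict) -> "Box":
        return cls(float(d["x"]), float(d["y"]), float(d["w"]), float(d["h"]))

    @classmethod
    def from_corners(cls, top_left, bottom_right) -> "Box":
        (x1, y1), (x2, y2) = top_left, bottom_right
        return cls((x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class FeatureMapGeometry:
    """Detection feature-map frame: W×H cells at a reference input size.

    ``downsample = input_ref / W`` is the head's downsampling ratio (8/16/32
    in YOLO-style heads for a 640-pixel input). All shipped configurations use
    square maps; non-square maps are accepted but flagged with a warning
    because the S-MPDIoU branch threshold is then a modelling choice.
    """

    W: float
    H: float
    input_ref: float = 640.0

    def __post_init__(self):
        if self.W <= 0 or self.H <= 0 or self.input_ref <= 0:
            raise ValueError("FeatureMapGeometry requires positive W, H, input_ref")
        if not self.is_square:
            warnings.warn(
                "non-square feature map: the pi/4 baseline branch threshold "
                "is kept for fidelity but is no longer the map diagonal angle",
                UserWarning,
                stacklevel=2,
            )

    @property
    def is_square(self) -> bool:
        return self.W == self.H

    @property
    def downsample(self) -> float:
        return self.input_ref / self.W

    @property
    def diagonal_sq(self) -> float:
        return self.W ** 2 + self.H ** 2

    def to_dict(self) -> dict:
        return {"W": self.W, "H": self.H, "input_ref": self.input_ref}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMapGeometry":
        return cls(float(d["W"]), float(d["H"]), float(d.get("input_ref", 640.0)))


# -- geometric primitives --------------------------------------------------

def corners(box: Box):
    """Top-left and bottom-right corners (minimum / maximum coordinates)."""
    tl = (box.x_c - box.w / 2.0, box.y_c - box.h / 2.0)
    br = (box.x_c + box.w / 2.0, box.y_c + box.h / 2.0)
    return tl, br


def iou(a: Box, b: Box) -> float:
    """Intersection over union; 0 for disjoint boxes, 1 iff ``a == b``."""
    (ax1, ay1), (ax2, ay2) = corners(a)
    (bx1, by1), (bx2, by2) = corners(b)
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


def enclosing(a: Box, b: Box) -> Box:
    """Smallest axis-aligned box containing both ``a`` and ``b``."""
    (ax1, ay1), (ax2, ay2) = corners(a)
    (bx1, by1), (bx2, by2) = corners(b)
    return Box.from_corners(
        (min(ax1, bx1), min(ay1, by1)), (max(ax2, bx2), max(ay2, by2))
    )


def center_offsets(a: Box, b: Box):
    """Absolute horizontal and vertical gaps ``(C_w, C_h)`` between centers."""
    return abs(a.x_c - b.x_c), abs(a.y_c - b.y_c)


def corner_distances(a: Box, b: Box):
    """Euclidean distances ``(d1, d2)`` between matching TL and BR corners."""
    (ax1, ay1), (ax2, ay2) = corners(a)
    (bx1, by1), (bx2, by2) = corners(b)
    d1 = math.hypot(ax1 - bx1, ay1 - by1)
    d2 = math.hypot(ax2 - bx2, ay2 - by2)
    return d1, d2


# -- array conversion and serialization ------------------------------------

def boxes_to_array(boxes: Iterable[Box]) -> np.ndarray:
    """Stack boxes into an ``(n, 4)`` array of ``(x_c, y_c, w, h)`` rows."""
    return np.array([b.as_array() for b in boxes], dtype=float).reshape(-1, 4)


def boxes_from_array(arr: Sequence) -> list[Box]:
    arr = np.asarray(arr, dtype=float).reshape(-1, 4)
    return [Box(*row) for row in arr]


def save_boxes_json(boxes: Iterable[Box], path):
    with open(path, "w") as fh:
        json.dump([b.to_dict() for b in boxes], fh, indent=2)


def load_boxes_json(path) -> list[Box]:
    with open(path) as fh:
        return [Box.from_dict(d) for d in json.load(fh)]


def save_boxes_csv(boxes: Iterable[Box], path):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "w", "h"])
        for b in boxes:
            writer.writerow([b.x_c, b.y_c, b.w, b.h])


def load_boxes_csv(path) -> list[Box]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(Box.from_dict(row))
    return out
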