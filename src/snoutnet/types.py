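"""Shared domain types: normalized bounding boxes and annotated images."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

CLASS_NAMES = ("Normal", "Cold", "Cough", "Fever")
NUM_CLASSES = len(CLASS_NAMES)


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box in normalized center format (YOLO convention).

    ``xc``/``yc`` are the box center, ``w``/``h`` its extent, all as
    fractions of the image side; after clipping the box lies fully inside
    the unit square and has positive area.
    """

    xc: float
    yc: float
    w: float
    h: float

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box must have positive extent, got w={self.w}, h={self.h}")
        eps = 1e-6
        if (self.xc - self.w / 2 < -eps or self.xc + self.w / 2 > 1 + eps
                or self.yc - self.h / 2 < -eps or self.yc + self.h / 2 > 1 + eps):
            raise ValueError(f"box exceeds the unit square: {self}")

    def to_xyxy(self, size: float = 1.0) -> Tuple[float, float, float, float]:
        """Corner coordinates, optionally scaled to ``size`` pixels."""
        return ((self.xc - self.w / 2) * size, (self.yc - self.h / 2) * size,
                (self.xc + self.w / 2) * size, (self.yc + self.h / 2) * size)

    @staticmethod
    def from_xyxy(x1: float, y1: float, x2: float, y2: float,
                  size: float = 1.0, clip: bool = True) -> "BBox":
        x1, y1, x2, y2 = x1 / size, y1 / size, x2 / size, y2 / size
        if clip:
            x1, y1 = max(0.0, x1), max(0.0, y1)
            x2, y2 = min(1.0, x2), min(1.0, y2)
        return BBox((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def approx_equal(self, other: "BBox", tol: float = 1e-6) -> bool:
        return (abs(self.xc - other.xc) <= tol and abs(self.yc - other.yc) <= tol
                and abs(self.w - other.w) <= tol and abs(self.h - other.h) <= tol)


@dataclass
class ImageRecord:
    """One annotated image: pixels, animal identity, and class/box labels.

    ``pixels`` is an H x W x 3 float array in [0, 1] (or standardized
    after preprocessing); ``annotations`` pairs a health-state class id
    (0 Normal, 1 Cold, 2 Cough, 3 Fever) with a normalized box.
    """

    pixels: np.ndarray
    animal_id: str
    annotations: List[Tuple[int, BBox]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        if not self.animal_id:
            raise ValueError("animal_id must be non-empty")
        for cid, _ in self.annotations:
            if cid not in range(NUM_CLASSES):
                raise ValueError(
                    f"class id {cid} outside vocabulary {list(range(NUM_CLASSES))}")

    @property
    def classes(self) -> List[int]:
        return [cid for cid, _ in self.annotations]
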