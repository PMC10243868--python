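"""Box algebra, Jaccard overlap, tiling and pyramid-level coordinate mapping.

Coordinate convention: 0-based, half-open pixel intervals ``[x_min, x_max) x
[y_min, y_max)``, so ``area = (x_max - x_min) * (y_max - y_min)``.  All
overlap computations use continuous box geometry; rasterized (integer pixel
membership) Jaccard agrees with the continuous value for integer-coordinate
boxes under this convention, which the test suite exploits as an independent
oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Box",
    "LevelMap",
    "TileGrid",
    "Direction",
    "jaccard",
    "pairwise_jaccard",
    "map_box",
    "make_tile_grid",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel space.

    Corners are ``(x_min, y_min)`` inclusive and ``(x_max, y_max)`` exclusive.
    Empty or inverted boxes are rejected at construction, as are negative or
    non-finite coordinates.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"box coordinates must be finite, got {coords}")
        if min(coords) < 0:
            raise ValueError(f"box coordinates must be non-negative, got {coords}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"empty box: need x_min < x_max and y_min < y_max, got {coords}"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def intersection_area(self, other: "Box") -> float:
        iw = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        ih = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih

    def as_corners(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    # COCO-style [x, y, width, height] serialization ----------------------
    def to_xywh(self) -> list[float]:
        return [self.x_min, self.y_min, self.width, self.height]

    @classmethod
    def from_xywh(cls, xywh: Sequence[float]) -> "Box":
        x, y, w, h = xywh
        return cls(x, y, x + w, y + h)


class Direction(str, Enum):
    """Direction of a pyramid-level coordinate mapping."""

    LOW_TO_HIGH = "low_to_high"
    HIGH_TO_LOW = "high_to_low"


@dataclass(frozen=True)
class LevelMap:
    """Scale relation between a low- and a high-magnification pyramid level.

    ``scale_x`` / ``scale_y`` are high-magnification pixels per
    low-magnification pixel and must be >= 1.
    """

    scale_x: float
    scale_y: float
    level_low: int = 0
    level_high: int = 1

    def __post_init__(self) -> None:
        if self.scale_x < 1 or self.scale_y < 1:
            raise ValueError(
                f"level scales must be >= 1, got ({self.scale_x}, {self.scale_y})"
            )


@dataclass(frozen=True)
class TileGrid:
    """Partition of a ``width x height`` image into ``tile_side``-sized tiles.

    Interior tiles are exactly square; tiles on the right/bottom edge are
    clipped to the image bounds so the grid covers the image exactly once.
    """

    image_width: int
    image_height: int
    tile_side: int
    tiles: tuple[Box, ...]

    def __len__(self) -> int:
        return len(self.tiles)


def jaccard(a: Box, b: Box) -> float:
    """Jaccard index (IoU) of two boxes: ``|a ∩ b| / |a ∪ b|``.

    Symmetric, in [0, 1], and equal to 1 iff the boxes coincide.
    """
    inter = a.intersection_area(b)
    union = a.area + b.area - inter
    return inter / union


def pairwise_jaccard(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Jaccard matrix between two arrays of corner-form boxes.

    Parameters
    ----------
    boxes_a, boxes_b
        Arrays of shape ``(n, 4)`` / ``(m, 4)`` with columns
        ``x_min, y_min, x_max, y_max``.

    Returns
    -------
    ndarray of shape ``(n, m)``.
    """
    a = np.asarray(boxes_a, dtype=float).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=float).reshape(-1, 4)
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return inter / union


def boxes_to_array(boxes: Iterable[Box]) -> np.ndarray:
    """Stack boxes into an ``(n, 4)`` corner-form float array."""
    arr = np.array([b.as_corners() for b in boxes], dtype=float)
    return arr.reshape(-1, 4)


def map_box(box: Box, level_map: LevelMap, direction: Direction | str) -> Box:
    """Map a box between pyramid levels.

    ``low_to_high`` multiplies coordinates by the level scales (a low-mag ROI
    expressed at high magnification); ``high_to_low`` divides.  The round trip
    low -> high -> low is the identity for integer scales.
    """
    direction = Direction(direction)
    sx, sy = level_map.scale_x, level_map.scale_y
    if direction is Direction.LOW_TO_HIGH:
        return Box(box.x_min * sx, box.y_min * sy, box.x_max * sx, box.y_max * sy)
    return Box(box.x_min / sx, box.y_min / sy, box.x_max / sx, box.y_max / sy)


def make_tile_grid(width: int, height: int, tile_side: int) -> TileGrid:
    """Tile a ``width x height`` image with ``tile_side``-sized square patches.

    Produces ``ceil(width / tile_side) * ceil(height / tile_side)`` tiles in
    row-major order; edge tiles are clipped to the image so the tiles
    partition the image area exactly.

    Raises
    ------
    ValueError
        If ``tile_side`` is not in ``[1, min(width, height)]``.
    """
    if tile_side < 1:
        raise ValueError(f"tile_side must be >= 1, got {tile_side}")
    if tile_side > width or tile_side > height:
        raise ValueError(
            f"degenerate grid: tile_side {tile_side} exceeds image "
            f"{width}x{height}"
        )
    tiles = []
    for y0 in range(0, height, tile_side):
        for x0 in range(0, width, tile_side):
            tiles.append(
                Box(x0, y0, min(x0 + tile_side, width), min(y0 + tile_side, height))
            )
    return TileGrid(width, height, tile_side, tuple(tiles))
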