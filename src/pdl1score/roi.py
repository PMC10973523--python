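"""Whole-slide region-of-interest delineation at tile resolution.

A slide is partitioned into non-overlapping tiles (half-open pixel bounds),
each tile is labelled in/out of the regions of interest, and the per-tile
labels assemble into a binary raster.  Two labelling routes are provided:

* inversion of expert non-ROI polygon annotations (a tile is out when its
  overlap fraction with the annotated area exceeds a threshold), matching
  the annotate-the-artifacts-then-invert workflow used for lymphoma slides
  where no delimited tumor region exists; and
* a pluggable per-tile classifier.  The shipping baseline is training-free:
  it calls a tile tissue when enough of its pixels are chromatic
  (hematoxylin/DAB stains are strongly saturated in HSV, while blank glass
  and achromatic debris are not).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import box as shapely_box
from shapely.geometry import Polygon as ShapelyPolygon

logger = logging.getLogger(__name__)

__all__ = [
    "Tile",
    "TileGrid",
    "RoiMask",
    "tile_slide",
    "invert_non_roi",
    "classify_tiles",
    "restrict_cells_to_roi",
    "baseline_tissue_classifier",
]

IN, OUT = "in", "out"


@dataclass(frozen=True)
class Tile:
    """One tile: grid position plus half-open pixel bounds [x0,x1) x [y0,y1)."""

    row: int
    col: int
    x0: int
    y0: int
    x1: int
    y1: int
    padded: bool = False  # True when clipped at the slide edge

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)


@dataclass
class TileGrid:
    """Non-overlapping tiling of a slide extent (width, height in pixels)."""

    tile_size: int
    width: int
    height: int
    tiles: list[Tile]

    @property
    def shape(self) -> tuple[int, int]:
        rows = max(t.row for t in self.tiles) + 1
        cols = max(t.col for t in self.tiles) + 1
        return rows, cols

    def tile_of_point(self, x: float, y: float) -> tuple[int, int]:
        """Grid position of a point under the half-open convention."""
        return int(y // self.tile_size), int(x // self.tile_size)


@dataclass
class RoiMask:
    """Per-tile in/out labels plus the assembled tile-resolution raster."""

    grid: TileGrid
    labels: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {IN, OUT}
        if bad:
            raise ValueError(f"tile labels must be 'in' or 'out', got {bad}")

    def to_raster(self) -> np.ndarray:
        """Boolean raster at tile resolution (True = in-ROI)."""
        rows, cols = self.grid.shape
        raster = np.zeros((rows, cols), dtype=bool)
        for (r, c), lab in self.labels.items():
            raster[r, c] = lab == IN
        return raster

    @classmethod
    def from_raster(cls, grid: TileGrid, raster: np.ndarray) -> "RoiMask":
        labels = {(t.row, t.col): (IN if raster[t.row, t.col] else OUT) for t in grid.tiles}
        return cls(grid=grid, labels=labels)

    def is_in(self, row: int, col: int) -> bool:
        return self.labels.get((row, col)) == IN


def tile_slide(extent: tuple[int, int], tile_size: int = 256) -> TileGrid:
    """Partition a (width, height) extent into half-open tiles.

    Edge tiles are clipped to the extent and flagged ``padded``; every pixel
    belongs to exactly one tile and the tile areas sum to the slide area.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    width, height = extent
    if width <= 0 or height <= 0:
        raise ValueError("slide extent must be positive")
    rows = math.ceil(height / tile_size)
    cols = math.ceil(width / tile_size)
    tiles = []
    for r in range(rows):
        for c in range(cols):
            x0, y0 = c * tile_size, r * tile_size
            x1, y1 = min(x0 + tile_size, width), min(y0 + tile_size, height)
            padded = (x1 - x0 != tile_size) or (y1 - y0 != tile_size)
            tiles.append(Tile(r, c, x0, y0, x1, y1, padded))
    return TileGrid(tile_size=tile_size, width=width, height=height, tiles=tiles)


def _repair(poly: ShapelyPolygon) -> shapely.Geometry:
    if poly.is_valid:
        return poly
    logger.warning("self-intersecting non-ROI polygon repaired by union of valid rings")
    return shapely.make_valid(poly)


def invert_non_roi(
    polygons: Sequence[Sequence[tuple[float, float]]],
    extent: tuple[int, int],
    grid: TileGrid | None = None,
    overlap_threshold: float = 0.5,
) -> RoiMask:
    """ROI mask by inversion of non-ROI polygon annotations.

    A tile is out-of-ROI iff its area overlap fraction with the union of the
    polygons strictly exceeds ``overlap_threshold``; the ROI is the
    complement.  An empty polygon list marks every tile in-ROI.
    """
    grid = grid or tile_slide(extent)
    if not polygons:
        return RoiMask(grid=grid, labels={(t.row, t.col): IN for t in grid.tiles})
    union = shapely.unary_union([_repair(ShapelyPolygon(p)) for p in polygons])
    labels = {}
    for t in grid.tiles:
        frac = union.intersection(shapely_box(t.x0, t.y0, t.x1, t.y1)).area / t.area
        labels[(t.row, t.col)] = OUT if frac > overlap_threshold else IN
    return RoiMask(grid=grid, labels=labels)


def baseline_tissue_classifier(
    saturation_threshold: float = 0.12,
    tissue_fraction_threshold: float = 0.02,
) -> Callable[[np.ndarray], tuple[str, float]]:
    """Training-free tile classifier on chromatic tissue fraction.

    Stained tissue pixels (blue nuclei, brown membranes) are strongly
    saturated in HSV; blank glass and achromatic artifact are not.  The
    returned callable maps an RGB tile to ``(label, score)`` where the score
    is the chromatic pixel fraction clipped to [0, 1].
    """
    from skimage.color import rgb2hsv

    def classify(tile: np.ndarray) -> tuple[str, float]:
        hsv = rgb2hsv(tile)
        frac = float(np.mean(hsv[..., 1] > saturation_threshold))
        return (IN if frac >= tissue_fraction_threshold else OUT), min(frac, 1.0)

    return classify


def classify_tiles(
    tiles: dict[tuple[int, int], np.ndarray],
    grid: TileGrid,
    classifier: Callable[[np.ndarray], tuple[str, float]] | None = None,
) -> RoiMask:
    """Label every tile with a pluggable patch classifier.

    The classifier contract is ``tile_rgb -> (label in {'in','out'}, score
    in [0,1])``; a violation raises ``ValueError``.
    """
    classifier = classifier or baseline_tissue_classifier()
    labels = {}
    for (r, c), img in tiles.items():
        out = classifier(img)
        try:
            label, score = out
        except (TypeError, ValueError) as exc:
            raise ValueError(f"classifier must return (label, score), got {out!r}") from exc
        if label not in (IN, OUT):
            raise ValueError(f"classifier returned label {label!r}, expected 'in' or 'out'")
        if not 0.0 <= float(score) <= 1.0:
            raise ValueError(f"classifier score {score} outside [0, 1]")
        labels[(r, c)] = label
    return RoiMask(grid=grid, labels=labels)


def restrict_cells_to_roi(cells: Iterable, mask: RoiMask) -> list:
    """Keep exactly the cells whose center lies in an in-ROI tile.

    Tile membership follows the half-open bound convention: a center sitting
    on a tile's right/bottom edge belongs to the adjacent tile.
    """
    kept = []
    for cell in cells:
        r, c = mask.grid.tile_of_point(*cell.center)
        if mask.is_in(r, c):
            kept.append(cell)
    return kept
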