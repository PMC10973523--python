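"""End-to-end slide scoring: ROI -> detect -> segment -> stain -> score.

A slide is a directory (or in-memory dict) of coordinate-named RGB tiles.
The pipeline restricts work to in-ROI tiles — obtained either by inverting
non-ROI polygon annotations or from the baseline tissue classifier — then,
per tile, detects nucleus centers, segments them, dilates the masks,
computes each cell's brown-area ratio, and finally applies the area-ranked
m/k/t rule to produce the slide's TPS* with full stage-by-stage counts.
All stages are deterministic, so a run is reproducible from its logged
configuration alone.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import detect as _detect
from . import roi as _roi
from . import segment as _segment
from . import stain as _stain
from .config import PipelineConfig
from .io import read_asap_annotations
from .score import ScoringParams, SlideScore, tps_star

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "load_slide_tiles", "cells_to_frame"]

_TILE_RE = re.compile(r"tile_r(\d+)_c(\d+)\.(?:png|tif|tiff)$")


@dataclass
class PipelineResult:
    """Slide score plus the per-cell records and the ROI mask behind it."""

    score: SlideScore
    cells: list[_segment.CellRecord]
    roi_mask: _roi.RoiMask
    config: PipelineConfig


def load_slide_tiles(slide_dir: str | Path) -> tuple[dict[tuple[int, int], np.ndarray], int]:
    """Read coordinate-named tiles (``tile_r{row}_c{col}.png``) from a directory."""
    slide_dir = Path(slide_dir)
    tiles: dict[tuple[int, int], np.ndarray] = {}
    for p in sorted(slide_dir.iterdir()):
        match = _TILE_RE.match(p.name)
        if match:
            tiles[(int(match.group(1)), int(match.group(2)))] = np.asarray(Image.open(p).convert("RGB"))
    if not tiles:
        raise FileNotFoundError(f"no tile_r*_c*.png tiles found in {slide_dir}")
    sizes = {img.shape[:2] for img in tiles.values()}
    if len(sizes) != 1:
        raise ValueError(f"tiles have inconsistent shapes: {sizes}")
    return tiles, sizes.pop()[0]


def _score_tile(
    img: np.ndarray,
    config: PipelineConfig,
) -> tuple[list[_segment.CellRecord], _detect.PointSet]:
    """Detect, segment, dilate, and stain-classify one tile's cells."""
    pts = _detect.detect_centers(
        img,
        min_distance=config.detect.min_distance,
        prominence=config.detect.prominence,
        sigma=config.detect.sigma,
    )
    labels = _segment.point_to_mask(
        img, pts.points, od_threshold=config.segment.od_threshold, sigma=config.segment.sigma
    )
    dilated = _segment.dilate_labels(labels, radius=config.segment.dilation_radius)
    cells = _segment.extract_cells(labels, dilated)
    channels = _stain.separate_stains(img)
    brown = _stain.brown_mask(channels, _stain.PositivityParams(dab_od_threshold=config.stain.dab_od_threshold))
    ratios = _stain.label_dab_ratios(dilated.labels, brown)
    for cell in cells:
        cell.dab_ratio = ratios.get(cell.id, 0.0)
        cell.is_positive = _stain.classify_positive(cell.dab_ratio, config.score.t)
    return cells, pts


def run_pipeline(
    slide: str | Path | dict[tuple[int, int], np.ndarray],
    annotations: str | Path | list | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Score one slide end to end.

    Parameters
    ----------
    slide:
        Tile directory path, or an in-memory ``{(row, col): rgb}`` dict.
    annotations:
        Non-ROI polygons — an ASAP XML path or a polygon list.  When None,
        tiles are triaged by the baseline tissue classifier instead.
    out_dir:
        When given, writes ``slide_score.json``, ``cells.csv`` and
        ``run_log.json`` there.

    An unscorable slide (too few cells) yields a structured result with
    ``score.scorable == False``; stage failures raise with the stage name.
    """
    config = config or PipelineConfig()
    if isinstance(slide, (str, Path)):
        tiles, tile_size = load_slide_tiles(slide)
    else:
        tiles = slide
        tile_size = next(iter(tiles.values())).shape[0]
    rows = max(r for r, _ in tiles) + 1
    cols = max(c for _, c in tiles) + 1
    grid = _roi.tile_slide((cols * tile_size, rows * tile_size), tile_size)

    try:
        if annotations is not None:
            polygons = (
                read_asap_annotations(annotations)
                if isinstance(annotations, (str, Path))
                else annotations
            )
            mask = _roi.invert_non_roi(
                polygons,
                (cols * tile_size, rows * tile_size),
                grid,
                overlap_threshold=config.roi.overlap_threshold,
            )
        else:
            mask = _roi.classify_tiles(tiles, grid)
    except Exception as exc:
        raise RuntimeError(f"roi stage failed: {exc}") from exc

    cells: list[_segment.CellRecord] = []
    next_id = 1
    for (r, c), img in sorted(tiles.items()):
        if not mask.is_in(r, c):
            continue
        try:
            tile_cells, _ = _score_tile(img, config)
        except Exception as exc:
            raise RuntimeError(f"cell stage failed on tile ({r}, {c}): {exc}") from exc
        for cell in tile_cells:
            cell.id = next_id
            cell.center = (cell.center[0] + c * tile_size, cell.center[1] + r * tile_size)
            next_id += 1
        cells.extend(tile_cells)

    cells = _roi.restrict_cells_to_roi(cells, mask)
    params = ScoringParams(
        m=config.score.m,
        k=config.score.k,
        t=config.score.t,
        cutoffs=tuple(config.score.cutoffs),
        min_cells=config.score.min_cells,
    )
    slide_score = tps_star(cells, params)
    result = PipelineResult(score=slide_score, cells=cells, roi_mask=mask, config=config)
    if out_dir is not None:
        _write_outputs(Path(out_dir), result)
    return result


def cells_to_frame(cells: list[_segment.CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "x": [c.center[0] for c in cells],
            "y": [c.center[1] for c in cells],
            "nucleus_area": [c.nucleus_area for c in cells],
            "dilated_area": [c.dilated_area for c in cells],
            "dab_ratio": [c.dab_ratio for c in cells],
            "is_positive": [c.is_positive for c in cells],
        }
    )


def _write_outputs(out_dir: Path, result: PipelineResult) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "slide_score.json").write_text(json.dumps(result.score.to_dict(), indent=2))
    cells_to_frame(result.cells).to_csv(out_dir / "cells.csv", index=False)
    log = {
        "config": result.config.to_dict(),
        "params": {"m": result.config.score.m, "k": result.config.score.k, "t": result.config.score.t},
        "n_tiles_in_roi": int(result.roi_mask.to_raster().sum()),
        "n_cells": len(result.cells),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    logger.info("wrote slide outputs to %s", out_dir)
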