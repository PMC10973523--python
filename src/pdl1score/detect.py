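"""Cell-center detection, density-map targets, and point matching.

The default detector is a classical operator over the hematoxylin channel
(nuclei are the one structure every cell shows regardless of PD-L1 status):
Gaussian smoothing of the hematoxylin optical density followed by local
maxima with a minimum separation and an absolute prominence threshold.  A
model-based detector can be plugged in through the same ``patch ->
PointSet`` contract.

``density_target`` builds the regression target used when training
density-map cell counters: one boundary-renormalised Gaussian kernel per
annotated center, so the map integrates to the cell count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .stain import separate_stains

__all__ = ["PointSet", "DetectionEval", "detect_centers", "density_target", "match_points"]


@dataclass
class PointSet:
    """Cell center points, (x, y) in patch pixel coordinates."""

    points: np.ndarray  # (n, 2) float
    patch_id: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) != len(np.unique(self.points, axis=0)):
            raise ValueError("PointSet contains exact duplicate points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class DetectionEval:
    """Point-matching detection quality at a given match radius."""

    tp: int
    fp: int
    fn: int
    match_radius: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def detect_centers(
    rgb: np.ndarray,
    min_distance: int = 6,
    prominence: float = 0.15,
    sigma: float = 1.5,
    patch_id: str | None = None,
) -> PointSet:
    """Detect nucleus centers on the smoothed hematoxylin OD channel.

    Parameters
    ----------
    min_distance:
        Minimum peak separation in pixels; the default equals the smallest
        nucleus diameter the synthetic generator produces.
    prominence:
        Absolute threshold on smoothed hematoxylin OD below which maxima are
        ignored (suppresses blank background).
    """
    rgb = np.asarray(rgb)
    if rgb.size == 0:
        return PointSet(points=np.empty((0, 2)), patch_id=patch_id)
    h = separate_stains(rgb).hematoxylin
    smoothed = gaussian(h, sigma=sigma, preserve_range=True)
    peaks = peak_local_max(smoothed, min_distance=min_distance, threshold_abs=prominence)
    # peak_local_max returns (row, col); points are (x, y)
    pts = peaks[:, ::-1].astype(float)
    return PointSet(points=pts, patch_id=patch_id)


def density_target(points: np.ndarray | PointSet, sigma: float, shape: tuple[int, int]) -> np.ndarray:
    """Gaussian density map whose integral equals the number of points.

    Each point contributes one Gaussian kernel truncated at +/- 4 sigma and
    renormalised to unit mass after boundary clipping, so mass is conserved
    even for points near the patch edge.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, dtype=float).reshape(-1, 2)
    h, w = shape
    out = np.zeros((h, w))
    half = int(np.ceil(4 * sigma))
    for x, y in pts:
        cx, cy = int(round(x)), int(round(y))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        k = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
        out[y0:y1, x0:x1] += k / k.sum()
    return out


def _greedy_match(pred: np.ndarray, truth: np.ndarray, radius: float) -> int:
    """One-to-one greedy matching by ascending pair distance.

    Ties are broken by the truth point's (y, x) and then the prediction
    index, so the matching is deterministic.
    """
    if len(pred) == 0 or len(truth) == 0:
        return 0
    d = np.hypot(pred[:, None, 0] - truth[None, :, 0], pred[:, None, 1] - truth[None, :, 1])
    pairs = [
        (d[i, j], truth[j, 1], truth[j, 0], i, j)
        for i in range(len(pred))
        for j in range(len(truth))
        if d[i, j] <= radius
    ]
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    tp = 0
    for _, _, _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    return tp


def _hungarian_match(pred: np.ndarray, truth: np.ndarray, radius: float) -> int:
    if len(pred) == 0 or len(truth) == 0:
        return 0
    d = np.hypot(pred[:, None, 0] - truth[None, :, 0], pred[:, None, 1] - truth[None, :, 1])
    cost = np.where(d <= radius, d, 1e9)
    ri, ci = linear_sum_assignment(cost)
    return int(np.sum(d[ri, ci] <= radius))


def match_points(
    pred: PointSet | np.ndarray,
    truth: PointSet | np.ndarray,
    radius: float = 5.0,
    method: str = "greedy",
) -> DetectionEval:
    """Evaluate predicted centers against ground-truth centers.

    One-to-one matching within ``radius`` pixels; precision of an empty
    prediction set is 0 by convention.  ``method`` selects the greedy
    nearest-distance matcher (default) or the optimal Hungarian assignment.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    p = pred.points if isinstance(pred, PointSet) else np.asarray(pred, dtype=float).reshape(-1, 2)
    t = truth.points if isinstance(truth, PointSet) else np.asarray(truth, dtype=float).reshape(-1, 2)
    if method == "greedy":
        tp = _greedy_match(p, t, radius)
    elif method == "hungarian":
        tp = _hungarian_match(p, t, radius)
    else:
        raise ValueError(f"unknown matching method {method!r}")
    return DetectionEval(tp=tp, fp=len(p) - tp, fn=len(t) - tp, match_radius=radius)
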