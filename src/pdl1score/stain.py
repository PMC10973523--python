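"""Hematoxylin / DAB stain separation and brown-ratio cell positivity.

Brightfield IHC obeys the Beer-Lambert law: the transmitted intensity of an
8-bit RGB pixel is ``I = I0 * exp(-OD)`` per channel, with the optical
density ``OD`` a linear mix of per-stain concentrations along fixed unit
absorption vectors.  With two stains (the hematoxylin nuclear counterstain
and the DAB chromogen marking PD-L1) and three channels the mix is
overdetermined, so concentrations are recovered by least squares with the
pseudo-inverse of the stain matrix.

A pixel is *brown* when its DAB optical density reaches ``dab_od_threshold``;
a cell is *PD-L1 positive* when the fraction of brown pixels inside its
dilated nucleus boundary reaches the threshold ``t`` (default 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HDAB_STAIN_MATRIX",
    "StainChannels",
    "PositivityParams",
    "forward_rgb",
    "separate_stains",
    "brown_mask",
    "cell_dab_ratio",
    "classify_positive",
    "label_dab_ratios",
]


def _unit_columns(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return m / np.linalg.norm(m, axis=0, keepdims=True)


#: Ruifrok-Johnston absorption vectors for hematoxylin (column 0) and
#: DAB (column 1), unit-normalised; rows are the R, G, B channels.
HDAB_STAIN_MATRIX: np.ndarray = _unit_columns(
    np.array(
        [
            [0.650, 0.269],
            [0.704, 0.568],
            [0.286, 0.776],
        ]
    )
)
HDAB_STAIN_MATRIX.setflags(write=False)


@dataclass
class StainChannels:
    """Per-pixel stain concentrations in optical-density units.

    Attributes
    ----------
    hematoxylin, dab:
        Non-negative float rasters, same shape as the input image.
    matrix:
        The 3x2 unit-column stain matrix used for the inversion.
    """

    hematoxylin: np.ndarray
    dab: np.ndarray
    matrix: np.ndarray = field(default_factory=lambda: HDAB_STAIN_MATRIX)

    def __post_init__(self) -> None:
        if self.hematoxylin.shape != self.dab.shape:
            raise ValueError("hematoxylin and dab rasters must share a shape")


@dataclass(frozen=True)
class PositivityParams:
    """Thresholds for the brown-ratio positivity rule.

    ``t`` is the minimum fraction of brown pixels within a cell's dilated
    boundary for the cell to count as PD-L1 positive; ``dab_od_threshold``
    is the DAB optical density at which a single pixel counts as brown.
    """

    t: float = 0.1
    dab_od_threshold: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"t must lie in [0, 1], got {self.t}")
        if self.dab_od_threshold <= 0:
            raise ValueError("dab_od_threshold must be positive")


def forward_rgb(
    c_h: np.ndarray,
    c_d: np.ndarray,
    matrix: np.ndarray = HDAB_STAIN_MATRIX,
    background: tuple[int, int, int] = (255, 255, 255),
) -> np.ndarray:
    """Render concentration rasters to an 8-bit RGB image (Beer-Lambert).

    ``rgb = background * exp(-(c_h * V_H + c_d * V_D))``, rounded to uint8.
    This is the exact forward model that :func:`separate_stains` inverts.
    """
    c_h = np.asarray(c_h, dtype=float)
    c_d = np.asarray(c_d, dtype=float)
    od = c_h[..., None] * matrix[:, 0] + c_d[..., None] * matrix[:, 1]
    bg = np.asarray(background, dtype=float)
    rgb = bg * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Optical density per channel, ``-ln(I / 255)`` with I floored at 1."""
    arr = np.asarray(rgb, dtype=float)
    return -np.log(np.clip(arr, 1.0, 255.0) / 255.0)


def separate_stains(rgb: np.ndarray, matrix: np.ndarray = HDAB_STAIN_MATRIX) -> StainChannels:
    """Unmix an RGB patch into hematoxylin and DAB concentration rasters.

    Parameters
    ----------
    rgb:
        8-bit image of shape (H, W, 3).
    matrix:
        3x2 stain matrix with unit columns; defaults to the standard
        H-DAB vectors but may be overridden per slide to absorb staining
        variation between cohorts.

    Returns
    -------
    StainChannels with concentrations clipped at zero.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {rgb.shape}")
    matrix = _unit_columns(matrix)
    od = rgb_to_od(rgb)
    conc = od @ np.linalg.pinv(matrix).T
    conc = np.clip(conc, 0.0, None)
    return StainChannels(hematoxylin=conc[..., 0], dab=conc[..., 1], matrix=matrix)


def brown_mask(channels: StainChannels, params: PositivityParams | None = None) -> np.ndarray:
    """Binary raster of DAB-brown pixels (DAB OD >= ``dab_od_threshold``)."""
    params = params or PositivityParams()
    return channels.dab >= params.dab_od_threshold


def cell_dab_ratio(region_mask: np.ndarray, brown: np.ndarray) -> float:
    """Fraction of brown pixels within one cell's dilated boundary region."""
    region_mask = np.asarray(region_mask, dtype=bool)
    n = int(region_mask.sum())
    if n == 0:
        raise ValueError("cell region is empty; DAB ratio undefined")
    return float(np.count_nonzero(brown & region_mask)) / n


def classify_positive(ratio: float, t: float) -> bool:
    """Positive iff ``ratio >= t`` (a ratio exactly at threshold is positive).

    At ``t = 0`` a cell must still show at least one brown pixel
    (``ratio > 0``), so t = 0 means "any brown pixel implies positive"
    rather than "every cell is positive".
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t must lie in [0, 1], got {t}")
    return ratio >= t if t > 0 else ratio > 0


def label_dab_ratios(dilated_labels: np.ndarray, brown: np.ndarray) -> dict[int, float]:
    """Brown-pixel fraction per label of a dilated label map, vectorised.

    Returns a mapping label -> ratio for every nonzero label present.
    """
    labels = np.asarray(dilated_labels)
    nmax = int(labels.max()) if labels.size else 0
    if nmax == 0:
        return {}
    flat = labels.ravel()
    total = np.bincount(flat, minlength=nmax + 1)
    browncnt = np.bincount(flat, weights=np.asarray(brown, dtype=float).ravel(), minlength=nmax + 1)
    out: dict[int, float] = {}
    for lab in range(1, nmax + 1):
        if total[lab] > 0:
            out[lab] = float(browncnt[lab] / total[lab])
    return out
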