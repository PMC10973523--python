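"""The area-ranked PD-L1 digital quantification rule for DLBCL.

DLBCL has no delimited tumor region, so viable tumor cells cannot be
outlined; they are instead *selected* by nuclear size, exploiting the fact
that DLBCL B cells are markedly larger than normal lymphocytes while the
very largest cells (macrophages, endothelium) are usually not tumor.  The
rule is:

1. rank all in-ROI cells by nucleus area, descending;
2. drop the top ``m`` fraction (oversized non-tumor cells);
3. take the next ``k`` largest — these are designated the tumor cells;
4. score ``TPS* = 100 * (PD-L1-positive cells among the k) / k``.

The traditional tumor proportion score ``TPS = 100 * positive tumor /
viable tumor`` is also provided for when a viable-tumor count exists (e.g.
synthetic ground truth).  Default parameters: ``m = 0.06``, ``k = 3000``,
positivity threshold ``t = 0.1``, clinical cutoffs 5% and 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segment import CellRecord

__all__ = [
    "ScoringParams",
    "SlideScore",
    "rank_by_area",
    "exclude_top_m",
    "select_top_k",
    "tps_star",
    "tps_traditional",
    "stratify",
    "sweep_parameters",
]

DEFAULT_CUTOFFS = (5.0, 50.0)
STRATUM_NAMES = ("low", "intermediate", "high")
LOG_MSE_EPS = 1e-12


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the quantification rule.

    ``m``: fraction of the largest-area cells excluded before selection;
    ``k``: number of top-area cells designated tumor cells;
    ``t``: brown-ratio threshold for per-cell positivity;
    ``cutoffs``: TPS percentages separating clinical strata;
    ``min_cells``: minimum total cells for a slide to be scorable
    (defaults to ``k`` when None).
    """

    m: float = 0.06
    k: int = 3000
    t: float = 0.1
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    min_cells: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.m < 1.0:
            raise ValueError(f"m must lie in [0, 1), got {self.m}")
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        cuts = tuple(float(c) for c in self.cutoffs)
        if any(not 0.0 < c < 100.0 for c in cuts) or list(cuts) != sorted(set(cuts)):
            raise ValueError("cutoffs must be strictly increasing within (0, 100)")

    @property
    def effective_min_cells(self) -> int:
        return self.k if self.min_cells is None else self.min_cells


@dataclass
class SlideScore:
    """TPS* with its full interpretability payload.

    Counts trace every filtering stage; ``under_k`` flags slides where
    fewer than ``k`` cells survived the exclusion (the denominator then
    falls back to the selected count).  Unscorable slides (fewer than
    ``min_cells`` cells in total) carry ``tps_star = None`` and a reason.
    """

    tps_star: float | None
    n_total: int
    n_after_exclusion: int
    n_selected: int
    n_positive_selected: int
    stratum: str | None = None
    under_k: bool = False
    scorable: bool = True
    reason: str | None = None
    tps_traditional: float | None = None
    area_histogram: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tps_star": self.tps_star,
            "tps_traditional": self.tps_traditional,
            "n_total": self.n_total,
            "n_after_exclusion": self.n_after_exclusion,
            "n_selected": self.n_selected,
            "n_positive_selected": self.n_positive_selected,
            "stratum": self.stratum,
            "under_k": self.under_k,
            "scorable": self.scorable,
            "reason": self.reason,
            "area_histogram": self.area_histogram,
        }


def _sort_key(cell: CellRecord):
    return (-cell.nucleus_area, cell.center[1], cell.center[0], cell.id)


def rank_by_area(cells: Iterable[CellRecord]) -> list[CellRecord]:
    """Descending nucleus-area order; ties broken by (y, x, id)."""
    return sorted(cells, key=_sort_key)


def exclude_top_m(ranked: Sequence[CellRecord], m: float) -> list[CellRecord]:
    """Drop the ``floor(m * N)`` largest cells, preserving order."""
    if not 0.0 <= m < 1.0:
        raise ValueError(f"m must lie in [0, 1), got {m}")
    drop = math.floor(m * len(ranked))
    return list(ranked[drop:])


def select_top_k(ranked: Sequence[CellRecord], k: int) -> tuple[list[CellRecord], bool]:
    """First ``min(k, N)`` cells and a flag marking fewer-than-k saturation."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    return list(ranked[:k]), len(ranked) < k


def _cell_positive(cell: CellRecord, t: float) -> bool:
    """Positivity at threshold t: from the DAB ratio when available,
    otherwise the precomputed flag."""
    if cell.dab_ratio is not None:
        return cell.dab_ratio >= t if t > 0 else cell.dab_ratio > 0
    return bool(cell.is_positive)


def _area_summary(cells: Sequence[CellRecord]) -> dict[str, float]:
    if not cells:
        return {}
    areas = np.array([c.nucleus_area for c in cells], dtype=float)
    qs = np.percentile(areas, [0, 25, 50, 75, 100])
    return {
        "min": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "max": float(qs[4]),
        "mean": float(areas.mean()),
    }


def tps_star(cells: Iterable[CellRecord], params: ScoringParams | None = None) -> SlideScore:
    """Apply the full rule (rank, exclude top-m, select top-k, count positives).

    The result is invariant to the input ordering of ``cells``.  Slides with
    fewer than ``min_cells`` cells are returned as a structured unscorable
    outcome rather than a numeric score, mirroring the clinical exclusion of
    low-cellularity slides.
    """
    params = params or ScoringParams()
    cells = list(cells)
    n_total = len(cells)
    if n_total < params.effective_min_cells:
        return SlideScore(
            tps_star=None,
            n_total=n_total,
            n_after_exclusion=0,
            n_selected=0,
            n_positive_selected=0,
            scorable=False,
            reason="insufficient cells",
            area_histogram=_area_summary(cells),
        )
    ranked = rank_by_area(cells)
    remaining = exclude_top_m(ranked, params.m)
    selected, under_k = select_top_k(remaining, params.k)
    n_pos = sum(_cell_positive(c, params.t) for c in selected)
    value = 100.0 * n_pos / len(selected)
    return SlideScore(
        tps_star=value,
        n_total=n_total,
        n_after_exclusion=len(remaining),
        n_selected=len(selected),
        n_positive_selected=n_pos,
        stratum=stratify(value, params.cutoffs),
        under_k=under_k,
        area_histogram=_area_summary(cells),
    )


def tps_traditional(n_positive_tumor: int, n_viable_tumor: int) -> float:
    """Traditional score: 100 * positive tumor cells / viable tumor cells."""
    if n_viable_tumor < 1:
        raise ValueError("viable tumor cell count must be at least 1")
    if not 0 <= n_positive_tumor <= n_viable_tumor:
        raise ValueError("positive count must lie in [0, viable count]")
    return 100.0 * n_positive_tumor / n_viable_tumor


def stratify(tps: float, cutoffs: Sequence[float] = DEFAULT_CUTOFFS) -> str:
    """Clinical stratum of a TPS value under left-closed cutoff intervals.

    With the default cutoffs (5, 50): [0,5) -> 'low', [5,50) ->
    'intermediate', [50,100] -> 'high'.  A score exactly at a cutoff enters
    the higher stratum.  Non-default cutoff lists yield generic stratum
    names ``stratum_0 .. stratum_n``.
    """
    if not 0.0 <= tps <= 100.0:
        raise ValueError(f"tps must lie in [0, 100], got {tps}")
    cuts = [float(c) for c in cutoffs]
    idx = sum(tps >= c for c in cuts)
    if len(cuts) == 2 and tuple(cuts) == DEFAULT_CUTOFFS:
        return STRATUM_NAMES[idx]
    return f"stratum_{idx}"


def sweep_parameters(
    slides: Sequence[Sequence[CellRecord]] | Sequence[CellRecord],
    m_values: Sequence[float],
    k_values: Sequence[int],
    t_values: Sequence[float],
    reference: Sequence[float] | float | None = None,
    base_params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Score a cohort over a (m, k, t) grid, with log-MSE against a reference.

    ``slides`` is a list of per-slide cell lists (a single flat cell list is
    treated as a one-slide cohort).  ``reference`` gives one reference TPS
    per slide (e.g. a rater mean, or the synthetic ground truth); when
    present, each grid row reports ``log10(MSE + 1e-12)`` between the
    computed TPS* values and the reference across scorable slides — the
    sensitivity analysis used to choose the rule's parameters.
    """
    if slides and isinstance(slides[0], CellRecord):
        slides = [list(slides)]  # type: ignore[list-item]
    if not (len(m_values) and len(k_values) and len(t_values)):
        raise ValueError("parameter grid must be non-empty")
    base = base_params or ScoringParams()
    ref = None if reference is None else np.atleast_1d(np.asarray(reference, dtype=float))
    if ref is not None and len(ref) != len(slides):
        raise ValueError("reference length must match the number of slides")
    rows = []
    for m in m_values:
        for k in k_values:
            for t in t_values:
                params = replace(base, m=m, k=int(k), t=t)
                scores = [tps_star(cells, params) for cells in slides]
                vals = np.array([s.tps_star for s in scores if s.scorable], dtype=float)
                row = {
                    "m": m,
                    "k": int(k),
                    "t": t,
                    "n_slides_scored": len(vals),
                    "tps_star_mean": float(vals.mean()) if len(vals) else float("nan"),
                }
                if len(slides) == 1:
                    row["tps_star"] = scores[0].tps_star
                if ref is not None:
                    mask = np.array([s.scorable for s in scores])
                    err = vals - ref[mask]
                    row["log_mse"] = float(np.log10(np.mean(err**2) + LOG_MSE_EPS)) if len(err) else float("nan")
                rows.append(row)
    return pd.DataFrame(rows)
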