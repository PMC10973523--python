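"""Inter-rater agreement statistics for TPS panels.

Agreement between pathologists (and between the algorithm and a rater
panel) is measured with ICC3k: the two-way mixed-effects, consistency,
average-measures intraclass correlation for a fixed rater set.  From the
two-way ANOVA decomposition with targets as rows and raters as columns,

    ICC3k = (MS_R - MS_E) / MS_R,      F = MS_R / MS_E,

with df1 = n - 1 and df2 = (n - 1)(k - 1); the p-value and the 95%
confidence interval come from the F distribution (CI by F-quantile
inversion).  Utilities for rater aggregation, cutoff-stratified agreement
tables, and the log-scale MSE used in parameter-sensitivity plots live
here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .score import DEFAULT_CUTOFFS, stratify

logger = logging.getLogger(__name__)

__all__ = ["ICCResult", "icc3k", "aggregate_raters", "stratified_agreement", "mse_log"]

LOG_MSE_EPS = 1e-12


@dataclass(frozen=True)
class ICCResult:
    """ICC3k with its test statistic, degrees of freedom, p-value and CI."""

    icc: float
    f_stat: float
    df1: int
    df2: int
    pval: float
    ci95: tuple[float, float]


def _as_matrix(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        table = table.to_numpy(dtype=float)
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("rater table must be 2-D (targets x raters)")
    complete = ~np.isnan(arr).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.warning("dropped %d target rows with missing ratings", dropped)
    arr = arr[complete]
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC requires at least 2 targets and 2 raters, got {n}x{k}")
    return arr


def icc3k(table: pd.DataFrame | np.ndarray, confidence: float = 0.95) -> ICCResult:
    """Two-way mixed, consistency, average-measures ICC (rows = targets).

    Rows with missing entries are dropped listwise.  Raises ``ValueError``
    on zero between-target variance, where the coefficient is undefined.
    """
    arr = _as_matrix(table)
    n, k = arr.shape
    grand = arr.mean()
    row_means = arr.mean(axis=1)
    col_means = arr.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((arr - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    msr = ss_rows / df1
    mse = max(ss_err / df2, 0.0)
    if msr <= 0:
        raise ValueError("zero between-target variance: ICC undefined")
    if mse == 0.0:
        return ICCResult(icc=1.0, f_stat=float("inf"), df1=df1, df2=df2, pval=0.0, ci95=(1.0, 1.0))
    f = msr / mse
    icc = (msr - mse) / msr
    pval = float(stats.f.sf(f, df1, df2))
    alpha = 1.0 - confidence
    fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci = (float(1 - 1 / fl), float(1 - 1 / fu))
    return ICCResult(icc=float(icc), f_stat=float(f), df1=df1, df2=df2, pval=pval, ci95=ci)


def aggregate_raters(
    table: pd.DataFrame,
    method: str = "mean",
    columns: list[str] | None = None,
) -> pd.Series:
    """Row-wise mean or median over the selected rater columns."""
    sub = table[columns] if columns is not None else table
    if sub.shape[1] < 1:
        raise ValueError("at least one rater column is required")
    if method == "mean":
        return sub.mean(axis=1)
    if method == "median":
        return sub.median(axis=1)
    raise ValueError(f"unknown aggregation method {method!r}")


def stratified_agreement(
    algorithm: pd.Series | np.ndarray,
    reference: pd.Series | np.ndarray,
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> tuple[pd.DataFrame, float]:
    """Cross-tabulate clinical strata of algorithm vs reference scores.

    Returns the contingency table (reference strata as rows, algorithm
    strata as columns; off-diagonal cells are clinically discordant calls)
    and the exact-match rate.
    """
    alg = np.asarray(algorithm, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if alg.shape != ref.shape:
        raise ValueError("algorithm and reference score vectors must align")
    # ordered stratum labels for this cutoff list (one probe value per stratum)
    ordered = [stratify(x, cutoffs) for x in [0.0, *cutoffs]]
    a = pd.Categorical([stratify(v, cutoffs) for v in alg], categories=ordered)
    r = pd.Categorical([stratify(v, cutoffs) for v in ref], categories=ordered)
    tab = pd.crosstab(
        pd.Series(r, name="reference"), pd.Series(a, name="algorithm"), dropna=False
    ).reindex(index=ordered, columns=ordered, fill_value=0)
    match_rate = float(np.mean(np.asarray(a) == np.asarray(r)))
    return tab, match_rate


def mse_log(pred: np.ndarray, ref: np.ndarray) -> float:
    """``log10(mean squared error + 1e-12)`` between two score vectors."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if pred.size == 0 or pred.shape != ref.shape:
        raise ValueError("pred and ref must be non-empty and equal-length")
    return float(np.log10(np.mean((pred - ref) ** 2) + LOG_MSE_EPS))
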