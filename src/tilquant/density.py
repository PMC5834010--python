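"""The K-nearest-neighbour lymphocyte-density statistic.

For every detected lymphocyte in a section, the average Euclidean distance
R to its N nearest lymphocytes (N = 50 by default) is computed; the local
density at that lymphocyte is estimated as N / (pi * R^2), and the median
over all lymphocytes is the slide's summary statistic.  On slides with
fewer than N + 1 lymphocytes, N is truncated to n - 1; with fewer than 2
lymphocytes the summary is undefined.  No edge correction is applied, so
densities are biased downward near the field boundary.

Units: densities are in lymphocytes per square micron when coordinates are
in microns; reports label the column "a.u." (arbitrary units) because only
relative comparisons are used downstream.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import CELL_CLASSES
from .errors import ContractViolation, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_N_NEIGHBOURS = 50


@dataclass
class CellMap:
    """A slide's detected cells as classed points in micron coordinates."""

    slide_id: str
    points: pd.DataFrame  # columns x_um, y_um, class
    width_um: float
    height_um: float

    def __post_init__(self) -> None:
        pts = self.points
        required = {"x_um", "y_um", "class"}
        if not required.issubset(pts.columns):
            raise ValidationError(f"CellMap needs columns {sorted(required)}")
        bad = set(pts["class"].unique()) - set(CELL_CLASSES)
        if bad:
            raise ValidationError(f"unknown cell classes: {sorted(bad)}")
        if len(pts) and (
            (pts["x_um"] < 0).any() or (pts["x_um"] > self.width_um).any()
            or (pts["y_um"] < 0).any() or (pts["y_um"] > self.height_um).any()
        ):
            raise ValidationError("cell coordinates fall outside the field")

    def class_xy(self, cls: str) -> np.ndarray:
        sub = self.points[self.points["class"] == cls]
        return sub[["x_um", "y_um"]].to_numpy(dtype=float)

    @classmethod
    def from_frame(cls, slide_id: str, frame: pd.DataFrame,
                   width_um: float, height_um: float,
                   class_column: str = "class") -> "CellMap":
        pts = frame.rename(columns={class_column: "class"})[["x_um", "y_um", "class"]]
        return cls(slide_id=slide_id, points=pts.reset_index(drop=True),
                   width_um=width_um, height_um=height_um)


@dataclass
class SlideDensitySummary:
    """Per-slide lymphocyte count and median KNN density."""

    slide_id: Optional[str]
    n_lymphocytes: int
    k_used: int
    median_density: Optional[float]  # None when undefined (n < 2)
    per_lymphocyte_densities: Optional[np.ndarray] = None
    patient_id: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.median_density is not None


@dataclass
class DensityChange:
    """Pre-to-post treatment density change for one patient."""

    patient_id: Optional[str]
    pre: SlideDensitySummary
    post: SlideDensitySummary
    delta: Optional[float]  # post - pre; None when either side undefined
    log_ratio: Optional[float]  # ln(post/pre) when both strictly positive


def knn_mean_distance(points: np.ndarray, index: int, k: int) -> float:
    """Mean of the k smallest distances from ``points[index]`` to the rest.

    The distance multiset (not point identity) determines the result: tied
    distances are included as values, so duplicated coordinates simply
    contribute zeros.  Exact reference semantics for the KD-tree path.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ContractViolation("need at least 2 points")
    if not (1 <= k <= n - 1):
        raise ContractViolation(f"k must be in [1, {n - 1}], got {k}")
    d = np.sqrt(((pts - pts[index]) ** 2).sum(axis=1))
    d = np.delete(d, index)
    return float(np.partition(d, k - 1)[:k].mean())


def lymphocyte_density(
    points: np.ndarray,
    n_target: int = DEFAULT_N_NEIGHBOURS,
    slide_id: Optional[str] = None,
    keep_per_cell: bool = False,
) -> SlideDensitySummary:
    """Median KNN density over all lymphocytes on one slide.

    k is truncated to n - 1 on sparse slides; with n < 2 the summary is
    flagged missing.  A lymphocyte whose R is exactly zero (all its k
    neighbours are coordinate duplicates) has no finite density; it is
    excluded from the median with a logged warning rather than mapped to
    infinity.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    k_used = max(0, min(int(n_target), n - 1))
    if n < 2:
        return SlideDensitySummary(slide_id, n, k_used, None,
                                   per_lymphocyte_densities=None)

    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k_used + 1)
    r = dist[:, 1:].mean(axis=1)  # drop self-distance (column 0)
    valid = r > 0
    n_degenerate = int((~valid).sum())
    if n_degenerate:
        logger.warning(
            "slide %s: %d lymphocyte(s) with zero mean NN distance "
            "(coordinate duplicates) excluded from the median",
            slide_id, n_degenerate,
        )
    densities = np.full(n, np.nan)
    densities[valid] = k_used / (math.pi * r[valid] ** 2)
    finite = densities[valid]
    median = float(np.median(finite)) if len(finite) else None
    return SlideDensitySummary(
        slide_id, n, k_used, median,
        per_lymphocyte_densities=densities if keep_per_cell else None,
    )


def density_from_cellmap(cellmap: CellMap, n_target: int = DEFAULT_N_NEIGHBOURS,
                         **kw) -> SlideDensitySummary:
    """Filter a cell map to lymphocytes and compute the slide summary."""
    return lymphocyte_density(cellmap.class_xy("lymphocyte"), n_target=n_target,
                              slide_id=cellmap.slide_id, **kw)


def density_change(pre: SlideDensitySummary, post: SlideDensitySummary) -> DensityChange:
    """Pre-to-post change; missing summaries propagate to a missing change."""
    if (
        pre.patient_id is not None and post.patient_id is not None
        and pre.patient_id != post.patient_id
    ):
        raise ContractViolation(
            f"patient ids differ: {pre.patient_id!r} vs {post.patient_id!r}"
        )
    patient_id = pre.patient_id or post.patient_id
    if not (pre.defined and post.defined):
        return DensityChange(patient_id, pre, post, None, None)
    delta = post.median_density - pre.median_density
    log_ratio = None
    if pre.median_density > 0 and post.median_density > 0:
        log_ratio = math.log(post.median_density / pre.median_density)
    return DensityChange(patient_id, pre, post, delta, log_ratio)


def rescale_unit_interval(values: Sequence[float]) -> np.ndarray:
    """Min-max rescale to [0, 1]; an all-equal vector maps to all zeros.

    Missing entries (NaN) are carried through unchanged and ignored when
    locating the extremes.  Used for presentation only, never in models.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ContractViolation("need at least one non-missing value")
    lo, hi = finite.min(), finite.max()
    if hi == lo:
        out = np.where(np.isfinite(arr), 0.0, np.nan)
        return out
    return (arr - lo) / (hi - lo)


def summaries_to_frame(summaries: Sequence[SlideDensitySummary]) -> pd.DataFrame:
    """Per-slide summary CSV layout; density column labelled a.u."""
    return pd.DataFrame(
        {
            "slide_id": [s.slide_id for s in summaries],
            "n_lymphocytes": [s.n_lymphocytes for s in summaries],
            "k_used": [s.k_used for s in summaries],
            "median_density_au": [
                s.median_density if s.defined else np.nan for s in summaries
            ],
        }
    )
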