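"""Section-placement accuracy, cycle-time statistics, and yield comparison.

Coordinate conventions
----------------------
The substrate frame uses millimetres (offsets reported in micrometres), x
rightward and y upward. Aperture centres sit on a regular grid:
``(origin_x + col * pitch_x, origin_y + row * pitch_y)``. A substrate photo
is mapped to this frame with image column = x and image row increasing
*downward*, so ``x_um = col_px * scale`` and ``y_um = (H - 1 - row_px) *
scale`` for a frame whose bottom-left pixel centre is at frame origin (0, 0).

A centroid set is a :class:`pandas.DataFrame` with columns
``section_id, row, col, dx_um, dy_um, fragment`` — per-section aperture grid
indices and the centroid offset from that aperture's centre. Sections that
broke into multiple pieces are fragment-flagged and carry no offset (NaN);
they are excluded from accuracy statistics but counted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher
from skimage.measure import label, regionprops

from .exceptions import ParameterError

__all__ = [
    "ApertureGrid",
    "PlacementStats",
    "FisherResult",
    "CENTROID_COLUMNS",
    "CYCLE_COLUMNS",
    "detect_section_centroids",
    "placement_statistics",
    "cycle_time_statistics",
    "fisher_exact_yield_comparison",
]

CENTROID_COLUMNS = ["section_id", "row", "col", "dx_um", "dy_um", "fragment"]
CYCLE_COLUMNS = ["section_id", "pickup_s", "cycle_s"]


@dataclass(frozen=True)
class ApertureGrid:
    """Regular grid of square imaging apertures on a substrate (all mm).

    Defaults match a microfabricated substrate with forty 1.4 mm apertures at
    1.9 mm pitch (8 columns x 5 rows).
    """

    rows: int = 5
    cols: int = 8
    aperture_side: float = 1.4
    pitch_x: float = 1.9
    pitch_y: float = 1.9
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ParameterError("grid must have at least one row and one column")
        if self.aperture_side > min(self.pitch_x, self.pitch_y):
            raise ParameterError("aperture_side cannot exceed the pitch")
        if self.aperture_side <= 0 or self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ParameterError("aperture_side and pitches must be positive")

    @property
    def n_apertures(self) -> int:
        return self.rows * self.cols

    def center_mm(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin[0] + col * self.pitch_x,
            self.origin[1] + row * self.pitch_y,
        )

    def centers_mm(self) -> np.ndarray:
        """(rows*cols, 2) array of centre coordinates, row-major."""
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.stack(
            [
                self.origin[0] + cc.ravel() * self.pitch_x,
                self.origin[1] + rr.ravel() * self.pitch_y,
            ],
            axis=1,
        )


@dataclass(frozen=True)
class PlacementStats:
    """Per-axis accuracy/repeatability and aperture-containment summary (um)."""

    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    n_analyzed: int
    n_excluded_fragments: int
    n_contained: int
    n_partial: int
    fraction_contained: float


@dataclass(frozen=True)
class FisherResult:
    p_one_sided: float
    p_two_sided: float
    odds_ratio: float
    odds_ratio_defined: bool = True


def detect_section_centroids(
    frame: np.ndarray,
    grid: ApertureGrid,
    scale: float,
    intensity_threshold: float,
    min_area_px: int = 1,
) -> pd.DataFrame:
    """Locate sections in a substrate photo and express centroids as
    offsets from their nearest aperture centre.

    Foreground pixels are those above ``intensity_threshold``; connected
    components (8-connectivity) with at least ``min_area_px`` pixels are
    candidate sections. Each component's unweighted pixel centroid is
    converted to frame coordinates with ``scale`` (um/px) and assigned to the
    nearest aperture centre. Apertures receiving two or more components hold
    a fragmented section: all of their components are fragment-flagged.
    Returns a (possibly empty) centroid-set DataFrame.
    """
    if scale <= 0:
        raise ParameterError(f"scale must be positive um/px, got {scale!r}")
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ParameterError("frame must be a 2-D grayscale image")
    labeled = label(img > intensity_threshold, connectivity=2)
    props = [p for p in regionprops(labeled) if p.area >= min_area_px]
    if not props:
        warnings.warn("no section components found in frame", stacklevel=2)
        return pd.DataFrame(columns=CENTROID_COLUMNS)

    h = img.shape[0]
    centers_um = grid.centers_mm() * 1000.0
    records = []
    for p in props:
        r_px, c_px = p.centroid
        x_um = c_px * scale
        y_um = (h - 1 - r_px) * scale
        d2 = (centers_um[:, 0] - x_um) ** 2 + (centers_um[:, 1] - y_um) ** 2
        idx = int(np.argmin(d2))
        row, col = divmod(idx, grid.cols)
        records.append(
            {
                "row": row,
                "col": col,
                "dx_um": x_um - centers_um[idx, 0],
                "dy_um": y_um - centers_um[idx, 1],
            }
        )
    df = pd.DataFrame(records)
    counts = df.groupby(["row", "col"])["dx_um"].transform("size")
    df["fragment"] = counts >= 2
    df.loc[df["fragment"], ["dx_um", "dy_um"]] = np.nan
    df = df.sort_values(["row", "col"]).reset_index(drop=True)
    df.insert(0, "section_id", np.arange(len(df)))
    return df[CENTROID_COLUMNS]


def placement_statistics(
    centroids: pd.DataFrame,
    section_side: float,
    grid: ApertureGrid,
) -> PlacementStats:
    """Accuracy/repeatability and containment over non-fragment centroids.

    A section (modeled as an axis-aligned ``section_side`` mm square) lies
    entirely within its aperture iff its centroid offset satisfies
    ``|offset| <= (aperture_side - section_side) / 2`` on both axes.
    """
    if section_side > grid.aperture_side:
        raise ParameterError("section_side must not exceed aperture_side")
    good = centroids.loc[~centroids["fragment"].astype(bool)]
    n = len(good)
    n_frag = len(centroids) - n
    if n == 0:
        raise ParameterError("no non-fragment centroids to analyze")
    dx = good["dx_um"].to_numpy(dtype=float)
    dy = good["dy_um"].to_numpy(dtype=float)
    bound_um = (grid.aperture_side - section_side) / 2.0 * 1000.0
    contained = (np.abs(dx) <= bound_um) & (np.abs(dy) <= bound_um)
    n_contained = int(contained.sum())
    return PlacementStats(
        mean_x=float(dx.mean()),
        sd_x=float(dx.std(ddof=1)) if n > 1 else 0.0,
        mean_y=float(dy.mean()),
        sd_y=float(dy.std(ddof=1)) if n > 1 else 0.0,
        n_analyzed=n,
        n_excluded_fragments=n_frag,
        n_contained=n_contained,
        n_partial=n - n_contained,
        fraction_contained=n_contained / n,
    )


def cycle_time_statistics(log: pd.DataFrame) -> dict:
    """Mean +/- sd of pickup and full cycle durations, and the dry-down time.

    Dry-down (section adhesion/drying on the heated substrate) is estimated
    as mean cycle minus mean pickup — a first-order figure that also absorbs
    loop travel time. Rows with pickup <= 0 or pickup > cycle are rejected
    with a validation error listing the offending section ids.
    """
    if len(log) == 0:
        raise ParameterError("empty cycle log")
    pickup = log["pickup_s"].to_numpy(dtype=float)
    cycle = log["cycle_s"].to_numpy(dtype=float)
    bad = (pickup <= 0) | (pickup > cycle)
    if bad.any():
        ids = log.loc[bad, "section_id"].tolist() if "section_id" in log else list(np.where(bad)[0])
        raise ParameterError(f"invalid rows (pickup <= 0 or pickup > cycle) for sections: {ids}")
    n = len(log)
    sd = lambda a: float(a.std(ddof=1)) if n > 1 else 0.0  # noqa: E731
    return {
        "n": n,
        "mean_pickup_s": float(pickup.mean()),
        "sd_pickup_s": sd(pickup),
        "mean_cycle_s": float(cycle.mean()),
        "sd_cycle_s": sd(cycle),
        "dry_down_estimate_s": float(cycle.mean() - pickup.mean()),
    }


def fisher_exact_yield_comparison(table) -> FisherResult:
    """Fisher's exact test on a 2x2 yield table.

    ``table`` rows are methods A and B, columns (collected, lost). The
    one-sided alternative is that method A's loss rate is *lower* than method
    B's; the two-sided p-value sums all tables whose point (hypergeometric)
    probability does not exceed the observed table's. The odds ratio is the
    cross-product ``(a d) / (b c)``; an indeterminate 0/0 is flagged.
    Degenerate margins (an all-zero row or column) carry no information:
    both p-values are 1, with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.isfinite(t).all():
        raise ParameterError("table must be a 2x2 array of non-negative counts")
    if int(t.sum()) == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 margins: Fisher test is uninformative", stacklevel=2)
        a, b, c, d = t.ravel()
        num, den = a * d, b * c
        defined = not (num == 0 and den == 0)
        return FisherResult(1.0, 1.0, num / den if den else math.inf if num else math.nan, defined)
    t_int = t.astype(int)
    # lower loss rate for A  <=>  greater odds on the 'collected' cell
    _, p_one = _scipy_fisher(t_int, alternative="greater")
    _, p_two = _scipy_fisher(t_int, alternative="two-sided")
    a, b, c, d = t.ravel()
    num, den = a * d, b * c
    if num == 0 and den == 0:
        return FisherResult(float(p_one), float(p_two), math.nan, False)
    odds = num / den if den else math.inf
    return FisherResult(float(p_one), float(p_two), float(odds), True)
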