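"""Edge-sharpness (ESF roll-off) and Michelson-contrast metrics for EM images.

The inputs are a single-channel raster image and point-pair annotations, one
per synaptic vesicle: an exterior point and an interior point. An intensity
profile is sampled along the exterior->interior line (the edge spread
function, ESF), the edge transition is bracketed by derivative-based
change-point detection, and a straight line is fit to the samples inside the
bracket — its slope is the mean roll-off of the ESF, a sharpness measure
(idealized edges have infinite slope). Michelson contrast compares the
interior and exterior plateau intensities.

Intensities are used in their native units (e.g. 8-bit counts) with no
normalization before slope fitting: a roll-off slope is only interpretable
relative to a fixed bit depth, so rescaling would silently change its
meaning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d, map_coordinates

from .exceptions import AnnotationError, NoEdgeError, ParameterError, ProfileError

__all__ = [
    "VesicleAnnotation",
    "LineProfile",
    "ESFResult",
    "MetricSummary",
    "sample_line_profile",
    "detect_change_points",
    "esf_slope",
    "michelson_contrast",
    "summarize_metric",
    "compare_film_groups",
    "measure_vesicles",
]

#: default sub-pixel sampling step along the annotation line (px)
DEFAULT_STEP = 0.25
#: default Gaussian smoothing applied before differentiating (samples)
DEFAULT_SMOOTH_SIGMA = 1.0
#: default fraction of the peak |derivative| at which the edge ends
DEFAULT_THRESHOLD_FRAC = 0.2


@dataclass(frozen=True)
class VesicleAnnotation:
    """Exterior and interior points of one vesicle, in pixel coordinates
    (x = column, y = row, 0-based, sub-pixel allowed)."""

    x_ext: float
    y_ext: float
    x_int: float
    y_int: float
    vesicle_id: int | str | None = None


@dataclass(frozen=True)
class LineProfile:
    """Uniformly spaced intensity samples along an exterior->interior line.

    ``positions`` are distances (px) from the exterior endpoint.
    """

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.intensities):
            raise ProfileError("positions and intensities must have equal length")
        if len(self.positions) < 8:
            raise ProfileError(f"profile needs >= 8 samples, got {len(self.positions)}")
        d = np.diff(self.positions)
        if not (d > 0).all() or not np.allclose(d, d[0]):
            raise ProfileError("positions must be strictly increasing and uniformly spaced")


@dataclass(frozen=True)
class ESFResult:
    change_point_low: float
    change_point_high: float
    slope: float
    intercept: float
    n_fit_points: int


@dataclass(frozen=True)
class MetricSummary:
    """Mean, sample standard deviation (n-1 denominator; 0 at n=1), count."""

    mean: float
    sd: float
    n: int


def sample_line_profile(
    image: np.ndarray,
    ann: VesicleAnnotation,
    step: float = DEFAULT_STEP,
) -> LineProfile:
    """Bilinearly sample the image along the annotation line.

    Samples run from the exterior endpoint toward the interior endpoint at a
    uniform ``step`` (0 < step <= 1 px); orientation is preserved so that a
    bright-exterior / dark-interior vesicle gives a falling profile.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 2 or img.shape[1] < 2:
        raise ParameterError("image must be a 2-D grid of at least 2x2 pixels")
    if not (0 < step <= 1):
        raise ParameterError(f"step must be in (0, 1] px, got {step!r}")
    h, w = img.shape
    for x, y in ((ann.x_ext, ann.y_ext), (ann.x_int, ann.y_int)):
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            raise AnnotationError(
                f"annotation point ({x}, {y}) outside image bounds {w - 1}x{h - 1}"
            )
    dx, dy = ann.x_int - ann.x_ext, ann.y_int - ann.y_ext
    length = math.hypot(dx, dy)
    if length == 0:
        raise AnnotationError("degenerate annotation: exterior and interior points coincide")
    n = int(math.floor(length / step)) + 1
    positions = np.arange(n) * step
    xs = ann.x_ext + positions * (dx / length)
    ys = ann.y_ext + positions * (dy / length)
    intensities = map_coordinates(img, [ys, xs], order=1, mode="nearest")
    return LineProfile(positions=positions, intensities=intensities)


def detect_change_points(
    profile: LineProfile,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> tuple[float, float]:
    """Bracket the edge transition by a derivative threshold rule.

    The profile is Gaussian-smoothed (sigma in samples), differentiated by
    central differences, and the global extremum of |derivative| located. The
    change points are the first positions, walking outward from the extremum
    in each direction, where |derivative| falls below
    ``threshold_frac * peak``; if it never does, the profile end is used.
    """
    if not (0 < threshold_frac < 1):
        raise ParameterError(f"threshold_frac must be in (0, 1), got {threshold_frac!r}")
    smoothed = gaussian_filter1d(profile.intensities, smooth_sigma, mode="nearest")
    deriv = np.gradient(smoothed, profile.positions)
    mag = np.abs(deriv)
    peak_idx = int(np.argmax(mag))
    peak = mag[peak_idx]
    if peak == 0:
        raise NoEdgeError("flat profile: no intensity edge present")
    thresh = threshold_frac * peak
    pos = profile.positions
    lo = peak_idx
    while lo > 0 and mag[lo] >= thresh:
        lo -= 1
    if mag[lo] >= thresh:  # never fell below: profile end
        low = float(pos[lo])
    else:  # sub-sample crossing between lo and lo+1
        f = (thresh - mag[lo]) / (mag[lo + 1] - mag[lo])
        low = float(pos[lo] + f * (pos[lo + 1] - pos[lo]))
    hi = peak_idx
    last = len(mag) - 1
    while hi < last and mag[hi] >= thresh:
        hi += 1
    if mag[hi] >= thresh:
        high = float(pos[hi])
    else:
        f = (thresh - mag[hi]) / (mag[hi - 1] - mag[hi])
        high = float(pos[hi] - f * (pos[hi] - pos[hi - 1]))
    return low, high


def esf_slope(profile: LineProfile, change_points: tuple[float, float]) -> ESFResult:
    """Least-squares line fit to the samples strictly between the change points.

    The slope is the mean roll-off of the ESF. Its sign follows the
    exterior->interior orientation of the profile: a bright exterior and dark
    interior give a negative slope.
    """
    lo, hi = change_points
    if not lo < hi:
        raise ParameterError(f"change points must satisfy low < high, got {change_points!r}")
    mask = (profile.positions > lo) & (profile.positions < hi)
    n_fit = int(mask.sum())
    if n_fit < 2:
        raise ProfileError(
            f"need >= 2 samples strictly between change points, got {n_fit}"
        )
    slope, intercept = np.polyfit(profile.positions[mask], profile.intensities[mask], 1)
    return ESFResult(
        change_point_low=lo,
        change_point_high=hi,
        slope=float(slope),
        intercept=float(intercept),
        n_fit_points=n_fit,
    )


def michelson_contrast(i_interior: float, i_exterior: float) -> float:
    """``|I_ext - I_int| / (I_ext + I_int)``, in [0, 1].

    Invariant under multiplicative rescaling of both intensities.
    """
    if i_interior < 0 or i_exterior < 0:
        raise ParameterError("intensities must be non-negative")
    total = i_interior + i_exterior
    if total == 0:
        raise ParameterError("contrast undefined: both intensities are zero")
    return abs(i_exterior - i_interior) / total


def summarize_metric(values) -> MetricSummary:
    """Sample mean and standard deviation (ddof=1; sd = 0 when n = 1)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ParameterError("cannot summarize an empty list of values")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return MetricSummary(mean=float(arr.mean()), sd=sd, n=int(arr.size))


def compare_film_groups(a, b) -> dict:
    """Descriptive comparison of a metric across two film groups.

    Returns both group summaries and the difference of means (a - b). No
    hypothesis test is attached: the comparison of film types is descriptive.
    """
    sa, sb = summarize_metric(a), summarize_metric(b)
    return {
        "group_a": sa,
        "group_b": sb,
        "difference_of_means": sa.mean - sb.mean,
    }


def _endpoint_intensity(profile: LineProfile, end: str) -> float:
    # mean of the 3 samples nearest the endpoint, for robustness to
    # single-pixel noise
    vals = profile.intensities[:3] if end == "exterior" else profile.intensities[-3:]
    return float(vals.mean())


def measure_vesicles(
    image: np.ndarray,
    annotations,
    step: float = DEFAULT_STEP,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> pd.DataFrame:
    """Run the full per-vesicle pipeline over a set of annotations.

    For each :class:`VesicleAnnotation`: sample the profile, bracket the
    edge, fit the ESF slope, and compute the Michelson contrast between the
    interior and exterior plateau intensities (each the mean of the 3 profile
    samples nearest that endpoint). Returns one row per vesicle with columns
    ``vesicle_id, slope, contrast, change_point_low, change_point_high,
    n_fit_points, i_exterior, i_interior``.
    """
    rows = []
    for i, ann in enumerate(annotations):
        profile = sample_line_profile(image, ann, step=step)
        cps = detect_change_points(profile, smooth_sigma=smooth_sigma, threshold_frac=threshold_frac)
        esf = esf_slope(profile, cps)
        i_ext = _endpoint_intensity(profile, "exterior")
        i_int = _endpoint_intensity(profile, "interior")
        rows.append(
            {
                "vesicle_id": ann.vesicle_id if ann.vesicle_id is not None else i,
                "slope": esf.slope,
                "contrast": michelson_contrast(i_int, i_ext),
                "change_point_low": esf.change_point_low,
                "change_point_high": esf.change_point_high,
                "n_fit_points": esf.n_fit_points,
                "i_exterior": i_ext,
                "i_interior": i_int,
            }
        )
    return pd.DataFrame(rows)
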