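"""Seeded synthetic-data generators with ground truth.

Every analysis input the package consumes can be generated here with known
ground truth, enabling recovery tests: blurred-edge vesicle images with known
plateau intensities and edge width, Gaussian-scattered section centroids on
an aperture grid (optionally rendered as substrate photos), and cycle-time
logs. Each generator is a pure function of its spec, including the seed —
identical specs give bit-identical outputs.

Vesicles are rendered with analytic error-function edges (not discrete
blurring), so the true maximum edge derivative has the closed form
``|I_ext - I_int| / (edge_sigma * sqrt(2 pi))`` for ESF validation. No
attempt is made at realistic EM texture; flat disks on a flat background
suffice for the metrics under test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exceptions import ParameterError
from .image_quality import VesicleAnnotation
from .placement import CENTROID_COLUMNS, CYCLE_COLUMNS, ApertureGrid

__all__ = [
    "VesicleImageSpec",
    "PlacementSpec",
    "CycleLogSpec",
    "vesicle_grid_spec",
    "generate_vesicle_image",
    "generate_placement_dataset",
    "render_placement_frame",
    "generate_cycle_log",
]


@dataclass(frozen=True)
class VesicleImageSpec:
    """Synthetic vesicle image: disks of ``i_interior`` on an ``i_exterior``
    background, with error-function edges of width ``edge_sigma`` px and
    optional additive Gaussian noise.

    ``vesicles`` is a sequence of ``(x_center, y_center, radius)`` in pixels
    (x = column). Disks must not overlap and radii must exceed ``edge_sigma``.
    """

    shape: tuple[int, int]  # (height, width) px
    vesicles: tuple[tuple[float, float, float], ...]
    i_interior: float = 60.0
    i_exterior: float = 100.0
    edge_sigma: float = 3.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h < 2 or w < 2:
            raise ParameterError("image must be at least 2x2")
        if not (0 <= self.i_interior and 0 <= self.i_exterior):
            raise ParameterError("intensities must be non-negative")
        if self.edge_sigma <= 0 or self.noise_sigma < 0:
            raise ParameterError("edge_sigma must be > 0 and noise_sigma >= 0")
        if len(self.vesicles) == 0:
            raise ParameterError("at least one vesicle required")
        for x, y, r in self.vesicles:
            if r <= self.edge_sigma:
                raise ParameterError("vesicle radii must exceed edge_sigma")
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise ParameterError(f"vesicle center ({x}, {y}) outside image")
        v = np.asarray(self.vesicles, dtype=float)
        for i in range(len(v)):
            for j in range(i + 1, len(v)):
                d = math.hypot(v[i, 0] - v[j, 0], v[i, 1] - v[j, 1])
                if d <= v[i, 2] + v[j, 2]:
                    raise ParameterError("vesicles must not overlap")


def vesicle_grid_spec(
    n_vesicles: int,
    radius: float = 18.0,
    spacing: float = 90.0,
    cols: int = 6,
    **kwargs,
) -> VesicleImageSpec:
    """Convenience layout: ``n_vesicles`` disks of equal ``radius`` on a
    regular grid with ``spacing`` px between centres."""
    rows = -(-n_vesicles // cols)
    centers = []
    for i in range(n_vesicles):
        r, c = divmod(i, cols)
        centers.append((spacing / 2 + c * spacing, spacing / 2 + r * spacing, radius))
    shape = (int(rows * spacing), int(min(n_vesicles, cols) * spacing))
    return VesicleImageSpec(shape=shape, vesicles=tuple(centers), **kwargs)


def generate_vesicle_image(
    spec: VesicleImageSpec,
) -> tuple[np.ndarray, list[VesicleAnnotation], dict]:
    """Render the image and matching radial annotations.

    Each pixel's intensity is ``i_exterior + (i_interior - i_exterior) *
    Phi((r - d) / edge_sigma)`` accumulated over vesicles (``d`` = distance
    from the vesicle centre, ``Phi`` the standard normal CDF), plus seeded
    Gaussian noise, clipped at zero. Annotations run radially from an
    exterior point (5 sigma outside the rim) to an interior point (5 sigma
    inside, bounded away from the centre), at a per-vesicle angle drawn from
    the seeded stream.

    Returns ``(image, annotations, ground_truth)`` where ``ground_truth``
    carries the true Michelson contrast, edge width, and the analytic
    maximum edge derivative ``|dI| / (edge_sigma * sqrt(2 pi))``.
    """
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    img = np.full((h, w), float(spec.i_exterior))
    delta = spec.i_interior - spec.i_exterior
    for x0, y0, r in spec.vesicles:
        d = np.hypot(xx - x0, yy - y0)
        img += delta * ndtr((r - d) / spec.edge_sigma)

    rng = np.random.default_rng(spec.seed)
    angles = rng.uniform(0.0, 2.0 * math.pi, size=len(spec.vesicles))
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, None)

    annotations = []
    for i, ((x0, y0, r), ang) in enumerate(zip(spec.vesicles, angles)):
        d_ext = r + 5.0 * spec.edge_sigma
        d_int = max(r - 5.0 * spec.edge_sigma, 0.25 * r)
        ux, uy = math.cos(ang), math.sin(ang)
        ann = VesicleAnnotation(
            x_ext=x0 + d_ext * ux,
            y_ext=y0 + d_ext * uy,
            x_int=x0 + d_int * ux,
            y_int=y0 + d_int * uy,
            vesicle_id=i,
        )
        if not (0 <= ann.x_ext <= w - 1 and 0 <= ann.y_ext <= h - 1):
            raise ParameterError(
                f"vesicle {i}: exterior annotation point falls outside the image; "
                "enlarge the image or shrink the vesicle"
            )
        annotations.append(ann)

    ground_truth = {
        "contrast": abs(spec.i_exterior - spec.i_interior)
        / (spec.i_exterior + spec.i_interior),
        "edge_sigma": spec.edge_sigma,
        "max_derivative": abs(delta) / (spec.edge_sigma * math.sqrt(2.0 * math.pi)),
        "i_interior": spec.i_interior,
        "i_exterior": spec.i_exterior,
    }
    return img, annotations, ground_truth


@dataclass(frozen=True)
class PlacementSpec:
    """Synthetic section placements: per-axis normal centroid offsets (um)
    around aperture centres, with a fraction of sections fragment-flagged."""

    n: int
    mean_um: tuple[float, float] = (-20.0, 60.0)
    sd_um: tuple[float, float] = (110.0, 150.0)
    grid: ApertureGrid = field(default_factory=ApertureGrid)
    section_side: float = 1.0
    fragment_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ParameterError(f"n must be an integer >= 1, got {self.n!r}")
        if not (0.0 <= self.fragment_fraction <= 1.0):
            raise ParameterError("fragment_fraction must be in [0, 1]")
        if self.sd_um[0] < 0 or self.sd_um[1] < 0:
            raise ParameterError("sds must be non-negative")
        if not (0 < self.section_side <= self.grid.aperture_side):
            raise ParameterError("section_side must be positive and fit the aperture")


def generate_placement_dataset(spec: PlacementSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a centroid set and its generating ground truth.

    Sections fill apertures sequentially (row-major, wrapping if ``n``
    exceeds the aperture count); offsets are independent per-axis normals;
    ``round(fragment_fraction * n)`` sections, chosen from the seeded stream,
    are fragment-flagged and carry no offset.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n)
    dx = rng.normal(spec.mean_um[0], spec.sd_um[0], size=n)
    dy = rng.normal(spec.mean_um[1], spec.sd_um[1], size=n)
    n_frag = int(round(spec.fragment_fraction * n))
    frag_idx = rng.choice(n, size=n_frag, replace=False)
    fragment = np.zeros(n, dtype=bool)
    fragment[frag_idx] = True

    idx = np.arange(n) % spec.grid.n_apertures
    df = pd.DataFrame(
        {
            "section_id": np.arange(n),
            "row": idx // spec.grid.cols,
            "col": idx % spec.grid.cols,
            "dx_um": np.where(fragment, np.nan, dx),
            "dy_um": np.where(fragment, np.nan, dy),
            "fragment": fragment,
        }
    )[CENTROID_COLUMNS]
    truth = {
        "mean_x_um": spec.mean_um[0],
        "mean_y_um": spec.mean_um[1],
        "sd_x_um": spec.sd_um[0],
        "sd_y_um": spec.sd_um[1],
        "n": n,
        "n_fragments": n_frag,
    }
    return df, truth


def render_placement_frame(
    centroids: pd.DataFrame,
    grid: ApertureGrid,
    scale: float,
    section_side: float = 1.0,
    foreground: float = 255.0,
) -> np.ndarray:
    """Render a centroid set as a substrate photo for detector testing.

    Non-fragment sections become uniform ``section_side`` mm squares at
    centre + offset; fragment-flagged sections become two disjoint half-size
    blocks within their aperture. The frame uses the mapping documented in
    :mod:`sstembatch.placement` (``scale`` in um/px, y up), with a half-pitch
    margin around the grid; the grid origin must leave room for that margin.
    """
    if scale <= 0:
        raise ParameterError("scale must be positive um/px")
    margin_x = grid.pitch_x / 2.0
    margin_y = grid.pitch_y / 2.0
    if grid.origin[0] < margin_x or grid.origin[1] < margin_y:
        raise ParameterError("grid origin too close to the frame edge to render sections")
    extent_x = grid.origin[0] + (grid.cols - 1) * grid.pitch_x + margin_x
    extent_y = grid.origin[1] + (grid.rows - 1) * grid.pitch_y + margin_y
    w = int(round(extent_x * 1000.0 / scale)) + 1
    h = int(round(extent_y * 1000.0 / scale)) + 1
    img = np.zeros((h, w))
    half_px = section_side * 1000.0 / scale / 2.0

    def _fill(x_um: float, y_um: float, half_x: float, half_y: float) -> None:
        col = x_um / scale
        row = (h - 1) - y_um / scale
        r0, r1 = int(round(row - half_y)), int(round(row + half_y))
        c0, c1 = int(round(col - half_x)), int(round(col + half_x))
        if r0 < 0 or c0 < 0 or r1 >= h or c1 >= w:
            raise ParameterError("section extends beyond the rendered frame")
        img[r0 : r1 + 1, c0 : c1 + 1] = foreground

    seen_occupied: set[tuple[int, int]] = set()
    for rec in centroids.itertuples(index=False):
        key = (int(rec.row), int(rec.col))
        cx_mm, cy_mm = grid.center_mm(*key)
        if key in seen_occupied:
            raise ParameterError(f"aperture {key} occupied by more than one section")
        seen_occupied.add(key)
        if bool(rec.fragment):
            # two disjoint blocks centred on the aperture
            shift_um = 0.375 * section_side * 1000.0
            _fill(cx_mm * 1000.0 - shift_um, cy_mm * 1000.0, half_px / 2, half_px / 2)
            _fill(cx_mm * 1000.0 + shift_um, cy_mm * 1000.0, half_px / 2, half_px / 2)
        else:
            _fill(cx_mm * 1000.0 + rec.dx_um, cy_mm * 1000.0 + rec.dy_um, half_px, half_px)
    return img


@dataclass(frozen=True)
class CycleLogSpec:
    """Synthetic pickup/cycle timings (s): ``cycle = pickup + dry_down`` with
    both terms positive truncated normals.

    Default dry-down sd (6.5 s) is chosen so that, under independence, the
    implied cycle sd matches the measured ~11.7 s given a pickup sd of 9.7 s
    (``sqrt(11.7^2 - 9.7^2)``).
    """

    n: int
    pickup_mean: float = 18.9
    pickup_sd: float = 9.7
    drydown_mean: float = 24.6
    drydown_sd: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ParameterError(f"n must be an integer >= 1, got {self.n!r}")
        if self.pickup_mean <= 0 or self.drydown_mean <= 0:
            raise ParameterError("means must be positive")
        if self.pickup_sd < 0 or self.drydown_sd < 0:
            raise ParameterError("sds must be non-negative")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Positive normal draws by resampling (keeps means interpretable for
    sd << mean, unlike clipping)."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def generate_cycle_log(spec: CycleLogSpec) -> pd.DataFrame:
    """Draw a cycle-time log with columns ``section_id, pickup_s, cycle_s``."""
    rng = np.random.default_rng(spec.seed)
    pickup = _truncated_normal(rng, spec.pickup_mean, spec.pickup_sd, int(spec.n))
    drydown = _truncated_normal(rng, spec.drydown_mean, spec.drydown_sd, int(spec.n))
    return pd.DataFrame(
        {
            "section_id": np.arange(int(spec.n)),
            "pickup_s": pickup,
            "cycle_s": pickup + drydown,
        }
    )[CYCLE_COLUMNS]
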