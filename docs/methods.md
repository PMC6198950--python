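# Methods

## Yield model

The failure event is the loss of two *consecutive* sections, which breaks the
3-D continuity of a serial-section reconstruction. Both regimes assume
independent losses: per section (rate `p`) for traditional handling, per
substrate (rate `p′`) for batched handling.

**Traditional.** The yield `(1 − p²)^(n−1)` treats the `n − 1` adjacent pair
slots as independent binomial trials. Pair slots overlap, so this is an
approximation; the exact probability of no two adjacent losses follows the
transfer-matrix recurrence `a_i = (1−p) a_{i−1} + p(1−p) a_{i−2}`
(`a_0 = a_1 = 1`), implemented as `exact_traditional_yield`. At
`n = 25000, p = 0.01` the binomial model gives 0.0821 and the exact recurrence
0.0841 — the approximation understates yield by < 0.5 points and we keep the
binomial form as the primary model because its whole-percent prediction (8%)
is the quantity of record.

**Batched.** Sections are assigned round-robin across the `m` substrates of a
batch (batch-local section `t` → substrate `t mod m`), which guarantees no
two consecutive sections share a substrate for `m ≥ 2`. A batch is counted as
failed when it loses ≥ 2 substrates, giving
`P = 1 − [(1−p′)^m + m p′ (1−p′)^(m−1)]`, and the run succeeds when none of
`k = ⌈n/(c m)⌉` batches fails: `Y = (1 − P)^k`. Choices worth noting:

* `k` is a ceiling, because all `n` sections must be housed; the partial
  final batch is treated as a full batch by the analytic model
  (conservative). The integer `k` is what makes the yield surface stepped.
* The ≥ 2-substrates criterion is itself conservative: in the round-robin
  cycle only *adjacent* substrates hold consecutive sections, so some
  two-substrate losses destroy no pair. The simulator's `physical` mode
  resolves actual pairs and consistently yields more than `strict` mode on
  shared random streams.
* Consecutive pairs straddling two batches are ignored by the analytic
  model; the simulator exposes them behind `include_cross_batch`.
* All powers are accumulated in log space (`exp(k·log1p(−P))`) so the model
  stays accurate at `n ~ 1e5` and tiny `P`.
* Default `p = p′ = 0.01`: the literature lower bound for experienced manual
  sectioning; the per-substrate rate is likely an overestimate since larger
  substrates are easier to handle.

The simulator draws one uniform per substrate per trial in (batch, substrate)
order, so strict and physical modes consume identical streams under one seed
and can be compared pairwise. The final batch is simulated with its actual
substrate count. `mc_stderr` uses the normal approximation
`sqrt(ŷ(1−ŷ)/T)`, which is unreliable when fewer than ~5 failures are
observed.

## Throughput and cost

Both totals are linear in `n`. The batched regime amortizes one TEM load over
the `c·m` sections of a batch and replaces per-section grids (default
USD 0.40) with wafer-batch substrates (default: 320 sections per wafer at
USD 500 per wafer processed — 8 substrates × 40 sections). The wafer count is
fractional by default, matching the cost equation as a rate; `whole_wafers=True`
rounds up for procurement. Time defaults: 120 s manual pickup (the ~2 min/section
figure for skilled manual collection), 43.5 s robotic cycle. Currency is
abstract; seconds are used throughout.

## Image-quality metrics

Inputs are a single-channel raster image and per-vesicle point pairs
(exterior → interior). The pipeline:

1. **Profile sampling** — bilinear interpolation at a uniform sub-pixel step
   along the annotation line (default 0.25 px). Sub-pixel sampling
   stabilizes the numerical derivative.
2. **Change-point detection** — Gaussian smoothing (default σ = 1 sample),
   central-difference derivative, global |derivative| peak; the edge is
   bracketed where |derivative| falls below 20% of the peak, with the
   crossing position refined by linear interpolation between samples. A flat
   profile raises a no-edge error; a monotone ramp brackets the whole
   profile.
3. **ESF slope** — ordinary least squares on the samples strictly inside the
   bracket. The sign follows the exterior→interior orientation (bright
   exterior, dark interior → negative). Intensities stay in native counts:
   a roll-off slope is only interpretable relative to a fixed bit depth, so
   no normalization is applied before fitting.
4. **Michelson contrast** — `|I_ext − I_int| / (I_ext + I_int)` between the
   plateau intensities, each estimated as the mean of the 3 profile samples
   nearest that endpoint (robust to single-pixel noise).

A known property of this estimator: the OLS line averages the erf roll-off
over the whole 20%-of-peak window, so its magnitude sits at ~0.76 of the
analytic maximum derivative `ΔI/(σ_e √(2π))` of a Gaussian-blurred step.
The recovery tests check the 25% agreement band that this implies; they do
not assert the analytic maximum itself.

## Placement analysis

The substrate frame is mm/μm, x rightward, y upward; aperture centres lie on
a regular grid (default: forty 1.4 mm apertures at 1.9 mm pitch, 8 × 5).
Substrate photos map to this frame with image row increasing downward.
Section detection: threshold → 8-connected components → unweighted pixel
centroid → nearest aperture centre; apertures with ≥ 2 components are
treated as fragmented sections, flagged, and excluded from accuracy
statistics (but counted). Containment models the section as an axis-aligned
square of side `section_side` (default 1 mm): contained iff
`|offset| ≤ (aperture_side − section_side)/2` on both axes. Rotation is
ignored — consistent with a box criterion on centroid position; containment
fractions are therefore approximate for rotated or irregular sections.

Cycle-time statistics report mean ± sd of pickup and full cycle, and
estimate dry-down (adhesion/drying of the wet section on the heated
substrate) as mean cycle − mean pickup; this first-order estimate absorbs
loop travel time and is documented as an overestimate.

The Fisher exact comparison takes a 2×2 table, rows = methods, columns =
(collected, lost). One-sided alternative: method A's loss rate is lower.
Two-sided p-values use the point-probability convention. Both sidedness
results are always reported. Degenerate margins return p = 1 with a warning.
The test itself is delegated to `scipy.stats.fisher_exact`; an independent
hypergeometric enumeration cross-checks it in the test suite.

## Synthetic data

Generators are pure functions of their spec (seed included) and always emit
ground truth alongside data.

* **Vesicle images** — disks of interior intensity on an exterior
  background, rendered with *analytic* error-function rims of width
  `edge_sigma` so the true maximum edge derivative has the closed form
  `ΔI/(σ_e √(2π))`; additive Gaussian noise; radial annotations 5σ outside
  and inside the rim. Default `edge_sigma = 3 px` (≈7.5 nm at the 2.5 nm/px
  imaging scale of high-magnification vesicle imaging): the edge width must
  dominate the pixel-sampling blur of profile interpolation (variance
  `h²/6` for bilinear sampling at random orientations, i.e. < 2% of σ² at
  3 px) for the closed-form derivative to describe the rendered image.
  Defaults `I_int = 60, I_ext = 100` give a true contrast of 0.25. No
  realistic EM texture is attempted — flat disks suffice for the metrics
  under test, which means the tests demonstrate estimator correctness, not
  performance on textured micrographs with confounding structure.
* **Placements** — per-axis normal offsets (defaults: mean (−20, 60) μm,
  sd (110, 150) μm, the realistic accuracy/repeatability scale of robotic
  placement), a seeded subset fragment-flagged, optional frame rendering as
  uniform squares (fragments: two disjoint blocks) for detector tests.
* **Cycle logs** — `cycle = pickup + dry-down`, both positive truncated
  normals (resampled, not clipped, to keep means interpretable). Defaults
  18.9 ± 9.7 s pickup and 24.6 s dry-down; the dry-down sd defaults to
  6.5 s so the implied cycle sd is `sqrt(9.7² + 6.5²) ≈ 11.7 s` under
  independence.

## Problem sizes and determinism

Monte-Carlo checks run at 10⁴ trials (standard error ~3×10⁻³ on a yield
near 0.9), the brute-force enumeration oracle covers `n ≤ 15` (2ⁿ
patterns), and recovery tests use 30 vesicles / 631 placements / 727 cycle
entries. All stochastic tests are seeded; simulation results are bit-stable
for a given seed, and the CLI derives per-component seeds from one global
seed via `seed + crc32(component) mod 2³¹`.

## Known limitations

* The yield model ignores cross-batch consecutive pairs and within-substrate
  spatial damage; substrate loss is modeled as total.
* The binomial traditional-yield model is an approximation (exact recurrence
  provided); both assume i.i.d. losses, while real loss events cluster.
* ESF slopes are bit-depth- and sampling-dependent quantities; compare them
  only between images measured under one convention.
* Containment assumes axis-aligned square sections of uniform size.
* No vesicle detection/segmentation: annotations are inputs. No MTF/Fourier
  sharpness analysis.
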