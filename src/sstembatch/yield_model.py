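"""Closed-form yield model for consecutive-section loss in serial sectioning.

The failure event that matters for 3-D reconstruction from serial sections is
the loss of two *adjacent* sections: a single lost section can be interpolated
across, but a lost pair breaks continuity. Two collection regimes are modeled:

* **traditional** — every section handled and imaged individually; each
  section is lost independently with probability ``p``, and the experiment
  succeeds when no adjacent pair is lost. Over the ``n - 1`` pair slots this
  is approximated binomially as ``(1 - p^2)^(n-1)``.
* **batched** — sections are distributed round-robin over ``m`` substrates per
  batch (``c`` sections per substrate), so no two consecutive sections share a
  substrate. A batch can only lose a consecutive pair if it loses two or more
  substrates (per-substrate loss rate ``p_sub``); the experiment succeeds when
  none of the ``k = ceil(n / (c m))`` batches fails.

All powers are accumulated in log space so the model stays accurate at
``n ~ 1e5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import LayoutError, ParameterError

__all__ = [
    "LossRates",
    "BatchLayout",
    "ExperimentPlan",
    "YieldSurface",
    "consecutive_pair_loss_probability",
    "traditional_experiment_yield",
    "num_batches",
    "batch_failure_probability",
    "batched_experiment_yield",
    "yield_surface",
    "recommend_layout",
]


def _check_probability(value: float, name: str) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and 0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class LossRates:
    """Loss probabilities of the collection process.

    Parameters
    ----------
    p:
        Per-section loss probability (traditional handling). Literature on
        manual serial sectioning puts its lower bound around 0.01.
    p_sub:
        Per-substrate loss probability (batched handling). Defaults to the
        same 0.01 bound; likely conservative, since larger substrates are
        easier to handle than individual grids.
    """

    p: float = 0.01
    p_sub: float = 0.01

    def __post_init__(self) -> None:
        _check_probability(self.p, "p")
        _check_probability(self.p_sub, "p_sub")


@dataclass(frozen=True)
class BatchLayout:
    """Batch geometry: ``m`` substrates per batch, ``c`` sections per substrate.

    ``m >= 2`` is required — with a single substrate per batch, consecutive
    sections could not be kept on different substrates.
    """

    m: int
    c: int

    def __post_init__(self) -> None:
        if int(self.m) != self.m or self.m < 2:
            raise LayoutError(f"m (substrates per batch) must be an integer >= 2, got {self.m!r}")
        if int(self.c) != self.c or self.c < 1:
            raise LayoutError(f"c (sections per substrate) must be an integer >= 1, got {self.c!r}")

    @property
    def sections_per_batch(self) -> int:
        return int(self.m) * int(self.c)


@dataclass(frozen=True)
class ExperimentPlan:
    """Total number of sections ``n`` to cut and collect (``n >= 1``)."""

    n: int

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise ParameterError(f"n (total sections) must be an integer >= 1, got {self.n!r}")


@dataclass(frozen=True)
class YieldSurface:
    """Experiment yield evaluated on an (m, c) grid; ``yields[i, j]``
    corresponds to ``m_values[i]``, ``c_values[j]``."""

    m_values: np.ndarray
    c_values: np.ndarray
    yields: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.yields.shape != (len(self.m_values), len(self.c_values)):
            raise ParameterError("yield matrix shape does not match m_values x c_values")


def consecutive_pair_loss_probability(rates: LossRates) -> float:
    """Probability that a specified pair of adjacent sections are both lost.

    With independent per-section losses this is simply ``p * p``.
    """
    return rates.p * rates.p


def traditional_experiment_yield(plan: ExperimentPlan, rates: LossRates) -> float:
    """Success probability of a traditionally processed run of ``n`` sections.

    Binomial pair-slot model: each of the ``n - 1`` adjacent pairs is
    independently "lost" with probability ``p^2``; success means zero lost
    pairs, i.e. ``(1 - p^2)^(n-1)``. This slightly understates the exact
    no-two-adjacent-losses probability (see
    :func:`sstembatch.simulator.exact_traditional_yield`) because pair slots
    overlap and are not truly independent.
    """
    n = int(plan.n)
    if n == 1:
        return 1.0
    q = rates.p * rates.p
    if q == 1.0:
        return 0.0
    return math.exp((n - 1) * math.log1p(-q))


def num_batches(plan: ExperimentPlan, layout: BatchLayout) -> int:
    """Number of batches ``k = ceil(n / (c m))``; the last may be partial."""
    return -(-int(plan.n) // layout.sections_per_batch)


def batch_failure_probability(rates: LossRates, layout: BatchLayout) -> float:
    """Probability that a single batch loses two or more of its ``m`` substrates.

    Losing a single substrate cannot destroy an adjacent pair (no two
    consecutive sections share a substrate), so a batch fails only on >= 2
    substrate losses::

        P = 1 - [(1 - p')^m + m p' (1 - p')^(m-1)]
    """
    p = rates.p_sub
    m = int(layout.m)
    # complement of {0 losses} + {exactly 1 loss}
    return 1.0 - ((1.0 - p) ** m + m * p * (1.0 - p) ** (m - 1))


def batched_experiment_yield(
    plan: ExperimentPlan, layout: BatchLayout, rates: LossRates
) -> float:
    """Success probability of a batch-processed run: no batch fails.

    Equals ``(1 - P)^k`` with ``P`` the per-batch failure probability and
    ``k`` the batch count; algebraically identical to one minus the binomial
    sum over 1..k failed batches. The final partial batch is treated as a full
    batch (conservative).
    """
    P = batch_failure_probability(rates, layout)
    k = num_batches(plan, layout)
    if P == 1.0:
        return 0.0
    return math.exp(k * math.log1p(-P))


def yield_surface(
    plan: ExperimentPlan,
    rates: LossRates,
    m_values,
    c_values,
) -> YieldSurface:
    """Evaluate the batched yield on the cartesian grid ``m_values x c_values``.

    The surface is stepped: yield changes discontinuously wherever
    ``ceil(n / (c m))`` crosses an integer boundary, because only whole
    batches enter the model.
    """
    m_arr = np.asarray(list(m_values), dtype=int)
    c_arr = np.asarray(list(c_values), dtype=int)
    if m_arr.size == 0 or c_arr.size == 0:
        raise ParameterError("m_values and c_values must be non-empty")
    out = np.empty((m_arr.size, c_arr.size), dtype=float)
    for i, m in enumerate(m_arr):
        for j, c in enumerate(c_arr):
            out[i, j] = batched_experiment_yield(plan, BatchLayout(m=int(m), c=int(c)), rates)
    return YieldSurface(m_values=m_arr, c_values=c_arr, yields=out)


def recommend_layout(
    plan: ExperimentPlan,
    rates: LossRates,
    m_max: int,
    c_max: int,
) -> tuple[int, int, float]:
    """Exhaustive argmax of the batched yield over ``2 <= m <= m_max``,
    ``1 <= c <= c_max``. Ties broken by smallest ``m``, then smallest ``c``.
    """
    if m_max < 2 or c_max < 1:
        raise ParameterError("bounds must satisfy m_max >= 2 and c_max >= 1")
    best: tuple[int, int, float] | None = None
    for m in range(2, int(m_max) + 1):
        for c in range(1, int(c_max) + 1):
            y = batched_experiment_yield(plan, BatchLayout(m=m, c=c), rates)
            if best is None or y > best[2]:
                best = (m, c, y)
    assert best is not None
    return best
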