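"""Throughput and consumable-cost models for serial-section collection.

Both regimes scale linearly in the section count ``n``; the batched regime
amortizes the microscope load time over the ``c * m`` sections of a batch and
replaces per-section grids (~USD 0.40 each) with wafer-batch microfabricated
substrates (cost ``w`` per wafer holding ``s`` sections).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ParameterError
from .yield_model import BatchLayout, ExperimentPlan

__all__ = [
    "TimingModel",
    "CostModel",
    "total_time_traditional",
    "total_time_batched",
    "cost_traditional",
    "cost_batched",
    "compare_designs",
]


@dataclass(frozen=True)
class TimingModel:
    """Per-step time constants, all in seconds.

    Defaults reflect typical figures for manual collection (~2 min per
    section pickup) and a measured robotic cycle time of 43.5 s.
    """

    t_imaging: float = 10.0
    t_pickup_traditional: float = 120.0
    t_load_traditional: float = 60.0
    t_pickup_robotic: float = 43.5
    t_load_batched: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "t_imaging",
            "t_pickup_traditional",
            "t_load_traditional",
            "t_pickup_robotic",
            "t_load_batched",
        ):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ParameterError(f"{name} must be a finite non-negative time, got {v!r}")


@dataclass(frozen=True)
class CostModel:
    """Consumable costs (abstract currency, documented as USD in examples).

    ``c_grid`` — one TEM grid (holds one large section); ``s`` — sections per
    microfabricated wafer; ``w`` — cost of processing one wafer.
    """

    c_grid: float = 0.40
    s: int = 320
    w: float = 500.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c_grid) and self.c_grid >= 0):
            raise ParameterError(f"c_grid must be non-negative, got {self.c_grid!r}")
        if int(self.s) != self.s or self.s < 1:
            raise ParameterError(f"s (sections per wafer) must be an integer >= 1, got {self.s!r}")
        if not (math.isfinite(self.w) and self.w >= 0):
            raise ParameterError(f"w (wafer cost) must be non-negative, got {self.w!r}")


def total_time_traditional(timing: TimingModel, plan: ExperimentPlan) -> float:
    """Total collection time, traditional: per-section image + pickup + load."""
    return (timing.t_imaging + timing.t_pickup_traditional + timing.t_load_traditional) * plan.n


def total_time_batched(
    timing: TimingModel, plan: ExperimentPlan, layout: BatchLayout
) -> float:
    """Total collection time, batched: the load is shared by a whole batch.

    ``(t_load / (c m) + t_imaging + t_pickup_robotic) * n`` — strictly
    decreasing in ``c m`` whenever the load time is positive.
    """
    per_section = (
        timing.t_load_batched / layout.sections_per_batch
        + timing.t_imaging
        + timing.t_pickup_robotic
    )
    return per_section * plan.n


def cost_traditional(plan: ExperimentPlan, cost: CostModel) -> float:
    """Substrate cost, traditional: one grid per section, ``n * c_grid``."""
    return plan.n * cost.c_grid


def cost_batched(plan: ExperimentPlan, cost: CostModel, *, whole_wafers: bool = False) -> float:
    """Substrate cost, batched: ``(n / s) * w``.

    Fractional wafers are allowed by default (the cost per section is exactly
    ``w / s``, independent of ``n``); pass ``whole_wafers=True`` to round the
    wafer count up for procurement realism.
    """
    if whole_wafers:
        return -(-int(plan.n) // int(cost.s)) * cost.w
    return (plan.n / cost.s) * cost.w


def compare_designs(
    timing: TimingModel,
    cost: CostModel,
    plan: ExperimentPlan,
    layout: BatchLayout,
) -> dict:
    """Head-to-head report of the two regimes.

    Ratios are traditional / batched (> 1 favors batching); a zero batched
    total makes the corresponding ratio undefined and is flagged as ``inf``
    with ``*_ratio_defined`` False.
    """
    t_trad = total_time_traditional(timing, plan)
    t_batch = total_time_batched(timing, plan, layout)
    c_trad = cost_traditional(plan, cost)
    c_batch = cost_batched(plan, cost)

    def _ratio(a: float, b: float) -> tuple[float, bool]:
        if b == 0.0:
            return (math.inf if a > 0 else math.nan), False
        return a / b, True

    time_ratio, time_ok = _ratio(t_trad, t_batch)
    cost_ratio, cost_ok = _ratio(c_trad, c_batch)
    n = plan.n
    return {
        "time_ratio": time_ratio,
        "time_ratio_defined": time_ok,
        "cost_ratio": cost_ratio,
        "cost_ratio_defined": cost_ok,
        "per_section_time_traditional": t_trad / n,
        "per_section_time_batched": t_batch / n,
        "per_section_cost_traditional": c_trad / n,
        "per_section_cost_batched": c_batch / n,
        "total_time_traditional": t_trad,
        "total_time_batched": t_batch,
        "total_cost_traditional": c_trad,
        "total_cost_batched": c_batch,
    }
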