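"""Design of syringe-pump flow programs for droplet concentration gradients.

A screening run dilutes one or two effector stock solutions against base
cultivation medium inside a constant total flow. Three aqueous channels
(cell suspension, effector(s), medium) plus the immiscible carrier liquid
sum to the total flow at every instant; the effector concentration inside a
droplet follows from simple mass balance over the aqueous channels:

    c(t) = c_stock * f_effector(t) / (f_cells + f_aqueous_dosing)

With the default flows (carrier 136, cells 32, dosing 32 uL/min; aqueous
total 64 uL/min) a 2x stock swept 0 -> 32 uL/min spans 0..100% of the target
maximum in a 1D ramp, and a 4x stock at up to 16 uL/min per effector does
the same on each axis of a 2D step grid.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Effector",
    "ScreeningPlan",
    "FlowProgram",
    "Segment",
    "CostEstimate",
    "design_1d_program",
    "design_2d_program",
    "concentration_at",
    "droplet_schedule",
    "estimate_screening_cost",
]

_FLOW_ATOL = 1e-9


@dataclass(frozen=True)
class Effector:
    """One medium component whose concentration is varied in a screen.

    ``stock_mM`` is the syringe stock concentration; ``stock_factor`` is the
    ratio of stock to the highest final in-droplet concentration (2 for 1D
    ramps, 4 for 2D grids, where each axis only receives half the dosing
    flow). ``max_final_mM = stock_mM / stock_factor``.
    """

    name: str
    stock_mM: float
    stock_factor: float | None = None

    def resolved(self, dimensionality: int) -> "Effector":
        if self.stock_factor is not None:
            return self
        return replace(self, stock_factor=2.0 if dimensionality == 1 else 4.0)

    @property
    def max_final_mM(self) -> float:
        if self.stock_factor is None:
            raise ValueError(f"effector {self.name!r}: stock_factor unresolved")
        return self.stock_mM / self.stock_factor


@dataclass(frozen=True)
class ScreeningPlan:
    """Configuration of one screening run (flows, droplets, effectors)."""

    effectors: tuple[Effector, ...]
    dimensionality: int = 1
    n_steps: int = 11            # 2D: concentration levels per axis
    droplets_per_step: int = 8   # 2D: droplets per grid cell
    n_droplets: int = 440        # 1D: droplets in the ramp sequence
    droplet_volume_nl: float = 500.0
    total_flow_ul_min: float = 200.0
    carrier_flow_ul_min: float = 136.0
    cells_flow_ul_min: float = 32.0
    aqueous_dosing_flow_ul_min: float = 32.0

    def __post_init__(self):
        if self.dimensionality not in (1, 2):
            raise ValueError("dimensionality must be 1 or 2")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.n_droplets < 1 or self.droplets_per_step < 1:
            raise ValueError("droplet counts must be >= 1")
        for f in (
            self.total_flow_ul_min,
            self.carrier_flow_ul_min,
            self.cells_flow_ul_min,
            self.aqueous_dosing_flow_ul_min,
        ):
            if f < 0:
                raise ValueError("flows must be non-negative")
        balance = (
            self.carrier_flow_ul_min
            + self.cells_flow_ul_min
            + self.aqueous_dosing_flow_ul_min
        )
        if abs(balance - self.total_flow_ul_min) > _FLOW_ATOL:
            raise ValueError(
                f"channel flows {balance} uL/min do not sum to total "
                f"{self.total_flow_ul_min} uL/min"
            )
        object.__setattr__(
            self,
            "effectors",
            tuple(e.resolved(self.dimensionality) for e in self.effectors),
        )

    @property
    def aqueous_flow_ul_min(self) -> float:
        """Dilution denominator: cell suspension + aqueous dosing flow."""
        return self.cells_flow_ul_min + self.aqueous_dosing_flow_ul_min

    @property
    def droplet_rate_per_min(self) -> float:
        """Droplet generation cadence (aqueous volumetric rate / volume)."""
        if self.aqueous_flow_ul_min <= 0:
            raise ValueError("zero aqueous flow: no droplets are generated")
        return self.aqueous_flow_ul_min * 1000.0 / self.droplet_volume_nl

    @property
    def droplet_period_min(self) -> float:
        return 1.0 / self.droplet_rate_per_min

    def total_droplets(self) -> int:
        if self.dimensionality == 1:
            return self.n_droplets
        return self.n_steps**2 * self.droplets_per_step


@dataclass(frozen=True)
class Segment:
    """One piece of a flow program; flows interpolate linearly in time."""

    t0_min: float
    t1_min: float
    start_flows: dict[str, float]
    end_flows: dict[str, float]

    def flow_at(self, t_min: float) -> dict[str, float]:
        if self.t1_min == self.t0_min:
            return dict(self.start_flows)
        w = (t_min - self.t0_min) / (self.t1_min - self.t0_min)
        return {
            ch: (1.0 - w) * self.start_flows[ch] + w * self.end_flows[ch]
            for ch in self.start_flows
        }


@dataclass(frozen=True)
class FlowProgram:
    """Piecewise-linear flow schedule for every pump channel."""

    channels: tuple[str, ...]
    segments: tuple[Segment, ...]
    metadata: dict = field(default_factory=dict)

    @property
    def duration_min(self) -> float:
        return self.segments[-1].t1_min

    def _segment_index(self, t_min: float) -> int:
        if t_min < -_FLOW_ATOL or t_min > self.duration_min + _FLOW_ATOL:
            raise ValueError(
                f"t={t_min} min outside program duration [0, {self.duration_min}]"
            )
        starts = [s.t0_min for s in self.segments]
        i = bisect_right(starts, t_min) - 1
        return max(0, min(i, len(self.segments) - 1))

    def flow_at(self, t_min: float) -> dict[str, float]:
        """Per-channel flow (uL/min) at time ``t_min``."""
        return self.segments[self._segment_index(t_min)].flow_at(t_min)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time_min, channel, flow_ul_min) at breakpoints."""
        rows = []
        for seg in self.segments:
            for t, flows in ((seg.t0_min, seg.start_flows), (seg.t1_min, seg.end_flows)):
                for ch in self.channels:
                    rows.append({"time_min": t, "channel": ch, "flow_ul_min": flows[ch]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _base_flows(plan: ScreeningPlan) -> dict[str, float]:
    return {
        "carrier": plan.carrier_flow_ul_min,
        "cells": plan.cells_flow_ul_min,
    }


def design_1d_program(plan: ScreeningPlan) -> FlowProgram:
    """Continuous 1D gradient: effector flow ramps linearly 0 -> full dosing
    flow while the diluting medium flow falls to zero; carrier and cell flows
    stay constant so the total is conserved throughout."""
    if plan.dimensionality != 1:
        raise ValueError("plan.dimensionality must be 1 for a 1D program")
    if len(plan.effectors) != 1:
        raise ValueError("1D program requires exactly one effector")
    eff = plan.effectors[0]
    duration = plan.n_droplets * plan.droplet_period_min
    ch_eff = f"effector_{eff.name}"
    start = {**_base_flows(plan), ch_eff: 0.0, "medium": plan.aqueous_dosing_flow_ul_min}
    end = {**_base_flows(plan), ch_eff: plan.aqueous_dosing_flow_ul_min, "medium": 0.0}
    seg = Segment(0.0, duration, start, end)
    return FlowProgram(
        channels=("carrier", "cells", ch_eff, "medium"),
        segments=(seg,),
        metadata={
            "kind": "1d_linear_ramp",
            "effector": eff.name,
            "n_droplets": plan.n_droplets,
        },
    )


def design_2d_program(plan: ScreeningPlan) -> FlowProgram:
    """Stepwise 2D grid: all ``n_steps**2`` ordered (A%, B%) level pairs as
    consecutive dwell periods, A outer / B inner (row-major in effector A).

    At level p% an effector receives p/100 of half the dosing flow; the
    medium channel takes the remainder, keeping the aqueous dosing total and
    thus the overall flow constant.
    """
    if plan.dimensionality != 2:
        raise ValueError("plan.dimensionality must be 2 for a 2D program")
    if len(plan.effectors) != 2:
        raise ValueError("2D program requires exactly two effectors")
    eff_a, eff_b = plan.effectors
    ch_a, ch_b = f"effector_{eff_a.name}", f"effector_{eff_b.name}"
    per_axis_flow = plan.aqueous_dosing_flow_ul_min / 2.0
    levels = np.linspace(0.0, 100.0, plan.n_steps) if plan.n_steps > 1 else np.array([0.0])
    dwell = plan.droplets_per_step * plan.droplet_period_min

    segments = []
    combos = []
    t = 0.0
    for pa in levels:
        for pb in levels:
            fa = pa / 100.0 * per_axis_flow
            fb = pb / 100.0 * per_axis_flow
            if fa + fb > plan.aqueous_dosing_flow_ul_min + _FLOW_ATOL:
                raise ValueError(
                    f"effector flows {fa}+{fb} exceed dosing flow "
                    f"{plan.aqueous_dosing_flow_ul_min} uL/min"
                )
            flows = {
                **_base_flows(plan),
                ch_a: fa,
                ch_b: fb,
                "medium": plan.aqueous_dosing_flow_ul_min - fa - fb,
            }
            segments.append(Segment(t, t + dwell, flows, dict(flows)))
            combos.append((float(pa), float(pb)))
            t += dwell
    return FlowProgram(
        channels=("carrier", "cells", ch_a, ch_b, "medium"),
        segments=tuple(segments),
        metadata={
            "kind": "2d_step_grid",
            "effectors": (eff_a.name, eff_b.name),
            "ordering": "A-outer-row-major",
            "levels_percent": [float(p) for p in levels],
            "combinations": combos,
            "droplets_per_step": plan.droplets_per_step,
        },
    )


def concentration_at(
    program: FlowProgram, plan: ScreeningPlan, t_min: float
) -> dict[str, dict[str, float]]:
    """Per-effector droplet concentration at program time ``t_min``.

    Returns ``{name: {"mM": c, "percent_of_max": p}}`` with
    ``c = stock_mM * f_effector / (f_cells + f_dosing)``.
    """
    flows = program.flow_at(t_min)
    denom = plan.aqueous_flow_ul_min
    if denom <= 0:
        raise ValueError("zero aqueous flow")
    out: dict[str, dict[str, float]] = {}
    for eff in plan.effectors:
        f = flows.get(f"effector_{eff.name}", 0.0)
        c = eff.stock_mM * f / denom
        out[eff.name] = {
            "mM": c,
            "percent_of_max": 100.0 * c / eff.max_final_mM if eff.max_final_mM > 0 else 0.0,
        }
    return out


def droplet_schedule(program: FlowProgram, plan: ScreeningPlan) -> pd.DataFrame:
    """Emission schedule: one droplet per ``droplet_volume`` of aqueous flow.

    Droplets are timestamped at the midpoint of the aqueous volume interval
    they collect, so a 2D dwell of ``droplets_per_step`` periods yields
    exactly that many droplets per grid cell. Columns: ``droplet_index``,
    ``generation_time_min``, ``conc_<name>_mM``, ``pct_<name>``.
    """
    period = plan.droplet_period_min
    n = plan.total_droplets()
    rows = []
    for i in range(n):
        t = (i + 0.5) * period
        t = min(t, program.duration_min)  # guard FP edge at the final droplet
        concs = concentration_at(program, plan, t)
        row: dict[str, float] = {"droplet_index": i, "generation_time_min": t}
        for name, c in concs.items():
            row[f"conc_{name}_mM"] = c["mM"]
            row[f"pct_{name}"] = c["percent_of_max"]
        rows.append(row)
    df = pd.DataFrame(rows)
    df["droplet_index"] = df["droplet_index"].astype(int)
    return df


@dataclass(frozen=True)
class CostEstimate:
    """Material comparison between a droplet screen and microtiter plates."""

    dimensionality: int
    resolution_percent: float
    n_steps: int
    droplets_per_step: int
    n_droplets: int
    droplet_volume_ul: float
    microfluidic_volume_ul: float
    mtp_wells: int
    well_volume_ul: float
    mtp_volume_ml: float
    mtp_plates: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def estimate_screening_cost(
    dimensionality: int,
    resolution_percent: float,
    droplets_per_step: int,
    droplet_volume_ul: float = 0.2,
    well_volume_ul: float = 200.0,
    wells_per_plate: int = 96,
) -> CostEstimate:
    """Steps, droplets and medium volume for a screen at a given resolution,
    against the microtiter-plate equivalent (one droplet = one 200 uL well).

    A resolution of r% over a 0..100% axis needs 100/r concentration steps
    per dimension, hence ``(100/r)**d`` steps in total.
    """
    if dimensionality not in (1, 2):
        raise ValueError("dimensionality must be 1 or 2")
    if resolution_percent <= 0 or droplets_per_step <= 0 or droplet_volume_ul <= 0:
        raise ValueError("inputs must be positive")
    if well_volume_ul <= 0 or wells_per_plate <= 0:
        raise ValueError("well geometry must be positive")
    steps_per_axis = 100.0 / resolution_percent
    if abs(steps_per_axis - round(steps_per_axis)) > 1e-9:
        raise ValueError("resolution_percent must divide 100")
    n_steps = int(round(steps_per_axis)) ** dimensionality
    n_droplets = n_steps * droplets_per_step
    wells = n_droplets
    return CostEstimate(
        dimensionality=dimensionality,
        resolution_percent=resolution_percent,
        n_steps=n_steps,
        droplets_per_step=droplets_per_step,
        n_droplets=n_droplets,
        droplet_volume_ul=droplet_volume_ul,
        microfluidic_volume_ul=n_droplets * droplet_volume_ul,
        mtp_wells=wells,
        well_volume_ul=well_volume_ul,
        mtp_volume_ml=wells * well_volume_ul / 1000.0,
        mtp_plates=math.ceil(wells / wells_per_plate),
    )
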