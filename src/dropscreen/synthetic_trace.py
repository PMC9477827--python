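"""Synthetic droplet trains and raw multi-channel sensor traces.

Stands in for the physical device: droplets scheduled by a flow program are
loaded with cells by Poisson statistics, grow for up to a week according to
a nutrient-dependent logistic model, and are "measured" daily by rendering a
250 Hz optical trace (four absorbance channels plus chlorophyll
autofluorescence) with configurable baseline, drift, pulse-height
heterogeneity and additive noise. Ground truth is retained per droplet so
downstream detection and analysis can be evaluated exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .gradient_design import FlowProgram, ScreeningPlan, droplet_schedule

__all__ = [
    "CHANNELS",
    "TruthDroplet",
    "TruthSet",
    "EffectorResponse",
    "GrowthParams",
    "OpticsModel",
    "SensorTrace",
    "TraceSchemaError",
    "sample_initial_cells",
    "grow",
    "render_trace",
    "simulate_run",
    "write_trace",
    "read_trace",
]

#: Detector channels: absorbance at 470/505/615/750 nm and autofluorescence
#: (405 nm excitation, 425 nm longpass emission).
CHANNELS = ("a470", "a505", "a615", "a750", "f405_425")

DEFAULT_SAMPLING_RATE_HZ = 250.0
DEFAULT_CELL_DENSITY_PER_NL = 10.0  # 1e7 cells/mL inoculum
N_DAYS = 7


class TraceSchemaError(ValueError):
    """Raised when a trace file does not match the expected schema."""


@dataclass
class TruthDroplet:
    """Ground truth for one simulated droplet."""

    index: int
    volume_nl: float
    concentrations_mM: dict[str, float]
    percent_of_max: dict[str, float]
    cells_t: np.ndarray  # cell count, day 0..7
    generation_time_min: float

    def density_per_nl(self, day: int) -> float:
        return float(self.cells_t[day]) / self.volume_nl


@dataclass
class TruthSet:
    """All ground-truth droplets of one simulated run, in generation order."""

    droplets: list[TruthDroplet]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.droplets)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.droplets:
            row: dict = {
                "droplet_index": d.index,
                "generation_time_min": d.generation_time_min,
                "volume_nl": d.volume_nl,
            }
            for name, c in d.concentrations_mM.items():
                row[f"conc_{name}_mM"] = c
            for name, p in d.percent_of_max.items():
                row[f"pct_{name}"] = p
            for day in range(N_DAYS + 1):
                row[f"cells_day{day}"] = d.cells_t[day]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EffectorResponse:
    """Dose dependence of growth on one effector: Monod limitation at low
    concentration, smooth (logistic) inhibition above a threshold."""

    half_saturation_mM: float
    inhibition_threshold_mM: float
    inhibition_steepness_per_mM: float = 0.5

    def __post_init__(self):
        if min(self.half_saturation_mM, self.inhibition_threshold_mM,
               self.inhibition_steepness_per_mM) <= 0:
            raise ValueError("response parameters must be positive")
        if self.inhibition_threshold_mM <= self.half_saturation_mM:
            raise ValueError("inhibition_threshold must exceed half_saturation")

    def factor(self, c_mM: float) -> float:
        if c_mM < 0:
            raise ValueError("negative concentration")
        monod = c_mM / (c_mM + self.half_saturation_mM)
        z = self.inhibition_steepness_per_mM * (c_mM - self.inhibition_threshold_mM)
        # clip to keep exp well-behaved for extreme concentrations
        inhibition = 1.0 / (1.0 + math.exp(min(z, 700.0)))
        return monod * inhibition


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth with a Liebig minimum over per-effector responses.

    The realized rate is ``max_rate * min_e factor_e(c_e)``; effectors with
    no entry in ``responses`` do not limit growth. Defaults give a strain
    doubling every ~14 h at optimum, saturating near 2000 cells/nL.
    """

    max_rate_per_day: float = 1.2
    carrying_capacity_per_nl: float = 2000.0
    lag_days: float = 0.5
    responses: dict[str, EffectorResponse] = field(default_factory=dict)

    def __post_init__(self):
        if min(self.max_rate_per_day, self.carrying_capacity_per_nl) <= 0:
            raise ValueError("max_rate and carrying_capacity must be positive")
        if self.lag_days < 0:
            raise ValueError("lag_days must be non-negative")

    def rate_factor(self, concentrations_mM: dict[str, float]) -> float:
        factors = [
            resp.factor(concentrations_mM[name])
            for name, resp in self.responses.items()
            if name in concentrations_mM
        ]
        return min(factors) if factors else 1.0


def sample_initial_cells(
    volume_nl: float, density_per_nl: float, rng: np.random.Generator
) -> int:
    """Poisson cell load of a droplet (mean = volume x inoculum density)."""
    if volume_nl <= 0:
        raise ValueError("volume must be positive")
    if density_per_nl < 0:
        raise ValueError("density must be non-negative")
    if density_per_nl == 0:
        return 0
    return int(rng.poisson(volume_nl * density_per_nl))


def grow(
    cells0: float,
    concentrations_mM: dict[str, float],
    day: float,
    params: GrowthParams,
    volume_nl: float = 500.0,
) -> float:
    """Cell count after ``day`` days of nutrient-dependent logistic growth.

    Closed-form logistic from the end of the lag phase with carrying
    capacity ``carrying_capacity_per_nl * volume_nl``; monotone
    non-decreasing in ``day`` and bounded by the capacity.
    """
    if day < 0:
        raise ValueError("day must be non-negative")
    for c in concentrations_mM.values():
        if c < 0:
            raise ValueError("negative concentration")
    if cells0 <= 0:
        return 0.0
    t = max(0.0, day - params.lag_days)
    r = params.max_rate_per_day * params.rate_factor(concentrations_mM)
    capacity = params.carrying_capacity_per_nl * volume_nl
    if cells0 >= capacity:
        return float(cells0)
    if r * t == 0.0:
        return float(cells0)
    return capacity / (1.0 + (capacity / cells0 - 1.0) * math.exp(-r * t))


@dataclass(frozen=True)
class OpticsModel:
    """Linear optics of the flow-through photo-fluorimeter.

    Each droplet renders as a plateau pulse on every channel with height
    ``droplet_offset + gain * cell_density`` above the carrier baseline; the
    offset is the blank-droplet signal (refractive-index step between the
    aqueous plug and the carrier). Pulse-height heterogeneity (lognormal,
    one factor per droplet-day) models inhomogeneous cell distribution.
    """

    gain_per_cells_nl: dict[str, float] = field(
        default_factory=lambda: {
            "a470": 0.0024, "a505": 0.0018, "a615": 0.0012,
            "a750": 0.0020, "f405_425": 0.005,
        }
    )
    droplet_offset: dict[str, float] = field(
        default_factory=lambda: {
            "a470": 0.50, "a505": 0.45, "a615": 0.40,
            "a750": 0.50, "f405_425": 0.02,
        }
    )
    carrier_level: dict[str, float] = field(
        default_factory=lambda: {ch: 0.05 for ch in CHANNELS}
    )
    drift_per_s: float = 0.0
    noise_sd: float = 0.01
    heterogeneity_sd: float = 0.10
    edge_sigma_samples: float = 2.0
    tube_id_mm: float = 1.0

    def __post_init__(self):
        if any(g < 0 for g in self.gain_per_cells_nl.values()):
            raise ValueError("gains must be non-negative")
        if self.noise_sd < 0 or self.heterogeneity_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.tube_id_mm <= 0:
            raise ValueError("tube inner diameter must be positive")

    def tube_area_mm2(self) -> float:
        return math.pi * (self.tube_id_mm / 2.0) ** 2

    def linear_velocity_mm_s(self, total_flow_ul_min: float) -> float:
        """Plug velocity in the detection tube (1 uL = 1 mm^3)."""
        return total_flow_ul_min / 60.0 / self.tube_area_mm2()

    def passage_time_s(self, volume_nl: float, total_flow_ul_min: float) -> float:
        """Time a droplet of given volume needs to pass the detector."""
        length_mm = volume_nl * 1e-3 / self.tube_area_mm2()
        return length_mm / self.linear_velocity_mm_s(total_flow_ul_min)

    def pulse_height(self, channel: str, density_per_nl: float) -> float:
        return (
            self.droplet_offset[channel]
            + self.gain_per_cells_nl[channel] * density_per_nl
        )


@dataclass
class SensorTrace:
    """Uniformly sampled multi-channel optical signal of one measurement."""

    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.time_s}
        data.update({ch: self.channels[ch] for ch in CHANNELS})
        return pd.DataFrame(data)


def render_trace(
    truth: TruthSet,
    day: int,
    optics: OpticsModel,
    plan: ScreeningPlan,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    rng: np.random.Generator | None = None,
    pad_s: float = 2.0,
) -> SensorTrace:
    """Render the day-``day`` sensor trace of a droplet sequence.

    Droplets appear in generation order at their scheduled cadence; each is
    a rectangular pulse of width = passage time, optionally edge-smoothed,
    with per-channel heights from the optics model. ``rng`` drives the
    heterogeneity and additive-noise draws; pass None for a noise-free
    render regardless of the configured noise parameters.
    """
    fs = sampling_rate_hz
    velocity = optics.linear_velocity_mm_s(plan.total_flow_ul_min)
    if velocity <= 0:
        raise ValueError("zero flow: droplets never reach the detector")

    last = truth.droplets[-1]
    duration_s = pad_s * 2 + last.generation_time_min * 60.0 + optics.passage_time_s(
        last.volume_nl, plan.total_flow_ul_min
    )
    n = int(math.ceil(duration_s * fs))
    t = np.arange(n) / fs

    signal = {
        ch: np.full(n, optics.carrier_level[ch]) + optics.drift_per_s * t
        for ch in CHANNELS
    }

    prev_end = -1
    for d in truth.droplets:
        pt = optics.passage_time_s(d.volume_nl, plan.total_flow_ul_min)
        center_s = pad_s + d.generation_time_min * 60.0
        i0 = int(round((center_s - pt / 2.0) * fs))
        i1 = i0 + max(1, int(round(pt * fs)))  # exclusive
        if i0 <= prev_end:
            raise ValueError(
                f"droplet {d.index} overlaps its predecessor in the trace"
            )
        if i0 < 0 or i1 > n:
            raise ValueError(f"droplet {d.index} falls outside the trace window")
        prev_end = i1 - 1
        density = d.density_per_nl(day)
        het = 1.0
        if rng is not None and optics.heterogeneity_sd > 0 and density > 0:
            sd = optics.heterogeneity_sd
            sigma = math.sqrt(math.log(1.0 + sd**2))
            het = rng.lognormal(-0.5 * sigma**2, sigma)
        for ch in CHANNELS:
            height = (
                optics.droplet_offset[ch]
                + optics.gain_per_cells_nl[ch] * density * het
            )
            signal[ch][i0:i1] += height

    if optics.edge_sigma_samples > 0:
        for ch in CHANNELS:
            base = optics.carrier_level[ch] + optics.drift_per_s * t
            signal[ch] = base + gaussian_filter1d(
                signal[ch] - base, optics.edge_sigma_samples
            )
    if rng is not None and optics.noise_sd > 0:
        for ch in CHANNELS:
            signal[ch] = signal[ch] + rng.normal(0.0, optics.noise_sd, n)

    return SensorTrace(
        sampling_rate_hz=fs,
        channels=signal,
        metadata={"day": day, "n_droplets": len(truth), "pad_s": pad_s},
    )


def simulate_run(
    plan: ScreeningPlan,
    program: FlowProgram,
    params: GrowthParams,
    optics: OpticsModel,
    seed: int,
    measure_days: tuple[int, ...] = tuple(range(N_DAYS + 1)),
    initial_density_per_nl: float = DEFAULT_CELL_DENSITY_PER_NL,
    volume_cv: float = 0.02,
    noise_free: bool = False,
) -> tuple[TruthSet, dict[int, SensorTrace]]:
    """Simulate a full screening run: droplet train plus daily traces.

    One ``TruthDroplet`` per scheduled droplet; traces are rendered for each
    requested measurement day with count, order and identity conserved.
    Deterministic under a fixed seed.
    """
    if not measure_days or min(measure_days) < 0 or max(measure_days) > N_DAYS:
        raise ValueError(f"measure_days must lie within 0..{N_DAYS}")
    rng = np.random.default_rng(seed)
    schedule = droplet_schedule(program, plan)

    conc_cols = [c for c in schedule.columns if c.startswith("conc_")]
    pct_cols = [c for c in schedule.columns if c.startswith("pct_")]
    droplets = []
    for row in schedule.itertuples(index=False):
        rowd = row._asdict()
        volume = plan.droplet_volume_nl
        if volume_cv > 0:
            sigma = math.sqrt(math.log(1.0 + volume_cv**2))
            volume *= rng.lognormal(-0.5 * sigma**2, sigma)
        cells0 = sample_initial_cells(volume, initial_density_per_nl, rng)
        concs = {c[len("conc_"):-len("_mM")]: rowd[c] for c in conc_cols}
        pcts = {c[len("pct_"):]: rowd[c] for c in pct_cols}
        cells_t = np.array(
            [grow(cells0, concs, day, params, volume) for day in range(N_DAYS + 1)]
        )
        droplets.append(
            TruthDroplet(
                index=int(rowd["droplet_index"]),
                volume_nl=volume,
                concentrations_mM=concs,
                percent_of_max=pcts,
                cells_t=cells_t,
                generation_time_min=rowd["generation_time_min"],
            )
        )
    truth = TruthSet(droplets=droplets, seed=seed)

    traces = {}
    for day in measure_days:
        traces[day] = render_trace(
            truth, day, optics, plan, rng=None if noise_free else rng
        )
        traces[day].metadata["seed"] = seed
    return truth, traces


# ---------------------------------------------------------------------------
# Trace file I/O: delimited text plus a JSON sidecar for metadata.

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace(trace: SensorTrace, path) -> None:
    """Write a trace as CSV (time_s + one column per channel) with a
    ``<name>.csv.meta.json`` sidecar carrying sampling rate and metadata."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")
    meta = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "metadata": _json_safe(trace.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True, indent=1))


def _json_safe(obj):
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_trace(path) -> SensorTrace:
    """Read a trace written by :func:`write_trace`; lossless round trip."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise TraceSchemaError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("time_s", *CHANNELS) if c not in df.columns]
    if missing:
        raise TraceSchemaError(f"trace file {path} lacks columns {missing}")
    if df.isna().any().any():
        raise TraceSchemaError(f"trace file {path} contains ragged/missing values")
    return SensorTrace(
        sampling_rate_hz=meta["sampling_rate_hz"],
        channels={ch: df[ch].to_numpy() for ch in CHANNELS},
        metadata=meta.get("metadata", {}),
    )
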