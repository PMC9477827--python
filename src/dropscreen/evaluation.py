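"""Evaluation of the pipeline against simulator ground truth.

Used to benchmark droplet detection (recall/precision against the known
droplet train) and end-to-end optimum recovery (does the full
simulate -> detect -> match -> bin pipeline find the growth model's true
concentration optimum?).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .droplet_detection import analyze_trace, records_to_frame
from .gradient_design import design_1d_program, design_2d_program, droplet_schedule
from .presets import (
    default_optics,
    nitrate_1d_plan,
    nitrate_growth_params,
    np_2d_plan,
    np_growth_params,
)
from .screening_analysis import assign_concentrations, bin_1d, grid_2d, nfu_table
from .synthetic_trace import GrowthParams, SensorTrace, TruthSet, grow, simulate_run


def detection_metrics(
    records: list,
    truth: TruthSet,
    trace: SensorTrace,
    match_tolerance_s: float = 0.2,
) -> tuple[float, float]:
    """Recall and precision of detected droplets against the ground truth.

    A detected record matches the nearest unmatched truth droplet whose
    pulse center lies within ``match_tolerance_s`` (< half the droplet
    period, so matches are unambiguous).
    """
    fs = trace.sampling_rate_hz
    pad_s = trace.metadata.get("pad_s", 0.0)
    truth_centers = np.array(
        [pad_s + d.generation_time_min * 60.0 for d in truth.droplets]
    )
    det_centers = np.array(
        [(r.start_sample + r.end_sample) / 2.0 / fs for r in records]
    )
    matched_truth: set[int] = set()
    n_matched = 0
    for c in det_centers:
        i = int(np.argmin(np.abs(truth_centers - c)))
        if i not in matched_truth and abs(truth_centers[i] - c) <= match_tolerance_s:
            matched_truth.add(i)
            n_matched += 1
    recall = n_matched / len(truth)
    precision = n_matched / len(records) if records else 0.0
    return recall, precision


def run_1d_screen(
    seed: int,
    n_droplets: int = 440,
    measure_days: tuple[int, int] = (0, 7),
    n_bins: int = 32,
):
    """Full 1D nitrate screen at default conditions; returns the truth set,
    per-day record tables and the binned dose-response curve."""
    plan = nitrate_1d_plan(n_droplets=n_droplets)
    program = design_1d_program(plan)
    truth, traces = simulate_run(
        plan, program, nitrate_growth_params(), default_optics(),
        seed=seed, measure_days=measure_days,
    )
    records = {
        day: records_to_frame(analyze_trace(trace)[1], trace.sampling_rate_hz)
        for day, trace in traces.items()
    }
    table, _ = nfu_table(records[measure_days[0]], records[measure_days[-1]])
    annotated = assign_concentrations(table, program, plan)
    curve = bin_1d(annotated, plan, n_bins=n_bins)
    return plan, truth, records, curve


def true_peak_bin(
    params: GrowthParams | None = None,
    max_conc_mM: float = 50.0,
    effector: str = "NaNO3",
    n_bins: int = 32,
    cells0: float = 5000.0,
    day: int = 7,
) -> int:
    """Bin index maximizing the growth model's endpoint, by brute force over
    the bin centers (the oracle for pipeline optimum recovery)."""
    params = params or nitrate_growth_params()
    edges = np.linspace(0.0, max_conc_mM, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    endpoint = [grow(cells0, {effector: c}, day, params) for c in centers]
    return int(np.argmax(endpoint))


def run_2d_screen(seed: int, droplets_per_step: int = 8):
    """Full 2D N x P screen at default conditions; returns the plan and the
    response matrix."""
    plan = np_2d_plan(droplets_per_step=droplets_per_step)
    program = design_2d_program(plan)
    truth, traces = simulate_run(
        plan, program, np_growth_params(), default_optics(),
        seed=seed, measure_days=(0, 7),
    )
    records = {
        day: records_to_frame(analyze_trace(trace)[1], trace.sampling_rate_hz)
        for day, trace in traces.items()
    }
    table, _ = nfu_table(records[0], records[7])
    annotated = assign_concentrations(table, program, plan)
    matrix = grid_2d(annotated, plan)
    return plan, matrix


def liebig_contrast(matrix: pd.DataFrame, plan) -> dict[str, float]:
    """Joint-optimum NFU versus the best single-nutrient increase with the
    other nutrient at its base (0%) level."""
    eff_a, eff_b = plan.effectors
    joint = float(matrix["mean_nfu"].max())
    single_a = float(matrix[matrix[f"pct_{eff_b.name}"] == 0.0]["mean_nfu"].max())
    single_b = float(matrix[matrix[f"pct_{eff_a.name}"] == 0.0]["mean_nfu"].max())
    return {"joint": joint, "single_A": single_a, "single_B": single_b}
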