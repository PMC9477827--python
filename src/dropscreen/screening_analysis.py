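"""Growth readouts and dose-response extraction from droplet records.

Growth of a droplet is quantified as normalized fluorescence units (NFU),
the relative increase of its autofluorescence intensity over the initial
measurement:

    NFU_t = (I_t - I_t0) / I_t0

Droplets are paired across measurement days by ordinal position (order is
conserved in the storage coil), annotated with their scheduled
concentrations, and aggregated into 1D dose-response curves (equal-width
percent bins) or 2D response matrices (exact grid cells). Optima are
reported as plateau ranges rather than bare argmax bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gradient_design import FlowProgram, ScreeningPlan, droplet_schedule

__all__ = [
    "nfu",
    "match_days",
    "assign_concentrations",
    "nfu_table",
    "bin_1d",
    "grid_2d",
    "growth_curves",
    "OptimumSummary",
    "find_optimum",
    "find_optimum_2d",
    "np_ratio",
    "compare_endpoints",
]

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 32
DEFAULT_NFU_CHANNEL = "f405_425"
DEFAULT_MATCH_TOLERANCE = 0.05
DEFAULT_PLATEAU_FRACTION = 0.05


def nfu(i_t, i_t0):
    """Normalized fluorescence units: ``(I_t - I_t0) / I_t0``.

    Inputs are background-subtracted intensities; an initial intensity of
    zero makes the readout undefined and returns NaN (callers exclude such
    droplets and log them).
    """
    i_t = np.asarray(i_t, dtype=float)
    i_t0 = np.asarray(i_t0, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (i_t - i_t0) / i_t0
    out = np.where(i_t0 == 0, np.nan, out)
    return float(out) if out.ndim == 0 else out


def match_days(
    day0_records: pd.DataFrame,
    dayt_records: pd.DataFrame,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """Pair droplets of two measurement days by ordinal index.

    If the counts differ by at most ``tolerance`` (fractional), both lists
    are aligned from the sequence start and truncated to the shorter one
    with a warning; a larger mismatch signals droplet coalescence or loss
    and raises.
    """
    n0, nt = len(day0_records), len(dayt_records)
    if n0 == 0 or nt == 0:
        raise ValueError("cannot match empty record lists")
    mismatch = abs(n0 - nt) / max(n0, nt)
    if mismatch > tolerance:
        raise ValueError(
            f"droplet count mismatch {n0} vs {nt} exceeds tolerance "
            f"{tolerance:.0%}: possible coalescence or loss, run flagged"
        )
    warned = n0 != nt
    if warned:
        logger.warning("droplet count mismatch %d vs %d: truncating to %d pairs",
                       n0, nt, min(n0, nt))
    n = min(n0, nt)
    return (
        day0_records.iloc[:n].reset_index(drop=True),
        dayt_records.iloc[:n].reset_index(drop=True),
        warned,
    )


def assign_concentrations(
    records: pd.DataFrame, program: FlowProgram, plan: ScreeningPlan
) -> pd.DataFrame:
    """Annotate ordered droplet records with their scheduled concentrations.

    Record ``i`` (in day-0 order) receives the concentration of scheduled
    droplet ``i``; more records than scheduled droplets is an error.
    """
    schedule = droplet_schedule(program, plan)
    if len(records) > len(schedule):
        raise ValueError(
            f"{len(records)} records exceed the {len(schedule)} scheduled droplets"
        )
    ann_cols = [c for c in schedule.columns if c.startswith(("conc_", "pct_"))]
    out = records.reset_index(drop=True).copy()
    for c in ann_cols:
        out[c] = schedule[c].to_numpy()[: len(out)]
    return out


def nfu_table(
    day0_records: pd.DataFrame,
    dayt_records: pd.DataFrame,
    channel: str = DEFAULT_NFU_CHANNEL,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
) -> tuple[pd.DataFrame, int]:
    """Per-droplet NFU between two matched days.

    Returns the matched day-0 table with an ``nfu`` column, plus the number
    of droplets excluded for an undefined readout (I_t0 <= 0).
    """
    d0, dt, _ = match_days(day0_records, dayt_records, tolerance)
    i0 = d0[channel].to_numpy(dtype=float)
    it = dt[channel].to_numpy(dtype=float)
    values = nfu(it, i0)
    values = np.where(i0 <= 0, np.nan, values)
    n_excluded = int(np.isnan(values).sum())
    if n_excluded:
        logger.warning("excluded %d droplet(s) with undefined NFU (I_t0 <= 0)",
                       n_excluded)
    out = d0.copy()
    out["nfu"] = values
    return out, n_excluded


def _bin_stats(values: np.ndarray) -> tuple[float, float, int]:
    values = values[~np.isnan(values)]
    n = values.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def bin_1d(
    annotated: pd.DataFrame,
    plan: ScreeningPlan,
    n_bins: int = DEFAULT_N_BINS,
    value_col: str = "nfu",
) -> pd.DataFrame:
    """Dose-response curve: equal-width percent-of-max bins over [0, 100].

    Bins are left-closed/right-open with the last bin closed; per bin the
    mean, SD (n-1 denominator) and droplet count of ``value_col`` are
    reported, with bin edges in both percent and mM of the effector.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(annotated) == 0:
        raise ValueError("no records to bin")
    eff = plan.effectors[0]
    pct = annotated[f"pct_{eff.name}"].to_numpy(dtype=float)
    values = annotated[value_col].to_numpy(dtype=float)
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    idx = np.clip(np.digitize(pct, edges, right=False) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mean, sd, n = _bin_stats(values[idx == b])
        rows.append(
            {
                "bin_lo_pct": edges[b],
                "bin_hi_pct": edges[b + 1],
                "conc_lo_mM": edges[b] / 100.0 * eff.max_final_mM,
                "conc_hi_mM": edges[b + 1] / 100.0 * eff.max_final_mM,
                f"mean_{value_col}": mean,
                f"sd_{value_col}": sd,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def grid_2d(
    annotated: pd.DataFrame,
    plan: ScreeningPlan,
    value_col: str = "nfu",
    atol_pct: float = 1e-6,
) -> pd.DataFrame:
    """Response matrix: group droplets by exact 2D grid cell.

    Every program combination appears in the output (long format); cells
    without droplets are reported with n = 0 and NaN mean, never as zero
    response. Annotations off the program grid raise.
    """
    if len(annotated) == 0:
        raise ValueError("no records to grid")
    eff_a, eff_b = plan.effectors
    levels = (
        np.linspace(0.0, 100.0, plan.n_steps) if plan.n_steps > 1 else np.array([0.0])
    )
    pa = annotated[f"pct_{eff_a.name}"].to_numpy(dtype=float)
    pb = annotated[f"pct_{eff_b.name}"].to_numpy(dtype=float)
    ia = np.argmin(np.abs(pa[:, None] - levels[None, :]), axis=1)
    ib = np.argmin(np.abs(pb[:, None] - levels[None, :]), axis=1)
    if (np.abs(pa - levels[ia]) > atol_pct).any() or (
        np.abs(pb - levels[ib]) > atol_pct
    ).any():
        raise ValueError("annotation off the program grid")
    values = annotated[value_col].to_numpy(dtype=float)
    rows = []
    for i, la in enumerate(levels):
        for j, lb in enumerate(levels):
            mean, sd, n = _bin_stats(values[(ia == i) & (ib == j)])
            rows.append(
                {
                    f"pct_{eff_a.name}": la,
                    f"pct_{eff_b.name}": lb,
                    f"conc_{eff_a.name}_mM": la / 100.0 * eff_a.max_final_mM,
                    f"conc_{eff_b.name}_mM": lb / 100.0 * eff_b.max_final_mM,
                    f"mean_{value_col}": mean,
                    f"sd_{value_col}": sd,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def growth_curves(
    records_by_day: dict[int, pd.DataFrame],
    channel: str = DEFAULT_NFU_CHANNEL,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
) -> pd.DataFrame:
    """Per-day mean/SD/n of NFU relative to the earliest measured day."""
    if len(records_by_day) < 2:
        raise ValueError("growth curves need at least two measured days")
    days = sorted(records_by_day)
    day0 = records_by_day[days[0]]
    rows = []
    for day in days:
        table, _ = nfu_table(day0, records_by_day[day], channel, tolerance)
        mean, sd, n = _bin_stats(table["nfu"].to_numpy(dtype=float))
        rows.append({"day": day, "mean_nfu": mean, "sd_nfu": sd, "n": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OptimumSummary:
    """Concentration range maximizing the mean response, per effector."""

    effector: str
    conc_lo_mM: float
    conc_hi_mM: float
    pct_lo: float
    pct_hi: float
    peak_mean: float
    plateau_fraction: float
    at_lower_boundary: bool
    at_upper_boundary: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _plateau_range(means: np.ndarray, plateau_fraction: float) -> tuple[int, int]:
    """Contiguous index run around the argmax whose mean stays within
    ``plateau_fraction`` of the maximum. NaN bins break the plateau."""
    finite = np.where(np.isnan(means), -np.inf, means)
    k = int(np.argmax(finite))
    vmax = finite[k]
    thr = vmax - plateau_fraction * abs(vmax)
    lo = k
    while lo > 0 and finite[lo - 1] >= thr:
        lo -= 1
    hi = k
    while hi < len(means) - 1 and finite[hi + 1] >= thr:
        hi += 1
    return lo, hi


def find_optimum(
    curve: pd.DataFrame,
    plan: ScreeningPlan,
    plateau_fraction: float = DEFAULT_PLATEAU_FRACTION,
    value_col: str = "nfu",
) -> OptimumSummary:
    """Optimum of a 1D dose-response curve as a plateau range.

    The reported range spans the contiguous bins around the best bin whose
    mean response is within ``plateau_fraction`` of the maximum; a range
    ending at a boundary bin flags that the true optimum may lie outside
    the tested interval.
    """
    means = curve[f"mean_{value_col}"].to_numpy(dtype=float)
    if np.isnan(means).all():
        raise ValueError("all bins are empty")
    lo, hi = _plateau_range(means, plateau_fraction)
    eff = plan.effectors[0]
    return OptimumSummary(
        effector=eff.name,
        conc_lo_mM=float(curve["conc_lo_mM"].iloc[lo]),
        conc_hi_mM=float(curve["conc_hi_mM"].iloc[hi]),
        pct_lo=float(curve["bin_lo_pct"].iloc[lo]),
        pct_hi=float(curve["bin_hi_pct"].iloc[hi]),
        peak_mean=float(np.nanmax(means)),
        plateau_fraction=plateau_fraction,
        at_lower_boundary=lo == 0,
        at_upper_boundary=hi == len(means) - 1,
    )


def find_optimum_2d(
    matrix: pd.DataFrame,
    plan: ScreeningPlan,
    plateau_fraction: float = DEFAULT_PLATEAU_FRACTION,
    value_col: str = "nfu",
) -> list[OptimumSummary]:
    """Optimum of a 2D response matrix: the argmax cell plus its plateau
    neighborhood, reported as one concentration range per effector."""
    eff_a, eff_b = plan.effectors
    mean_col = f"mean_{value_col}"
    means = matrix[mean_col].to_numpy(dtype=float)
    if np.isnan(means).all():
        raise ValueError("all cells are empty")
    vmax = np.nanmax(means)
    thr = vmax - plateau_fraction * abs(vmax)
    plateau = matrix[matrix[mean_col] >= thr]
    out = []
    for eff in (eff_a, eff_b):
        pcts = plateau[f"pct_{eff.name}"].to_numpy(dtype=float)
        lo_pct, hi_pct = float(pcts.min()), float(pcts.max())
        out.append(
            OptimumSummary(
                effector=eff.name,
                conc_lo_mM=lo_pct / 100.0 * eff.max_final_mM,
                conc_hi_mM=hi_pct / 100.0 * eff.max_final_mM,
                pct_lo=lo_pct,
                pct_hi=hi_pct,
                peak_mean=float(vmax),
                plateau_fraction=plateau_fraction,
                at_lower_boundary=lo_pct == 0.0,
                at_upper_boundary=hi_pct == 100.0,
            )
        )
    return out


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def np_ratio(nitrate_mM: float, phosphate_mM: float) -> tuple[float, str]:
    """Molar N:P ratio of a medium, rounded to two significant figures.

    Returns the rounded ratio and its conventional "R:1" rendering, e.g.
    BG-11 (17.6 mM NaNO3, 0.175 mM K2HPO4) -> (100.0, "100:1").
    """
    if phosphate_mM <= 0:
        raise ValueError("phosphate concentration must be positive")
    if nitrate_mM < 0:
        raise ValueError("nitrate concentration must be non-negative")
    r = _round_sig(nitrate_mM / phosphate_mM, 2)
    text = f"{int(r)}:1" if float(r).is_integer() else f"{r:g}:1"
    return r, text


def compare_endpoints(group_a, group_b) -> tuple[float, float]:
    """Percent increase of group B over group A plus a two-sided
    independent-sample Student's t-test p-value (alpha convention 0.05)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    mean_a, mean_b = a.mean(), b.mean()
    if mean_a == 0:
        raise ValueError("group A mean is zero: percent increase undefined")
    increase = 100.0 * (mean_b - mean_a) / mean_a
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate variance: identical groups are indistinguishable
        return float(increase), 1.0 if mean_a == mean_b else 0.0
    t = stats.ttest_ind(a, b, equal_var=True)
    return float(increase), float(t.pvalue)
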