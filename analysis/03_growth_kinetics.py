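#!/usr/bin/env python
"""Droplet growth kinetics of three synthetic strain archetypes.

Simulates 50-droplet sequences in plain medium (no gradient) for a
slow-growing strain and two fast growers with different lag phases,
measures them daily through the detection pipeline, and writes the
per-day NFU growth curves to results/growth_curves.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from dropscreen.droplet_detection import analyze_trace, records_to_frame
from dropscreen.gradient_design import design_1d_program
from dropscreen.presets import default_optics, nitrate_1d_plan
from dropscreen.screening_analysis import growth_curves
from dropscreen.synthetic_trace import GrowthParams, simulate_run

OUT = Path(__file__).resolve().parent.parent / "results"

STRAINS = {
    # archetypes: (max rate /day, lag days) — one slow model strain and two
    # fast growers, one with a pronounced lag
    "slow_grower": GrowthParams(max_rate_per_day=0.7, lag_days=0.5),
    "fast_grower": GrowthParams(max_rate_per_day=1.6, lag_days=0.3),
    "fast_grower_lagged": GrowthParams(max_rate_per_day=1.6, lag_days=1.5),
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    plan = nitrate_1d_plan(n_droplets=50)
    program = design_1d_program(plan)
    all_curves = []
    for name, params in STRAINS.items():
        _, traces = simulate_run(
            plan, program, params, default_optics(),
            seed=args.seed, measure_days=tuple(range(8)),
        )
        records = {
            day: records_to_frame(analyze_trace(tr)[1], tr.sampling_rate_hz)
            for day, tr in traces.items()
        }
        curve = growth_curves(records)
        curve.insert(0, "strain", name)
        all_curves.append(curve)
    df = pd.concat(all_curves, ignore_index=True)
    df.to_csv(OUT / "growth_curves.csv", index=False)

    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    final = df[df["day"] == 7].set_index("strain")["mean_nfu"]
    print(
        f"\nDay-7 NFU: slow {final['slow_grower']:.1f} vs fast "
        f"{final['fast_grower']:.1f}; the lagged fast grower ends at "
        f"{final['fast_grower_lagged']:.1f} (lag delays, but does not cap, growth)."
    )


if __name__ == "__main__":
    main()
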