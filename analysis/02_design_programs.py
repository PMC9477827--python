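#!/usr/bin/env python
"""Design the standard 1D and 2D syringe-pump flow programs.

Writes the 1D nitrate ramp (440 droplets, 0-50 mM) and the 11x11 N x P step
grid as CSV flow tables, and verifies flow conservation (total 200 uL/min)
on a dense time grid.
"""

from pathlib import Path

import numpy as np

from dropscreen.gradient_design import (
    design_1d_program,
    design_2d_program,
    droplet_schedule,
)
from dropscreen.presets import nitrate_1d_plan, np_2d_plan

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    plan_1d = nitrate_1d_plan()
    program_1d = design_1d_program(plan_1d)
    program_1d.to_csv(OUT / "program_1d.csv")

    plan_2d = np_2d_plan()
    program_2d = design_2d_program(plan_2d)
    program_2d.to_csv(OUT / "program_2d.csv")

    for label, plan, program in (
        ("1D", plan_1d, program_1d),
        ("2D", plan_2d, program_2d),
    ):
        worst = max(
            abs(sum(program.flow_at(t).values()) - plan.total_flow_ul_min)
            for t in np.linspace(0, program.duration_min, 1001)
        )
        sched = droplet_schedule(program, plan)
        print(
            f"{label}: {len(sched)} droplets over {program.duration_min:.2f} min "
            f"at {plan.droplet_rate_per_min:.0f} droplets/min; "
            f"max |total flow - {plan.total_flow_ul_min:g}| = {worst:.1e} uL/min"
        )
    combos = program_2d.metadata["combinations"]
    print(f"2D grid: {len(combos)} concentration combinations "
          f"({program_2d.metadata['ordering']})")
    print(f"flow tables written to {OUT}/program_1d.csv and program_2d.csv")


if __name__ == "__main__":
    main()
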