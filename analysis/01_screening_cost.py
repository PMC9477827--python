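#!/usr/bin/env python
"""Multiplexing capacity: droplet screens versus 96-well microtiter plates.

Computes the material cost of 1% resolution 1D and 2D screens as droplet
trains (0.2 uL/droplet) and as the equivalent number of 200 uL MTP wells,
and writes the comparison to results/screening_cost.csv.
"""

from pathlib import Path

import pandas as pd

from dropscreen.gradient_design import estimate_screening_cost

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    scenarios = [
        ("1D, 1% resolution, 10 droplets/step", 1, 1.0, 10),
        ("2D, 1% resolution, 1 droplet/step", 2, 1.0, 1),
        ("2D, 10% resolution, 8 droplets/step", 2, 10.0, 8),
    ]
    rows = []
    for label, dim, res, dps in scenarios:
        est = estimate_screening_cost(dim, res, droplets_per_step=dps)
        rows.append({"scenario": label, **est.to_dict()})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "screening_cost.csv", index=False)

    print(df[["scenario", "n_steps", "n_droplets", "microfluidic_volume_ul",
              "mtp_volume_ml", "mtp_plates"]].to_string(index=False))
    one_d, two_d = df.iloc[0], df.iloc[1]
    print(
        f"\nA 1% 1D screen needs {one_d.n_droplets:.0f} droplets "
        f"({one_d.microfluidic_volume_ul:.0f} uL of medium) against "
        f"{one_d.mtp_volume_ml:.0f} mL in {one_d.mtp_plates:.0f} MTPs — "
        f"a {one_d.mtp_volume_ml * 1000 / one_d.microfluidic_volume_ul:.0f}x "
        "volume reduction."
    )
    print(
        f"A 1% 2D screen needs {two_d.n_steps:.0f} steps: "
        f"{two_d.microfluidic_volume_ul / 1000:.0f} mL in droplets vs "
        f"{two_d.mtp_volume_ml / 1000:.0f} L across {two_d.mtp_plates:.0f} MTPs."
    )


if __name__ == "__main__":
    main()
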