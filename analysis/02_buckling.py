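#!/usr/bin/env python
"""Euler buckling loads of the candidate shuttles and the design space.

Computes critical loads for the study's shuttles (1.5 mm long, fixed-pinned
tip) and shows how strongly the answer depends on the tip boundary
condition; then sweeps rectangle thickness over the fabricable 5-52 µm range
to map the attainable buckling-load envelope.

Writes results/buckling_loads.csv and results/thickness_sweep.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from shuttlesim.buckling import (
    BoundaryCondition,
    ShuttleBeam,
    buckling_load,
    design_space_sweep,
)
from shuttlesim.geometry import RectangularSection, SILICON, TBeamSection, UNCD

RESULTS = Path(__file__).resolve().parents[1] / "results"
LENGTH_MM = 1.5

SHUTTLES = {
    "T-UNCD": (TBeamSection(65, 11, 27.5, 16, 2), UNCD),
    "P-UNCD": (RectangularSection(65, 11), UNCD),
    "Si-15": (RectangularSection(65, 15), SILICON),
    "Si-50": (RectangularSection(65, 50), SILICON),
}
CONDITIONS = ["fixed-pinned", "fixed-guided", "fixed-free"]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, (sec, mat) in SHUTTLES.items():
        row = {"name": name, "length_mm": LENGTH_MM}
        for cond in CONDITIONS:
            beam = ShuttleBeam(sec, mat, LENGTH_MM, BoundaryCondition.named(cond))
            row[f"P_cr_mN_{cond}"] = buckling_load(beam)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "buckling_loads.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.1f}"))

    ratio = (2 / 0.699) ** 2
    print(
        f"\nMoving the tip boundary condition from fixed-pinned to the "
        f"worst-case fixed-free divides every load by {ratio:.1f}: a shuttle "
        f"sized for the pinned case needs ~8x the stiffness to survive "
        f"slipping tips on curved peripheral targets."
    )

    sweep = design_space_sweep(
        lambda h: RectangularSection(65.0, h),
        np.linspace(5.0, 52.0, 48),
        SILICON,
        LENGTH_MM,
        BoundaryCondition.named("fixed-pinned"),
    )
    sweep.to_csv(RESULTS / "thickness_sweep.csv", index=False)
    lo, hi = sweep.P_cr_mN.iloc[0], sweep.P_cr_mN.iloc[-1]
    print(
        f"\nSilicon rectangles 5-52 µm thick (65 µm wide, {LENGTH_MM} mm, "
        f"fixed-pinned) span buckling loads {lo:.1f} to {hi:.0f} mN "
        f"(the h³ law: ratio {(hi / lo):.0f} = (52/5)³)."
    )


if __name__ == "__main__":
    main()
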