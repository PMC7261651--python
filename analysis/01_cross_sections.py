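#!/usr/bin/env python
"""Cross-section geometry of the candidate shuttles.

Tabulates area, centroid depth and second moment of area for the probe
cross-sections considered in the study -- the diamond T-beam, the planar
diamond, and the 15/34/50 µm silicon rectangles -- and answers two design
questions: how thick must a silicon rectangle be to match the T-beam's
bending stiffness, and how much cross-sectional area does the T-beam save
against that equally stiff rectangle?

Writes results/cross_sections.csv and results/tbeam_contour.csv.
"""

from pathlib import Path

import pandas as pd

from shuttlesim.geometry import (
    RectangularSection,
    SILICON,
    TBeamSection,
    UNCD,
    area_reduction_percent,
    contour_to_csv,
    equivalent_rect_thickness,
    make_contour,
    second_moment,
    section_area,
    section_centroid_depth,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"

SECTIONS = {
    "T-UNCD": (TBeamSection(65, 11, 27.5, 16, 2), UNCD),
    "P-UNCD": (RectangularSection(65, 11), UNCD),
    "Si-15": (RectangularSection(65, 15), SILICON),
    "Si-34": (RectangularSection(65, 34), SILICON),
    "Si-50": (RectangularSection(65, 50), SILICON),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, (sec, mat) in SECTIONS.items():
        rows.append(
            {
                "name": name,
                "material": mat.name,
                "E_GPa": mat.youngs_modulus_gpa,
                "area_um2": section_area(sec),
                "centroid_depth_um": section_centroid_depth(sec),
                "I_um4": second_moment(sec),
                "EI_GPa_um4": mat.youngs_modulus_gpa * second_moment(sec),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "cross_sections.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

    tbeam, uncd = SECTIONS["T-UNCD"]
    contour_to_csv(make_contour(tbeam), RESULTS / "tbeam_contour.csv")

    ei = uncd.youngs_modulus_gpa * second_moment(tbeam)
    h_eq = equivalent_rect_thickness(ei, 65.0, SILICON)
    print(
        f"\nA silicon rectangle (65 µm wide, E = {SILICON.youngs_modulus_gpa} GPa) "
        f"matching the T-beam's EI must be {h_eq:.1f} µm thick."
    )
    red34 = area_reduction_percent(tbeam, RectangularSection(65, 34))
    red50 = area_reduction_percent(tbeam, RectangularSection(65, 50))
    print(
        f"Against the 65x34 µm rectangle of matched buckling strength the "
        f"T-beam carries {red34:.1f}% less area; against a 65x50 µm "
        f"commercial-scale probe, {red50:.1f}% less."
    )


if __name__ == "__main__":
    main()
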