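"""Euler buckling of shuttle beams.

The dominant mechanical failure mode of a slender insertion shuttle is
elastic buckling: once the axial insertion force exceeds the critical load

    P_cr = pi^2 * E * I / (K * L)^2

the shank deflects without bound and fractures.  E is the Young's modulus,
I the second moment of area of the cross-section, L the free length, and K
the effective-length factor set by the boundary condition at the tip:

    fixed-pinned  K = 0.699   tip pinned to stationary tissue (the textbook
                              assumption for rodent brain insertions)
    fixed-guided  K = 1       tip pinned but the tissue itself translates
    fixed-free    K = 2       tip slips on the surface (steep contact angle,
                              curved nerve or ganglion, dull tip)

Boundary-condition sensitivity is the central design lesson: a shuttle sized
for fixed-pinned conditions is (2/0.699)^2 ~ 8.2x too compliant for the
worst case, so peripheral-nerve designs should budget for fixed-free.

Internal unit discipline: E in GPa, I in um^4, L in mm, P_cr in mN.  The
conversion is exact: GPa * um^4 / um^2 = 1e9 N/m^2 * 1e-12 m^2 = mN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .geometry import CrossSection, Material, second_moment, section_area

__all__ = [
    "BoundaryCondition",
    "K_FACTORS",
    "k_factor",
    "ShuttleBeam",
    "buckling_load",
    "design_space_sweep",
    "worst_case_required_load",
]

#: Effective-length factors for the three generic insertion boundary conditions.
K_FACTORS = {
    "fixed-pinned": 0.699,
    "fixed-guided": 1.0,
    "fixed-free": 2.0,
}


@dataclass(frozen=True)
class BoundaryCondition:
    """A named boundary condition with its effective-length factor K."""

    name: str
    K: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise ValueError(f"effective-length factor must be positive, got {self.K}")

    @classmethod
    def named(cls, name: str) -> "BoundaryCondition":
        return cls(name, k_factor(name))


def k_factor(condition_name: str) -> float:
    """Effective-length factor K for a named boundary condition."""
    try:
        return K_FACTORS[condition_name]
    except KeyError:
        raise ValueError(
            f"unknown boundary condition {condition_name!r}; "
            f"known: {sorted(K_FACTORS)}"
        ) from None


@dataclass(frozen=True)
class ShuttleBeam:
    """A shuttle as a column: cross-section, material, length and boundary."""

    section: CrossSection
    material: Material
    length_mm: float
    boundary: BoundaryCondition

    def __post_init__(self) -> None:
        if not self.length_mm > 0:
            raise ValueError(f"beam length must be positive, got {self.length_mm}")


def buckling_load(beam: ShuttleBeam) -> float:
    """Euler critical load P_cr in mN.

    P_cr = pi^2 E I / (K L)^2 with I taken about the horizontal centroidal
    axis of the cross-section (bending in the insertion-depth direction).
    """
    e_gpa = beam.material.youngs_modulus_gpa
    i_um4 = second_moment(beam.section)
    kl_um = beam.boundary.K * beam.length_mm * 1000.0
    return float(np.pi ** 2 * e_gpa * i_um4 / kl_um ** 2)


def design_space_sweep(
    section_family: Callable[[float], CrossSection],
    thicknesses_um: Iterable[float],
    material: Material,
    length_mm: float,
    boundary: BoundaryCondition,
) -> pd.DataFrame:
    """Sweep a thickness-parametrised section family.

    ``section_family`` maps a thickness (µm) to a section; each row of the
    returned frame holds (thickness_um, area_um2, I_um4, P_cr_mN).  Thickness
    grid must be strictly increasing and non-empty; P_cr is then strictly
    increasing within any family whose I grows with thickness.
    """
    th = np.asarray(list(thicknesses_um), dtype=float)
    if th.size == 0:
        raise ValueError("empty thickness range")
    if th.size > 1 and not np.all(np.diff(th) > 0):
        raise ValueError("thickness grid must be strictly increasing")
    rows = []
    for t in th:
        sec = section_family(float(t))
        rows.append(
            {
                "thickness_um": float(t),
                "area_um2": section_area(sec),
                "I_um4": second_moment(sec),
                "P_cr_mN": buckling_load(
                    ShuttleBeam(sec, material, length_mm, boundary)
                ),
            }
        )
    return pd.DataFrame(rows)


def worst_case_required_load(
    required_load_mn: float, design_k: float = K_FACTORS["fixed-pinned"],
    worst_k: float = K_FACTORS["fixed-free"],
) -> float:
    """Scale a required buckling load to a worse boundary condition.

    Convenience derived from the Euler scaling P_cr ∝ 1/K²: a structure that
    must carry ``required_load_mn`` under the design boundary condition needs
    (worst_k/design_k)² times that capacity to survive the worst case.  With
    the defaults this is the ~8.2x "design for fixed-free" margin.
    """
    if required_load_mn < 0:
        raise ValueError("required load must be non-negative")
    return required_load_mn * (worst_k / design_k) ** 2
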