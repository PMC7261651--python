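"""Parametric probe-shuttle cross-sections.

A shuttle cross-section is either a plain rectangle (a conventional planar
probe, width ``b`` by thickness ``h``) or a T-beam: a planar rectangle with a
trapezoidal vertical fin hanging centred beneath it.  The fin raises the
second moment of area -- and hence the Euler buckling load -- at a small cost
in added cross-sectional area, which is the whole design argument for the
T-shaped shuttle.

Coordinate convention (used consistently by the damage simulator as well):
the section lives in a 2-D plane with ``x`` lateral and ``y`` pointing *down*
into the tissue (depth-positive-down), origin at the top-left corner of the
planar portion.  All lengths are micrometres; unit conversions happen only at
I/O boundaries.

Closed-form area, centroid and second moment are provided for both section
types, together with an independent polygon-integration oracle
(:func:`polygon_second_moment`) based on the exact shoelace-type vertex sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "Material",
    "SILICON",
    "UNCD",
    "RectangularSection",
    "TBeamSection",
    "CrossSection",
    "SectionPolygon",
    "make_contour",
    "section_area",
    "section_centroid_depth",
    "second_moment",
    "polygon_area",
    "polygon_centroid",
    "polygon_second_moment",
    "equivalent_rect_thickness",
    "area_reduction_percent",
    "section_from_config",
    "load_geometry_config",
    "contour_to_csv",
]


@dataclass(frozen=True)
class Material:
    """An isotropic elastic material characterised by its Young's modulus.

    Parameters
    ----------
    name : str
        Human-readable label, carried through result tables.
    youngs_modulus_gpa : float
        Young's modulus E in GPa.  Must be positive.
    """

    name: str
    youngs_modulus_gpa: float

    def __post_init__(self) -> None:
        if not self.youngs_modulus_gpa > 0:
            raise ValueError(
                f"Young's modulus must be positive, got {self.youngs_modulus_gpa}"
            )


#: Single-crystal silicon along <110>, the common value for micromachined probes.
#: Configurable -- pass your own :class:`Material` wherever one is accepted.
SILICON = Material("silicon", 169.0)

#: Ultrananocrystalline diamond; modulus estimated from buckling-load fits of
#: fabricated shuttles (literature range 800-1000 GPa).
UNCD = Material("UNCD", 800.0)


@dataclass(frozen=True)
class RectangularSection:
    """Rectangular cross-section, width ``b`` (lateral) by thickness ``h`` (depth)."""

    width_um: float
    thickness_um: float

    def __post_init__(self) -> None:
        if not (self.width_um > 0 and self.thickness_um > 0):
            raise ValueError(
                f"rectangle dimensions must be positive, got "
                f"b={self.width_um}, h={self.thickness_um}"
            )


@dataclass(frozen=True)
class TBeamSection:
    """T-shaped cross-section: planar rectangle + centred trapezoidal fin below.

    The fin is ``fin_depth_um`` deep, ``fin_top_width_um`` wide where it joins
    the planar portion and tapers to ``fin_tip_width_um`` at the free tip.
    """

    planar_width_um: float
    planar_thickness_um: float
    fin_depth_um: float
    fin_top_width_um: float
    fin_tip_width_um: float

    def __post_init__(self) -> None:
        if not (
            self.planar_width_um > 0
            and self.planar_thickness_um > 0
            and self.fin_depth_um > 0
            and self.fin_top_width_um > 0
        ):
            raise ValueError("T-beam dimensions must be positive")
        if self.fin_tip_width_um < 0:
            raise ValueError("fin tip width must be non-negative")
        if self.fin_top_width_um > self.planar_width_um:
            raise ValueError("fin top width cannot exceed planar width")
        if self.fin_tip_width_um > self.fin_top_width_um:
            raise ValueError("fin must taper: tip width cannot exceed top width")


CrossSection = Union[RectangularSection, TBeamSection]


class SectionPolygon:
    """A closed simple polygon in the section plane (µm, y depth-positive-down).

    Vertices are stored *without* repeating the first vertex; closure is
    implicit.  The polygon must be simple (non-self-intersecting) and enclose
    positive area.
    """

    def __init__(self, vertices: np.ndarray) -> None:
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("polygon needs an (n>=3, 2) vertex array")
        # drop an explicitly repeated closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("polygon degenerates to fewer than 3 distinct vertices")
        self.vertices = v
        if not self.to_shapely().is_valid:
            raise ValueError("polygon is self-intersecting or otherwise invalid")
        if self.area <= 0:
            raise ValueError("polygon encloses zero area")

    def __len__(self) -> int:
        return len(self.vertices)

    def to_shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)

    @property
    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return 0.5 * float(np.sum(x * yn - xn * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area)

    @property
    def centroid(self) -> np.ndarray:
        return polygon_centroid(self)

    def translated(self, dx: float, dy: float) -> "SectionPolygon":
        return SectionPolygon(self.vertices + np.array([dx, dy]))


def section_area(section: CrossSection) -> float:
    """Exact closed-form cross-sectional area in µm²."""
    if isinstance(section, RectangularSection):
        return section.width_um * section.thickness_um
    _check_tbeam(section)
    planar = section.planar_width_um * section.planar_thickness_um
    fin = section.fin_depth_um * (section.fin_top_width_um + section.fin_tip_width_um) / 2.0
    return planar + fin


def section_centroid_depth(section: CrossSection) -> float:
    """Centroid depth (µm below the top surface).

    For a rectangle this is h/2; for a T-beam the area-weighted composite of
    the planar rectangle and the trapezoidal fin.  The trapezoid centroid sits
    h(a+2c)/(3(a+c)) below its wide edge, where a and c are the junction and
    tip widths.
    """
    if isinstance(section, RectangularSection):
        return section.thickness_um / 2.0
    _check_tbeam(section)
    a = section.fin_top_width_um
    c = section.fin_tip_width_um
    h = section.fin_depth_um
    area_p = section.planar_width_um * section.planar_thickness_um
    area_f = h * (a + c) / 2.0
    cy_p = section.planar_thickness_um / 2.0
    cy_f = section.planar_thickness_um + h * (a + 2.0 * c) / (3.0 * (a + c))
    return (area_p * cy_p + area_f * cy_f) / (area_p + area_f)


def second_moment(section: CrossSection) -> float:
    """Second moment of area I (µm⁴) about the horizontal centroidal axis.

    Bending is in the depth direction, the direction that matters for column
    buckling during insertion.  Rectangle: b·h³/12.  T-beam: composite-beam
    theory -- own-axis moments of the rectangle and trapezoid plus
    parallel-axis terms about the shared composite centroid.
    """
    if isinstance(section, RectangularSection):
        return section.width_um * section.thickness_um ** 3 / 12.0
    _check_tbeam(section)
    a = section.fin_top_width_um
    c = section.fin_tip_width_um
    h = section.fin_depth_um
    area_p = section.planar_width_um * section.planar_thickness_um
    area_f = h * (a + c) / 2.0
    cy_p = section.planar_thickness_um / 2.0
    cy_f = section.planar_thickness_um + h * (a + 2.0 * c) / (3.0 * (a + c))
    cy = (area_p * cy_p + area_f * cy_f) / (area_p + area_f)
    i_p = section.planar_width_um * section.planar_thickness_um ** 3 / 12.0
    # trapezoid about its own centroidal axis parallel to the bases
    i_f = h ** 3 * (a ** 2 + 4.0 * a * c + c ** 2) / (36.0 * (a + c))
    return i_p + area_p * (cy_p - cy) ** 2 + i_f + area_f * (cy_f - cy) ** 2


def make_contour(section: CrossSection) -> SectionPolygon:
    """Closed polygon contour of a section, origin at planar top-left, y down.

    The rectangle becomes its 4 corners; the T-beam is the union outline of
    the planar rectangle and the centred trapezoidal fin (8 vertices, or 7
    when the fin tip tapers to a point).
    """
    if isinstance(section, RectangularSection):
        b, h = section.width_um, section.thickness_um
        return SectionPolygon(np.array([[0.0, 0.0], [b, 0.0], [b, h], [0.0, h]]))
    _check_tbeam(section)
    b = section.planar_width_um
    t = section.planar_thickness_um
    d = section.fin_depth_um
    a = section.fin_top_width_um
    c = section.fin_tip_width_um
    cx = b / 2.0
    tip_y = t + d
    verts = [[0.0, 0.0], [b, 0.0], [b, t], [cx + a / 2.0, t]]
    if c > 0:
        verts += [[cx + c / 2.0, tip_y], [cx - c / 2.0, tip_y]]
    else:
        verts += [[cx, tip_y]]
    verts += [[cx - a / 2.0, t], [0.0, t]]
    poly = SectionPolygon(np.array(verts))
    assert abs(poly.area - section_area(section)) <= 1e-9 * section_area(section)
    return poly


def _check_tbeam(section: CrossSection) -> None:
    if not isinstance(section, TBeamSection):
        raise TypeError(f"unsupported section type: {type(section).__name__}")


# ---------------------------------------------------------------------------
# Polygon-integration oracle: exact vertex-sum (Green's theorem) moments.
# ---------------------------------------------------------------------------

def _cross_terms(poly: SectionPolygon):
    v = poly.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    return x, y, xn, yn, cross


def polygon_area(poly: SectionPolygon) -> float:
    """Shoelace area, orientation-independent."""
    return poly.area


def polygon_centroid(poly: SectionPolygon) -> np.ndarray:
    x, y, xn, yn, cross = _cross_terms(poly)
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def polygon_second_moment(poly: SectionPolygon) -> float:
    """Second moment of area about the polygon's own centroidal horizontal axis.

    Exact vertex-sum formula: I_x = (1/12) Σ (y_i² + y_i y_{i+1} + y_{i+1}²)
    (x_i y_{i+1} − x_{i+1} y_i) about the origin axis, then shifted to the
    centroid by the parallel-axis theorem.  Independent of vertex orientation
    and translation; used as the oracle for the closed-form section moments.
    """
    x, y, xn, yn, cross = _cross_terms(poly)
    a = 0.5 * np.sum(cross)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    i_origin = np.sum((y ** 2 + y * yn + yn ** 2) * cross) / 12.0
    # signed moments flip together with orientation; the centroidal I is |.|
    return float(abs(i_origin - a * cy ** 2))


# ---------------------------------------------------------------------------
# Design helpers
# ---------------------------------------------------------------------------

def equivalent_rect_thickness(
    target_ei_gpa_um4: float, width_um: float, material: Material
) -> float:
    """Thickness of a rectangle matching a target bending stiffness EI.

    Inverts EI = E·b·h³/12:  h = (12·EI / (E·b))^(1/3).  Used to answer "how
    thick must a silicon shuttle be to buckle at the same load as this
    T-beam?".
    """
    if target_ei_gpa_um4 <= 0 or width_um <= 0:
        raise ValueError("target EI and width must be positive")
    e = material.youngs_modulus_gpa
    return float((12.0 * target_ei_gpa_um4 / (e * width_um)) ** (1.0 / 3.0))


def area_reduction_percent(section_a: CrossSection, section_b: CrossSection) -> float:
    """Percent area reduction of ``section_a`` relative to reference ``section_b``.

    100·(1 − area(a)/area(b)).  Positive when a is the smaller section.
    """
    area_b = section_area(section_b)
    if area_b <= 0:
        raise ValueError("reference section has zero area")
    return 100.0 * (1.0 - section_area(section_a) / area_b)


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def section_from_config(cfg: dict) -> tuple[CrossSection, Material | None]:
    """Build a section (and optional material) from a config mapping.

    Expected keys: ``type: rect|tbeam``; dimension fields in µm matching the
    dataclass field names (the ``_um`` suffix may be omitted); optionally
    ``material: {name, E_GPa}``.
    """
    kind = cfg.get("type")
    if kind not in ("rect", "tbeam"):
        raise ValueError(f"unknown section type {kind!r}; expected 'rect' or 'tbeam'")

    def grab(key: str) -> float:
        for k in (key, key.removesuffix("_um")):
            if k in cfg:
                return float(cfg[k])
        raise KeyError(f"geometry config missing field {key!r}")

    if kind == "rect":
        section: CrossSection = RectangularSection(grab("width_um"), grab("thickness_um"))
    else:
        section = TBeamSection(
            grab("planar_width_um"),
            grab("planar_thickness_um"),
            grab("fin_depth_um"),
            grab("fin_top_width_um"),
            grab("fin_tip_width_um"),
        )
    material = None
    if "material" in cfg:
        m = cfg["material"]
        material = Material(m.get("name", "unnamed"), float(m["E_GPa"]))
    return section, material


def load_geometry_config(path: str | Path) -> tuple[CrossSection, Material | None]:
    """Load a YAML/JSON geometry config file (YAML is a JSON superset)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return section_from_config(cfg)


def contour_to_csv(poly: SectionPolygon, path: str | Path) -> None:
    """Export a contour as a two-column CSV vertex list for plotting."""
    np.savetxt(path, poly.vertices, delimiter=",", header="x_um,y_um", comments="")
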