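"""3-D microvascular networks: file I/O, projection, statistics, synthesis.

The damage model treats the cortical microvasculature as a collection of
straight vessel segments (endpoint coordinates plus a diameter).  Real data
come as piecewise-straight segments between branch/sample nodes -- each
straight piece is an independent damage unit.  Because probe insertion is
vertical and straight, the 3-D network is orthographically projected onto the
horizontal plane before counting transections.

Two file paths are supported:

* a canonical CSV (``id, x0, y0, z0, x1, y1, z1, diameter_um``), the lossless
  round-trip format, and
* a structured node/segment text format as published for rat-brain network
  reconstructions: header lines, then a segment block (count line, then one
  record per segment: name, type, from-node, to-node, diameter, ...), then a
  node block (count line, then name, x, y, z per node).  The column layout is
  declarative (:class:`NetworkDialect`) so dialect drift fails loudly instead
  of silently corrupting coordinates.

The synthetic generator produces the statistical structure the damage model
assumes: segment midpoints homogeneously Poisson in a box, isotropic
orientations, i.i.d. lengths and diameters -- a Boolean model of sticks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VesselSegment",
    "VascularNetwork",
    "Projected2DSegment",
    "NetworkDialect",
    "SynthNetworkConfig",
    "NetworkStats",
    "read_network",
    "write_network",
    "project_to_plane",
    "network_stats",
    "generate_synthetic",
]


@dataclass(frozen=True)
class VesselSegment:
    """A straight vessel segment: endpoints (µm) and diameter (µm)."""

    id: int
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    diameter_um: float

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError(f"segment {self.id}: diameter must be positive")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))

    @property
    def is_zero_length(self) -> bool:
        """Degenerate segment (p0 == p1); flagged, never silently dropped."""
        return self.length_um == 0.0

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.p0) + np.asarray(self.p1)) / 2.0


@dataclass
class VascularNetwork:
    """A set of vessel segments with an axis-aligned bounding box (µm).

    ``bounding_box`` is tight around all endpoints.  ``domain_box``, when
    set (synthetic networks), is the generation domain in which segment
    midpoints were placed; statistics use it as the reference volume so that
    sticks poking beyond the domain do not bias the length density.
    """

    segments: list[VesselSegment]
    bounding_box: np.ndarray  # shape (2, 3): [[xmin,ymin,zmin],[xmax,ymax,zmax]]
    source: str = "unknown"
    domain_box: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(ids) != len(set(ids)):
            raise ValueError("segment ids must be unique")
        self.bounding_box = np.asarray(self.bounding_box, dtype=float)
        if self.segments:
            pts = np.array([p for s in self.segments for p in (s.p0, s.p1)])
            if (pts < self.bounding_box[0] - 1e-9).any() or (
                pts > self.bounding_box[1] + 1e-9
            ).any():
                raise ValueError("bounding box does not contain all endpoints")

    @classmethod
    def from_segments(
        cls, segments: list[VesselSegment], source: str = "unknown"
    ) -> "VascularNetwork":
        if segments:
            pts = np.array([p for s in segments for p in (s.p0, s.p1)])
            bbox = np.vstack([pts.min(axis=0), pts.max(axis=0)])
        else:
            bbox = np.zeros((2, 3))
        return cls(segments, bbox, source)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class Projected2DSegment:
    """A vessel segment after orthographic projection along the insertion axis."""

    id: int
    q0: tuple[float, float]
    q1: tuple[float, float]
    diameter_um: float

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.subtract(self.q1, self.q0)))

    @property
    def is_degenerate(self) -> bool:
        """Segment was parallel to the insertion axis; projects to a point."""
        return self.length_um == 0.0


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", "x0", "y0", "z0", "x1", "y1", "z1", "diameter_um"]


@dataclass(frozen=True)
class NetworkDialect:
    """Declarative layout of a structured node/segment network text file.

    ``header_lines`` may be None, in which case the reader scans for the
    first line whose first token is a positive integer and which is followed
    by a plausible segment record (>= 5 whitespace tokens).  Column indices
    are zero-based positions within a whitespace-split record.
    """

    header_lines: int | None = None
    comment_chars: str = "#%"
    seg_name_col: int = 0
    seg_type_col: int = 1
    seg_from_col: int = 2
    seg_to_col: int = 3
    seg_diameter_col: int = 4
    node_name_col: int = 0
    node_x_col: int = 1
    node_y_col: int = 2
    node_z_col: int = 3
    coord_scale: float = 1.0  # multiply coordinates into µm


def read_network(
    path: str | Path, dialect: str | NetworkDialect = "csv"
) -> VascularNetwork:
    """Read a network file.

    ``dialect`` is ``"csv"`` for the canonical CSV, ``"nodes-segments"`` (or a
    :class:`NetworkDialect` instance) for the structured text format.
    Malformed files raise ``ValueError`` naming the first offending line.
    """
    path = Path(path)
    if isinstance(dialect, str) and dialect == "csv":
        return _read_csv(path)
    if isinstance(dialect, str):
        if dialect != "nodes-segments":
            raise ValueError(f"unknown dialect {dialect!r}")
        dialect = NetworkDialect()
    return _read_nodes_segments(path, dialect)


def _read_csv(path: Path) -> VascularNetwork:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty network file") from None
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (line 1)")
    segments = [
        VesselSegment(
            int(r.id),
            (r.x0, r.y0, r.z0),
            (r.x1, r.y1, r.z1),
            float(r.diameter_um),
        )
        for r in df.itertuples()
    ]
    _warn_zero_length(segments, str(path))
    return VascularNetwork.from_segments(segments, source=f"file:{path.name}")


def _read_nodes_segments(path: Path, d: NetworkDialect) -> VascularNetwork:
    lines = path.read_text().splitlines()
    rows = [
        (i + 1, ln.strip())
        for i, ln in enumerate(lines)
        if ln.strip() and ln.strip()[0] not in d.comment_chars
    ]
    if not rows:
        raise ValueError(f"{path}: empty network file")

    pos = 0
    if d.header_lines is not None:
        pos = d.header_lines
        if pos >= len(rows):
            raise ValueError(f"{path}: file ends inside declared header")
    else:
        # heuristic: first count line followed by a plausible segment record
        while pos < len(rows):
            lineno, text = rows[pos]
            tok = text.split()
            if (
                tok[0].lstrip("+").isdigit()
                and int(tok[0]) > 0
                and pos + 1 < len(rows)
                and len(rows[pos + 1][1].split()) > max(
                    d.seg_to_col, d.seg_diameter_col
                )
            ):
                break
            pos += 1
        if pos >= len(rows):
            raise ValueError(f"{path}: no segment-count line found")

    def read_count(p: int, what: str) -> int:
        if p >= len(rows):
            raise ValueError(f"{path}: file ends before {what} count")
        lineno, text = rows[p]
        tok = text.split()[0]
        try:
            return int(tok)
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: expected {what} count, got {text!r}"
            ) from None

    n_seg = read_count(pos, "segment")
    pos += 1
    raw_segments = []
    for k in range(n_seg):
        if pos + k >= len(rows):
            raise ValueError(f"{path}: file ends inside segment block")
        lineno, text = rows[pos + k]
        tok = text.split()
        try:
            raw_segments.append(
                (
                    int(float(tok[d.seg_name_col])),
                    int(float(tok[d.seg_from_col])),
                    int(float(tok[d.seg_to_col])),
                    float(tok[d.seg_diameter_col]),
                )
            )
        except (IndexError, ValueError):
            raise ValueError(f"{path}: line {lineno}: malformed segment record") from None
    pos += n_seg

    n_nod = read_count(pos, "node")
    pos += 1
    nodes: dict[int, tuple[float, float, float]] = {}
    for k in range(n_nod):
        if pos + k >= len(rows):
            raise ValueError(f"{path}: file ends inside node block")
        lineno, text = rows[pos + k]
        tok = text.split()
        try:
            nodes[int(float(tok[d.node_name_col]))] = (
                float(tok[d.node_x_col]) * d.coord_scale,
                float(tok[d.node_y_col]) * d.coord_scale,
                float(tok[d.node_z_col]) * d.coord_scale,
            )
        except (IndexError, ValueError):
            raise ValueError(f"{path}: line {lineno}: malformed node record") from None

    segments = []
    for sid, nfrom, nto, diam in raw_segments:
        if nfrom not in nodes or nto not in nodes:
            raise ValueError(
                f"{path}: segment {sid} references unknown node "
                f"{nfrom if nfrom not in nodes else nto}"
            )
        segments.append(VesselSegment(sid, nodes[nfrom], nodes[nto], diam))
    _warn_zero_length(segments, str(path))
    return VascularNetwork.from_segments(segments, source=f"file:{path.name}")


def _warn_zero_length(segments: list[VesselSegment], where: str) -> None:
    n_zero = sum(s.is_zero_length for s in segments)
    if n_zero:
        warnings.warn(
            f"{where}: {n_zero} zero-length segment(s) retained and flagged",
            stacklevel=3,
        )


def write_network(net: VascularNetwork, path: str | Path) -> None:
    """Write the canonical CSV (lossless round-trip to 1e-6 µm and better)."""
    df = pd.DataFrame(
        [
            {
                "id": s.id,
                "x0": s.p0[0], "y0": s.p0[1], "z0": s.p0[2],
                "x1": s.p1[0], "y1": s.p1[1], "z1": s.p1[2],
                "diameter_um": s.diameter_um,
            }
            for s in net.segments
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Projection and statistics
# ---------------------------------------------------------------------------

_AXIS = {"x": 0, "y": 1, "z": 2}


def project_to_plane(
    net: VascularNetwork, insertion_axis: str = "z"
) -> list[Projected2DSegment]:
    """Orthographic projection dropping the insertion-axis coordinate.

    Diameters are unchanged.  Segments parallel to the insertion axis project
    to points; they are retained and flagged (``is_degenerate``), since a
    vertical vessel under a footprint is still at risk.
    """
    try:
        drop = _AXIS[insertion_axis]
    except KeyError:
        raise ValueError(f"insertion axis must be one of x, y, z, got {insertion_axis!r}")
    keep = [i for i in range(3) if i != drop]
    out = []
    for s in net.segments:
        q0 = (s.p0[keep[0]], s.p0[keep[1]])
        q1 = (s.p1[keep[0]], s.p1[keep[1]])
        out.append(Projected2DSegment(s.id, q0, q1, s.diameter_um))
    return out


@dataclass(frozen=True)
class NetworkStats:
    n_segments: int
    n_zero_length: int
    total_length_um: float
    box_volume_um3: float
    length_density_um_per_um3: float
    diameter_quantiles_um: dict[str, float] = field(default_factory=dict)
    mean_segment_length_um: float = 0.0


def network_stats(net: VascularNetwork) -> NetworkStats:
    """Descriptive statistics: counts, total length, length density, diameters.

    Length density is total vessel length divided by bounding-box volume
    (µm/µm³, numerically µm⁻²).  An empty network yields zeros with a warning.
    """
    if not net.segments:
        warnings.warn("network is empty; statistics are all zero", stacklevel=2)
        return NetworkStats(0, 0, 0.0, 0.0, 0.0, {}, 0.0)
    lengths = np.array([s.length_um for s in net.segments])
    diams = np.array([s.diameter_um for s in net.segments])
    box = net.domain_box if net.domain_box is not None else net.bounding_box
    extent = np.asarray(box)[1] - np.asarray(box)[0]
    volume = float(np.prod(extent))
    total = float(lengths.sum())
    qs = np.quantile(diams, [0.05, 0.25, 0.5, 0.75, 0.95])
    return NetworkStats(
        n_segments=len(net.segments),
        n_zero_length=int(sum(s.is_zero_length for s in net.segments)),
        total_length_um=total,
        box_volume_um3=volume,
        length_density_um_per_um3=total / volume if volume > 0 else 0.0,
        diameter_quantiles_um={
            "q05": float(qs[0]), "q25": float(qs[1]), "q50": float(qs[2]),
            "q75": float(qs[3]), "q95": float(qs[4]),
        },
        mean_segment_length_um=float(lengths.mean()),
    )


# ---------------------------------------------------------------------------
# Synthetic networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynthNetworkConfig:
    """Configuration of the synthetic stick-process network.

    ``box_um`` is the (x, y, z) extent of the field in which segment
    *midpoints* are placed (homogeneous Poisson); endpoints may extend
    slightly beyond it, and the resulting network's bounding box covers them.
    ``length_density_um_per_um3`` is the target total vessel length per unit
    volume of that box.  Distributions are ``(name, params)`` pairs with
    ``name`` in {lognormal, constant, uniform}: lognormal takes
    ``{median, sigma}`` (sigma in log space), uniform takes ``{low, high}``,
    constant takes ``{value}``.
    """

    box_um: tuple[float, float, float] = (500.0, 500.0, 500.0)
    length_density_um_per_um3: float = 1.0e-4
    segment_length_dist: tuple[str, dict] = (
        "lognormal", {"median": 60.0, "sigma": 0.6}
    )
    diameter_dist: tuple[str, dict] = ("lognormal", {"median": 6.0, "sigma": 0.4})
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(e > 0 for e in self.box_um):
            raise ValueError("box extents must be positive")
        if not self.length_density_um_per_um3 > 0:
            raise ValueError("length density must be positive")


def _dist_mean(name: str, params: dict) -> float:
    if name == "lognormal":
        return params["median"] * float(np.exp(params["sigma"] ** 2 / 2.0))
    if name == "constant":
        return params["value"]
    if name == "uniform":
        return (params["low"] + params["high"]) / 2.0
    raise ValueError(f"unknown distribution {name!r}")


def _dist_sample(name: str, params: dict, rng: np.random.Generator, n: int):
    if name == "lognormal":
        if params["median"] <= 0 or params["sigma"] <= 0:
            raise ValueError("lognormal params must be positive")
        return rng.lognormal(np.log(params["median"]), params["sigma"], n)
    if name == "constant":
        if params["value"] <= 0:
            raise ValueError("constant value must be positive")
        return np.full(n, float(params["value"]))
    if name == "uniform":
        if params["low"] <= 0 or params["high"] < params["low"]:
            raise ValueError("uniform params must satisfy 0 < low <= high")
        return rng.uniform(params["low"], params["high"], n)
    raise ValueError(f"unknown distribution {name!r}")


def generate_synthetic(cfg: SynthNetworkConfig) -> VascularNetwork:
    """Generate a Boolean stick-process network, reproducible from the seed.

    The segment count is Poisson with mean rho*V / E[length] so that the
    expected total length equals the configured density times the box volume.
    Orientations are isotropic on the sphere (uniform cos(polar angle)).
    """
    rng = np.random.default_rng(cfg.seed)
    box = np.asarray(cfg.box_um)
    volume = float(np.prod(box))
    lname, lparams = cfg.segment_length_dist
    dname, dparams = cfg.diameter_dist
    mean_len = _dist_mean(lname, lparams)
    n = int(rng.poisson(cfg.length_density_um_per_um3 * volume / mean_len))
    domain = np.vstack([np.zeros(3), box])
    if n == 0:
        return VascularNetwork(
            [], domain, source=f"synthetic(seed={cfg.seed})", domain_box=domain
        )
    mid = rng.uniform(0.0, 1.0, (n, 3)) * box
    lengths = _dist_sample(lname, lparams, rng, n)
    diams = _dist_sample(dname, dparams, rng, n)
    # isotropic directions: uniform azimuth, uniform cos(theta)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    cos_t = rng.uniform(-1.0, 1.0, n)
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    u = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    half = (lengths / 2.0)[:, None] * u
    p0s, p1s = mid - half, mid + half
    segments = [
        VesselSegment(i, tuple(p0s[i]), tuple(p1s[i]), float(diams[i]))
        for i in range(n)
    ]
    net = VascularNetwork.from_segments(segments, source=f"synthetic(seed={cfg.seed})")
    net.domain_box = domain
    return net
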