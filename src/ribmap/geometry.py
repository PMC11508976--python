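"""Standard thorax template and arc-length parameterization of rib centerlines.

Every rib is represented by an ordered 3D polyline running from the
costovertebral joint (the posterior landmark, 0 % of arc length) to the
costochondral junction (anterior, 100 %).  Fracture positions expressed as a
percentage of rib length map onto 3D template coordinates through this
parameterization, and 3D points map back to percentages for round-trip
validation and coordinate import.

The built-in template is parametric: 24 planar-ish elliptical arcs whose radii,
span and droop vary smoothly with rib index.  It stands in for a patient-derived
healthy-adult rib model; real centerlines can be supplied as an ordered-vertex
CSV or a polyline PLY.  Floating ribs (11-12) have no costochondral junction,
so their distal tip plays the role of the 100 % landmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Side = Literal["left", "right"]

SIDES: tuple[Side, Side] = ("left", "right")
RIB_INDICES: tuple[int, ...] = tuple(range(1, 13))

#: Aliases accepted wherever a side is read from user input.
SIDE_ALIASES = {
    "left": "left", "l": "left", "lt": "left",
    "right": "right", "r": "right", "rt": "right",
}


def normalize_side(value: str) -> Side:
    """Map a user-supplied side label (``left``/``L``/``r`` ...) to the enum."""
    key = str(value).strip().lower()
    if key not in SIDE_ALIASES:
        raise ValueError(f"unrecognized side {value!r}; expected left/right (or L/R)")
    return SIDE_ALIASES[key]  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Arc length and the RibCurve container
# ---------------------------------------------------------------------------

def arc_length(vertices: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Total polyline length (mm): the sum of Euclidean segment lengths.

    This is the package's realization of an along-the-bone distance: fracture
    positions are 1D fractions of rib length, so a centerline polyline carries
    all the information the mapping needs.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
        raise ValueError("arc_length requires an (n, 3) array with n >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("vertices contain non-finite coordinates")
    return float(np.linalg.norm(np.diff(v, axis=0), axis=1).sum())


@dataclass(frozen=True)
class RibCurve:
    """Ordered centerline polyline of one rib, arc-length parameterized.

    The first vertex is the costovertebral landmark (0 %), the last vertex the
    costochondral landmark (100 %).  ``cumulative_length`` is strictly
    increasing; consecutive duplicate vertices are rejected.
    """

    rib_index: int
    side: Side
    vertices: np.ndarray
    cumulative_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rib_index not in RIB_INDICES:
            raise ValueError(f"rib_index must be 1-12, got {self.rib_index}")
        if self.side not in SIDES:
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 2:
            raise ValueError("a rib curve needs at least 2 vertices of shape (n, 3)")
        if not np.all(np.isfinite(v)):
            raise ValueError("rib curve vertices contain non-finite coordinates")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive duplicate vertices are not allowed")
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "cumulative_length", cum)

    @property
    def length(self) -> float:
        """Total arc length (mm)."""
        return float(self.cumulative_length[-1])

    def vertex_percents(self) -> np.ndarray:
        """Arc-length percentage of every vertex (0 at the spine end)."""
        return 100.0 * self.cumulative_length / self.length


def point_at_percent(curve: RibCurve, p: float) -> np.ndarray:
    """3D point at arc-length fraction ``p``/100 from the costovertebral end.

    Linear interpolation within the containing segment; ``p`` must lie in
    [0, 100].
    """
    if not (0.0 <= p <= 100.0):
        raise ValueError(f"percent position must be in [0, 100], got {p}")
    target = p / 100.0 * curve.length
    cum = curve.cumulative_length
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, len(cum) - 2)
    seg = cum[i + 1] - cum[i]
    t = (target - cum[i]) / seg
    return (1.0 - t) * curve.vertices[i] + t * curve.vertices[i + 1]


def percent_at_point(curve: RibCurve, point: Sequence[float], tol: float = 10.0) -> float:
    """Arc-length percentage of the on-curve point nearest to ``point``.

    The inverse of :func:`point_at_percent` for points on (or near) the curve;
    used for round-trip validation and for importing fracture sites given as
    coordinates.  Raises if the point is farther than ``tol`` mm from the
    curve.
    """
    p = np.asarray(point, dtype=float)
    v0 = curve.vertices[:-1]
    d = np.diff(curve.vertices, axis=0)
    seg_len2 = np.einsum("ij,ij->i", d, d)
    t = np.clip(np.einsum("ij,ij->i", p - v0, d) / seg_len2, 0.0, 1.0)
    closest = v0 + t[:, None] * d
    dist = np.linalg.norm(closest - p, axis=1)
    i = int(np.argmin(dist))
    if dist[i] > tol:
        raise ValueError(
            f"point is {dist[i]:.2f} mm from the curve (tolerance {tol} mm)"
        )
    arc = curve.cumulative_length[i] + t[i] * math.sqrt(seg_len2[i])
    return float(100.0 * arc / curve.length)


# ---------------------------------------------------------------------------
# Thorax template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThoraxTemplate:
    """24 rib centerline curves: exactly one per (rib_index, side) pair."""

    curves: tuple[RibCurve, ...]
    metadata: str = "unspecified"

    def __post_init__(self) -> None:
        keys = [(c.rib_index, c.side) for c in self.curves]
        expected = {(r, s) for r in RIB_INDICES for s in SIDES}
        if len(keys) != 24 or set(keys) != expected or len(set(keys)) != 24:
            raise ValueError(
                "a thorax template needs exactly one curve per (rib, side), 24 total"
            )

    def get(self, rib_index: int, side: Side) -> RibCurve:
        for c in self.curves:
            if c.rib_index == rib_index and c.side == side:
                return c
        raise KeyError((rib_index, side))

    def side_curves(self, side: Side) -> list[RibCurve]:
        return [c for c in self.curves if c.side == side]


@dataclass(frozen=True)
class TemplateConfig:
    """Shape parameters for the parametric template.

    scale multiplies every linear dimension of each rib curve (half-axes and
    droop), so arc lengths scale linearly with it; rib_spacing is the vertical
    offset between consecutive ribs and does not affect per-curve length.
    """

    n_vertices: int = 100
    scale: float = 1.0
    rib_spacing: float = 25.0

    def __post_init__(self) -> None:
        if self.n_vertices < 2:
            raise ValueError("n_vertices must be >= 2")
        for name in ("scale", "rib_spacing"):
            val = getattr(self, name)
            if not (np.isfinite(val) and val > 0):
                raise ValueError(f"{name} must be finite and positive, got {val}")


def _rib_shape(rib_index: int) -> tuple[float, float, float, float, float]:
    """Smoothly varying (half_width, half_depth, theta_start, theta_end, droop)."""
    t = (rib_index - 1) / 11.0
    a = 60.0 + 75.0 * math.sin(math.pi * (0.10 + 0.75 * t))  # lateral half-axis, mm
    b = 0.72 * a                                             # antero-posterior half-axis
    theta0 = 0.12 * math.pi
    # floating ribs (11-12) sweep a shorter arc and end at the rib tip
    short = max(0.0, (rib_index - 10) / 2.0)
    theta1 = math.pi * (0.85 - 0.25 * short)
    droop = 20.0 + 15.0 * t                                  # inferior slope along the arc
    return a, b, theta0, theta1, droop


def build_default_template(config: TemplateConfig | None = None) -> ThoraxTemplate:
    """Parametric 24-curve standard thorax: elliptical arcs, deterministic.

    Each curve sweeps from a posterior paraspinal point to an anterior
    parasternal point; span angle, radii and droop vary smoothly with rib
    index.  Identical configs produce identical vertex arrays.
    """
    cfg = config or TemplateConfig()
    curves: list[RibCurve] = []
    for rib in RIB_INDICES:
        a, b, theta0, theta1, droop = _rib_shape(rib)
        a *= cfg.scale
        b *= cfg.scale
        droop *= cfg.scale
        theta = np.linspace(theta0, theta1, cfg.n_vertices)
        frac = (theta - theta0) / (theta1 - theta0)
        z0 = -cfg.rib_spacing * (rib - 1)
        for side in SIDES:
            sgn = -1.0 if side == "left" else 1.0
            x = sgn * a * np.sin(theta)
            y = -b * np.cos(theta)
            z = z0 - droop * frac
            curves.append(RibCurve(rib, side, np.column_stack([x, y, z])))
    return ThoraxTemplate(tuple(curves), metadata=f"parametric(scale={cfg.scale})")


def mirror_template(template: ThoraxTemplate) -> ThoraxTemplate:
    """Reflect the template across the sagittal plane (left and right swap)."""
    mirrored = []
    for c in template.curves:
        v = c.vertices.copy()
        v[:, 0] = -v[:, 0]
        other: Side = "left" if c.side == "right" else "right"
        mirrored.append(RibCurve(c.rib_index, other, v))
    return ThoraxTemplate(tuple(mirrored), metadata=template.metadata + "+mirrored")


# ---------------------------------------------------------------------------
# Template I/O: ordered-vertex CSV and polyline PLY
# ---------------------------------------------------------------------------

def template_to_csv(template: ThoraxTemplate, path: str | Path) -> None:
    """Write curves as an ordered-vertex CSV (rib,side,x,y,z; row order = curve order)."""
    rows = []
    for c in template.curves:
        for v in c.vertices:
            rows.append((c.rib_index, c.side, v[0], v[1], v[2]))
    pd.DataFrame(rows, columns=["rib", "side", "x", "y", "z"]).to_csv(path, index=False)


def template_from_csv(path: str | Path, metadata: str | None = None) -> ThoraxTemplate:
    """Read a template from the ordered-vertex CSV schema written by template_to_csv."""
    df = pd.read_csv(path)
    required = {"rib", "side", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"template CSV needs columns {sorted(required)}")
    curves = []
    df["side"] = df["side"].map(normalize_side)
    for (rib, side), grp in df.groupby(["rib", "side"], sort=False):
        curves.append(RibCurve(int(rib), side, grp[["x", "y", "z"]].to_numpy(float)))
    return ThoraxTemplate(tuple(curves), metadata=metadata or str(path))


def template_to_ply(template: ThoraxTemplate, path: str | Path) -> None:
    """Write centerlines as an ASCII PLY with vertex + edge elements.

    Each rib polyline is a run of consecutive edges; per-vertex ``rib`` and
    ``side`` properties (side encoded 0 = left, 1 = right) make the file
    self-describing.  trimesh does not round-trip edge-element PLY, hence this
    small dedicated writer.
    """
    verts: list[tuple[float, float, float, int, int]] = []
    edges: list[tuple[int, int]] = []
    for c in template.curves:
        base = len(verts)
        s = 0 if c.side == "left" else 1
        for v in c.vertices:
            verts.append((v[0], v[1], v[2], c.rib_index, s))
        edges.extend((base + i, base + i + 1) for i in range(len(c.vertices) - 1))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment {template.metadata}\n")
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar rib\nproperty uchar side\n")
        fh.write(f"element edge {len(edges)}\n")
        fh.write("property int vertex1\nproperty int vertex2\nend_header\n")
        for x, y, z, rib, s in verts:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f} {rib} {s}\n")
        for e1, e2 in edges:
            fh.write(f"{e1} {e2}\n")


def template_from_ply(path: str | Path) -> ThoraxTemplate:
    """Read a polyline PLY written by :func:`template_to_ply`."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    if not lines or lines[0] != "ply":
        raise ValueError("not a PLY file")
    n_vertex = n_edge = 0
    metadata = "ply import"
    i = 1
    while lines[i] != "end_header":
        parts = lines[i].split()
        if parts[0] == "element" and parts[1] == "vertex":
            n_vertex = int(parts[2])
        elif parts[0] == "element" and parts[1] == "edge":
            n_edge = int(parts[2])
        elif parts[0] == "comment":
            metadata = " ".join(parts[1:])
        i += 1
    body = lines[i + 1:]
    vdata = np.array([[float(x) for x in body[j].split()] for j in range(n_vertex)])
    # edges are implied consecutive within each (rib, side) run; the vertex
    # properties alone reconstruct the curves
    curves = []
    ribs = vdata[:, 3].astype(int)
    sides = vdata[:, 4].astype(int)
    start = 0
    for j in range(1, n_vertex + 1):
        if j == n_vertex or ribs[j] != ribs[start] or sides[j] != sides[start]:
            side: Side = "left" if sides[start] == 0 else "right"
            curves.append(RibCurve(int(ribs[start]), side, vdata[start:j, :3]))
            start = j
    if n_edge != n_vertex - len(curves):
        raise ValueError("edge count inconsistent with per-rib polyline runs")
    return ThoraxTemplate(tuple(curves), metadata=metadata)


# ---------------------------------------------------------------------------
# Tube sweep (shared by the heat-map painter and STL export)
# ---------------------------------------------------------------------------

def tube_mesh(curve: RibCurve, radius: float = 4.0, n_sides: int = 16):
    """Sweep a circle along the centerline -> (vertices, faces, vertex_percent).

    Uses parallel-transport frames so the tube does not twist.  Every tube
    vertex inherits the arc-length percentage of its centerline vertex, which
    is how 1D positional data transfers onto the 3D surface.
    """
    pts = curve.vertices
    n = len(pts)
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # initial normal: any vector not parallel to the first tangent
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    normal = np.cross(tangents[0], ref)
    normal /= np.linalg.norm(normal)
    angles = np.linspace(0.0, 2.0 * np.pi, n_sides, endpoint=False)
    rings = np.empty((n, n_sides, 3))
    for i in range(n):
        if i > 0:  # transport the normal to the new tangent
            normal = normal - np.dot(normal, tangents[i]) * tangents[i]
            normal /= np.linalg.norm(normal)
        binormal = np.cross(tangents[i], normal)
        rings[i] = (
            pts[i]
            + radius * np.cos(angles)[:, None] * normal
            + radius * np.sin(angles)[:, None] * binormal
        )
    verts = rings.reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        for k in range(n_sides):
            a = i * n_sides + k
            b = i * n_sides + (k + 1) % n_sides
            c = (i + 1) * n_sides + k
            d = (i + 1) * n_sides + (k + 1) % n_sides
            faces.append((a, b, d))
            faces.append((a, d, c))
    percent = np.repeat(curve.vertex_percents(), n_sides)
    return verts, np.asarray(faces, dtype=np.int64), percent
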