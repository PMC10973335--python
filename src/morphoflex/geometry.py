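"""Chain-of-vesicles domain construction and triangulation.

The early embryonic head is modelled as a row of hollow circular cavities
(brain vesicles) embedded in a thin tissue shell, separated by solid
columns (the contractile cell belts in the inter-vesicle valleys) and
clamped at the neck end.  The chain axis is x: x increases posteriorly
toward the clamped neck, y increases dorsally, so ventral (forward)
bending moves the free anterior end toward negative y.

The mesh is an unstructured triangulation built from explicitly placed
boundary vertices (cavity circles, exterior offset arcs, bridge segments
over the columns, a flat clamp face) and a hexagonal lattice of interior
points, connected by Delaunay triangulation and filtered to the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "GeometryConfigError",
    "GeometryConfig",
    "Mesh2D",
    "build_chain",
    "mesh_quality",
    "cavity_label",
    "EXTERIOR_DORSAL",
    "EXTERIOR_VENTRAL",
    "CLAMP",
]

def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the cross product of stacked 2D vectors."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


EXTERIOR_DORSAL = "exterior_dorsal"
EXTERIOR_VENTRAL = "exterior_ventral"
CLAMP = "clamp"


def cavity_label(i: int) -> str:
    """Boundary label of the i-th cavity (anterior = 0)."""
    return f"cavity_{i}"


class GeometryConfigError(ValueError):
    """Raised when a geometry configuration violates its invariants."""


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the vesicle-chain domain (dimensionless lengths).

    The cavity radius R sets the length unit (R = 1 by default).  The
    shell is thin relative to R and the mesh resolves it with at least
    two elements across its thickness.
    """

    n_vesicles: int = 1
    cavity_radius: float = 1.0
    shell_thickness: float = 0.1
    column_width: float = 0.2
    target_edge_length: float = 0.05

    def __post_init__(self) -> None:
        if not isinstance(self.n_vesicles, (int, np.integer)) or isinstance(
            self.n_vesicles, bool
        ):
            raise GeometryConfigError("n_vesicles must be an integer")
        if not 1 <= self.n_vesicles <= 10:
            raise GeometryConfigError(
                f"n_vesicles must be in 1..10, got {self.n_vesicles}"
            )
        for name in ("cavity_radius", "shell_thickness", "column_width",
                     "target_edge_length"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise GeometryConfigError(f"{name} must be positive, got {v}")
        if self.shell_thickness >= self.cavity_radius:
            raise GeometryConfigError(
                "shell_thickness must be smaller than cavity_radius"
            )
        if self.target_edge_length >= self.shell_thickness:
            raise GeometryConfigError(
                "target_edge_length must be smaller than shell_thickness"
            )

    @property
    def spacing(self) -> float:
        """Center-to-center distance of adjacent cavities."""
        return 2.0 * self.cavity_radius + self.column_width

    @property
    def centers(self) -> np.ndarray:
        """Cavity centers on the chain axis, anterior to posterior."""
        return np.stack(
            [np.arange(self.n_vesicles) * self.spacing,
             np.zeros(self.n_vesicles)], axis=1
        )


@dataclass
class Mesh2D:
    """Triangulated vesicle-chain domain with labelled boundary loops.

    ``boundary_loops`` maps a label to an ordered vertex-index sequence:
    cavity loops are closed (first vertex repeats implicitly), the
    exterior dorsal/ventral chains and the clamp face are open chains.
    Cavity loops are oriented counterclockwise (cavity to the left of
    travel).  ``boundary_edges`` is derived from the loops.
    """

    vertices: np.ndarray            # (N, 2) float
    triangles: np.ndarray           # (M, 3) int, counterclockwise
    boundary_loops: Dict[str, np.ndarray] = field(default_factory=dict)

    # -- derived -----------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cavities(self) -> int:
        return sum(1 for k in self.boundary_loops if k.startswith("cavity_"))

    def cavity_labels(self) -> List[str]:
        return [cavity_label(i) for i in range(self.n_cavities)]

    def loop_is_closed(self, label: str) -> bool:
        return label.startswith("cavity_")

    def boundary_edges(self, label: str) -> np.ndarray:
        """Edges (vertex-index pairs) of one labelled boundary chain."""
        loop = self.boundary_loops[label]
        if self.loop_is_closed(label):
            return np.stack([loop, np.roll(loop, -1)], axis=1)
        return np.stack([loop[:-1], loop[1:]], axis=1)

    def all_boundary_edges(self) -> Dict[str, np.ndarray]:
        return {lab: self.boundary_edges(lab) for lab in self.boundary_loops}

    def signed_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])

    def boundary_vertex_indices(self) -> np.ndarray:
        idx = np.concatenate([v for v in self.boundary_loops.values()])
        return np.unique(idx)

    def copy(self) -> "Mesh2D":
        return Mesh2D(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            boundary_loops={k: v.copy() for k, v in self.boundary_loops.items()},
        )

    def validate(self) -> None:
        areas = self.signed_areas()
        if np.any(areas <= 0):
            raise ValueError(
                f"{int(np.sum(areas <= 0))} triangles are inverted or degenerate"
            )
        if self.n_cavities == 0:
            raise ValueError("mesh has no cavity loops")
        if CLAMP not in self.boundary_loops:
            raise ValueError("mesh has no clamp chain")


@dataclass
class QualityReport:
    min_angle_deg: float
    min_area: float
    inverted_count: int
    n_triangles: int


def mesh_quality(mesh: Mesh2D) -> QualityReport:
    """Per-triangle quality statistics (angles, areas, inversions)."""
    if mesh.triangles is None or len(mesh.triangles) == 0:
        raise ValueError("mesh has no triangles")
    p = mesh.vertices[mesh.triangles]          # (M, 3, 2)
    areas = mesh.signed_areas()
    # interior angles from edge vectors at each corner
    angles = np.empty((len(mesh.triangles), 3))
    for k in range(3):
        a = p[:, (k + 1) % 3] - p[:, k]
        b = p[:, (k + 2) % 3] - p[:, k]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        angles[:, k] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return QualityReport(
        min_angle_deg=float(angles.min()),
        min_area=float(areas.min()),
        inverted_count=int(np.sum(areas <= 0)),
        n_triangles=len(mesh.triangles),
    )


# ---------------------------------------------------------------------------
# boundary polyline construction
# ---------------------------------------------------------------------------

def _arc_points(center, radius, theta0, theta1, h, include_last=True):
    """Points along a circular arc at spacing ~h (theta in radians)."""
    span = abs(theta1 - theta0)
    n = max(2, int(round(span * radius / h)) + 1)
    t = np.linspace(theta0, theta1, n)
    if not include_last:
        t = t[:-1]
    return np.stack([center[0] + radius * np.cos(t),
                     center[1] + radius * np.sin(t)], axis=1)


def _segment_points(p0, p1, h, include_last=True):
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(2, int(round(np.linalg.norm(p1 - p0) / h)) + 1)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = p0 * (1 - t) + p1 * t
    return pts if include_last else pts[:-1]


def _chain_geometry(cfg: GeometryConfig):
    """Analytic description of the outer boundary and clamp cut."""
    R = cfg.cavity_radius
    t = cfg.shell_thickness
    Ro = R + t
    centers = cfg.centers[:, 0]
    # bridge (valley floor) height: outer circle height above the point
    # where the cavity ends, so adjacent offset circles join the flat
    # bridge without a gap
    h_bridge = np.sqrt(Ro**2 - R**2)
    theta_b = np.arccos(R / Ro)          # junction angle on outer circles
    x_clamp = centers[-1] + R + 0.5 * t  # flat neck face location
    cos_c = (x_clamp - centers[-1]) / Ro
    theta_c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    y_clamp = Ro * np.sin(theta_c)
    return centers, Ro, h_bridge, theta_b, x_clamp, theta_c, y_clamp


def _dorsal_chain(cfg: GeometryConfig) -> np.ndarray:
    """Exterior dorsal polyline from the anterior apex to the clamp top."""
    centers, Ro, hb, th_b, x_clamp, th_c, _ = _chain_geometry(cfg)
    h = cfg.target_edge_length
    n = cfg.n_vesicles
    parts = []
    for i, cx in enumerate(centers):
        th_start = np.pi if i == 0 else np.pi - th_b
        th_end = th_c if i == n - 1 else th_b
        parts.append(_arc_points((cx, 0.0), Ro, th_start, th_end, h,
                                 include_last=True))
        if i < n - 1:
            # flat valley floor over the column, endpoints shared with arcs
            p0 = parts[-1][-1]
            p1 = np.array([centers[i + 1] - cfg.cavity_radius, hb])
            seg = _segment_points(p0, p1, h, include_last=True)
            parts[-1] = parts[-1][:-1]   # dedupe junction vertex
            parts.append(seg)
    pts = np.concatenate(parts, axis=0)
    # drop duplicated junction points between consecutive parts
    keep = np.ones(len(pts), bool)
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep[1:] = d > 1e-12
    return pts[keep]


def build_chain(config: GeometryConfig) -> Mesh2D:
    """Build the triangulated vesicle-chain domain.

    Cavities are congruent circles evenly spaced on the x axis; the
    exterior is the outward offset of the cavities bridged flat over the
    inter-vesicle columns; the posterior end is cut by a vertical clamp
    face at the neck.
    """
    cfg = config
    R = cfg.cavity_radius
    h = cfg.target_edge_length
    centers, Ro, hb, th_b, x_clamp, th_c, y_clamp = _chain_geometry(cfg)

    vertices: List[np.ndarray] = []
    loops: Dict[str, np.ndarray] = {}

    def add(points: np.ndarray) -> np.ndarray:
        start = sum(len(v) for v in vertices)
        vertices.append(points)
        return np.arange(start, start + len(points))

    # cavity circles, counterclockwise, symmetric about y = 0
    for i, cx in enumerate(centers):
        m = int(round(2 * np.pi * R / h))
        m += m % 2                      # even count -> mirror symmetric
        th = 2 * np.pi * np.arange(m) / m
        pts = np.stack([cx + R * np.cos(th), R * np.sin(th)], axis=1)
        loops[cavity_label(i)] = add(pts)

    # exterior dorsal chain (anterior apex -> clamp top), ventral mirror;
    # both chains share the apex vertex at y = 0
    dorsal = _dorsal_chain(cfg)
    ventral = dorsal.copy()
    ventral[:, 1] *= -1.0
    idx_d = add(dorsal)
    idx_v_rest = add(ventral[1:])
    loops[EXTERIOR_DORSAL] = idx_d
    loops[EXTERIOR_VENTRAL] = np.concatenate([[idx_d[0]], idx_v_rest])

    # clamp face: vertical chord at x_clamp, sharing the chain end vertices
    n_cl = max(2, int(round(2 * y_clamp / h)) + 1)
    ys = np.linspace(y_clamp, -y_clamp, n_cl)[1:-1]
    clamp_mid = add(np.stack([np.full(len(ys), x_clamp), ys], axis=1))
    loops[CLAMP] = np.concatenate([[idx_d[-1]], clamp_mid,
                                   [loops[EXTERIOR_VENTRAL][-1]]])

    boundary = np.concatenate(vertices, axis=0)

    interior = _interior_points(cfg, boundary)
    all_pts = np.concatenate([boundary, interior], axis=0)

    tri = Delaunay(all_pts)
    triangles = _filter_triangles(cfg, all_pts, tri.simplices)

    mesh = Mesh2D(vertices=all_pts, triangles=triangles, boundary_loops=loops)
    _orient_ccw(mesh)
    mesh.validate()
    return mesh


def _inside_domain(cfg: GeometryConfig, pts: np.ndarray) -> np.ndarray:
    """Vectorized membership test for the tissue domain."""
    centers, Ro, hb, th_b, x_clamp, th_c, y_clamp = _chain_geometry(cfg)
    x, y = pts[:, 0], pts[:, 1]
    d2 = (x[:, None] - centers[None, :]) ** 2 + y[:, None] ** 2
    in_outer_disk = (d2 <= Ro**2).any(axis=1)
    in_cavity = (d2 <= cfg.cavity_radius**2).any(axis=1)
    in_bridge = np.zeros(len(pts), bool)
    for i in range(cfg.n_vesicles - 1):
        in_bridge |= (
            (x >= centers[i]) & (x <= centers[i + 1]) & (np.abs(y) <= hb)
        )
    return (in_outer_disk | in_bridge) & (~in_cavity) & (x <= x_clamp)


def _boundary_distance(cfg: GeometryConfig, pts: np.ndarray) -> np.ndarray:
    """Distance from points to the analytic boundary curves (lower bound)."""
    centers, Ro, hb, th_b, x_clamp, th_c, y_clamp = _chain_geometry(cfg)
    x, y = pts[:, 0], pts[:, 1]
    r = np.sqrt((x[:, None] - centers[None, :]) ** 2 + y[:, None] ** 2)
    d_cav = np.abs(r - cfg.cavity_radius).min(axis=1)
    d_outer = np.abs(r - Ro).min(axis=1)
    d_bridge = np.full(len(pts), np.inf)
    for i in range(cfg.n_vesicles - 1):
        x0 = centers[i] + cfg.cavity_radius
        x1 = centers[i + 1] - cfg.cavity_radius
        dx = np.clip(x0 - x, 0, None) + np.clip(x - x1, 0, None)
        d_seg = np.sqrt(dx**2 + (np.abs(y) - hb) ** 2)
        d_bridge = np.minimum(d_bridge, d_seg)
    d_clamp = np.where(np.abs(y) <= y_clamp, np.abs(x - x_clamp), np.inf)
    return np.minimum.reduce([d_cav, d_outer, d_bridge, d_clamp])


def _interior_points(cfg: GeometryConfig, boundary: np.ndarray) -> np.ndarray:
    """Hexagonal interior lattice, mirror-symmetric about the chain axis."""
    h = cfg.target_edge_length
    dy = h * np.sqrt(3) / 2
    lo = boundary.min(axis=0) - h
    hi = boundary.max(axis=0) + h
    jmax = int(np.ceil(hi[1] / dy))
    rows = []
    for j in range(-jmax, jmax + 1):
        yj = j * dy
        off = (abs(j) % 2) * 0.5 * h   # |j| keeps the lattice y-symmetric
        xs = np.arange(lo[0] + off, hi[0] + h, h)
        rows.append(np.stack([xs, np.full(len(xs), yj)], axis=1))
    grid = np.concatenate(rows, axis=0)
    ok = _inside_domain(cfg, grid)
    grid = grid[ok]
    ok = _boundary_distance(cfg, grid) > 0.55 * h
    return grid[ok]


def _filter_triangles(cfg: GeometryConfig, pts: np.ndarray,
                      simplices: np.ndarray) -> np.ndarray:
    cent = pts[simplices].mean(axis=1)
    keep = _inside_domain(cfg, cent)
    # drop slivers the convex hull adds across concave valleys
    p = pts[simplices]
    area = 0.5 * _cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    edge = np.maximum.reduce([
        np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
        np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
        np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
    ])
    keep &= np.abs(area) > 1e-10 * edge**2
    return simplices[keep]


def _orient_ccw(mesh: Mesh2D) -> None:
    areas = mesh.signed_areas()
    flip = areas < 0
    if np.any(flip):
        tri = mesh.triangles
        tri[flip] = tri[flip][:, [0, 2, 1]]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_vtk(mesh: Mesh2D, path) -> None:
    """Write the mesh as an ASCII legacy-VTK unstructured grid."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nmorphoflex mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y in mesh.vertices:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        m = len(mesh.triangles)
        f.write(f"CELLS {m} {4 * m}\n")
        for a, b, c in mesh.triangles:
            f.write(f"3 {a} {b} {c}\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("\n".join(["5"] * m) + "\n")


def write_csv(mesh: Mesh2D, vertices_path, triangles_path) -> None:
    """Plain CSV dump of vertices and triangle connectivity."""
    np.savetxt(vertices_path, mesh.vertices, delimiter=",",
               header="x,y", comments="")
    np.savetxt(triangles_path, mesh.triangles, fmt="%d", delimiter=",",
               header="v0,v1,v2", comments="")
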