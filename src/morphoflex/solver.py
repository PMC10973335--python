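"""Quasi-static compressible-viscous finite-element solver.

The tissue follows a viscous constitutive law relating stress to the
rate of deformation: sigma = 2*mu*dev(eps_dot) + eta*tr(eps_dot)*I,
with mu the shear viscosity and eta the dilational viscosity that lets
living tissue expand or shrink under normal stress.  Inertia is
neglected: at every step the velocity field solves static equilibrium
of this stress with the current boundary tractions (internal cavity
pressure, curvature-dependent shell tension by the Laplace law, and a
tangential apex-to-neck surface shear), with zero velocity on the
clamped neck face.  The mesh is then advected with the velocity in a
Lagrangian incremental update, so the load is always applied on the
deformed, moving boundary.

Two loading modes mirror the two experimental situations:

* ELECTRIC - stimulation raises tension in the shell and cell belts:
  effective cavity pressure P - T*kappa plus a posterior shear on the
  dorsal exterior; shrinks the vesicles and uplifts the head.
* BLOOD - increased blood flow relaxes the capillary-plexus tension
  over the vesicles: effective pressure P + T*kappa plus a posterior
  shear on the ventral exterior; dilates the vesicles and rocks the
  head forward.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import Delaunay

from .geometry import (  # noqa: F401
    CLAMP,
    _cross2,
    EXTERIOR_DORSAL,
    EXTERIOR_VENTRAL,
    GeometryConfig,
    Mesh2D,
    build_chain,
    mesh_quality,
)

__all__ = [
    "TensionMode",
    "MaterialParams",
    "LoadSpec",
    "RemeshPolicy",
    "SimulationConfig",
    "CurvatureField",
    "boundary_curvature",
    "assemble_tractions",
    "solve_step",
    "advance_mesh",
    "run_simulation",
    "StepSizeError",
]


class StepSizeError(RuntimeError):
    """Raised when a Lagrangian update would tangle the boundary;
    reduce the timestep."""


class TensionMode(str, enum.Enum):
    ELECTRIC = "electric"   # effective cavity pressure P - T*kappa
    BLOOD = "blood"         # effective cavity pressure P + T*kappa


@dataclass(frozen=True)
class MaterialParams:
    """Viscosity matrix of the tissue (dimensionless).

    shear_viscosity (mu) resists shape change, dilational_viscosity
    (eta) resists area change; both must be positive for the discrete
    operator to be coercive.
    """

    shear_viscosity: float = 1.0
    dilational_viscosity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("shear_viscosity", "dilational_viscosity"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class LoadSpec:
    """Boundary loads, all dimensionless (P = R = 1 sets the scales).

    internal_pressure P acts outward on every cavity shell.
    shell_tension T enters through the Laplace term T*kappa: it lowers
    the effective pressure in ELECTRIC mode (tensed shell) and raises
    it in BLOOD mode (pressurized capillary plexus relaxing the cover).
    dorsal_shear / ventral_shear are tangential tractions on the
    exterior surface oriented from the anterior apex toward the clamped
    neck; ELECTRIC applies the dorsal one, BLOOD the ventral one.
    """

    internal_pressure: float = 1.0
    shell_tension: float = 0.0
    tension_mode: TensionMode = TensionMode.BLOOD
    dorsal_shear: float = 5e-4
    ventral_shear: float = 5e-4

    def __post_init__(self) -> None:
        object.__setattr__(self, "tension_mode", TensionMode(self.tension_mode))
        for name in ("internal_pressure", "shell_tension",
                     "dorsal_shear", "ventral_shear"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.shell_tension < 0:
            raise ValueError("shell_tension must be >= 0")
        if self.dorsal_shear < 0 or self.ventral_shear < 0:
            raise ValueError("shear tractions must be >= 0")


@dataclass(frozen=True)
class RemeshPolicy:
    """Quality thresholds triggering interior re-triangulation."""

    min_angle_deg: float = 10.0
    min_area: float = 1e-4

    def triggered(self, mesh: Mesh2D) -> bool:
        q = mesh_quality(mesh)
        return (q.min_angle_deg < self.min_angle_deg
                or q.min_area < self.min_area)


@dataclass(frozen=True)
class SimulationConfig:
    """Full simulation setup.

    The default timestep (2e-4 dimensionless time units) sits well
    below the explicit scheme's stability limit for the default loads;
    larger steps excite a spurious flapping mode of the floppy chain.
    ``burn_in_steps`` settle the idealized initial geometry (perfectly
    circular shells with sharp valley notches creep abnormally fast
    under the surface shear) before the recorded trajectory starts;
    the reference configuration for morphometrics is the post-burn-in
    mesh.
    """

    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    material: MaterialParams = field(default_factory=MaterialParams)
    loads: Union[LoadSpec, Sequence[LoadSpec]] = field(default_factory=LoadSpec)
    timestep: float = 2e-4
    n_steps: int = 400
    burn_in_steps: int = 150
    remesh_policy: RemeshPolicy = field(default_factory=RemeshPolicy)

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be >= 0")
        if not isinstance(self.loads, LoadSpec):
            loads = tuple(self.loads)
            if len(loads) == 0:
                raise ValueError("load schedule must not be empty")
            if self.n_steps % len(loads) != 0:
                raise ValueError(
                    "schedule length must divide n_steps evenly"
                )
            object.__setattr__(self, "loads", loads)

    def load_at(self, step: int) -> LoadSpec:
        if isinstance(self.loads, LoadSpec):
            return self.loads
        per = self.n_steps // len(self.loads)
        return self.loads[min(step // per, len(self.loads) - 1)]


# ---------------------------------------------------------------------------
# boundary curvature
# ---------------------------------------------------------------------------

@dataclass
class CurvatureField:
    """Per-boundary-vertex signed curvature of one labelled loop.

    kappa > 0 where the boundary bulges outward (convex toward the
    non-tissue side), so a circular cavity of radius R has kappa = 1/R
    and the Laplace balance T = P/kappa cancels the effective load.
    """

    label: str
    vertex_indices: np.ndarray
    kappa: np.ndarray

    def on_vertex(self) -> Dict[int, float]:
        return dict(zip(self.vertex_indices.tolist(), self.kappa.tolist()))


def _circumcircle_kappa(p, v, n):
    """Unsigned curvature (1/circumradius) of each vertex triple."""
    a = np.linalg.norm(v - p, axis=1)
    b = np.linalg.norm(n - v, axis=1)
    c = np.linalg.norm(n - p, axis=1)
    cross = _cross2(v - p, n - v)
    area2 = np.abs(cross)                      # 2 * triangle area
    denom = a * b * c
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(denom > 0, 2.0 * area2 / denom, 0.0)
    return kappa, cross


def boundary_curvature(mesh: Mesh2D, loop_label: str) -> CurvatureField:
    """Pointwise curvature along one boundary loop.

    Each vertex's curvature is the reciprocal circumradius of the
    circle through the vertex and its two loop neighbours, signed by
    the local turning direction, then smoothed with a 3-point moving
    average along the loop (the raw pointwise value is noisy at mesh
    scale).
    """
    if loop_label not in mesh.boundary_loops:
        raise KeyError(f"no boundary loop labelled {loop_label!r}")
    loop = mesh.boundary_loops[loop_label]
    closed = mesh.loop_is_closed(loop_label)
    if len(loop) < 3:
        raise ValueError(f"loop {loop_label!r} has fewer than 3 vertices")
    pts = mesh.vertices[loop]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg < 1e-14):
        raise ValueError(f"duplicate consecutive vertices in {loop_label!r}")

    if closed:
        p = np.roll(pts, 1, axis=0)
        n = np.roll(pts, -1, axis=0)
        kappa, cross = _circumcircle_kappa(p, pts, n)
    else:
        kappa = np.zeros(len(pts))
        cross = np.zeros(len(pts))
        k_in, c_in = _circumcircle_kappa(pts[:-2], pts[1:-1], pts[2:])
        kappa[1:-1] = k_in
        cross[1:-1] = c_in
        kappa[0], cross[0] = kappa[1], cross[1]
        kappa[-1], cross[-1] = kappa[-2], cross[-2]

    # sign: cavity loops run counterclockwise (cavity on the left), so a
    # convex-outward bulge turns left (positive cross product); the
    # exterior chains run anterior->posterior, where a convex-outward
    # bulge turns clockwise on the dorsal side (tissue below) and
    # counterclockwise on the ventral side (tissue above).
    if loop_label == EXTERIOR_DORSAL:
        signed = np.where(cross <= 0, kappa, -kappa)
    else:
        signed = np.where(cross >= 0, kappa, -kappa)

    # 3-point moving average along the loop
    if closed:
        sm = (np.roll(signed, 1) + signed + np.roll(signed, -1)) / 3.0
    else:
        sm = signed.copy()
        sm[1:-1] = (signed[:-2] + signed[1:-1] + signed[2:]) / 3.0
    return CurvatureField(label=loop_label, vertex_indices=loop.copy(),
                          kappa=sm)


# ---------------------------------------------------------------------------
# traction assembly
# ---------------------------------------------------------------------------

@dataclass
class Tractions:
    """Per-boundary-edge traction vectors (force per unit length)."""

    edges: np.ndarray       # (E, 2) vertex indices
    vectors: np.ndarray     # (E, 2) traction
    labels: List[str]

    def scaled(self, factor: float) -> "Tractions":
        return Tractions(self.edges.copy(), self.vectors * factor,
                         list(self.labels))


def assemble_tractions(mesh: Mesh2D, loads: LoadSpec,
                       curvature: Dict[str, CurvatureField]) -> Tractions:
    """Build boundary tractions from the load specification.

    Cavity edges carry a normal traction of magnitude P - T*kappa
    (ELECTRIC) or P + T*kappa (BLOOD), kappa averaged over the edge
    endpoints, pushing the shell away from the cavity.  The exterior
    dorsal (ELECTRIC) or ventral (BLOOD) chain carries a tangential
    traction of the configured shear magnitude oriented posteriorly
    (toward the clamp).  Clamp edges carry no traction.
    """
    edges_all = []
    vecs_all = []
    labels_all: List[str] = []
    sign = -1.0 if loads.tension_mode == TensionMode.ELECTRIC else 1.0
    shear_label = (EXTERIOR_DORSAL if loads.tension_mode == TensionMode.ELECTRIC
                   else EXTERIOR_VENTRAL)
    shear_mag = (loads.dorsal_shear if loads.tension_mode == TensionMode.ELECTRIC
                 else loads.ventral_shear)

    for lab in mesh.cavity_labels():
        if lab not in curvature:
            raise ValueError(f"missing curvature for loaded loop {lab!r}")
        kv = curvature[lab].on_vertex()
        edges = mesh.boundary_edges(lab)
        p0 = mesh.vertices[edges[:, 0]]
        p1 = mesh.vertices[edges[:, 1]]
        t = p1 - p0
        L = np.linalg.norm(t, axis=1, keepdims=True)
        t = t / L
        # loop is counterclockwise around the cavity, so the cavity lies
        # to the left of travel; the pressure pushes the tissue away
        # from the cavity along the right-hand normal (ty, -tx)
        n_out = np.stack([t[:, 1], -t[:, 0]], axis=1)
        kappa_e = 0.5 * (
            np.array([kv[int(i)] for i in edges[:, 0]])
            + np.array([kv[int(i)] for i in edges[:, 1]])
        )
        p_eff = loads.internal_pressure + sign * loads.shell_tension * kappa_e
        edges_all.append(edges)
        vecs_all.append(n_out * p_eff[:, None])
        labels_all += [lab] * len(edges)

    if shear_mag > 0:
        edges = mesh.boundary_edges(shear_label)
        p0 = mesh.vertices[edges[:, 0]]
        p1 = mesh.vertices[edges[:, 1]]
        t = p1 - p0
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        # orient toward increasing x (posteriorly, toward the clamp)
        flip = t[:, 0] < 0
        t[flip] *= -1.0
        edges_all.append(edges)
        vecs_all.append(t * shear_mag)
        labels_all += [shear_label] * len(edges)

    return Tractions(
        edges=np.concatenate(edges_all, axis=0),
        vectors=np.concatenate(vecs_all, axis=0),
        labels=labels_all,
    )


# ---------------------------------------------------------------------------
# finite-element solve
# ---------------------------------------------------------------------------

def _stiffness(mesh: Mesh2D, material: MaterialParams) -> sp.csr_matrix:
    """Vectorized P1 assembly of the viscous operator.

    The constitutive matrix in Voigt form (engineering shear) is that
    of isotropic linear response with Lame-like parameters
    lambda = eta - mu, mu; positive definiteness needs mu > 0 and
    lambda + mu = eta > 0.
    """
    mu = material.shear_viscosity
    lam = material.dilational_viscosity - mu
    D = np.array([
        [lam + 2 * mu, lam, 0.0],
        [lam, lam + 2 * mu, 0.0],
        [0.0, 0.0, mu],
    ])
    tris = mesh.triangles
    p = mesh.vertices[tris]                    # (M, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]],
                 axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]],
                 axis=1)
    area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
    area = 0.5 * area2                         # signed, positive (CCW)
    inv = 1.0 / area2[:, None]
    bx = b * inv                               # d(phi_k)/dx
    by = c * inv                               # d(phi_k)/dy
    M = len(tris)
    B = np.zeros((M, 3, 6))
    B[:, 0, 0::2] = bx
    B[:, 1, 1::2] = by
    B[:, 2, 0::2] = by
    B[:, 2, 1::2] = bx
    Ke = np.einsum("mji,jk,mkl,m->mil", B, D, B, area, optimize=True)
    dof = np.empty((M, 6), dtype=np.int64)
    dof[:, 0::2] = 2 * tris
    dof[:, 1::2] = 2 * tris + 1
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(2 * mesh.n_vertices, 2 * mesh.n_vertices))
    return K.tocsr()


def _load_vector(mesh: Mesh2D, tractions: Tractions) -> np.ndarray:
    f = np.zeros(2 * mesh.n_vertices)
    p0 = mesh.vertices[tractions.edges[:, 0]]
    p1 = mesh.vertices[tractions.edges[:, 1]]
    L = np.linalg.norm(p1 - p0, axis=1)
    contrib = 0.5 * tractions.vectors * L[:, None]
    for k in range(2):
        idx = tractions.edges[:, k]
        np.add.at(f, 2 * idx, contrib[:, 0])
        np.add.at(f, 2 * idx + 1, contrib[:, 1])
    return f


def solve_step(mesh: Mesh2D, tractions: Tractions,
               material: MaterialParams) -> np.ndarray:
    """Solve one quasi-static step; returns per-vertex velocity (N, 2).

    Zero velocity is imposed on the clamp face; without it the
    quasi-static problem has rigid-body null modes and is singular.
    """
    if CLAMP not in mesh.boundary_loops or len(mesh.boundary_loops[CLAMP]) == 0:
        raise ValueError(
            "no clamp constraint: the quasi-static system is singular "
            "without a clamped neck face"
        )
    K = _stiffness(mesh, material)
    f = _load_vector(mesh, tractions)
    clamp_idx = np.unique(mesh.boundary_loops[CLAMP])
    fixed = np.zeros(2 * mesh.n_vertices, dtype=bool)
    fixed[2 * clamp_idx] = True
    fixed[2 * clamp_idx + 1] = True
    # vertices belonging to no triangle carry zero stiffness: pin them
    used = np.zeros(mesh.n_vertices, dtype=bool)
    used[np.unique(mesh.triangles)] = True
    if not used.all():
        iso = np.flatnonzero(~used)
        fixed[2 * iso] = True
        fixed[2 * iso + 1] = True
    free = ~fixed
    Kff = K[free][:, free].tocsc()
    v = np.zeros(2 * mesh.n_vertices)
    v[free] = spla.spsolve(Kff, f[free])
    if not np.all(np.isfinite(v)):
        raise RuntimeError("singular quasi-static system (solver returned NaN)")
    return v.reshape(-1, 2)


# ---------------------------------------------------------------------------
# Lagrangian update and remeshing
# ---------------------------------------------------------------------------

def _point_in_loops(points: np.ndarray, loops: List[np.ndarray]) -> np.ndarray:
    """Crossing-number test of points against each closed polygon; returns
    an (n_points, n_loops) boolean array."""
    res = np.zeros((len(points), len(loops)), dtype=bool)
    x, y = points[:, 0], points[:, 1]
    for j, poly in enumerate(loops):
        x0, y0 = poly[:, 0], poly[:, 1]
        x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
        inside = np.zeros(len(points), dtype=bool)
        for a0, b0, a1, b1 in zip(x0, y0, x1, y1):
            cond = (b0 > y) != (b1 > y)
            with np.errstate(divide="ignore", invalid="ignore"):
                xin = a0 + (y - b0) * (a1 - a0) / (b1 - b0)
            inside ^= cond & (x < xin)
        res[:, j] = inside
    return res


def _outer_loop(mesh: Mesh2D) -> np.ndarray:
    """Closed outer boundary polygon: dorsal chain, clamp, reversed ventral."""
    d = mesh.boundary_loops[EXTERIOR_DORSAL]
    c = mesh.boundary_loops[CLAMP]
    v = mesh.boundary_loops[EXTERIOR_VENTRAL]
    idx = np.concatenate([d, c[1:-1], v[::-1]])
    return mesh.vertices[idx]


def _segment_distance(points: np.ndarray, segs_p0: np.ndarray,
                      segs_p1: np.ndarray, chunk: int = 2000) -> np.ndarray:
    """Min distance from each point to a set of segments (chunked)."""
    out = np.full(len(points), np.inf)
    d = segs_p1 - segs_p0
    L2 = np.einsum("ij,ij->i", d, d)
    L2[L2 == 0] = 1e-30
    for s in range(0, len(points), chunk):
        P = points[s:s + chunk]
        w = P[:, None, :] - segs_p0[None, :, :]
        t = np.clip(np.einsum("pij,ij->pi", w, d) / L2[None, :], 0.0, 1.0)
        proj = segs_p0[None, :, :] + t[..., None] * d[None, :, :]
        dist = np.linalg.norm(P[:, None, :] - proj, axis=2)
        out[s:s + chunk] = dist.min(axis=1)
    return out


def remesh_interior(mesh: Mesh2D, target_h: Optional[float] = None) -> Mesh2D:
    """Re-triangulate the interior of a deformed domain.

    Boundary vertices (and their labels/ordering) are preserved exactly;
    interior vertices are discarded and reseeded on a hexagonal lattice
    inside the current boundary polygons.
    """
    b_idx = mesh.boundary_vertex_indices()
    old_to_new = -np.ones(mesh.n_vertices, dtype=np.int64)
    old_to_new[b_idx] = np.arange(len(b_idx))
    b_pts = mesh.vertices[b_idx]

    if target_h is None:
        e = mesh.boundary_edges(mesh.cavity_labels()[0])
        target_h = float(np.median(np.linalg.norm(
            mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)))

    outer = _outer_loop(mesh)
    holes = [mesh.vertices[mesh.boundary_loops[lab]]
             for lab in mesh.cavity_labels()]

    h = target_h
    dy = h * np.sqrt(3) / 2
    lo = b_pts.min(axis=0) - h
    hi = b_pts.max(axis=0) + h
    if (hi[0] - lo[0]) * (hi[1] - lo[1]) / h**2 > 2e6:
        raise StepSizeError(
            "domain exploded beyond remeshing capacity; the run is "
            "unstable at this timestep"
        )
    rows = []
    j = 0
    yj = lo[1]
    while yj <= hi[1]:
        off = (j % 2) * 0.5 * h
        xs = np.arange(lo[0] + off, hi[0] + h, h)
        rows.append(np.stack([xs, np.full(len(xs), yj)], axis=1))
        yj += dy
        j += 1
    grid = np.concatenate(rows, axis=0)
    in_outer = _point_in_loops(grid, [outer])[:, 0]
    grid = grid[in_outer]
    if holes:
        in_hole = _point_in_loops(grid, holes).any(axis=1)
        grid = grid[~in_hole]
    # keep clear of the boundary
    seg_p0, seg_p1 = [], []
    for lab in mesh.boundary_loops:
        e = mesh.boundary_edges(lab)
        seg_p0.append(mesh.vertices[e[:, 0]])
        seg_p1.append(mesh.vertices[e[:, 1]])
    seg_p0 = np.concatenate(seg_p0)
    seg_p1 = np.concatenate(seg_p1)
    dist = _segment_distance(grid, seg_p0, seg_p1)
    grid = grid[dist > 0.55 * h]

    all_pts = np.concatenate([b_pts, grid], axis=0)
    tri = Delaunay(all_pts)
    cent = all_pts[tri.simplices].mean(axis=1)
    keep = _point_in_loops(cent, [outer])[:, 0]
    if holes:
        keep &= ~_point_in_loops(cent, holes).any(axis=1)
    triangles = tri.simplices[keep]

    # drop interior points that ended up in no kept triangle (they would
    # make the quasi-static system singular)
    used = np.zeros(len(all_pts), dtype=bool)
    used[np.unique(triangles)] = True
    used[:len(b_pts)] = True              # boundary always kept
    remap = -np.ones(len(all_pts), dtype=np.int64)
    remap[used] = np.arange(int(used.sum()))
    all_pts = all_pts[used]
    triangles = remap[triangles]

    loops = {lab: old_to_new[v] for lab, v in mesh.boundary_loops.items()}
    new = Mesh2D(vertices=all_pts, triangles=triangles, boundary_loops=loops)
    areas = new.signed_areas()
    flip = areas < 0
    new.triangles[flip] = new.triangles[flip][:, [0, 2, 1]]
    return new


def advance_mesh(mesh: Mesh2D, velocity: np.ndarray, dt: float,
                 policy: Optional[RemeshPolicy] = None) -> Mesh2D:
    """Move vertices by velocity*dt; remesh the interior if quality drops.

    Raises StepSizeError if the update inverts elements beyond what
    interior remeshing can repair (boundary tangling): reduce dt.
    """
    velocity = np.asarray(velocity, float)
    if velocity.shape != mesh.vertices.shape:
        raise ValueError("velocity must be defined on every vertex")
    new = mesh.copy()
    new.vertices = mesh.vertices + velocity * dt
    if policy is not None and policy.triggered(new):
        new = remesh_interior(new)
        if np.any(new.signed_areas() <= 0):
            raise StepSizeError(
                "boundary became tangled during the update; reduce the "
                "timestep"
            )
    elif np.any(new.signed_areas() <= 0):
        new = remesh_interior(new)
        if np.any(new.signed_areas() <= 0):
            raise StepSizeError(
                "element inversion not repairable by interior remeshing; "
                "reduce the timestep"
            )
    return new


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

def _one_step(mesh: Mesh2D, loads: LoadSpec, config: SimulationConfig,
              step: int) -> Mesh2D:
    try:
        curv = {lab: boundary_curvature(mesh, lab)
                for lab in mesh.cavity_labels()}
        trac = assemble_tractions(mesh, loads, curv)
        vel = solve_step(mesh, trac, config.material)
        return advance_mesh(mesh, vel, config.timestep, config.remesh_policy)
    except Exception as exc:
        raise RuntimeError(
            f"simulation aborted at step {step}: {exc}") from exc


def run_simulation(config: SimulationConfig, verbose: bool = False):
    """Iterate curvature -> tractions -> solve -> advect.

    Runs ``burn_in_steps`` settling steps under the step-0 loads, then
    ``n_steps`` recorded steps (the load schedule, if any, spans the
    recorded phase).  Returns a Trajectory holding every recorded mesh
    and per-step morphometrics (flexure angle, equivalent cavity
    diameters), with time zero and the flexure reference at the end of
    burn-in.
    """
    from .morphometrics import Trajectory  # deferred: avoids import cycle

    mesh = build_chain(config.geometry)
    for step in range(config.burn_in_steps):
        mesh = _one_step(mesh, config.load_at(0), config, step
                         - config.burn_in_steps)
    times = [0.0]
    meshes = [mesh]
    t = 0.0
    for step in range(config.n_steps):
        mesh = _one_step(mesh, config.load_at(step), config, step)
        t += config.timestep
        times.append(t)
        meshes.append(mesh)
        if verbose and (step + 1) % 50 == 0:
            q = mesh_quality(mesh)
            print(f"step {step + 1}/{config.n_steps} t={t:.4f} "
                  f"min_angle={q.min_angle_deg:.1f}")
    return Trajectory.from_meshes(times, meshes)
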