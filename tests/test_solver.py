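"""Curvature, traction assembly, and the quasi-static viscous solve."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from morphoflex.geometry import (CLAMP, GeometryConfig, Mesh2D, build_chain,
                                 cavity_label, mesh_quality)
from morphoflex.solver import (LoadSpec, MaterialParams, RemeshPolicy,
                               SimulationConfig, TensionMode,
                               advance_mesh, assemble_tractions,
                               boundary_curvature, solve_step)


def _loop_mesh(points, label="cavity_0"):
    """Mesh2D carrying only one boundary loop (curvature-only tests)."""
    return Mesh2D(vertices=np.asarray(points, float),
                  triangles=np.zeros((0, 3), dtype=int),
                  boundary_loops={label: np.arange(len(points))})


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------

def test_curvature_of_unit_circle_polygon():
    """A regular 256-gon approximating the unit circle has kappa = 1."""
    th = 2 * np.pi * np.arange(256) / 256
    mesh = _loop_mesh(np.stack([np.cos(th), np.sin(th)], axis=1))
    cf = boundary_curvature(mesh, "cavity_0")
    assert np.all(np.abs(cf.kappa - 1.0) < 1e-3)


def test_curvature_of_straight_segment_is_zero():
    pts = np.stack([np.linspace(0, 1, 7), np.zeros(7)], axis=1)
    mesh = Mesh2D(vertices=pts, triangles=np.zeros((0, 3), int),
                  boundary_loops={"exterior_dorsal": np.arange(7)})
    cf = boundary_curvature(mesh, "exterior_dorsal")
    assert np.allclose(cf.kappa[1:-1], 0.0, atol=1e-12)


def test_curvature_of_ellipse_semi_major_vertex():
    """Ellipse a=2, b=1: closed form kappa = a/b^2 = 2 at (2, 0)."""
    th = 2 * np.pi * np.arange(512) / 512
    mesh = _loop_mesh(np.stack([2 * np.cos(th), np.sin(th)], axis=1))
    cf = boundary_curvature(mesh, "cavity_0")
    at_vertex = cf.kappa[0]              # theta = 0 -> (2, 0)
    assert at_vertex == pytest.approx(2.0, rel=0.01)


def test_curvature_rejects_degenerate_loops():
    with pytest.raises(ValueError, match="fewer than 3"):
        boundary_curvature(_loop_mesh([[0, 0], [1, 0]]), "cavity_0")
    with pytest.raises(ValueError, match="duplicate"):
        boundary_curvature(_loop_mesh([[0, 0], [0, 0], [1, 0], [0, 1]]),
                           "cavity_0")
    with pytest.raises(KeyError):
        boundary_curvature(_loop_mesh([[0, 0], [1, 0], [0, 1]]), "nope")


def test_cavity_curvature_sign_is_positive_on_chain(single_vesicle_mesh):
    cf = boundary_curvature(single_vesicle_mesh, "cavity_0")
    assert np.all(cf.kappa > 0.9)
    assert np.all(cf.kappa < 1.1)


# ---------------------------------------------------------------------------
# tractions
# ---------------------------------------------------------------------------

def _cavity_traction_magnitudes(mesh, loads):
    curv = {lab: boundary_curvature(mesh, lab) for lab in mesh.cavity_labels()}
    tr = assemble_tractions(mesh, loads, curv)
    lab = np.array(tr.labels)
    mags = np.linalg.norm(tr.vectors, axis=1)
    return mags[lab == "cavity_0"], tr


def test_electric_tension_reduces_effective_pressure(single_vesicle_mesh):
    """On the unit cavity (kappa = 1), P=1, T=0.08 gives magnitude 0.92."""
    mags, _ = _cavity_traction_magnitudes(
        single_vesicle_mesh,
        LoadSpec(internal_pressure=1.0, shell_tension=0.08,
                 tension_mode=TensionMode.ELECTRIC, dorsal_shear=0.0,
                 ventral_shear=0.0))
    assert np.allclose(mags, 0.92, atol=5e-3)


def test_blood_tension_raises_effective_pressure(single_vesicle_mesh):
    mags, _ = _cavity_traction_magnitudes(
        single_vesicle_mesh,
        LoadSpec(internal_pressure=1.0, shell_tension=0.02,
                 tension_mode=TensionMode.BLOOD, dorsal_shear=0.0,
                 ventral_shear=0.0))
    assert np.allclose(mags, 1.02, atol=5e-3)


def test_zero_tension_gives_uniform_pressure_and_no_shear(single_vesicle_mesh):
    mags, tr = _cavity_traction_magnitudes(
        single_vesicle_mesh,
        LoadSpec(internal_pressure=1.0, shell_tension=0.0,
                 dorsal_shear=0.0, ventral_shear=0.0))
    assert np.allclose(mags, 1.0, atol=1e-12)
    assert set(tr.labels) == {"cavity_0"}


def test_shear_points_toward_clamp(four_vesicle_mesh):
    loads = LoadSpec(internal_pressure=0.0, shell_tension=0.0,
                     tension_mode=TensionMode.ELECTRIC,
                     dorsal_shear=0.1, ventral_shear=0.0)
    curv = {lab: boundary_curvature(four_vesicle_mesh, lab)
            for lab in four_vesicle_mesh.cavity_labels()}
    tr = assemble_tractions(four_vesicle_mesh, loads, curv)
    lab = np.array(tr.labels)
    shear = tr.vectors[lab == "exterior_dorsal"]
    assert len(shear) > 0
    assert np.all(shear[:, 0] > 0)       # posteriorly, toward the clamp
    assert np.allclose(np.linalg.norm(shear, axis=1), 0.1)


def test_missing_curvature_is_an_error(single_vesicle_mesh):
    with pytest.raises(ValueError, match="curvature"):
        assemble_tractions(single_vesicle_mesh, LoadSpec(), {})


# ---------------------------------------------------------------------------
# solve_step
# ---------------------------------------------------------------------------

def _solve(mesh, loads, material=None):
    curv = {lab: boundary_curvature(mesh, lab) for lab in mesh.cavity_labels()}
    tr = assemble_tractions(mesh, loads, curv)
    return solve_step(mesh, tr, material or MaterialParams()), tr


def test_unloaded_equilibrium_is_at_rest(single_vesicle_mesh):
    v, _ = _solve(single_vesicle_mesh,
                  LoadSpec(internal_pressure=0.0, shell_tension=0.0,
                           dorsal_shear=0.0, ventral_shear=0.0))
    assert np.abs(v).max() < 1e-10


def test_laplace_balance_suppresses_motion(single_vesicle_mesh):
    """T = P/kappa on a circular cavity kills the load: velocity drops
    by more than four orders of magnitude relative to T = 0."""
    v_free, _ = _solve(single_vesicle_mesh,
                       LoadSpec(internal_pressure=1.0, shell_tension=0.0,
                                tension_mode=TensionMode.ELECTRIC,
                                dorsal_shear=0.0, ventral_shear=0.0))
    v_bal, _ = _solve(single_vesicle_mesh,
                      LoadSpec(internal_pressure=1.0, shell_tension=1.0,
                               tension_mode=TensionMode.ELECTRIC,
                               dorsal_shear=0.0, ventral_shear=0.0))
    assert np.abs(v_bal).max() < 1e-4 * np.abs(v_free).max()


def test_single_step_is_linear_in_the_load(single_vesicle_mesh):
    curv = {lab: boundary_curvature(single_vesicle_mesh, lab)
            for lab in single_vesicle_mesh.cavity_labels()}
    tr = assemble_tractions(
        single_vesicle_mesh,
        LoadSpec(internal_pressure=1.0, dorsal_shear=0.0, ventral_shear=0.0),
        curv)
    mat = MaterialParams()
    v1 = solve_step(single_vesicle_mesh, tr, mat)
    v2 = solve_step(single_vesicle_mesh, tr.scaled(2.0), mat)
    assert np.allclose(v2, 2 * v1, atol=1e-9 * np.abs(v1).max())


def test_symmetric_load_gives_mirror_symmetric_velocity(single_vesicle_mesh):
    """Pure pressure on the mirror-symmetric mesh: vy is antisymmetric
    about the chain axis, so the flexure increment vanishes."""
    mesh = single_vesicle_mesh
    v, _ = _solve(mesh, LoadSpec(internal_pressure=1.0, dorsal_shear=0.0,
                                 ventral_shear=0.0))
    idx = cKDTree(mesh.vertices).query(mesh.vertices * [1, -1])[1]
    err = np.abs(v - v[idx] * np.array([1, -1])).max()
    assert err < 1e-8 * np.abs(v).max()
    # net y-motion of the cavity centroid ~ 0
    cav = mesh.boundary_loops[cavity_label(0)]
    assert abs(v[cav, 1].mean()) < 1e-10 * np.abs(v).max()


def test_solve_requires_clamp_constraint(single_vesicle_mesh):
    mesh = single_vesicle_mesh.copy()
    loops = dict(mesh.boundary_loops)
    loops[CLAMP] = np.array([], dtype=int)
    mesh.boundary_loops = loops
    curv = {lab: boundary_curvature(mesh, lab) for lab in mesh.cavity_labels()}
    tr = assemble_tractions(mesh, LoadSpec(), curv)
    with pytest.raises(ValueError, match="clamp"):
        solve_step(mesh, tr, MaterialParams())


def test_material_params_validated():
    with pytest.raises(ValueError):
        MaterialParams(shear_viscosity=0.0)
    with pytest.raises(ValueError):
        MaterialParams(dilational_viscosity=-1.0)


# ---------------------------------------------------------------------------
# dense direct oracle
# ---------------------------------------------------------------------------

def _dense_oracle(mesh, tractions, material):
    """Independent dense assembly-and-solve of the same weak form.

    Element loop with explicit shape-function gradients from the
    inverse Jacobian; numpy dense solve; no code shared with
    solver.solve_step.
    """
    mu = material.shear_viscosity
    lam = material.dilational_viscosity - mu
    nv = mesh.n_vertices
    K = np.zeros((2 * nv, 2 * nv))
    D = np.array([[lam + 2 * mu, lam, 0],
                  [lam, lam + 2 * mu, 0],
                  [0, 0, mu]], float)
    for tri in mesh.triangles:
        p = mesh.vertices[tri]
        J = np.array([p[1] - p[0], p[2] - p[0]]).T       # 2x2
        detJ = np.linalg.det(J)
        grad_ref = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
        grads = grad_ref @ np.linalg.inv(J)              # (3, 2) dN/dx
        B = np.zeros((3, 6))
        for k in range(3):
            B[0, 2 * k] = grads[k, 0]
            B[1, 2 * k + 1] = grads[k, 1]
            B[2, 2 * k] = grads[k, 1]
            B[2, 2 * k + 1] = grads[k, 0]
        Ke = 0.5 * abs(detJ) * B.T @ D @ B
        dof = np.array([[2 * i, 2 * i + 1] for i in tri]).ravel()
        K[np.ix_(dof, dof)] += Ke
    f = np.zeros(2 * nv)
    for (i, j), t in zip(tractions.edges, tractions.vectors):
        L = np.linalg.norm(mesh.vertices[j] - mesh.vertices[i])
        for k in (i, j):
            f[2 * k] += 0.5 * L * t[0]
            f[2 * k + 1] += 0.5 * L * t[1]
    fixed = np.zeros(2 * nv, bool)
    for k in np.unique(mesh.boundary_loops[CLAMP]):
        fixed[2 * k] = fixed[2 * k + 1] = True
    free = ~fixed
    v = np.zeros(2 * nv)
    v[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
    return v.reshape(-1, 2)


def test_solve_matches_independent_dense_oracle(coarse_mesh):
    """Sparse vectorized solve equals a dense per-element reference
    vertex-wise to 1e-8 on a coarse (<200-vertex) mesh."""
    assert coarse_mesh.n_vertices <= 200
    mat = MaterialParams(shear_viscosity=1.3, dilational_viscosity=0.7)
    loads = LoadSpec(internal_pressure=1.0, shell_tension=0.05,
                     tension_mode=TensionMode.ELECTRIC,
                     dorsal_shear=0.02, ventral_shear=0.0)
    curv = {lab: boundary_curvature(coarse_mesh, lab)
            for lab in coarse_mesh.cavity_labels()}
    tr = assemble_tractions(coarse_mesh, loads, curv)
    v_impl = solve_step(coarse_mesh, tr, mat)
    v_ref = _dense_oracle(coarse_mesh, tr, mat)
    scale = np.abs(v_ref).max()
    assert np.abs(v_impl - v_ref).max() < 1e-8 * max(scale, 1.0)


# ---------------------------------------------------------------------------
# mesh advection
# ---------------------------------------------------------------------------

def test_zero_velocity_leaves_mesh_unchanged(single_vesicle_mesh):
    out = advance_mesh(single_vesicle_mesh,
                       np.zeros_like(single_vesicle_mesh.vertices), 0.1)
    assert np.array_equal(out.vertices, single_vesicle_mesh.vertices)
    assert np.array_equal(out.triangles, single_vesicle_mesh.triangles)


def test_uniform_velocity_translates_rigidly(single_vesicle_mesh):
    vel = np.tile([1.0, 0.0], (single_vesicle_mesh.n_vertices, 1))
    out = advance_mesh(single_vesicle_mesh, vel, 0.1)
    assert np.allclose(out.vertices,
                       single_vesicle_mesh.vertices + [0.1, 0.0])


def test_remesh_preserves_boundary_vertices(single_vesicle_mesh):
    """A policy that always triggers re-triangulates the interior but
    leaves every boundary vertex coordinate untouched."""
    mesh = single_vesicle_mesh
    policy = RemeshPolicy(min_angle_deg=90.0)        # always triggers
    out = advance_mesh(mesh, np.zeros_like(mesh.vertices), 0.1, policy)
    for lab, loop in mesh.boundary_loops.items():
        np.testing.assert_allclose(out.vertices[out.boundary_loops[lab]],
                                   mesh.vertices[loop])
    assert mesh_quality(out).inverted_count == 0


def test_velocity_shape_is_validated(single_vesicle_mesh):
    with pytest.raises(ValueError):
        advance_mesh(single_vesicle_mesh, np.zeros((3, 2)), 0.1)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def test_schedule_must_divide_steps_evenly():
    with pytest.raises(ValueError, match="divide"):
        SimulationConfig(loads=[LoadSpec(), LoadSpec(), LoadSpec()],
                         n_steps=100)
    cfg = SimulationConfig(loads=[LoadSpec(shell_tension=0.0),
                                  LoadSpec(shell_tension=0.02)], n_steps=100)
    assert cfg.load_at(0).shell_tension == 0.0
    assert cfg.load_at(49).shell_tension == 0.0
    assert cfg.load_at(50).shell_tension == 0.02
    assert cfg.load_at(99).shell_tension == 0.02


def test_load_spec_validation():
    with pytest.raises(ValueError):
        LoadSpec(shell_tension=-0.1)
    with pytest.raises(ValueError):
        LoadSpec(dorsal_shear=-1.0)
    assert LoadSpec(tension_mode="electric").tension_mode \
        is TensionMode.ELECTRIC
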