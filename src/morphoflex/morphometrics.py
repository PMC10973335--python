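"""Morphometrics of simulated vesicle-chain trajectories.

Quantifies a trajectory the way the time-lapse observations are
quantified: the flexure angle of the head (signed, dorsal-positive),
the equivalent diameters of the vesicles, the diameter-angle allometry
with time eliminated, and the breakpoint between the slow linear
bending regime and the accelerating non-linear one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geometry import CLAMP, Mesh2D

__all__ = [
    "Trajectory",
    "flexure_angle",
    "vesicle_diameters",
    "allometry_curve",
    "regime_breakpoint",
    "AllometryFit",
    "Breakpoint",
]


def _loop_polygon(mesh: Mesh2D, label: str) -> np.ndarray:
    return mesh.vertices[mesh.boundary_loops[label]]


def _polygon_area_centroid(poly: np.ndarray) -> Tuple[float, np.ndarray]:
    """Signed shoelace area and area centroid of a closed polygon."""
    x, y = poly[:, 0], poly[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return a, np.array([cx, cy])


def _chord(mesh: Mesh2D) -> Tuple[np.ndarray, np.ndarray]:
    """Posterior and anterior reference points of the measurement chord.

    Multi-vesicle meshes use the most-posterior and most-anterior cavity
    centroids; a single-vesicle mesh falls back to the clamp-chain
    centroid and the cavity centroid.
    """
    labels = mesh.cavity_labels()
    if not labels:
        raise ValueError("mesh has no cavity loops")
    cents = [_polygon_area_centroid(_loop_polygon(mesh, lab))[1]
             for lab in labels]
    if len(cents) == 1:
        if CLAMP not in mesh.boundary_loops:
            raise ValueError("single-cavity mesh is missing the clamp chain")
        clamp_c = mesh.vertices[mesh.boundary_loops[CLAMP]].mean(axis=0)
        return clamp_c, cents[0]
    order = np.argsort([c[0] for c in cents])
    return cents[order[-1]], cents[order[0]]     # posterior, anterior


def flexure_angle(mesh: Mesh2D, reference: Mesh2D) -> float:
    """Signed flexure angle (degrees) of `mesh` relative to `reference`.

    Measured as the rotation of the posterior-to-anterior chord joining
    the extreme cavity centroids.  Positive = dorsal (retrograde
    uplift), negative = ventral (forward physiological flexure).
    """
    for m in (mesh, reference):
        if not m.cavity_labels():
            raise ValueError("mesh is missing cavity labels")
    p_ref, a_ref = _chord(reference)
    p_cur, a_cur = _chord(mesh)
    v_ref = a_ref - p_ref
    v_cur = a_cur - p_cur
    cross = v_ref[0] * v_cur[1] - v_ref[1] * v_cur[0]
    dot = float(np.dot(v_ref, v_cur))
    # the chord points in -x; a counterclockwise chord rotation moves the
    # anterior tip ventrally (down), hence the sign flip to make dorsal
    # positive
    return -float(np.degrees(np.arctan2(cross, dot)))


def vesicle_diameters(mesh: Mesh2D) -> np.ndarray:
    """Equivalent-circle diameters 2*sqrt(area/pi), anterior to posterior."""
    labels = mesh.cavity_labels()
    out = []
    for lab in labels:
        poly = _loop_polygon(mesh, lab)
        if not Polygon(poly).is_valid:
            raise ValueError(f"cavity loop {lab!r} is self-intersecting")
        a, c = _polygon_area_centroid(poly)
        out.append((c[0], 2.0 * np.sqrt(abs(a) / np.pi)))
    out.sort(key=lambda t: t[0])                 # anterior (min x) first
    return np.array([d for _, d in out])


@dataclass
class Trajectory:
    """Time-ordered meshes with per-step morphometrics."""

    times: np.ndarray
    meshes: List[Mesh2D]
    angles_deg: np.ndarray = field(default=None)
    diameters: np.ndarray = field(default=None)   # (n_steps, n_cavities)

    @classmethod
    def from_meshes(cls, times: Sequence[float],
                    meshes: Sequence[Mesh2D]) -> "Trajectory":
        times = np.asarray(times, float)
        if len(times) != len(meshes):
            raise ValueError("times and meshes must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        ref = meshes[0]
        angles = np.array([flexure_angle(m, ref) for m in meshes])
        diams = np.stack([vesicle_diameters(m) for m in meshes])
        return cls(times=times, meshes=list(meshes), angles_deg=angles,
                   diameters=diams)

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        cols = {f"d{i + 1}": self.diameters[:, i]
                for i in range(self.diameters.shape[1])}
        return pd.DataFrame({"time": self.times,
                             "angle_deg": self.angles_deg, **cols})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AllometryFit:
    mean_diameter: np.ndarray
    abs_angle_deg: np.ndarray
    slope: float
    intercept: float
    correlation: float
    degenerate: bool = False


def allometry_curve(traj: Trajectory) -> AllometryFit:
    """Angle-diameter allometry: |flexure| against mean vesicle diameter.

    One point per step (time eliminated); an ordinary least-squares line
    is fitted and the Pearson correlation reported.  A constant-diameter
    series has no defined correlation and is flagged degenerate.
    """
    if traj.n_steps < 3:
        raise ValueError("allometry needs at least 3 steps")
    d = traj.diameters.mean(axis=1)
    a = np.abs(traj.angles_deg)
    sd = d.std()
    if sd < 1e-12 * max(1.0, abs(d.mean())):
        return AllometryFit(d, a, slope=np.nan, intercept=np.nan,
                            correlation=np.nan, degenerate=True)
    slope, intercept = np.polyfit(d, a, 1)
    sa = a.std()
    corr = float(np.corrcoef(d, a)[0, 1]) if sa > 0 else 0.0
    return AllometryFit(d, a, slope=float(slope), intercept=float(intercept),
                        correlation=corr)


@dataclass
class Breakpoint:
    time: float
    slope_before: float
    slope_after: float
    sse: float


def regime_breakpoint(times: Sequence[float],
                      values: Sequence[float]) -> Breakpoint:
    """Single-knot continuous piecewise-linear fit of a time series.

    Every interior grid time is tried as the knot; the knot minimizing
    the total squared error of the continuous two-slope fit is
    returned.  Used to locate the transition between the slow linear
    bending regime and the accelerating non-linear one.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if len(t) != len(y):
        raise ValueError("times and values must have equal length")
    if len(t) < 6:
        raise ValueError("breakpoint fit needs at least 6 points")
    best: Optional[Breakpoint] = None
    # knots leave >= 2 points strictly on each side so both slopes exist
    for k in range(2, len(t) - 2):
        knot = t[k]
        X = np.stack([np.ones_like(t), t - knot,
                      np.maximum(t - knot, 0.0)], axis=1)
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ coef
        sse = float(np.sum((y - pred) ** 2))
        if best is None or sse < best.sse - 1e-15:
            best = Breakpoint(time=float(knot),
                              slope_before=float(coef[1]),
                              slope_after=float(coef[1] + coef[2]),
                              sse=sse)
    return best
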