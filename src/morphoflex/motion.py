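"""Motion analysis of time-lapse image stacks.

Grid cross-correlation PIV between frame pairs, least-squares rigid
hinge-rotation fitting of the displacement field, affine strain-rate
estimation, rigid registration of whole stacks, and contour-based
orientation tracking.

Coordinate and sign conventions
-------------------------------
Internally all positions are pixel (x, y) with the image-array
convention: origin top-left, x = column to the right, y = row downward.
Rotation angles are *reported* counterclockwise-positive in the
standard y-up orientation (what an observer watching the video calls
counterclockwise); since the internal y axis points down, the reported
angle is the negative of the angle measured in array coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.registration import phase_cross_correlation

__all__ = [
    "VideoStack",
    "PivConfig",
    "DisplacementField",
    "RigidMotion",
    "piv_field",
    "fit_rigid_motion",
    "strain_rates",
    "StrainRates",
    "register_stack",
    "contour_orientation",
]

#: sign conversion between array-coordinate angles (y down) and the
#: reported visual convention (counterclockwise positive, y up)
ARRAY_TO_VISUAL = -1.0


@dataclass
class VideoStack:
    """Grayscale frame sequence with acquisition metadata.

    frame_interval is in seconds (default 10 s, the usual time-lapse
    acquisition rate of 1 frame per 10 s); pixel_size in micrometres
    per pixel when known.
    """

    frames: np.ndarray                 # (T, H, W)
    frame_interval: float = 10.0
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]

    @classmethod
    def from_tiff(cls, path, frame_interval: float = 10.0,
                  pixel_size: Optional[float] = None) -> "VideoStack":
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=frames, frame_interval=frame_interval,
                   pixel_size=pixel_size)

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames, photometric="minisblack")


@dataclass(frozen=True)
class PivConfig:
    """PIV interrogation parameters (pixels).

    A grid of virtual reference points at `grid_spacing` is laid inside
    `grid_box` (x0, y0, x1, y1); around each point a square `window` is
    correlated against the second frame over +-`search_radius`.
    """

    grid_box: Optional[Tuple[int, int, int, int]] = None
    grid_spacing: int = 16
    window: int = 32
    search_radius: int = 10
    min_peak_correlation: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 8:
            raise ValueError("window must be >= 8 px")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1 px")
        if self.grid_spacing < 1:
            raise ValueError("grid_spacing must be >= 1 px")


@dataclass
class DisplacementField:
    """PIV output: grid points with per-point displacement vectors."""

    points: np.ndarray                  # (N, 2) x, y
    vectors: np.ndarray                 # (N, 2) dx, dy
    valid: np.ndarray                   # (N,) bool
    frame_pair_interval: float          # seconds
    peak_correlation: np.ndarray = None

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "x": self.points[:, 0], "y": self.points[:, 1],
            "dx": self.vectors[:, 0], "dy": self.vectors[:, 1],
            "valid": self.valid.astype(int),
        })


def _grid_points(shape, cfg: PivConfig) -> np.ndarray:
    h, w = shape
    margin = cfg.window // 2 + cfg.search_radius
    if cfg.grid_box is None:
        x0, y0, x1, y1 = margin, margin, w - margin, h - margin
    else:
        x0, y0, x1, y1 = cfg.grid_box
    xs = np.arange(x0, x1 + 1, cfg.grid_spacing)
    ys = np.arange(y0, y1 + 1, cfg.grid_spacing)
    gx, gy = np.meshgrid(xs, ys)
    return np.stack([gx.ravel(), gy.ravel()], axis=1)


def _batched_ncc(templates: np.ndarray, patches: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation of N templates against N patches.

    templates (N, w, w), patches (N, s, s) with s = w + 2r; returns the
    (N, 2r+1, 2r+1) correlation surface.  The numerator is a batched
    zero-padded FFT cross-correlation (exact linear correlation of the
    zero-mean template); window means and variances come from integral
    images.  Orders of magnitude faster than per-point correlation at
    the grid densities used here.
    """
    n, w, _ = templates.shape
    s = patches.shape[1]
    m = s - w + 1
    area = float(w * w)

    from scipy import fft as sfft

    t = templates.astype(np.float32)
    p = patches.astype(np.float32)
    t0 = t - t.mean(axis=(1, 2), keepdims=True, dtype=np.float64).astype(
        np.float32)
    t_norm = np.sqrt(np.einsum("nij,nij->n", t0, t0, dtype=np.float64))

    # linear cross-correlation num[k] = sum_i patch[i + k] * t0[i],
    # k = 0..m-1, via zero-padded FFTs (single precision: the NCC only
    # steers peak picking and subpixel refinement)
    P = sfft.next_fast_len(s + w - 1, real=True)
    Fp = sfft.rfft2(p, s=(P, P))
    Ft = sfft.rfft2(t0, s=(P, P))
    corr = sfft.irfft2(Fp * np.conj(Ft), s=(P, P))
    num = corr[:, :m, :m].astype(np.float64)

    # local window sums via 2D cumulative sums (integral images)
    p = p.astype(np.float64)
    ii = np.pad(p, ((0, 0), (1, 0), (1, 0))).cumsum(axis=1).cumsum(axis=2)
    ii2 = np.pad(p**2, ((0, 0), (1, 0), (1, 0))).cumsum(axis=1).cumsum(axis=2)

    def box(a):
        return (a[:, w:, w:] - a[:, w:, :-w] - a[:, :-w, w:]
                + a[:, :-w, :-w])

    s1 = box(ii)                                        # (n, m, m)
    var = np.maximum(box(ii2) - s1**2 / area, 0.0)
    denom = np.sqrt(var) * t_norm[:, None, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(denom > 1e-10, num / denom, 0.0)
    return np.clip(ncc, -1.0, 1.0)


def _parabolic_offset(c_minus: np.ndarray, c0: np.ndarray,
                      c_plus: np.ndarray) -> np.ndarray:
    denom = c_minus - 2 * c0 + c_plus
    off = np.where(np.abs(denom) > 1e-12,
                   0.5 * (c_minus - c_plus) / denom, 0.0)
    return np.clip(off, -1.0, 1.0)


def piv_field(frame_a: np.ndarray, frame_b: np.ndarray,
              config: Optional[PivConfig] = None,
              frame_pair_interval: float = 10.0) -> DisplacementField:
    """Displacement field between two frames by windowed NCC.

    Each grid point's window from `frame_a` is correlated against the
    search neighbourhood in `frame_b`; the integer peak is refined to
    subpixel by parabolic interpolation of the correlation surface.
    Points whose correlation peak falls below the acceptance threshold,
    or whose window leaves the frame, are masked invalid.
    """
    cfg = config or PivConfig()
    a = np.asarray(frame_a, np.float32)
    b = np.asarray(frame_b, np.float32)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    h, w = a.shape
    pts = _grid_points(a.shape, cfg)
    hw = cfg.window // 2
    r = cfg.search_radius
    s = cfg.window + 2 * r

    in_a = ((pts[:, 0] - hw >= 0) & (pts[:, 0] + hw <= w)
            & (pts[:, 1] - hw >= 0) & (pts[:, 1] + hw <= h))
    in_b = ((pts[:, 0] - hw - r >= 0) & (pts[:, 0] + hw + r <= w)
            & (pts[:, 1] - hw - r >= 0) & (pts[:, 1] + hw + r <= h))
    usable = in_a & in_b
    if not np.any(usable):
        raise ValueError("no PIV point has a full window inside the frame")

    pu = pts[usable]
    n = len(pu)
    templates = np.empty((n, cfg.window, cfg.window), np.float32)
    patches = np.empty((n, s, s), np.float32)
    for i, (x, y) in enumerate(pu):
        templates[i] = a[y - hw:y + hw, x - hw:x + hw]
        patches[i] = b[y - hw - r:y + hw + r, x - hw - r:x + hw + r]

    vectors = np.zeros((len(pts), 2))
    valid = np.zeros(len(pts), bool)
    peaks = np.zeros(len(pts))

    chunk = 512
    m = 2 * r + 1
    for st in range(0, n, chunk):
        sl = slice(st, min(st + chunk, n))
        ncc = _batched_ncc(templates[sl], patches[sl])
        flat = ncc.reshape(ncc.shape[0], -1)
        arg = flat.argmax(axis=1)
        py, px = np.unravel_index(arg, (m, m))
        pk = flat[np.arange(len(arg)), arg]
        dx = px.astype(float) - r
        dy = py.astype(float) - r
        # subpixel refinement only when the match is imperfect: a
        # perfect (integer-shift) peak must be returned exactly
        refine = pk < 1.0 - 1e-5
        interior_x = (px > 0) & (px < m - 1) & refine
        interior_y = (py > 0) & (py < m - 1) & refine
        ii = np.arange(len(arg))
        dx[interior_x] += _parabolic_offset(
            ncc[ii[interior_x], py[interior_x], px[interior_x] - 1],
            ncc[ii[interior_x], py[interior_x], px[interior_x]],
            ncc[ii[interior_x], py[interior_x], px[interior_x] + 1])
        dy[interior_y] += _parabolic_offset(
            ncc[ii[interior_y], py[interior_y] - 1, px[interior_y]],
            ncc[ii[interior_y], py[interior_y], px[interior_y]],
            ncc[ii[interior_y], py[interior_y] + 1, px[interior_y]])
        g = np.flatnonzero(usable)[sl]
        vectors[g, 0] = dx
        vectors[g, 1] = dy
        valid[g] = pk >= cfg.min_peak_correlation
        peaks[g] = pk

    if not np.any(valid):
        raise ValueError("all PIV points are invalid (no correlation peak "
                         "above threshold)")
    return DisplacementField(points=pts.astype(float), vectors=vectors,
                             valid=valid,
                             frame_pair_interval=frame_pair_interval,
                             peak_correlation=peaks)


# ---------------------------------------------------------------------------
# rigid-motion fitting
# ---------------------------------------------------------------------------

@dataclass
class RigidMotion:
    """Rigid rotation + translation fitted to a displacement field.

    angle_per_interval is in degrees per frame-pair interval,
    counterclockwise-positive in the visual (y-up) sense.  center is
    the fixed point of the rotation (grid centroid for a pure
    translation).  rate_deg_per_min converts using the pair interval.
    """

    center: np.ndarray
    angle_per_interval: float
    translation: np.ndarray
    residual_rms: float
    frame_pair_interval: float = 10.0

    @property
    def rate_deg_per_min(self) -> float:
        return self.angle_per_interval * 60.0 / self.frame_pair_interval


def fit_rigid_motion(field: DisplacementField) -> RigidMotion:
    """Least-squares rigid (rotation + translation) fit of a PIV field.

    Solves the orthogonal Procrustes problem between the grid points
    and their displaced positions (exact rotation, no small-angle
    assumption) and derives the rotation center as the fixed point.
    """
    p = field.points[field.valid]
    q = p + field.vectors[field.valid]
    if len(p) < 3:
        raise ValueError("rigid fit needs at least 3 valid points")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    P = p - pc
    if np.linalg.matrix_rank(np.cov(P.T)) < 2:
        raise ValueError("valid PIV points are collinear")
    Q = q - qc
    # 2D Procrustes: angle from the cross/dot sums
    s_cos = float(np.einsum("ij,ij->", P, Q))
    s_sin = float(np.einsum("i,i->", P[:, 0], Q[:, 1])
                  - np.einsum("i,i->", P[:, 1], Q[:, 0]))
    theta = np.arctan2(s_sin, s_cos)            # array-coordinate CCW
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    t = qc - R @ pc
    resid = q - (p @ R.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    if abs(theta) > 1e-12:
        center = np.linalg.solve(np.eye(2) - R, t)
    else:
        center = pc.copy()
    return RigidMotion(
        center=center,
        angle_per_interval=ARRAY_TO_VISUAL * float(np.degrees(theta)),
        translation=t,
        residual_rms=rms,
        frame_pair_interval=field.frame_pair_interval,
    )


# ---------------------------------------------------------------------------
# strain rates
# ---------------------------------------------------------------------------

@dataclass
class StrainRates:
    """Affine decomposition of a displacement field into rates.

    linear_rate_per_min is the radial (one-dimensional) strain rate,
    half the areal rate; both are negative for contraction.
    rotation_deg_per_min comes from the antisymmetric part, reported in
    the visual (y-up counterclockwise-positive) sense.
    """

    gradient: np.ndarray                # fitted A (2x2), per interval
    linear_rate_per_min: float
    areal_rate_per_min: float
    rotation_deg_per_min: float


def strain_rates(field: DisplacementField, dt: float) -> StrainRates:
    """Least-squares affine fit u = A (x - xbar) + b of a PIV field."""
    p = field.points[field.valid]
    u = field.vectors[field.valid]
    if len(p) < 6:
        raise ValueError("strain-rate fit needs at least 6 valid points")
    pc = p - p.mean(axis=0)
    if np.linalg.matrix_rank(np.cov(pc.T)) < 2:
        raise ValueError("valid PIV points do not span 2D")
    X = np.column_stack([pc, np.ones(len(p))])
    coef, *_ = np.linalg.lstsq(X, u, rcond=None)
    A = coef[:2].T                      # u ~ A pc + b
    trace = float(A[0, 0] + A[1, 1])
    omega = 0.5 * (A[1, 0] - A[0, 1])   # array-coordinate CCW, per interval
    return StrainRates(
        gradient=A,
        linear_rate_per_min=trace / 2.0 / dt * 60.0,
        areal_rate_per_min=trace / dt * 60.0,
        rotation_deg_per_min=ARRAY_TO_VISUAL * np.degrees(omega) / dt * 60.0,
    )


# ---------------------------------------------------------------------------
# stack registration
# ---------------------------------------------------------------------------

def _rotate_about_center(img: np.ndarray, angle_deg: float,
                         order: int = 1) -> np.ndarray:
    """Rotate image content by angle_deg (visual CCW+) about its center."""
    return ndimage.rotate(img, ARRAY_TO_VISUAL * angle_deg, reshape=False,
                          order=order, mode="nearest")


def _hann2(shape: Tuple[int, int]) -> np.ndarray:
    return np.outer(np.hanning(shape[0]), np.hanning(shape[1]))


def _translation_error(a: np.ndarray, b: np.ndarray):
    """Subpixel translation of b relative to a by cross-correlation.

    The frames are demeaned and Hann-windowed first: embryo textures
    are smooth and edge discontinuities otherwise bias the correlation
    peak toward zero shift.
    """
    win = _hann2(a.shape)
    shift, error, _ = phase_cross_correlation(
        (a - a.mean()) * win, (b - b.mean()) * win,
        upsample_factor=20, normalization=None)
    return shift, float(error)


def register_stack(stack: VideoStack, max_rotation_deg: float = 15.0,
                   angle_tol: float = 0.01):
    """Rigidly align every frame to the first.

    Translation by phase correlation, rotation by golden-section search
    (within +-max_rotation_deg, refined to angle_tol degrees) on the
    phase-correlation residual.  Returns the registered stack and the
    recovered per-frame motions (the motion that was removed).
    """
    frames = stack.frames.astype(np.float64)
    if len(frames) < 2:
        return VideoStack(stack.frames.copy(), stack.frame_interval,
                          stack.pixel_size), []
    ref = frames[0]
    if np.ptp(ref) == 0:
        raise ValueError("reference frame is featureless (constant)")
    out = [stack.frames[0].copy()]
    motions: List[RigidMotion] = []
    center = (np.array(ref.shape[::-1], float) - 1) / 2.0

    gr = (np.sqrt(5) - 1) / 2.0
    for idx, frame in enumerate(frames[1:], start=1):
        if np.ptp(frame) == 0:
            raise ValueError(f"frame {idx} is featureless (constant)")

        def err_at(theta):
            cand = _rotate_about_center(frame, -theta) if theta else frame
            _, e = _translation_error(ref, cand)
            return e

        if max_rotation_deg > 0:
            a, b = -max_rotation_deg, max_rotation_deg
            c1 = b - gr * (b - a)
            c2 = a + gr * (b - a)
            f1, f2 = err_at(c1), err_at(c2)
            while (b - a) > angle_tol:
                if f1 < f2:
                    b, c2, f2 = c2, c1, f1
                    c1 = b - gr * (b - a)
                    f1 = err_at(c1)
                else:
                    a, c1, f1 = c1, c2, f2
                    c2 = a + gr * (b - a)
                    f2 = err_at(c2)
            theta = 0.5 * (a + b)
            if err_at(0.0) <= min(f1, f2):
                theta = 0.0              # prefer no rotation when equal
        else:
            theta = 0.0

        # final resample at cubic order (the search above runs at linear
        # order for speed; cubic keeps the registered frames sharp)
        unrot = (_rotate_about_center(frame, -theta, order=3)
                 if theta else frame)
        shift, _ = _translation_error(ref, unrot)   # (dy, dx) of unrot vs ref
        if np.any(shift):
            reg = ndimage.shift(unrot, shift, order=3, mode="nearest")
        else:
            reg = unrot
        out.append(reg.astype(stack.frames.dtype, copy=False))
        motions.append(RigidMotion(
            center=center.copy(),
            angle_per_interval=theta,
            translation=np.array([-shift[1], -shift[0]]),
            residual_rms=float(np.sqrt(np.mean((reg - ref) ** 2))),
            frame_pair_interval=stack.frame_interval,
        ))
    reg_stack = VideoStack(np.stack(out), stack.frame_interval,
                           stack.pixel_size)
    return reg_stack, motions


# ---------------------------------------------------------------------------
# contour-based orientation tracking
# ---------------------------------------------------------------------------

@dataclass
class OrientationSeries:
    angles_deg: np.ndarray     # unwrapped, visual convention
    reliable: np.ndarray       # per-frame flag (False near circular)
    times: np.ndarray


def contour_orientation(stack: VideoStack,
                        threshold=None) -> OrientationSeries:
    """Per-frame orientation of the largest foreground component.

    The frame is thresholded (Otsu by default, or a fixed value), the
    largest connected component kept, and its orientation taken from
    the principal axis of the second-order moments.  The series is
    unwrapped (orientation has period 180 degrees) to be continuous.
    Frames whose component is nearly circular (axis ratio < 1.05) are
    flagged unreliable.
    """
    angles = []
    reliable = []
    for i, frame in enumerate(stack.frames):
        f = frame.astype(float)
        thr = threshold_otsu(f) if threshold is None else threshold
        fg = f > thr
        if not fg.any():
            raise ValueError(f"frame {i}: empty foreground")
        lab = cc_label(fg)
        props = regionprops(lab)
        big = max(props, key=lambda p: p.area)
        # regionprops orientation: angle of the major axis w.r.t. rows,
        # in (-pi/2, pi/2]; convert to visual degrees w.r.t. the x axis
        # regionprops measures from the row axis; shift by 90 degrees
        # (mod 180) to the visual x-axis convention
        ang = np.degrees(big.orientation)
        angles.append(ang - 90.0 if ang >= 0 else ang + 90.0)
        axr = (big.axis_major_length / big.axis_minor_length
               if big.axis_minor_length > 0 else np.inf)
        reliable.append(axr >= 1.05)
    angles = np.asarray(angles, float)
    # unwrap with period 180 degrees
    out = angles.copy()
    for i in range(1, len(out)):
        d = out[i] - out[i - 1]
        out[i] -= 180.0 * np.round(d / 180.0)
    times = np.arange(len(out)) * stack.frame_interval
    return OrientationSeries(angles_deg=out,
                             reliable=np.asarray(reliable),
                             times=times)
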