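"""Ground-truthed synthetic time-lapse generators.

Every analysis stage in this package is exercised against videos whose
motion is known exactly: a band-limited random texture undergoing rigid
hinge rotation (the retrograde-rotation episodes, about 1.5 deg/min
sampled at one frame per 10 s), isotropic contraction (brain shrinkage
at about 0.02/min), composed rotation+contraction episodes, a beating
heart imaged at 60 frames/s, and dark particles advected along a vessel
path over a few hundred frames.

The generators render by bilinear resampling of a seeded texture and
share no code with the analysis modules, so parameter recovery is a
genuine round trip.  All generators are pure functions of their
arguments including the seed.

Angle convention matches the analysis modules: rotation rates are
counterclockwise-positive in the visual (y-up) sense.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .motion import VideoStack

__all__ = [
    "GroundTruth",
    "EpisodeSegment",
    "gen_rotation_video",
    "gen_contraction_video",
    "gen_stimulation_episode",
    "gen_heart_video",
    "gen_vessel_video",
    "band_limited_texture",
]

#: default additive noise, as a fraction of the dynamic range
DEFAULT_NOISE = 0.02
#: texture correlation length in pixels (low-pass sigma ~ half of it)
TEXTURE_CORR_PX = 8.0

_U16 = 65535.0


@dataclass
class EpisodeSegment:
    """One piece of a stimulation episode."""

    duration_s: float
    omega_deg_per_min: float = 0.0
    strain_per_min: float = 0.0


@dataclass
class GroundTruth:
    """Truth embedded in every synthetic stack (JSON-serializable)."""

    motion_model: str
    seed: int
    noise_sigma: float = DEFAULT_NOISE
    center: Optional[Tuple[float, float]] = None
    omega_deg_per_min: float = 0.0
    strain_per_min: float = 0.0
    schedule: Optional[List[EpisodeSegment]] = None
    frequency_hz: float = 0.0
    waveform: str = "sine"
    roi: Optional[Tuple[int, int, int, int]] = None
    path: Optional[List[Tuple[float, float]]] = None
    particle_rate_per_frame: float = 0.0
    particle_speed_px_per_frame: float = 0.0
    jitter_px: float = 0.0
    total_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise_sigma < 0.5):
            raise ValueError("noise_sigma must be in [0, 0.5)")

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as f:
            json.dump(d, f, indent=1)


def band_limited_texture(shape: Tuple[int, int], seed: int,
                         corr_px: float = TEXTURE_CORR_PX) -> np.ndarray:
    """Seeded low-pass-filtered noise in [0.15, 0.85] of unit range."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    tex = ndimage.gaussian_filter(noise, corr_px / 2.0)
    tex = (tex - tex.min()) / np.ptp(tex)
    return 0.15 + 0.7 * tex


def _finalize(frames_float: List[np.ndarray], noise_sigma: float,
              rng: np.random.Generator, frame_interval: float) -> VideoStack:
    out = []
    for fr in frames_float:
        f = fr + noise_sigma * rng.standard_normal(fr.shape)
        out.append(np.clip(f, 0.0, 1.0))
    arr = (np.stack(out) * _U16).round().astype(np.uint16)
    return VideoStack(frames=arr, frame_interval=frame_interval)


def _sample_rigid(base: np.ndarray, pad: int, shape: Tuple[int, int],
                  angle_deg: float, scale: float,
                  center: Tuple[float, float],
                  offset: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Render a frame by sampling `base` under rotation+scale about center.

    angle_deg is visual counterclockwise-positive; in array (x, y-down)
    coordinates this is a rotation by -angle.  scale < 1 shrinks the
    content.  base is the texture on a canvas padded by `pad` on each
    side; offset is an additional content translation in pixels.
    """
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = center
    dx = xs - cx - offset[0]
    dy = ys - cy - offset[1]
    th = np.radians(-angle_deg)          # visual -> array-coordinate angle
    c, s = np.cos(th), np.sin(th)
    # inverse map: source = R(-theta_arr) (p - c)/scale + c
    sx = (c * dx + s * dy) / scale + cx + pad
    sy = (-s * dx + c * dy) / scale + cy + pad
    return ndimage.map_coordinates(base, [sy, sx], order=1, mode="nearest")


def gen_rotation_video(shape: Tuple[int, int] = (512, 512),
                       n_frames: int = 120,
                       frame_interval: float = 10.0,
                       omega_deg_per_min: float = 1.5,
                       center: Optional[Tuple[float, float]] = None,
                       noise_sigma: float = DEFAULT_NOISE,
                       seed: int = 0):
    """Textured video rotating rigidly about a hinge.

    The default rate, 1.5 deg/min at one frame per 10 s, is the
    retrograde rotation speed observed in the stimulation assay
    (0.25 deg per frame).
    """
    per_frame = omega_deg_per_min * frame_interval / 60.0
    if abs(per_frame) > 15.0:
        raise ValueError("rotation exceeds 15 deg/frame: resampling between "
                         "consecutive frames would be invalid")
    h, w = shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    total = abs(omega_deg_per_min) * (n_frames - 1) * frame_interval / 60.0
    rad = 0.5 * np.hypot(h, w)
    pad = int(np.ceil(rad * min(np.radians(total), 2.0))) + 8
    base = band_limited_texture((h + 2 * pad, w + 2 * pad), seed)
    rng = np.random.default_rng(seed + 1)
    frames = [
        _sample_rigid(base, pad, shape, omega_deg_per_min * k
                      * frame_interval / 60.0, 1.0, center)
        for k in range(n_frames)
    ]
    gt = GroundTruth(motion_model="ROTATION", seed=seed,
                     noise_sigma=noise_sigma, center=tuple(center),
                     omega_deg_per_min=omega_deg_per_min,
                     total_angle_deg=omega_deg_per_min
                     * (n_frames - 1) * frame_interval / 60.0)
    return _finalize(frames, noise_sigma, rng, frame_interval), gt


def gen_contraction_video(shape: Tuple[int, int] = (512, 512),
                          n_frames: int = 60,
                          frame_interval: float = 10.0,
                          strain_per_min: float = 0.02,
                          center: Optional[Tuple[float, float]] = None,
                          noise_sigma: float = DEFAULT_NOISE,
                          seed: int = 0):
    """Textured video contracting isotropically about a center.

    strain_per_min is the linear (radial) rate s; content is rescaled
    by exp(-s t), the physiological brain deformation rate being about
    0.02/min.
    """
    h, w = shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    t_total_min = (n_frames - 1) * frame_interval / 60.0
    max_growth = float(np.exp(abs(strain_per_min) * t_total_min))
    pad = int(np.ceil(0.5 * np.hypot(h, w) * (max_growth - 1.0))) + 8
    base = band_limited_texture((h + 2 * pad, w + 2 * pad), seed)
    rng = np.random.default_rng(seed + 1)
    frames = []
    for k in range(n_frames):
        t_min = k * frame_interval / 60.0
        scale = float(np.exp(-strain_per_min * t_min))
        frames.append(_sample_rigid(base, pad, shape, 0.0, scale, center))
    gt = GroundTruth(motion_model="CONTRACTION", seed=seed,
                     noise_sigma=noise_sigma, center=tuple(center),
                     strain_per_min=strain_per_min)
    return _finalize(frames, noise_sigma, rng, frame_interval), gt


def gen_stimulation_episode(schedule: Sequence[EpisodeSegment],
                            shape: Tuple[int, int] = (512, 512),
                            frame_interval: float = 10.0,
                            center: Optional[Tuple[float, float]] = None,
                            noise_sigma: float = DEFAULT_NOISE,
                            seed: int = 0):
    """Piecewise rotation+contraction episode about a common center.

    Each segment runs at its own angular rate and linear strain rate;
    the cumulative rotation and log-scale are integrated over the
    schedule (they commute about a shared center).  Emulates a
    stimulation response followed by the later rocking back.
    """
    schedule = list(schedule)
    if len(schedule) < 1:
        raise ValueError("schedule needs at least one segment")
    h, w = shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    # frame times across the whole episode
    total_s = sum(seg.duration_s for seg in schedule)
    n_frames = int(round(total_s / frame_interval)) + 1

    def state_at(t_s: float):
        ang = 0.0
        logs = 0.0
        rem = t_s
        for seg in schedule:
            d = min(rem, seg.duration_s)
            ang += seg.omega_deg_per_min * d / 60.0
            logs += -seg.strain_per_min * d / 60.0
            rem -= d
            if rem <= 0:
                break
        return ang, float(np.exp(logs))

    angs = [state_at(k * frame_interval)[0] for k in range(n_frames)]
    max_ang = max(abs(a) for a in angs)
    scales = [state_at(k * frame_interval)[1] for k in range(n_frames)]
    max_growth = max(max(scales), 1.0 / min(scales))
    rad = 0.5 * np.hypot(h, w)
    pad = int(np.ceil(rad * (min(np.radians(max_ang), 2.0)
                             + (max_growth - 1.0)))) + 8
    base = band_limited_texture((h + 2 * pad, w + 2 * pad), seed)
    rng = np.random.default_rng(seed + 1)
    frames = []
    for k in range(n_frames):
        ang, scale = state_at(k * frame_interval)
        frames.append(_sample_rigid(base, pad, shape, ang, scale, center))
    gt = GroundTruth(motion_model="EPISODE", seed=seed,
                     noise_sigma=noise_sigma, center=tuple(center),
                     schedule=schedule,
                     total_angle_deg=state_at(total_s)[0])
    return _finalize(frames, noise_sigma, rng, frame_interval), gt


def gen_heart_video(shape: Tuple[int, int] = (128, 128),
                    n_frames: int = 600,
                    fps: float = 60.0,
                    frequency_hz: float = 2.0,
                    waveform: str = "sine",
                    noise_sigma: float = DEFAULT_NOISE,
                    seed: int = 0):
    """Beating-heart video: a bright wall feature oscillating through a ROI.

    A bright elliptical blob moves in and out of a fixed ROI at the
    given frequency (60 frames/s being the cardiography acquisition
    rate).  waveform 'sine' or 'pulse' (sharpened rise).  The ROI that
    the wall sweeps is recorded in the ground truth.
    """
    if frequency_hz > 0 and fps < 4 * frequency_hz:
        raise ValueError("fps must be at least 4x the beat frequency")
    h, w = shape
    base = 0.35 * np.ones(shape) + 0.1 * band_limited_texture(shape, seed)
    rng = np.random.default_rng(seed + 1)
    cx0, cy = 0.35 * w, 0.5 * h
    amp = 0.18 * w
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    frames = []
    for k in range(n_frames):
        t = k / fps
        ph = 2 * np.pi * frequency_hz * t
        if waveform == "pulse":
            # sharpened rise: raised cosine to a power
            osc = ((1 + np.cos(ph - np.pi)) / 2.0) ** 3 * 2 - 1
        else:
            osc = np.sin(ph)
        cx = cx0 + amp * osc
        blob = np.exp(-(((xs - cx) / (0.10 * w)) ** 2
                        + ((ys - cy) / (0.22 * h)) ** 2))
        frames.append(np.clip(base + 0.5 * blob, 0, 1))
    roi = (int(0.45 * w), int(0.35 * h), int(0.62 * w), int(0.65 * h))
    gt = GroundTruth(motion_model="HEART", seed=seed,
                     noise_sigma=noise_sigma, frequency_hz=frequency_hz,
                     waveform=waveform, roi=roi)
    return _finalize(frames, noise_sigma, rng, 1.0 / fps), gt


def gen_vessel_video(path: Sequence[Tuple[float, float]] = ((30, 40), (110, 70), (200, 180)),
                     shape: Tuple[int, int] = (256, 256),
                     n_frames: int = 300,
                     frame_interval: float = 1 / 30.0,
                     particle_rate_per_frame: float = 1.5,
                     particle_speed_px_per_frame: float = 3.0,
                     particle_sigma_px: float = 2.0,
                     jitter_px: float = 0.0,
                     noise_sigma: float = DEFAULT_NOISE,
                     seed: int = 0):
    """Blood-flow video: dark particles advected along a vessel polyline.

    Erythrocyte-like dark Gaussian blobs enter the path at a Poisson
    rate and travel at constant speed over a bright textured
    background.  Optional per-frame rigid jitter (uniform in
    +-jitter_px with a small rotation) exercises registration before
    min-projection.  The true path polyline is embedded in the ground
    truth.
    """
    pathv = np.asarray(path, float)
    if len(pathv) < 2:
        raise ValueError("path needs at least 2 points")
    seglen = np.linalg.norm(np.diff(pathv, axis=0), axis=1)
    if np.any(seglen <= 0):
        raise ValueError("degenerate path segment")
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total_len = cum[-1]

    def point_at(s: float) -> np.ndarray:
        s = np.clip(s, 0, total_len)
        i = min(np.searchsorted(cum, s, side="right") - 1, len(seglen) - 1)
        f = (s - cum[i]) / seglen[i]
        return pathv[i] * (1 - f) + pathv[i + 1] * f

    h, w = shape
    pad = int(np.ceil(jitter_px)) + 8
    base = 0.55 + 0.35 * band_limited_texture((h + 2 * pad, w + 2 * pad),
                                              seed)
    rng = np.random.default_rng(seed + 1)
    # particle birth times (Poisson arrivals per frame)
    births = []
    for k in range(n_frames):
        for _ in range(rng.poisson(particle_rate_per_frame)):
            births.append(k + rng.random())
    births = np.array(sorted(births))
    jit_rng = np.random.default_rng(seed + 2)
    jitters = (jit_rng.uniform(-jitter_px, jitter_px, size=(n_frames, 2))
               if jitter_px > 0 else np.zeros((n_frames, 2)))
    jit_rot = (jit_rng.uniform(-1.0, 1.0, size=n_frames)
               if jitter_px > 0 else np.zeros(n_frames))
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    halo = int(np.ceil(4 * particle_sigma_px))
    frames = []
    for k in range(n_frames):
        ang = jit_rot[k]
        off = tuple(jitters[k])
        fr = _sample_rigid(base, pad, shape, ang, 1.0, center, offset=off)
        alive = births[(births <= k)
                       & ((k - births) * particle_speed_px_per_frame
                          <= total_len)]
        th = np.radians(-ang)
        c, s = np.cos(th), np.sin(th)
        for b in alive:
            p = point_at((k - b) * particle_speed_px_per_frame)
            # apply the same rigid jitter to the particle position
            dx, dy = p[0] - center[0], p[1] - center[1]
            px = center[0] + (c * dx - s * dy) + off[0]
            py = center[1] + (s * dx + c * dy) + off[1]
            # render the dark blob only on its local patch
            x0, x1 = int(px) - halo, int(px) + halo + 1
            y0, y1 = int(py) - halo, int(py) + halo + 1
            if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
                continue
            x0, x1 = max(x0, 0), min(x1, w)
            y0, y1 = max(y0, 0), min(y1, h)
            yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
            fr[y0:y1, x0:x1] -= 0.35 * np.exp(
                -((xx - px) ** 2 + (yy - py) ** 2)
                / (2 * particle_sigma_px**2))
        frames.append(np.clip(fr, 0, 1))
    gt = GroundTruth(motion_model="VESSEL", seed=seed,
                     noise_sigma=noise_sigma,
                     path=[tuple(p) for p in pathv],
                     particle_rate_per_frame=particle_rate_per_frame,
                     particle_speed_px_per_frame=particle_speed_px_per_frame,
                     jitter_px=jitter_px)
    return _finalize(frames, noise_sigma, rng, frame_interval), gt
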