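"""Video cardiography and vessel-cast imaging.

The beating heart is monitored by the mean gray level of an operator
ROI placed where a bright wall feature moves in and out: the trace
rises and falls with each beat, and the steepness of the rising phase
is proportional to the wall speed, hence a proxy for heart thrust.

Blood vessels are imaged without staining by registering a blood-flow
video and taking the per-pixel minimum over a few hundred frames: the
dark moving erythrocytes accumulate into a composite "digital cast" of
the vessel paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .motion import VideoStack, register_stack

__all__ = [
    "IntensityTrace",
    "BeatStats",
    "roi_trace",
    "beat_stats",
    "vessel_cast",
]


@dataclass
class IntensityTrace:
    """Mean ROI intensity per frame with timestamps (seconds)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(self.times)))

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter=",", header="t_s,intensity", comments="")


@dataclass
class BeatStats:
    """Heart rate and thrust proxy extracted from an intensity trace.

    thrust_proxy is the rising-phase slope (grayscale units per
    second) averaged over beats: a comparative measure of wall speed,
    not an absolute flow.
    """

    rate_bpm: float
    thrust_proxy: float
    n_beats: int
    peak_times: np.ndarray


def roi_trace(stack: VideoStack, roi: Tuple[int, int, int, int]) -> IntensityTrace:
    """Mean intensity inside roi = (x0, y0, x1, y1) for every frame."""
    x0, y0, x1, y1 = roi
    h, w = stack.shape
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"roi {roi} is empty or outside the {w}x{h} frame")
    vals = stack.frames[:, y0:y1, x0:x1].mean(axis=(1, 2))
    times = np.arange(len(stack)) * stack.frame_interval
    return IntensityTrace(times=times, values=vals)


def beat_stats(trace: IntensityTrace,
               detrend_window_s: float = 2.0,
               prominence_fraction: float = 0.25) -> BeatStats:
    """Detect beats in a cardiography trace and summarize them.

    The trace is detrended by subtracting a moving median (2 s window
    by default); beats are peaks with prominence of at least 25% of
    the detrended amplitude range; the rate comes from the span
    between the first and last peak.
    """
    t, v = trace.times, trace.values
    if len(t) < 2 or t[-1] - t[0] < 5.0:
        raise ValueError("need at least 5 s of signal")
    dt = trace.sampling_interval
    win = max(3, int(round(detrend_window_s / dt)) | 1)
    detr = v - ndimage.median_filter(v, size=win, mode="nearest")
    amp = np.ptp(detr)
    if amp <= 0:
        raise ValueError("no beats detected")
    peaks, _ = find_peaks(detr, prominence=prominence_fraction * amp)
    if len(peaks) < 2:
        raise ValueError("no beats detected")
    span = t[peaks[-1]] - t[peaks[0]]
    rate = 60.0 * (len(peaks) - 1) / span
    # thrust: max rising-phase slope before each peak, averaged
    slopes = np.diff(v) / np.diff(t)
    thrust = []
    prev = 0
    for pk in peaks:
        seg = slopes[prev:max(pk, prev + 1)]
        if len(seg):
            thrust.append(seg.max())
        prev = pk
    return BeatStats(rate_bpm=float(rate),
                     thrust_proxy=float(np.mean(thrust)) if thrust else 0.0,
                     n_beats=int(len(peaks)),
                     peak_times=t[peaks])


def vessel_cast(stack: VideoStack, frame_window: int = 300,
                register: bool = True,
                max_rotation_deg: float = 5.0,
                flatten_sigma: Optional[float] = None) -> np.ndarray:
    """Minimum-intensity vessel cast of a blood-flow video.

    Frames are rigidly registered to the first (unless register=False),
    then the per-pixel minimum over the first `frame_window` frames is
    taken, accumulating the dark erythrocytes into a cast of the vessel
    paths.  Optional background flattening divides by a large-sigma
    Gaussian blur of the cast.  Output is scaled back to the input
    dtype range.
    """
    if frame_window < 2:
        raise ValueError("frame_window must be >= 2")
    if frame_window > len(stack):
        raise ValueError(
            f"frame_window {frame_window} exceeds stack length {len(stack)}"
        )
    sub = VideoStack(stack.frames[:frame_window], stack.frame_interval,
                     stack.pixel_size)
    if register:
        sub, _ = register_stack(sub, max_rotation_deg=max_rotation_deg)
    cast = sub.frames.astype(np.float64).min(axis=0)
    if flatten_sigma:
        bg = ndimage.gaussian_filter(cast, flatten_sigma)
        bg[bg <= 0] = 1.0
        cast = cast / bg
        cast = cast / cast.max() if cast.max() > 0 else cast
        lo, hi = cast.min(), cast.max()
        cast = (cast - lo) / (hi - lo) if hi > lo else cast
        if np.issubdtype(stack.frames.dtype, np.integer):
            info = np.iinfo(stack.frames.dtype)
            cast = cast * info.max
    if np.issubdtype(stack.frames.dtype, np.integer):
        cast = np.clip(np.round(cast), np.iinfo(stack.frames.dtype).min,
                       np.iinfo(stack.frames.dtype).max)
        return cast.astype(stack.frames.dtype)
    return cast
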