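"""Activation mapping and wavefront-speed estimation for sensor movies.

An intracellular H₂O₂ (or Ca²⁺) wave crossing a cell appears as a per-pixel
activation delay.  Each pixel's fluorescence deviation from its own baseline
is normalized to its full dynamic range ("sensor activation", 0–100%), the
activation is binarized at a threshold (default 50%), a sub-frame arrival
time is interpolated per pixel, and the front speed is the slope of a
least-squares fit of arrival time against projected distance.  Absolute
deviation |F − F₀| is used so the same code serves direct and
inverse-response reporters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ActivationMovie",
    "ActivationParams",
    "FrontEstimate",
    "FrontUnresolvedError",
    "activation_fraction",
    "binarize",
    "arrival_time_map",
    "front_speed",
]


class FrontUnresolvedError(RuntimeError):
    """Raised when arrival times carry no usable spatial/temporal spread."""


@dataclass(frozen=True)
class ActivationMovie:
    """Fluorescence stack (frames first: T × H × W) with physical scales."""

    frames: np.ndarray
    frame_interval: float  # s
    pixel_size: float  # µm per pixel
    mask: np.ndarray | None = None  # optional boolean cell mask (H × W)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        object.__setattr__(self, "frames", f)
        if f.ndim != 3 or f.shape[0] < 3:
            raise ValueError("movie must be (T, H, W) with T >= 3")
        if self.frame_interval <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_interval and pixel_size must be positive")
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != f.shape[1:]:
                raise ValueError("mask must match the frame shape")
            object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class ActivationParams:
    threshold: float = 0.5
    baseline_frames: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")
        if self.baseline_frames < 1:
            raise ValueError("baseline_frames must be >= 1")


@dataclass(frozen=True)
class FrontEstimate:
    speed_um_s: float  # negative when the front retreats (flagged)
    intercept_s: float
    residual_rms_s: float
    n_used: int
    mode: str  # "pixel" or "roi"

    @property
    def retreating(self) -> bool:
        return self.speed_um_s < 0


def activation_fraction(
    movie: ActivationMovie, params: ActivationParams | None = None
) -> np.ndarray:
    """Per-pixel sensor activation a(x, t) ∈ [0, 1].

    ``a = |F - F₀| / max_t |F - F₀|`` with F₀ the per-pixel mean over the
    baseline frames.  Per-pixel normalization makes the result invariant to
    heterogeneous expression levels and per-pixel affine intensity changes.
    Pixels with zero dynamic range (and pixels outside the mask) are NaN.
    """
    params = params or ActivationParams()
    f = movie.frames
    f0 = f[: params.baseline_frames].mean(axis=0)
    dev = np.abs(f - f0[None])
    denom = dev.max(axis=0)
    valid = denom > 0
    if movie.mask is not None:
        valid &= movie.mask
    if not valid.any():
        raise ValueError("no pixel has a positive dynamic range inside the mask")
    a = np.full_like(f, np.nan)
    a[:, valid] = dev[:, valid] / denom[valid]
    return a


def binarize(activation: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """True where activation is at or above the threshold (inclusive)."""
    return activation >= threshold


def arrival_time_map(
    activation: np.ndarray,
    threshold: float = 0.5,
    frame_interval: float = 1.0,
) -> np.ndarray:
    """Per-pixel first-crossing time of the threshold, in seconds.

    Linear interpolation between the straddling frames; NaN where the pixel
    never reaches the threshold.
    """
    t_frames, h, w = activation.shape
    reached = binarize(activation, threshold)
    first = np.argmax(reached, axis=0).astype(float)
    never = ~reached.any(axis=0)
    k = first.astype(int)
    flat_idx = np.arange(h * w)
    a_k = activation.reshape(t_frames, -1)[k.ravel(), flat_idx].reshape(h, w)
    km1 = np.maximum(k - 1, 0)
    a_km1 = activation.reshape(t_frames, -1)[km1.ravel(), flat_idx].reshape(h, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(
            (k > 0) & (a_k > a_km1), (threshold - a_km1) / (a_k - a_km1), 0.0
        )
    arrival = (km1 + frac) * frame_interval
    arrival = np.where(k == 0, 0.0, arrival)
    arrival[never] = np.nan
    arrival[np.isnan(activation).all(axis=0)] = np.nan
    return arrival


def _mean_gradient_direction(arrival: np.ndarray) -> tuple[float, float]:
    gy, gx = np.gradient(arrival)
    my = np.nanmean(gy)
    mx = np.nanmean(gx)
    norm = math.hypot(my, mx)
    if not np.isfinite(norm) or norm == 0:
        raise FrontUnresolvedError(
            "propagation direction is undefined (no arrival-time gradient)"
        )
    return my / norm, mx / norm


def _fit_time_on_distance(d_um: np.ndarray, t_s: np.ndarray, mode: str) -> FrontEstimate:
    if len(d_um) < 3 or len(np.unique(np.round(d_um, 9))) < 3:
        raise FrontUnresolvedError("need >= 3 distinct projected distances")
    if np.ptp(t_s) == 0:
        raise FrontUnresolvedError("front unresolved at this frame rate "
                                   "(simultaneous arrival everywhere)")
    A = np.vstack([d_um, np.ones_like(d_um)]).T
    coef, _res, rank, _sv = np.linalg.lstsq(A, t_s, rcond=None)
    if rank < 2:
        raise FrontUnresolvedError("rank-deficient fit")
    slope, intercept = coef
    if slope == 0:
        raise FrontUnresolvedError("zero time-vs-distance slope")
    resid = t_s - A @ coef
    return FrontEstimate(
        speed_um_s=1.0 / float(slope),
        intercept_s=float(intercept),
        residual_rms_s=float(np.sqrt(np.mean(resid**2))),
        n_used=int(len(d_um)),
        mode=mode,
    )


def front_speed(
    arrival: np.ndarray,
    pixel_size: float,
    direction: tuple[float, float] | None = None,
    roi_centroids: np.ndarray | None = None,
) -> FrontEstimate:
    """Estimate front speed from an arrival-time map.

    Pixel mode (default): arrival times of all finite pixels are regressed
    on their positions projected (in µm) onto the propagation direction —
    given as a (dy, dx) vector, or estimated as the mean arrival-time
    gradient.  Speed is the inverse slope of the time-vs-distance fit, so
    the intercept and residual RMS are in seconds.

    ROI mode: pass ``roi_centroids`` (n × 2 array of (row, col) pixel
    coordinates); per-ROI arrival times are read from the map, ROIs are
    ordered by arrival, and distance is accumulated along the centroid
    chain — the few-ROI analogue of the pixel fit.

    A retreating front yields a negative speed (``FrontEstimate.retreating``).
    """
    arrival = np.asarray(arrival, dtype=float)
    if roi_centroids is not None:
        cents = np.asarray(roi_centroids, dtype=float)
        rr = np.clip(np.round(cents[:, 0]).astype(int), 0, arrival.shape[0] - 1)
        cc = np.clip(np.round(cents[:, 1]).astype(int), 0, arrival.shape[1] - 1)
        t_roi = arrival[rr, cc]
        ok = np.isfinite(t_roi)
        if ok.sum() < 3:
            raise FrontUnresolvedError("need >= 3 ROIs with finite arrival")
        cents, t_roi = cents[ok], t_roi[ok]
        order = np.argsort(t_roi, kind="stable")
        cents, t_roi = cents[order], t_roi[order]
        steps = np.linalg.norm(np.diff(cents, axis=0), axis=1) * pixel_size
        d = np.concatenate([[0.0], np.cumsum(steps)])
        return _fit_time_on_distance(d, t_roi, mode="roi")

    finite = np.isfinite(arrival)
    if finite.sum() < 3:
        raise FrontUnresolvedError("fewer than 3 finite arrival times")
    if direction is None:
        direction = _mean_gradient_direction(arrival)
    dy, dx = direction
    norm = math.hypot(dy, dx)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    dy, dx = dy / norm, dx / norm
    yy, xx = np.nonzero(finite)
    d = (yy * dy + xx * dx) * pixel_size
    return _fit_time_on_distance(d, arrival[finite], mode="pixel")
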