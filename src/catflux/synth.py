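"""Seeded synthetic-data generators with embedded ground truth.

Every input class the pipeline consumes can be generated here with known
truth, so recovery tests close the loop analytically:

* periodic calcium-transient traces (half-cosine rise, exponential decay
  whose time constant is solved in closed form from the requested CaTD90),
* step-response sensor traces (direct or inverse polarity) with a 5–95%
  rise time set through ``tau = rise_time / ln 19``,
* travelling activation wavefronts crossing a cell mask at a set speed,
* dual-channel trace pairs with a set peak-to-peak lag.

All generators are pure functions of (parameters, seed): the same seed
reproduces outputs bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import CaTrace

__all__ = [
    "CaTGroundTruth",
    "WaveGroundTruth",
    "gen_cat_trace",
    "gen_sensor_trace",
    "gen_wave_movie",
    "gen_dual_channel",
    "decay_tau_from_catd90",
    "tau_from_rise_time",
]

LN10 = math.log(10.0)
LN19 = math.log(19.0)


def decay_tau_from_catd90(ttp_s: float, catd90_s: float) -> float:
    """Decay time constant so a pure-exponential decay hits 90% recovery at
    ``catd90``: tau = (catd90 - ttp) / ln 10."""
    if catd90_s <= ttp_s:
        raise ValueError("catd90 must exceed ttp")
    return (catd90_s - ttp_s) / LN10


def tau_from_rise_time(rise_time_5_95_s: float) -> float:
    """Exponential time constant giving a requested 5–95% rise time:
    tau = rise / ln 19."""
    if rise_time_5_95_s <= 0:
        raise ValueError("rise time must be positive")
    return rise_time_5_95_s / LN19


@dataclass(frozen=True)
class CaTGroundTruth:
    """Programmed truth for a periodic calcium-transient trace."""

    rate_hz: float = 1.0
    baseline: float = 0.1
    amplitude: float = 0.6
    ttp_s: float = 0.15
    catd90_s: float = 0.6
    drift_per_s: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.catd90_s <= self.ttp_s:
            raise ValueError("catd90 must exceed ttp (infeasible beat shape)")
        if self.catd90_s >= 1.0 / self.rate_hz:
            raise ValueError("catd90 must fit within one beat period")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.__dataclass_fields__}


def _beat_shape(phi: np.ndarray, gt: CaTGroundTruth, period: float) -> np.ndarray:
    """Unit-amplitude beat waveform on beat phase [0, period).

    Half-cosine rise to 1 at ttp; exponential decay with the closed-form tau
    so the 90%-recovery crossing falls exactly at catd90; past catd90 the
    residual tail is tapered by a smooth cos² window that reaches 0 with zero
    slope at the period end, so each beat returns exactly to baseline without
    moving the CaTD90 crossing.
    """
    tau = decay_tau_from_catd90(gt.ttp_s, gt.catd90_s)
    shape = np.empty_like(phi)
    rising = phi < gt.ttp_s
    shape[rising] = 0.5 * (1.0 - np.cos(np.pi * phi[rising] / gt.ttp_s))
    dec = ~rising
    val = np.exp(-(phi[dec] - gt.ttp_s) / tau)
    taper = np.ones_like(val)
    late = phi[dec] > gt.catd90_s
    x = (phi[dec][late] - gt.catd90_s) / (period - gt.catd90_s)
    taper[late] = np.cos(0.5 * np.pi * x) ** 2
    shape[dec] = val * taper
    return shape


def gen_cat_trace(
    gt: CaTGroundTruth,
    duration: float = 20.0,
    sample_rate: float = 100.0,
    kind: str = "fluorescence",
) -> tuple[CaTrace, CaTGroundTruth]:
    """Generate a periodic CaT trace plus its ground-truth record."""
    rng = np.random.default_rng(gt.seed)
    period = 1.0 / gt.rate_hz
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    phi = np.mod(t, period)
    value = gt.baseline + gt.amplitude * _beat_shape(phi, gt, period)
    value = value + gt.drift_per_s * t
    if gt.noise_sigma > 0:
        value = value + rng.normal(0.0, gt.noise_sigma, size=value.shape)
    if kind == "cai":
        value = np.maximum(value, 1e-6)
    return CaTrace(t, value, kind=kind, sample_rate=sample_rate), gt


def gen_sensor_trace(
    plateau_pct: float,
    rise_time_s: float = 0.96,
    polarity: str = "inverse",
    noise_sigma_pct: float = 0.0,
    stimulus_time: float = 2.0,
    duration: float = 20.0,
    sample_rate: float = 20.0,
    fo: float = 100.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate a step-response sensor fluorescence trace.

    The noiseless ΔF/F₀ magnitude follows ``P (1 - exp(-(t - t0)/tau))``
    with ``tau = rise_time / ln 19``; inverse polarity makes fluorescence
    fall as the analyte rises.  Returns ``(t, F, truth)`` where F is raw
    fluorescence around a baseline ``fo`` with seeded Gaussian noise
    (``noise_sigma_pct`` in ΔF/F₀ percent units).
    """
    if plateau_pct == 0:
        raise ValueError("plateau must be non-zero")
    if polarity not in ("direct", "inverse"):
        raise ValueError(f"polarity must be direct|inverse, got {polarity!r}")
    tau = tau_from_rise_time(rise_time_s)
    sign = -1.0 if polarity == "inverse" else 1.0
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    mag = abs(plateau_pct) * (1.0 - np.exp(-np.maximum(t - stimulus_time, 0.0) / tau))
    mag[t < stimulus_time] = 0.0
    dff = sign * mag
    f = fo * (1.0 + dff / 100.0)
    if noise_sigma_pct > 0:
        f = f + fo * (rng.normal(0.0, noise_sigma_pct, size=f.shape) / 100.0)
    truth = {
        "plateau_pct": sign * abs(plateau_pct),
        "rise_time_5_95_s": rise_time_s,
        "tau_s": tau,
        "stimulus_time_s": stimulus_time,
        "polarity": polarity,
        "fo": fo,
        "seed": seed,
    }
    return t, f, truth


@dataclass(frozen=True)
class WaveGroundTruth:
    """Programmed truth for a travelling activation wavefront movie."""

    speed_um_s: float = 10.0
    direction: tuple[float, float] = (1.0, 0.0)  # (dy, dx) unit vector
    onset_s: float = 1.0
    tau_s: float = 0.3  # per-pixel response time constant
    polarity: str = "inverse"
    noise_sigma_pct: float = 0.0
    pixel_size_um: float = 1.0
    frame_rate_hz: float = 20.0
    plateau_pct: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_um_s <= 0:
            raise ValueError("speed must be positive")
        step = self.speed_um_s / (self.frame_rate_hz * self.pixel_size_um)
        if step >= 5.0:
            raise ValueError(
                "frame rate too low: front moves >= 5 pixels per frame"
            )
        n = math.hypot(*self.direction)
        if n == 0:
            raise ValueError("direction must be a non-zero vector")
        object.__setattr__(
            self, "direction", (self.direction[0] / n, self.direction[1] / n)
        )


def gen_wave_movie(
    gt: WaveGroundTruth,
    shape: tuple[int, int] = (48, 48),
    duration: float = 12.0,
    mask: np.ndarray | None = None,
    fo: float = 100.0,
):
    """Generate an activation movie (T, H, W) with a plane wavefront.

    Pixel onset time = gt.onset + (projection of the pixel position on the
    propagation direction) / speed; each pixel then follows the step-response
    kinetics of :func:`gen_sensor_trace`.  Outside-mask pixels stay constant.
    Returns ``(frames, mask, truth_dict)``.
    """
    from .front import ActivationMovie  # local import to avoid a cycle

    h, w = shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape or not mask.any():
        raise ValueError("degenerate cell mask")
    rng = np.random.default_rng(gt.seed)
    dt = 1.0 / gt.frame_rate_hz
    t = np.arange(0.0, duration, dt)
    yy, xx = np.mgrid[0:h, 0:w]
    proj_um = (yy * gt.direction[0] + xx * gt.direction[1]) * gt.pixel_size_um
    proj_um = proj_um - proj_um[mask].min()
    onset = gt.onset_s + proj_um / gt.speed_um_s
    rel = t[:, None, None] - onset[None, :, :]
    mag = np.where(rel > 0, 1.0 - np.exp(-np.maximum(rel, 0.0) / gt.tau_s), 0.0)
    sign = -1.0 if gt.polarity == "inverse" else 1.0
    dff = sign * gt.plateau_pct * mag
    frames = fo * (1.0 + dff / 100.0)
    frames = np.where(mask[None, :, :], frames, fo)
    if gt.noise_sigma_pct > 0:
        noise = rng.normal(0.0, gt.noise_sigma_pct / 100.0 * fo, size=frames.shape)
        frames = frames + np.where(mask[None, :, :], noise, 0.0)
    movie = ActivationMovie(
        frames=frames,
        frame_interval=dt,
        pixel_size=gt.pixel_size_um,
        mask=mask,
    )
    truth = {
        "speed_um_s": gt.speed_um_s,
        "direction": gt.direction,
        "onset_s": gt.onset_s,
        "arrival_offset_map": onset,
        "seed": gt.seed,
    }
    return movie, truth


def gen_dual_channel(
    lag_s: float,
    plateau_pct: float = 50.0,
    rise_time_s: float = 2.0,
    polarity: str = "direct",
    noise_sigma_pct: float = 0.0,
    stimulus_time: float = 2.0,
    duration: float = 30.0,
    sample_rate: float = 20.0,
    seed: int = 0,
):
    """Two traces where channel B repeats channel A's response ``lag_s`` later.

    Peaked (rise-then-fall) responses so each channel has a well-defined
    extremum; noise is independent between channels.  Returns
    ``(t, f_a, f_b, truth)``.
    """
    if abs(lag_s) >= duration / 2:
        raise ValueError("|lag| must be below half the duration")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    tau = tau_from_rise_time(rise_time_s)
    sign = -1.0 if polarity == "inverse" else 1.0
    fo = 100.0

    def response(t0: float) -> np.ndarray:
        rel = np.maximum(t - t0, 0.0)
        # gamma-like pulse: sharp rise, slower decay -> unique extremum
        pulse = (rel / tau) * np.exp(1.0 - rel / tau)
        pulse[t < t0] = 0.0
        return fo * (1.0 + sign * plateau_pct * pulse / 100.0)

    f_a = response(stimulus_time)
    f_b = response(stimulus_time + lag_s)
    if noise_sigma_pct > 0:
        f_a = f_a + fo * rng.normal(0.0, noise_sigma_pct / 100.0, size=t.shape)
        f_b = f_b + fo * rng.normal(0.0, noise_sigma_pct / 100.0, size=t.shape)
    truth = {
        "lag_s": lag_s,
        "peak_time_a_s": stimulus_time + tau,
        "peak_time_b_s": stimulus_time + lag_s + tau,
        "polarity": polarity,
        "seed": seed,
    }
    return t, f_a, f_b, truth
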