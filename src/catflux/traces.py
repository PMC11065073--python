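"""Fluorescence time-series analytics for ROI traces.

Covers the standard imaging workflow: per-ROI trace extraction from a
labelled movie, ΔF/F₀ normalization against a pre-stimulus baseline,
maximum-response and 5–95% rise-time kinetics, percentile-bootstrap
confidence intervals, dual-channel peak-to-peak latency, and Welch group
comparison.  Sensors may be direct (fluorescence rises with the analyte) or
inverse (falls); polarity is explicit throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

__all__ = [
    "ROITraceSet",
    "DffTrace",
    "KineticsResult",
    "CIResult",
    "LatencyResult",
    "NoResponseError",
    "extract_roi_traces",
    "dff",
    "max_response",
    "rise_time_5_95",
    "bootstrap_ci",
    "peak_latency",
    "compare_groups",
]

MIN_BASELINE_FRAMES = 5
DEFAULT_SMOOTH_FRAMES = 3
NOISE_FLOOR_SDS = 3.0


class NoResponseError(RuntimeError):
    """Raised when a trace's plateau does not clear the noise floor."""


@dataclass(frozen=True)
class ROITraceSet:
    """Per-ROI raw fluorescence traces on a shared time base."""

    roi_ids: np.ndarray
    traces: np.ndarray  # shape (n_roi, n_frames)
    frame_interval: float
    channel: str = ""
    stimulus_time: float | None = None

    def __post_init__(self) -> None:
        if self.traces.ndim != 2 or len(self.roi_ids) != self.traces.shape[0]:
            raise ValueError("traces must be (n_roi, n_frames) matching roi_ids")
        if np.any(self.traces < 0):
            raise ValueError("fluorescence must be non-negative")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.traces.shape[1]) * self.frame_interval


@dataclass(frozen=True)
class DffTrace:
    """ΔF/F₀ trace in percent, with its baseline bookkeeping."""

    t: np.ndarray
    dff: np.ndarray  # percent
    fo: float
    baseline_window: tuple[float, float]
    polarity: Literal["direct", "inverse"] = "direct"

    def __post_init__(self) -> None:
        if self.fo <= 0:
            raise ValueError("Fo must be positive")


@dataclass(frozen=True)
class KineticsResult:
    rise_time_5_95_s: float
    plateau_pct: float  # mean |dff| over the final 10% of the window
    t05_s: float
    t95_s: float


@dataclass(frozen=True)
class CIResult:
    estimate: float
    lo: float
    hi: float
    level: float
    n_boot: int
    seed: int


@dataclass(frozen=True)
class LatencyResult:
    lag_s: float  # extremum time of A minus extremum time of B
    peak_time_a_s: float
    peak_time_b_s: float


def extract_roi_traces(
    frames: np.ndarray,
    labels: np.ndarray,
    frame_interval: float,
    channel: str = "",
    stimulus_time: float | None = None,
    expected_ids: Sequence[int] | None = None,
) -> ROITraceSet:
    """Mean pixel value per ROI per frame, ROIs in ascending label order.

    ``labels`` is a label image (0 = background) with the movie's spatial
    shape.  Expected labels with no pixels are dropped with a warning.
    """
    frames = np.asarray(frames, dtype=float)
    labels = np.asarray(labels)
    if frames.ndim != 3 or labels.shape != frames.shape[1:]:
        raise ValueError("labels must match the movie's spatial shape")
    present = np.unique(labels)
    present = present[present > 0]
    if expected_ids is not None:
        missing = sorted(set(expected_ids) - set(present.tolist()))
        if missing:
            warnings.warn(f"ROI labels with no pixels dropped: {missing}", stacklevel=2)
        ids = np.array([i for i in sorted(expected_ids) if i in present])
    else:
        ids = present
    if len(ids) == 0:
        raise ValueError("no non-empty ROI labels")
    traces = np.stack([frames[:, labels == i].mean(axis=1) for i in ids])
    return ROITraceSet(
        roi_ids=ids,
        traces=traces,
        frame_interval=frame_interval,
        channel=channel,
        stimulus_time=stimulus_time,
    )


def _window_slice(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    sel = (t >= window[0]) & (t <= window[1])
    if not sel.any():
        raise ValueError(f"window {window} contains no samples")
    return sel


def dff(
    f: np.ndarray,
    t: np.ndarray,
    baseline_window: tuple[float, float] | None = None,
    stimulus_time: float | None = None,
    polarity: Literal["direct", "inverse"] = "direct",
) -> DffTrace:
    """ΔF/F₀ in percent against the mean fluorescence of the baseline window.

    The default window is all frames before ``stimulus_time`` (no fewer than
    five frames).  ``dff(t) = 100 (F(t) - Fo) / Fo``.
    """
    f = np.asarray(f, dtype=float)
    t = np.asarray(t, dtype=float)
    if baseline_window is None:
        if stimulus_time is None:
            raise ValueError("provide baseline_window or stimulus_time")
        baseline_window = (float(t[0]), float(stimulus_time))
    sel = _window_slice(t, baseline_window)
    if sel.sum() < MIN_BASELINE_FRAMES:
        raise ValueError(
            f"baseline window holds {int(sel.sum())} frames; "
            f"at least {MIN_BASELINE_FRAMES} required"
        )
    fo = float(f[sel].mean())
    if fo <= 0:
        raise ValueError("baseline fluorescence Fo must be positive")
    return DffTrace(
        t=t,
        dff=100.0 * (f - fo) / fo,
        fo=fo,
        baseline_window=baseline_window,
        polarity=polarity,
    )


def max_response(
    trace: DffTrace,
    window: tuple[float, float] | None = None,
    smooth_frames: int = DEFAULT_SMOOTH_FRAMES,
) -> float:
    """Signed extremum of ΔF/F₀ within the window (min for inverse sensors).

    A short moving average (default 3 frames) is applied first so a single
    noisy frame cannot set the response; pass ``smooth_frames=1`` to disable.
    """
    sel = (
        _window_slice(trace.t, window)
        if window is not None
        else np.ones(len(trace.t), dtype=bool)
    )
    if not sel.any():
        raise ValueError("empty response window")
    d = trace.dff
    if smooth_frames > 1:
        d = uniform_filter1d(d, size=smooth_frames, mode="nearest")
    seg = d[sel]
    return float(seg.min() if trace.polarity == "inverse" else seg.max())


def rise_time_5_95(
    trace: DffTrace,
    stimulus_time: float | None = None,
) -> KineticsResult:
    """5–95% rise time of the response magnitude after the stimulus.

    The plateau is the mean |ΔF/F₀| over the final 10% of the post-stimulus
    window; t05/t95 are the first linear-interpolated crossings of 5% and
    95% of that plateau.  Raises :class:`NoResponseError` when the plateau
    does not exceed three baseline standard deviations.
    """
    t, d = trace.t, np.abs(trace.dff)
    if stimulus_time is None:
        stimulus_time = trace.baseline_window[1]
    post = t >= stimulus_time
    if post.sum() < 10:
        raise ValueError("too few post-stimulus samples")
    tp, dp = t[post], d[post]
    tail = max(1, int(round(0.1 * len(dp))))
    plateau = float(dp[-tail:].mean())
    base_sel = _window_slice(t, trace.baseline_window)
    floor = NOISE_FLOOR_SDS * float(np.abs(trace.dff)[base_sel].std())
    if plateau <= floor:
        raise NoResponseError(
            f"no response: plateau {plateau:.3g}% <= noise floor {floor:.3g}%"
        )

    def first_crossing(level: float) -> float:
        above = np.nonzero(dp >= level)[0]
        if len(above) == 0:
            raise NoResponseError(f"response never reaches {level:.3g}%")
        j = int(above[0])
        if j == 0:
            return float(tp[0])
        frac = (level - dp[j - 1]) / (dp[j] - dp[j - 1])
        return float(tp[j - 1] + frac * (tp[j] - tp[j - 1]))

    t05 = first_crossing(0.05 * plateau)
    t95 = first_crossing(0.95 * plateau)
    return KineticsResult(
        rise_time_5_95_s=t95 - t05, plateau_pct=plateau, t05_s=t05, t95_s=t95
    )


def bootstrap_ci(
    values: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_boot: int = 10_000,
    level: float = 95.0,
    seed: int | None = None,
) -> CIResult:
    """Seeded percentile bootstrap of a statistic's central tendency."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot = np.apply_along_axis(statistic, 1, values[idx]) \
        if statistic is not np.mean else values[idx].mean(axis=1)
    alpha = (100.0 - level) / 2.0
    lo, hi = np.percentile(boot, [alpha, 100.0 - alpha])
    return CIResult(
        estimate=float(statistic(values)),
        lo=float(lo),
        hi=float(hi),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )


def peak_latency(chan_a: DffTrace, chan_b: DffTrace) -> LatencyResult:
    """Peak-to-peak lag between two channels (extremum time A − B).

    Each channel's extremum respects its own polarity.  Raises when either
    channel lacks a finite extremum.
    """
    if len(chan_a.t) != len(chan_b.t) or not np.allclose(chan_a.t, chan_b.t):
        raise ValueError("channels must share a common time base")

    def extremum_time(tr: DffTrace) -> float:
        d = tr.dff
        if not np.isfinite(d).all() or np.ptp(d) == 0:
            raise ValueError("channel has no detectable extremum")
        i = int(np.argmin(d) if tr.polarity == "inverse" else np.argmax(d))
        return float(tr.t[i])

    ta, tb = extremum_time(chan_a), extremum_time(chan_b)
    return LatencyResult(lag_s=ta - tb, peak_time_a_s=ta, peak_time_b_s=tb)


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided independent-samples t test (Welch by default).

    Degenerate zero-variance cases follow the documented convention:
    identical constants compare equal (t=0, p=1); distinct constants give
    p → 0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("degenerate: zero variance with unequal means", stacklevel=2)
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t_stat, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t_stat), float(p)
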