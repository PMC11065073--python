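"""1-D and 2-D perturbation scans over the calcium-handling model.

A scan runs the simulator over a Cartesian grid of perturbation multipliers
(SERCA uptake, SR leak, L-type conductance, IK1) and phenotypes every grid
point.  Axis values are constructed by integer stepping and rounded to the
step's decimals, so grids like 0.1..1.0 step 0.1 are exact and round-trip
through CSV bit-identically.  Per-point simulation failures are recorded in
the ``converged`` column rather than aborting the scan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    MinimalParams,
    PerturbScales,
    SimConfig,
    SimulationError,
    default_params,
    simulate,
)
from .phenotypes import analyze_trace

__all__ = ["ScanSpec", "ScanResult", "scale_axis", "build_grid", "run_scan"]

SCAN_PARAMETERS = ("serca", "leak", "gcal", "ik1")

SCAN_COLUMNS = [
    "serca_scale",
    "leak_scale",
    "gcal_scale",
    "ik1_scale",
    "baseline_uM",
    "amplitude_uM",
    "ttp_s",
    "catd90_s",
    "rate_hz",
    "converged",
]


def scale_axis(start: float, stop: float, step: float) -> list[float]:
    """Build an exact, drift-free axis: start, start+step, ..., stop.

    Values are constructed as ``start + i*step`` and rounded to the step's
    decimal places, avoiding 0.1-accumulation float drift.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    decimals = max(0, -int(np.floor(np.log10(step))) + 1)
    n = int(round((stop - start) / step)) + 1
    vals = [round(start + i * step, decimals) for i in range(n)]
    if not vals or abs(vals[-1] - stop) > step * 1e-6:
        raise ValueError(f"({start}, {stop}) is not an integer number of steps {step}")
    return vals


@dataclass(frozen=True)
class ScanSpec:
    """Axes (ordered!) plus fixed scales and the shared simulation config."""

    axes: tuple[tuple[str, tuple[float, ...]], ...]
    fixed: PerturbScales = PerturbScales()
    config: SimConfig = SimConfig()

    def __post_init__(self) -> None:
        axes = tuple((name, tuple(vals)) for name, vals in self.axes)
        object.__setattr__(self, "axes", axes)
        if len(axes) == 0:
            raise ValueError("at least one scan axis is required")
        seen = set()
        for name, vals in axes:
            if name not in SCAN_PARAMETERS:
                raise ValueError(
                    f"unknown scan parameter {name!r}; expected one of {SCAN_PARAMETERS}"
                )
            if name in seen:
                raise ValueError(f"duplicate axis {name!r}")
            seen.add(name)
            if len(vals) == 0:
                raise ValueError(f"axis {name!r} is empty")
            if len(vals) >= 2:
                if len(set(vals)) != len(vals) or list(vals) != sorted(vals):
                    raise ValueError(
                        f"axis {name!r} values must be distinct and strictly increasing"
                    )
            if any(v <= 0 for v in vals):
                raise ValueError(f"axis {name!r} values must be positive")


@dataclass(frozen=True)
class ScanResult:
    """One record per grid point, in grid (row-major) order."""

    table: pd.DataFrame
    spec: ScanSpec

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_grid(spec: ScanSpec) -> list[PerturbScales]:
    """Cartesian product of the axes, first axis slowest (row-major)."""
    names = [name for name, _ in spec.axes]
    value_lists = [vals for _, vals in spec.axes]
    fixed = spec.fixed.as_dict()
    grid = []
    for combo in itertools.product(*value_lists):
        d = dict(fixed)
        d.update(dict(zip(names, combo)))
        grid.append(PerturbScales(**d))
    return grid


def run_scan(spec: ScanSpec, params: MinimalParams | None = None) -> ScanResult:
    """Simulate and phenotype every grid point.

    Point failures (solver non-convergence, undetectable transients) are
    recorded with ``converged=False`` and NaN phenotypes.  Raises if every
    point fails.
    """
    if params is None:
        params = default_params()
    grid = build_grid(spec)
    rows = []
    for scales in grid:
        row = {
            "serca_scale": scales.serca,
            "leak_scale": scales.leak,
            "gcal_scale": scales.gcal,
            "ik1_scale": scales.ik1,
        }
        try:
            ph = analyze_trace(simulate(scales, spec.config, params))
            row.update(
                baseline_uM=ph.baseline,
                amplitude_uM=ph.amplitude,
                ttp_s=ph.ttp_s,
                catd90_s=ph.catd90_s,
                rate_hz=ph.rate_hz,
                converged=True,
            )
        except (SimulationError, ValueError):
            row.update(
                baseline_uM=np.nan,
                amplitude_uM=np.nan,
                ttp_s=np.nan,
                catd90_s=np.nan,
                rate_hz=np.nan,
                converged=False,
            )
        rows.append(row)
    table = pd.DataFrame(rows, columns=SCAN_COLUMNS)
    if not table["converged"].any():
        raise SimulationError("every grid point failed to simulate")
    return ScanResult(table=table, spec=spec)
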