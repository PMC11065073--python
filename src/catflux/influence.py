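"""Additively weighted CaT influence map over a 2-D perturbation grid.

Each phenotype array from a gCaL × SERCA scan is normalized to [0, 1]
(min–max over converged cells; a constant array maps to zeros so that zero
variation contributes nothing), and the normalized arrays are combined by
an additive weighted mean.  The axis-bias statistic compares the map's mean
absolute sensitivity per unit of gCaL multiplier against per unit of SERCA
multiplier; a ratio above 1 means L-type conductance dominates the
phenotypic response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeGrid",
    "InfluenceConfig",
    "normalize_phenotype",
    "influence_map",
    "axis_bias",
]

PHENOTYPE_KEYS = ("baseline", "amplitude", "ttp", "catd90")

_SCAN_COLUMN_OF = {
    "baseline": "baseline_uM",
    "amplitude": "amplitude_uM",
    "ttp": "ttp_s",
    "catd90": "catd90_s",
}


@dataclass(frozen=True)
class PhenotypeGrid:
    """Phenotype arrays over a (gcal × serca) grid, with a failure mask."""

    gcal_values: np.ndarray  # shape (n_g,)
    serca_values: np.ndarray  # shape (n_s,)
    arrays: dict[str, np.ndarray]  # each shape (n_g, n_s)
    mask: np.ndarray  # True where the point did NOT converge

    def __post_init__(self) -> None:
        shape = (len(self.gcal_values), len(self.serca_values))
        for k, a in self.arrays.items():
            if a.shape != shape:
                raise ValueError(f"array {k!r} has shape {a.shape}, expected {shape}")
        if self.mask.shape != shape:
            raise ValueError("mask shape mismatch")

    @classmethod
    def from_scan_table(cls, table: pd.DataFrame) -> "PhenotypeGrid":
        """Pivot a scan table (one row per grid point) into phenotype arrays."""
        gcal = np.array(sorted(table["gcal_scale"].unique()))
        serca = np.array(sorted(table["serca_scale"].unique()))
        if len(gcal) * len(serca) != len(table):
            raise ValueError("scan table is not a full 2-D gcal × serca grid")
        arrays = {}
        for key, col in _SCAN_COLUMN_OF.items():
            piv = table.pivot(index="gcal_scale", columns="serca_scale", values=col)
            arrays[key] = piv.loc[gcal, serca].to_numpy(dtype=float)
        conv = table.pivot(
            index="gcal_scale", columns="serca_scale", values="converged"
        ).loc[gcal, serca].to_numpy(dtype=bool)
        mask = ~conv
        for a in arrays.values():
            mask |= np.isnan(a)
        return cls(gcal_values=gcal, serca_values=serca, arrays=arrays, mask=mask)


@dataclass(frozen=True)
class InfluenceConfig:
    """Weights and normalization mode for the additive map."""

    weights: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in PHENOTYPE_KEYS}
    )
    mode: Literal["minmax", "zscore"] = "minmax"
    # Per-phenotype sign override (+1/-1); all phenotypes increase under the
    # stress directions studied, so no flipping by default.
    direction: dict[str, int] = field(
        default_factory=lambda: {k: 1 for k in PHENOTYPE_KEYS}
    )

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        if sum(self.weights.values()) <= 0:
            raise ValueError("at least one weight must be positive")


def normalize_phenotype(
    array: np.ndarray,
    mask: np.ndarray | None = None,
    mode: Literal["minmax", "zscore"] = "minmax",
) -> np.ndarray:
    """Normalize a phenotype array over its unmasked cells.

    Min–max maps onto [0, 1]; a constant array maps to all zeros.  Masked
    cells come back as NaN.
    """
    a = np.asarray(array, dtype=float)
    if mask is None:
        mask = np.zeros(a.shape, dtype=bool)
    valid = ~mask & ~np.isnan(a)
    if not valid.any():
        raise ValueError("all cells are masked")
    out = np.full(a.shape, np.nan)
    vals = a[valid]
    if mode == "minmax":
        lo, hi = vals.min(), vals.max()
        out[valid] = (vals - lo) / (hi - lo) if hi > lo else 0.0
    elif mode == "zscore":
        mu, sd = vals.mean(), vals.std()
        out[valid] = (vals - mu) / sd if sd > 0 else 0.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return out


def influence_map(grid: PhenotypeGrid, cfg: InfluenceConfig | None = None) -> np.ndarray:
    """Weighted additive combination of the normalized phenotype arrays.

    ``map = Σ_k w_k · normalize(phenotype_k) / Σ_k w_k``; with min–max
    normalization the result lies in [0, 1] on unmasked cells.
    """
    cfg = cfg or InfluenceConfig()
    total = np.zeros(
        (len(grid.gcal_values), len(grid.serca_values)), dtype=float
    )
    wsum = 0.0
    for key, w in cfg.weights.items():
        if key not in grid.arrays:
            raise ValueError(f"phenotype {key!r} missing from the grid")
        if w == 0:
            continue
        arr = grid.arrays[key] * cfg.direction.get(key, 1)
        total += w * normalize_phenotype(arr, grid.mask, cfg.mode)
        wsum += w
    return total / wsum


def axis_bias(
    map_array: np.ndarray,
    gcal_values: np.ndarray,
    serca_values: np.ndarray,
) -> tuple[float, float, float]:
    """Mean |∂map/∂gcal|, mean |∂map/∂serca| (per unit multiplier), and ratio.

    Central finite differences in scale units over unmasked (finite) cells.
    A zero SERCA sensitivity yields an infinite ratio.
    """
    gcal_values = np.asarray(gcal_values, dtype=float)
    serca_values = np.asarray(serca_values, dtype=float)
    if len(gcal_values) < 2 or len(serca_values) < 2:
        raise ValueError("both axes need at least two levels")
    dg = np.gradient(map_array, gcal_values, axis=0)
    ds = np.gradient(map_array, serca_values, axis=1)
    g_sens = float(np.nanmean(np.abs(dg)))
    s_sens = float(np.nanmean(np.abs(ds)))
    # snap float-epsilon residue from the finite differences to an exact zero
    floor = 1e-12 * max(g_sens, s_sens, 1.0)
    g_sens = 0.0 if g_sens < floor else g_sens
    s_sens = 0.0 if s_sens < floor else s_sens
    ratio = g_sens / s_sens if s_sens > 0 else math.inf
    return g_sens, s_sens, ratio
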