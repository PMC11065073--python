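"""Optional "ported" backend: a faithful published hiPSC-CM ionic model.

The exact published ionic model is not redistributed with this package; the
backend ingests a user-supplied model source instead.  Point
``CATFLUX_PORTED_MODEL`` (environment variable) or the ``model_source``
argument at a Python file that defines:

``STATES``
    1-D sequence of initial state values.
``CAI_INDEX``
    index of cytosolic [Ca²⁺] (µM or mM — documented by the source) in the
    state vector.
``VM_INDEX``
    index of the membrane potential (mV) in the state vector.
``rhs(t, y, scales)``
    the model derivatives; ``scales`` is a dict with keys
    ``serca, leak, gcal, ik1`` that the source must apply to its own
    maximal-flux/conductance parameters (multiplicatively).

The source must document which published model and variant it implements.
With such a source in place the unmodified model is expected to beat at
1.1 Hz and, with IK1 scaled by 1.71484375, at 0.5 Hz.
"""

from __future__ import annotations

import importlib.util
import os
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .model import CaTrace, PerturbScales, SimConfig, SimulationError

__all__ = ["PortedModelUnavailable", "load_model_source", "simulate_ported"]

ENV_VAR = "CATFLUX_PORTED_MODEL"


class PortedModelUnavailable(RuntimeError):
    """Raised when no ported model source is configured."""

    def __init__(self) -> None:
        super().__init__(
            "the 'ported' backend needs an external ionic-model source: set "
            f"the {ENV_VAR} environment variable (or pass model_source=) to a "
            "Python file defining STATES, CAI_INDEX, VM_INDEX and "
            "rhs(t, y, scales); see catflux.ported module docs"
        )


def load_model_source(model_source: str | os.PathLike | None = None):
    """Import and validate a user-supplied ported-model module."""
    path = model_source or os.environ.get(ENV_VAR)
    if not path:
        raise PortedModelUnavailable()
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"ported model source not found: {path}")
    spec = importlib.util.spec_from_file_location("catflux_ported_model", path)
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)  # type: ignore[union-attr]
    for attr in ("STATES", "CAI_INDEX", "VM_INDEX", "rhs"):
        if not hasattr(mod, attr):
            raise ValueError(f"ported model source lacks required attribute {attr!r}")
    return mod


def simulate_ported(
    scales: PerturbScales,
    config: SimConfig,
    model_source: str | os.PathLike | None = None,
) -> tuple[CaTrace, CaTrace]:
    """Run the ported backend; returns (Cai trace, membrane-potential trace)."""
    mod = load_model_source(model_source)
    scale_dict = scales.as_dict()

    def rhs(t, y):
        return mod.rhs(t, y, scale_dict)

    t_eval = np.arange(0.0, config.duration, 1.0 / config.sample_rate)
    sol = solve_ivp(
        rhs,
        (0.0, config.duration),
        np.asarray(mod.STATES, dtype=float),
        method="LSODA",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise SimulationError(
            f"ported model failed at rtol={config.rtol}, atol={config.atol}: "
            f"{sol.message}"
        )
    keep = sol.t >= config.discard
    t = sol.t[keep] - config.discard
    cai = sol.y[mod.CAI_INDEX][keep]
    if np.any(cai <= 0):
        raise SimulationError("negative-state excursion in ported Cai")
    vm = sol.y[mod.VM_INDEX][keep]
    fs = config.sample_rate
    return (
        CaTrace(t, cai, kind="cai", sample_rate=fs),
        CaTrace(t, vm, kind="vm", sample_rate=fs),
    )
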