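"""Shared fixtures: the calibrated model and reference scans are expensive,
so they are computed once per session and reused across test modules."""

import numpy as np
import pytest

from catflux.model import PerturbScales, SimConfig, default_params, simulate_full
from catflux.scan import ScanSpec, run_scan, scale_axis


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def sim_default(params):
    return simulate_full(PerturbScales(), SimConfig(), params)


@pytest.fixture(scope="session")
def sim_slow_ik1(params):
    from catflux.model import IK1_RATE_ANCHOR_SCALE

    return simulate_full(
        PerturbScales(ik1=IK1_RATE_ANCHOR_SCALE),
        SimConfig(duration=50.0, discard=20.0),
        params,
    )


@pytest.fixture(scope="session")
def serca_scan(params):
    spec = ScanSpec(axes=(("serca", tuple(scale_axis(0.1, 1.0, 0.1))),))
    return run_scan(spec, params)


@pytest.fixture(scope="session")
def gcal_scan(params):
    spec = ScanSpec(axes=(("gcal", tuple(scale_axis(1.0, 2.0, 0.1))),))
    return run_scan(spec, params)


@pytest.fixture(scope="session")
def leak_scan(params):
    spec = ScanSpec(axes=(("leak", (1.0, 2.0)),))
    return run_scan(spec, params)


@pytest.fixture(scope="session")
def grid_scan(params):
    """The full 11x10 gCaL x SERCA perturbation grid."""
    spec = ScanSpec(
        axes=(
            ("gcal", tuple(scale_axis(1.0, 2.0, 0.1))),
            ("serca", tuple(scale_axis(0.1, 1.0, 0.1))),
        )
    )
    return run_scan(spec, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
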