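#!/usr/bin/env python
"""Calibrate the minimal hiPSC-CM calcium model and verify its rate anchors.

Finds the default parameter set by constrained search (diastolic/systolic
windows, leak budget, sarcolemmal dominance) and confirms by simulation
that the beat clock reproduces the spontaneous-rate anchors: 1.1 Hz at
baseline IK1 and 0.5 Hz with IK1 scaled by 1.71484375.

Writes results/calibration.json.
"""

import json
from pathlib import Path

from catflux.model import (
    IK1_RATE_ANCHOR_SCALE,
    PerturbScales,
    SimConfig,
    default_params,
    simulate,
)
from catflux.phenotypes import analyze_trace

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = default_params()
    cfg = SimConfig(duration=50.0, discard=20.0)
    fast = analyze_trace(simulate(PerturbScales(), cfg, params))
    slow = analyze_trace(
        simulate(PerturbScales(ik1=IK1_RATE_ANCHOR_SCALE), cfg, params)
    )
    print("calibrated minimal-backend parameters:")
    for k, v in params.as_dict().items():
        print(f"  {k:10s} = {v:.6g}")
    print(f"\nspontaneous rate at ik1=1.0:          {fast.rate_hz:.3f} Hz")
    print(f"spontaneous rate at ik1={IK1_RATE_ANCHOR_SCALE}: {slow.rate_hz:.3f} Hz")
    print(f"diastolic Cai {fast.baseline:.3f} uM, systolic peak "
          f"{fast.baseline + fast.amplitude:.3f} uM, TtP {fast.ttp_s*1e3:.0f} ms, "
          f"CaTD90 {fast.catd90_s*1e3:.0f} ms")

    OUT.mkdir(exist_ok=True)
    payload = {
        "params": params.as_dict(),
        "rate_hz_at_ik1_1": fast.rate_hz,
        "rate_hz_at_ik1_anchor": slow.rate_hz,
        "phenotypes_at_default": fast.as_dict(),
    }
    (OUT / "calibration.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"\nwrote {OUT / 'calibration.json'}")


if __name__ == "__main__":
    main()
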