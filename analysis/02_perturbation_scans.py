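#!/usr/bin/env python
"""One-dimensional perturbation scans of the calcium-handling model.

Reproduces the single-axis stress sweeps: SERCA uptake reduced 1.0 -> 0.1,
L-type conductance and SR leak each raised 1.0 -> 2.0 (0.1 steps), with all
other scales at 1.0.  Reports the directional phenotype trends — lowering
SERCA raises diastolic Ca, TtP and CaTD90; raising ICaL raises baseline
and amplitude; raising SR leak barely moves anything.

Writes results/scan_serca.csv, scan_gcal.csv, scan_leak.csv.
"""

from pathlib import Path

import numpy as np

from catflux.model import default_params
from catflux.scan import ScanSpec, run_scan, scale_axis

OUT = Path(__file__).resolve().parents[1] / "results"


def trend(series, ascending: bool) -> str:
    d = np.diff(series)
    ok = (d >= 0).all() if ascending else (d <= 0).all()
    return "monotone" if ok else "non-monotone"


def main() -> None:
    params = default_params()
    OUT.mkdir(exist_ok=True)

    axes = {
        "serca": tuple(scale_axis(0.1, 1.0, 0.1)),
        "gcal": tuple(scale_axis(1.0, 2.0, 0.1)),
        "leak": tuple(scale_axis(1.0, 2.0, 0.1)),
    }
    tables = {}
    for name, values in axes.items():
        result = run_scan(ScanSpec(axes=((name, values),)), params)
        path = OUT / f"scan_{name}.csv"
        result.to_csv(path)
        tables[name] = result.table
        print(f"wrote {path} ({len(result.table)} points, "
              f"{int(result.table['converged'].sum())} converged)")

    serca = tables["serca"].sort_values("serca_scale", ascending=False)
    print("\nSERCA 1.0 -> 0.1 (stress direction):")
    for col in ("baseline_uM", "ttp_s", "catd90_s"):
        lo, hi = serca[col].iloc[0], serca[col].iloc[-1]
        print(f"  {col:12s} {lo:.4f} -> {hi:.4f}  [{trend(serca[col], True)}]")

    gcal = tables["gcal"]
    print("ICaL 1.0 -> 2.0:")
    for col in ("baseline_uM", "amplitude_uM"):
        lo, hi = gcal[col].iloc[0], gcal[col].iloc[-1]
        print(f"  {col:12s} {lo:.4f} -> {hi:.4f}  [{trend(gcal[col], True)}]")

    leak = tables["leak"]
    print("SR leak 1.0 -> 2.0 (comparative insensitivity vs SERCA 1.0 -> 0.5):")
    s_by = tables["serca"].set_index("serca_scale")
    for col in ("baseline_uM", "amplitude_uM", "ttp_s", "catd90_s"):
        d_leak = abs(leak[col].iloc[-1] - leak[col].iloc[0])
        d_serca = abs(s_by.loc[0.5, col] - s_by.loc[1.0, col])
        print(f"  {col:12s} |d_leak| = {d_leak:.5f}  vs  |d_serca50| = "
              f"{d_serca:.5f}  ({'smaller' if d_leak < d_serca else 'LARGER'})")


if __name__ == "__main__":
    main()
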