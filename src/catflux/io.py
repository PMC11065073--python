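"""File formats and run provenance.

Plain-text first: traces and scans travel as CSV, summaries as JSON,
image stacks and maps as TIFF (via :mod:`tifffile`).  Every CLI run writes
a manifest recording the full parameter set, seeds, SHA-256 digests of all
inputs and outputs, a timestamp and the code version, so deterministic
commands can be re-verified digest-for-digest.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CaTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_map_csv",
    "read_map_csv",
    "write_json",
    "read_json",
    "write_tiff",
    "read_tiff",
    "sha256_file",
    "RunManifest",
]


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_trace_csv(path, trace: CaTrace, value_column: str | None = None) -> None:
    col = value_column or ("cai_uM" if trace.kind == "cai" else "value")
    pd.DataFrame({"time_s": trace.t, col: trace.value}).to_csv(path, index=False)


def read_trace_csv(path, kind: str | None = None) -> CaTrace:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time_s,<value>")
    value_col = [c for c in df.columns if c != "time_s"][0]
    if kind is None:
        kind = "cai" if value_col == "cai_uM" else "fluorescence"
    return CaTrace(df["time_s"].to_numpy(), df[value_col].to_numpy(), kind=kind)


def write_map_csv(path, array: np.ndarray, row_values, col_values) -> None:
    """2-D map with a header row/column of axis values (rows gcal, cols serca)."""
    df = pd.DataFrame(array, index=list(row_values), columns=list(col_values))
    df.to_csv(path, index_label="gcal\\serca")


def read_map_csv(path):
    df = pd.read_csv(path, index_col=0)
    return (
        df.to_numpy(dtype=float),
        df.index.to_numpy(dtype=float),
        df.columns.to_numpy(dtype=float),
    )


def write_json(path, payload) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, allow_nan=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_tiff(path, array: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Provenance record for a pipeline command."""

    def __init__(self, command: str, parameters: dict, seed: int | None = None):
        from . import __version__

        self.payload = {
            "command": command,
            "parameters": _jsonable(parameters),
            "seed": seed,
            "inputs": {},
            "outputs": {},
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "code_version": __version__,
            "python": platform.python_version(),
        }

    def add_input(self, path) -> None:
        self.payload["inputs"][str(path)] = sha256_file(path)

    def add_output(self, path) -> None:
        self.payload["outputs"][str(path)] = sha256_file(path)

    def write(self, path) -> None:
        write_json(path, self.payload)
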