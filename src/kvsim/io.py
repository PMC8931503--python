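"""File formats: trace CSV, feature tables, config/result JSON, run manifests.

Traces travel as long-format CSV with columns ``time_ms, current_pApf,
v_step_mv, kind`` (one block per step potential); features as CSV
``kind,v_step_mv,A,tau,C,rss,converged``; parameters, GA configuration and
results as JSON.  Every stochastic command records a run manifest (command,
config snapshot, seed, package version, timestamp, outputs) so any run can be
reproduced through the library API alone.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import GAConfig
from .clamp import CurrentTrace

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "write_features_csv",
    "read_ga_config",
    "write_json",
    "write_manifest",
]

TRACE_COLUMNS = ["time_ms", "current_pApf", "v_step_mv", "kind"]


def write_trace_csv(traces, path) -> None:
    """Write one or more traces as long-format CSV at full float precision."""
    if isinstance(traces, CurrentTrace):
        traces = [traces]
    frames = [tr.to_frame() for tr in traces]
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace_csv(path) -> list[CurrentTrace]:
    """Read a trace CSV; long-format files split into one trace per step."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; header must "
            f"contain {TRACE_COLUMNS}"
        )
    traces = []
    for (v_step, kind), grp in df.groupby(["v_step_mv", "kind"], sort=False):
        t = grp["time_ms"].to_numpy(dtype=float)
        I = grp["current_pApf"].to_numpy(dtype=float)
        if len(t) != len(I):
            raise ValueError(f"{path}: time/current length mismatch at step {v_step}")
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if bad.size:
            line = grp.index[bad[0] + 1] + 2  # header + 0-based index
            raise ValueError(
                f"{path}: non-monotone time at line {line} (step {v_step} mV)"
            )
        traces.append(CurrentTrace(t, I, float(v_step), str(kind)))
    if not traces:
        raise ValueError(f"{path}: no trace rows found")
    return traces


def write_features_csv(rows, path) -> None:
    """Write extracted features; rows are dicts with the standard columns."""
    df = pd.DataFrame(rows)
    cols = ["kind", "v_step_mv", "A", "tau", "C", "rss", "converged"]
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(path, index=False, float_format="%.17g")


def read_ga_config(path) -> GAConfig:
    with open(path) as fh:
        data = json.load(fh)
    fields = {f.name for f in dataclasses.fields(GAConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"{path}: unknown GA config keys {sorted(unknown)}")
    return GAConfig(**data)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        if isinstance(o, pd.Series):
            return o.to_dict()
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_Encoder)
        fh.write("\n")


def write_manifest(command: str, config: dict, seed, outputs, path) -> dict:
    """Record how a run was produced; the seed is captured before use."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seed": seed,
        "package_version": __version__,
        "python": sys.version.split()[0],
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(Path(p)) for p in outputs],
    }
    write_json(manifest, path)
    return manifest
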