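"""Plain-text readers/writers for traces, events and block summaries.

Traces are two-column TSV (time_ms, voltage_mV) with a JSON sidecar holding
dt, seed and protocol/parameter provenance; events and summaries are
TSV/CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import BlockSummary, Event
from .simulate import Trace

__all__ = [
    "write_trace", "read_trace",
    "write_events", "read_events",
    "write_summaries", "read_summaries",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"time_ms": trace.times, "voltage_mV": trace.voltages})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = dict(trace.meta)
    meta.update({"dt": trace.dt, "seed": trace.seed,
                 "n_samples": len(trace)})
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    t = df["time_ms"].to_numpy()
    if len(t) > 1:
        dt = float(t[1] - t[0])
    else:
        dt = float(meta.get("dt", 0.1))
    return Trace(voltages=df["voltage_mV"].to_numpy(dtype=float), dt=dt,
                 seed=meta.get("seed"), meta=meta)


def write_events(events: list[Event], path: str | Path) -> None:
    rows = [{"t_start_ms": e.t_start, "t_end_ms": e.t_end,
             "duration_ms": e.duration, "peak_mV": e.peak, "class": e.kind,
             "truncated": e.truncated} for e in events]
    pd.DataFrame(rows, columns=["t_start_ms", "t_end_ms", "duration_ms",
                                "peak_mV", "class", "truncated"]).to_csv(
        path, sep="\t", index=False)


def read_events(path: str | Path) -> list[Event]:
    df = pd.read_csv(path, sep="\t")
    return [Event(t_start=r["t_start_ms"], t_end=r["t_end_ms"],
                  peak=r["peak_mV"], kind=r["class"],
                  truncated=bool(r["truncated"]))
            for _, r in df.iterrows()]


def write_summaries(summaries: list[BlockSummary], path: str | Path) -> None:
    pd.DataFrame([s.as_dict() for s in summaries]).to_csv(path, index=False)


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
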