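"""Small IO helpers: trace CSV round-trip and tidy measurement tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .traces import APTrace


def write_trace_csv(trace: APTrace, path: str | Path) -> None:
    """Write a trace as two-column CSV (t_ms, V_mV)."""
    pd.DataFrame({"t_ms": trace.t, "V_mV": trace.values}).to_csv(
        path, index=False)


def read_trace_csv(path: str | Path) -> APTrace:
    df = pd.read_csv(path)
    t = df["t_ms"].to_numpy(dtype=float)
    dts = np.diff(t)
    if dts.size == 0 or np.ptp(dts) > 1e-6 * dts[0]:
        raise ValueError("trace CSV must be uniformly sampled")
    return APTrace(dt=float(dts[0]), values=df["V_mV"].to_numpy(dtype=float),
                   t0=float(t[0]))


def read_nested_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy (group, animal, slice, value) measurement table."""
    df = pd.read_csv(path)
    required = {"group", "animal", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"nested CSV missing columns: {sorted(missing)}")
    return df
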