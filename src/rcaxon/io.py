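"""Plain-text trace I/O.

Traces are stored as two-column CSV (time_s, voltage_V) with a structured
``#``-comment header carrying the sampling step, averaging count and any
metadata, e.g.::

    # dt_s = 2.5e-09
    # n_averages = 16
    # condition = emf
    time_s,voltage_V
    0.0,-1.34e+00
    ...

The reader tolerates oscilloscope-style scientific notation and unknown
header keys (kept as string metadata).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .circuit import Trace

__all__ = ["read_trace", "write_trace"]

_NUMERIC_META = {"t_min", "c_true"}


def write_trace(trace: Trace, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# dt_s = {trace.dt!r}", f"# n_averages = {trace.n_averages}"]
    for key, value in trace.metadata.items():
        lines.append(f"# {key} = {value}")
    header = "\n".join(lines)
    body = pd.DataFrame({"time_s": trace.times, "voltage_V": trace.voltages}).to_csv(
        index=False, float_format="%.9e"
    )
    path.write_text(header + "\n" + body)


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        key, _, value = line.lstrip("# ").partition("=")
        meta[key.strip()] = value.strip()
    dt = float(meta.pop("dt_s", "nan"))
    n_averages = int(meta.pop("n_averages", "1"))
    for key in list(meta):
        if key in _NUMERIC_META:
            meta[key] = float(meta[key])
    frame = pd.read_csv(path, skiprows=n_header)
    times = frame["time_s"].to_numpy(dtype=float)
    volts = frame["voltage_V"].to_numpy(dtype=float)
    if math.isnan(dt):
        dt = float(np.median(np.diff(times))) if times.size > 1 else float("nan")
    return Trace(times=times, voltages=volts, dt=dt, n_averages=n_averages, metadata=meta)
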