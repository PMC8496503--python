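"""Trace serialization: CSV with a JSON metadata header.

The on-disk format is plain text: comment lines ``# hhmem-trace v1`` and
``# meta: {...}`` followed by an ordinary CSV table with a ``t`` column and
one column per recorded series.  Floats are written with their shortest
round-trip representation and parsed back with the correctly rounding
converter, so a round trip preserves every series bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Trace

__all__ = ["write_trace", "read_trace", "TraceParseError"]

_MAGIC = "# hhmem-trace v1"


class TraceParseError(ValueError):
    """Malformed trace file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


def write_trace(path: str | Path, trace: Trace) -> None:
    path = Path(path)
    df = trace.to_dataframe()
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write("# meta: " + json.dumps(trace.metadata, default=str) + "\n")
        # default float formatting is the shortest round-trip repr
        df.to_csv(fh, index=False)


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise TraceParseError(f"not a trace file (expected {_MAGIC!r})", line=1)
        pos = 2
        line = fh.readline().rstrip("\n")
        while line.startswith("#"):
            if line.startswith("# meta: "):
                try:
                    meta = json.loads(line[len("# meta: "):])
                except json.JSONDecodeError as exc:
                    raise TraceParseError(f"bad metadata JSON: {exc}", line=pos) from exc
            pos += 1
            line = fh.readline().rstrip("\n")
        header_line = pos
        if not line:
            raise TraceParseError("missing CSV header", line=header_line)
        try:
            df = pd.read_csv(path, comment="#", float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise TraceParseError(f"unparseable CSV body: {exc}", line=header_line) from exc
    if "t" not in df.columns:
        raise TraceParseError("missing required column 't'", line=header_line)
    if "V" not in df.columns:
        raise TraceParseError("missing required column 'V'", line=header_line)
    t = df["t"].to_numpy(float)
    data = {c: df[c].to_numpy(float) for c in df.columns if c != "t"}
    return Trace(t=t, data=data, metadata=meta)
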