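"""Synthetic analytic traces for exercising the analysis layer without
running a simulation: sines, rectangle trains, decaying exponentials and
constants, packaged as ordinary :class:`~hhmem.simulate.Trace` objects with
only a voltage series."""

from __future__ import annotations

import numpy as np

from .simulate import Trace

__all__ = ["make_fixture"]


def make_fixture(kind: str, duration: float = 20.0, dt: float = 0.005, **params) -> Trace:
    """Build a synthetic voltage trace.

    kind
        ``constant`` (value), ``sine`` (amplitude, offset, period),
        ``rectangles`` (n, high, low, period, width), or
        ``decaying_exp`` (amplitude, offset, tau).
    """
    t = np.arange(int(round(duration / dt)) + 1) * dt
    if kind == "constant":
        V = np.full_like(t, params.get("value", -65.0))
    elif kind == "sine":
        amp = params.get("amplitude", 40.0)
        off = params.get("offset", -10.0)
        per = params.get("period", 5.0)
        V = amp * np.sin(2 * np.pi * t / per) + off
    elif kind == "rectangles":
        n = params.get("n", 3)
        high = params.get("high", 20.0)
        low = params.get("low", -65.0)
        onset = params.get("onset", 1.0)  # start low so each event is a crossing
        per = params.get("period", (duration - onset) / max(n, 1))
        width = params.get("width", per / 2)
        tt = np.mod(t - onset, per)
        V = np.where((t >= onset) & (tt < width) & (t - onset < n * per), high, low)
    elif kind == "decaying_exp":
        amp = params.get("amplitude", 80.0)
        off = params.get("offset", -65.0)
        tau = params.get("tau", 2.0)
        V = off + amp * np.exp(-t / tau)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    md = {"model": "fixture", "dt": dt, "protocol_kind": "fixture",
          "protocol": {"kind": kind, **params}}
    return Trace(t=t, data={"V": V}, metadata=md)
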