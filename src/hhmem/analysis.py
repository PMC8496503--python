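"""Spike detection and trace metrics.

A spike is an upward crossing of the detection threshold followed by the
local maximum of the supra-threshold segment; maxima closer together than
``min_separation`` are merged, keeping the higher one.  The default
threshold of -20 mV counts both full-height action potentials and the
reduced-amplitude spikes of strongly driven trains (whose peaks sit between
roughly -1 and -19 mV at high stimulus intensity) while rejecting
subthreshold responses, which stay below about -55 mV under the protocols
considered here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import Trace

__all__ = [
    "SpikeMetrics",
    "TraceExtrema",
    "SpikeStats",
    "InvalidComparisonError",
    "detect_spikes",
    "spike_stats",
    "trace_extrema",
    "compare_models",
    "DEFAULT_THRESHOLD",
    "DEFAULT_MIN_SEPARATION",
]

DEFAULT_THRESHOLD = -20.0  # mV
DEFAULT_MIN_SEPARATION = 1.0  # ms


class InvalidComparisonError(ValueError):
    """The two traces being compared were not produced by the same protocol."""


@dataclass(frozen=True)
class SpikeMetrics:
    count: int
    peak_times: list[float]
    peak_values: list[float]
    isi: list[float]
    fwhm: list[float]
    threshold: float


@dataclass(frozen=True)
class SpikeStats:
    mean_isi: float | None
    mean_fwhm: float | None
    first_spike_latency: float | None


@dataclass(frozen=True)
class TraceExtrema:
    """Per-series (max, argmax time, min, argmin time)."""

    series: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def max_of(self, name: str) -> float:
        return self.series[name][0]

    def time_of_max(self, name: str) -> float:
        return self.series[name][1]

    def min_of(self, name: str) -> float:
        return self.series[name][2]

    def time_of_min(self, name: str) -> float:
        return self.series[name][3]


def _fwhm(t: np.ndarray, V: np.ndarray, i_peak: int, baseline: float) -> float:
    """Full width of the spike at half its height above baseline, ms."""
    half = baseline + (V[i_peak] - baseline) / 2.0
    i = i_peak
    while i > 0 and V[i] > half:
        i -= 1
    j = i_peak
    while j < len(V) - 1 and V[j] > half:
        j += 1
    return float(t[j] - t[i])


def detect_spikes(
    trace: Trace,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation: float = DEFAULT_MIN_SEPARATION,
) -> SpikeMetrics:
    """Locate action-potential peaks in the voltage series of a trace."""
    if len(trace) == 0:
        raise ValueError("cannot detect spikes in an empty trace")
    t = np.asarray(trace.t, float)
    V = np.asarray(trace["V"], float)
    dt = np.diff(t)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("spike detection requires a uniform time grid")

    above = V > threshold
    # segments of consecutive supra-threshold samples entered from below
    peaks: list[tuple[float, float]] = []
    i = 0
    n = len(V)
    while i < n - 1:
        if not above[i] and above[i + 1]:
            j = i + 1
            while j < n - 1 and above[j + 1]:
                j += 1
            k = i + 1 + int(np.argmax(V[i + 1 : j + 1]))
            peaks.append((float(t[k]), float(V[k])))
            i = j + 1
        else:
            i += 1

    merged: list[tuple[float, float]] = []
    for p in peaks:
        if merged and p[0] - merged[-1][0] < min_separation:
            if p[1] > merged[-1][1]:
                merged[-1] = p
        else:
            merged.append(p)

    baseline = float(V[0])
    fwhm = []
    for pt, _ in merged:
        i_peak = int(np.argmin(np.abs(t - pt)))
        fwhm.append(_fwhm(t, V, i_peak, baseline))
    times = [p[0] for p in merged]
    return SpikeMetrics(
        count=len(merged),
        peak_times=times,
        peak_values=[p[1] for p in merged],
        isi=list(np.diff(times)),
        fwhm=fwhm,
        threshold=threshold,
    )


def spike_stats(metrics: SpikeMetrics) -> SpikeStats:
    """Mean interspike interval, mean width and first-spike latency."""
    return SpikeStats(
        mean_isi=float(np.mean(metrics.isi)) if metrics.count >= 2 else None,
        mean_fwhm=float(np.mean(metrics.fwhm)) if metrics.count >= 1 else None,
        first_spike_latency=metrics.peak_times[0] if metrics.count >= 1 else None,
    )


def trace_extrema(trace: Trace) -> TraceExtrema:
    """Extremum value and arg-time of every recorded series."""
    if len(trace) == 0:
        raise ValueError("cannot compute extrema of an empty trace")
    t = np.asarray(trace.t, float)
    out = {}
    for name, series in trace.data.items():
        s = np.asarray(series, float)
        imax, imin = int(np.argmax(s)), int(np.argmin(s))
        out[name] = (float(s[imax]), float(t[imax]), float(s[imin]), float(t[imin]))
    return TraceExtrema(series=out)


_PROTOCOL_KEYS = ("protocol_kind", "protocol", "dt")


def compare_models(
    trace_a: Trace,
    trace_b: Trace,
    threshold: float = DEFAULT_THRESHOLD,
    min_separation: float = DEFAULT_MIN_SEPARATION,
):
    """Paired table of spike counts, voltage peaks and channel peaks for two
    traces recorded under the same protocol (typically HH vs MHH).

    Returns a pandas DataFrame with one row per metric and columns for each
    model plus their difference (b - a).
    """
    import pandas as pd

    for key in _PROTOCOL_KEYS:
        if trace_a.metadata.get(key) != trace_b.metadata.get(key):
            raise InvalidComparisonError(
                f"traces disagree on {key!r}: "
                f"{trace_a.metadata.get(key)!r} vs {trace_b.metadata.get(key)!r}"
            )

    rows = []
    names = (
        trace_a.metadata.get("model", "a"),
        trace_b.metadata.get("model", "b"),
    )
    sp = [detect_spikes(tr, threshold, min_separation) for tr in (trace_a, trace_b)]
    ex = [trace_extrema(tr) for tr in (trace_a, trace_b)]

    def row(metric: str, va: float | None, vb: float | None):
        delta = (vb - va) if va is not None and vb is not None else None
        rows.append({"metric": metric, names[0]: va, names[1]: vb, "delta": delta})

    row("spike_count", sp[0].count, sp[1].count)
    row(
        "first_peak_time",
        sp[0].peak_times[0] if sp[0].count else None,
        sp[1].peak_times[0] if sp[1].count else None,
    )
    row("peak_V", ex[0].max_of("V"), ex[1].max_of("V"))
    row("time_of_peak_V", ex[0].time_of_max("V"), ex[1].time_of_max("V"))
    for series in ("g_Na", "g_K", "J_K"):
        row(f"peak_{series}", ex[0].max_of(series), ex[1].max_of(series))
        row(f"time_of_peak_{series}", ex[0].time_of_max(series), ex[1].time_of_max(series))
    row("min_J_Na", ex[0].min_of("J_Na"), ex[1].min_of("J_Na"))
    row("min_J_total", ex[0].min_of("J_total"), ex[1].min_of("J_total"))
    return pd.DataFrame(rows)
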