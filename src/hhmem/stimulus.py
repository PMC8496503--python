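"""Declarative stimulus waveforms and voltage-clamp protocols.

A :class:`StimulusSpec` describes an injected current-density waveform
J_ext(t) in mA/cm^2; :func:`stimulus_value` evaluates it at any time.
Rectangular windows are half-open, [onset, onset + width), so a pulse edge
that coincides with an integration grid point is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["StimulusSpec", "ClampSpec", "StimulusError", "stimulus_value"]

_KINDS = ("constant", "pulse", "pulse_train", "sinusoid", "none")


class StimulusError(ValueError):
    """Malformed stimulus specification."""


@dataclass(frozen=True)
class StimulusSpec:
    """Injected current waveform.

    kind
        ``constant`` — amplitude from ``onset`` for ``width`` ms (the
        stimulus "action time"); ``width=None`` means the whole run.
        ``pulse`` — one rectangle of the given width.
        ``pulse_train`` — ``n_pulses`` rectangles of the given width,
        starting at ``onset``, one per ``period``.
        ``sinusoid`` — amplitude * sin(2 pi t / sine_period).
        ``none`` — zero everywhere.
    amplitude
        mA/cm^2 (may be negative for a reverse stimulus).
    """

    kind: str = "none"
    amplitude: float = 0.0
    onset: float = 0.0
    width: float | None = None
    n_pulses: int = 1
    period: float | None = None
    sine_period: float | None = None
    duration: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise StimulusError(f"unknown stimulus kind {self.kind!r}; expected one of {_KINDS}")
        if self.duration <= 0:
            raise StimulusError("duration must be positive")
        if self.kind == "pulse" and (self.width is None or self.width <= 0):
            raise StimulusError("pulse requires a positive width")
        if self.kind == "pulse_train":
            if self.width is None or self.period is None:
                raise StimulusError("pulse_train requires width and period")
            if self.width > self.period:
                raise StimulusError("pulse width must not exceed the train period")
            if self.n_pulses < 1:
                raise StimulusError("pulse_train requires n_pulses >= 1")
        if self.kind == "sinusoid" and (self.sine_period is None or self.sine_period <= 0):
            raise StimulusError("sinusoid requires a positive sine_period")


@dataclass(frozen=True)
class ClampSpec:
    """Voltage-clamp protocol: the membrane is held at ``V_clamp + V_rest``
    (the clamp value is an offset above rest, in mV) for ``duration`` ms."""

    V_clamp: float
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("clamp duration must be positive")


def stimulus_value(spec: StimulusSpec, t: float) -> float:
    """J_ext(t) in mA/cm^2 for the given waveform; t in ms, t >= 0."""
    if spec.kind == "none":
        return 0.0
    if spec.kind == "constant":
        end = spec.duration if spec.width is None else spec.onset + spec.width
        return spec.amplitude if spec.onset <= t < end else 0.0
    if spec.kind == "pulse":
        return spec.amplitude if spec.onset <= t < spec.onset + spec.width else 0.0
    if spec.kind == "pulse_train":
        tt = t - spec.onset
        if tt < 0 or tt >= spec.n_pulses * spec.period:
            return 0.0
        return spec.amplitude if (tt % spec.period) < spec.width else 0.0
    if spec.kind == "sinusoid":
        return spec.amplitude * math.sin(2.0 * math.pi * t / spec.sine_period)
    raise StimulusError(f"unknown stimulus kind {spec.kind!r}")
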