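"""Fixed-step time integration of the HH and MHH membranes.

Both current clamp and voltage clamp use the classical fourth-order
Runge-Kutta scheme on a uniform grid (default dt = 0.005 ms).  A fixed-step
explicit scheme keeps every run bit-reproducible and lets the clamped-gate
trajectories be checked against their closed-form single-exponential
solutions.  There is no randomness anywhere in the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np

from .kinetics import KineticsOptions
from .membrane import (
    GatingState,
    HHState,
    MemristorConfig,
    MHHState,
    NeuronParams,
    hh_rhs,
    initial_hh_state,
    initial_mhh_state,
    memristance,
    mhh_rhs,
)
from .stimulus import ClampSpec, StimulusSpec, stimulus_value

__all__ = ["Trace", "DivergenceError", "run_current_clamp", "run_voltage_clamp"]

MAX_STEPS = 10_000_000


class DivergenceError(RuntimeError):
    """The state left the finite domain during integration."""

    def __init__(self, t: float):
        super().__init__(f"integration diverged (non-finite state) at t = {t:.6g} ms")
        self.t = t


@dataclass
class Trace:
    """Time-indexed record of a simulation.

    ``t`` is a uniform grid in ms; ``data`` maps series names (V, m, n, h,
    J_Na, J_K, J_L, J_total, J_ext, g_Na, g_K and, for the memristive
    model, flux_Na, flux_K, M_Na, M_K) to arrays of the same length.
    ``metadata`` records the model variant, parameters, protocol and step
    size that produced the trace.
    """

    t: np.ndarray
    data: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    def __len__(self) -> int:
        return len(self.t)

    @property
    def columns(self) -> list[str]:
        return list(self.data)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"t": self.t, **self.data})


def _rk4(
    deriv: Callable[[float, tuple], tuple],
    y0: tuple,
    dt: float,
    n_steps: int,
) -> np.ndarray:
    """Classical RK4 on a tuple state; returns an (n_steps+1, dim) array."""
    dim = len(y0)
    out = np.empty((n_steps + 1, dim))
    out[0] = y0
    y = tuple(y0)
    half = dt / 2.0
    sixth = dt / 6.0
    for i in range(n_steps):
        t = i * dt
        try:
            k1 = deriv(t, y)
            k2 = deriv(t + half, tuple(a + half * b for a, b in zip(y, k1)))
            k3 = deriv(t + half, tuple(a + half * b for a, b in zip(y, k2)))
            # the end stage samples time with a left bias so a stimulus edge
            # sitting exactly on the grid belongs to the step it starts, not
            # the one it ends (rectangular windows are half-open)
            k4 = deriv(t + dt * (1.0 - 1e-9), tuple(a + dt * b for a, b in zip(y, k3)))
        except OverflowError:
            raise DivergenceError(t) from None
        y = tuple(
            a + sixth * (b + 2.0 * c + 2.0 * d + e)
            for a, b, c, d, e in zip(y, k1, k2, k3, k4)
        )
        if not all(math.isfinite(v) for v in y):
            raise DivergenceError((i + 1) * dt)
        out[i + 1] = y
    return out


def _n_steps(duration: float, dt: float) -> int:
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    if n < 1 or n > MAX_STEPS:
        raise ValueError(f"duration/dt = {duration / dt:.3g} outside (1, {MAX_STEPS})")
    return n


def _hh_series(V, m, n, h, params: NeuronParams) -> dict[str, np.ndarray]:
    g_na = params.g_Na_max * m**3 * h
    g_k = params.g_K_max * n**4
    j_na = g_na * (V - params.E_Na) / 1000.0
    j_k = g_k * (V - params.E_K) / 1000.0
    j_l = params.g_L_max * (V - params.E_L) / 1000.0
    return {
        "V": V, "m": m, "n": n, "h": h,
        "g_Na": g_na, "g_K": g_k,
        "J_Na": j_na, "J_K": j_k, "J_L": j_l, "J_total": j_na + j_k + j_l,
    }


def _mhh_series(
    V, m, n, h, flux_na, flux_k, params: NeuronParams, mem: MemristorConfig
) -> dict[str, np.ndarray]:
    M_na = np.array([memristance(p, mem, "na") for p in flux_na])
    M_k = np.array([memristance(p, mem, "k") for p in flux_k])
    g_na = 1000.0 * m**3 * h / M_na  # mS/cm^2, for comparability with HH traces
    g_k = 1000.0 * n**4 / M_k
    j_na = g_na * (V - params.E_Na) / 1000.0
    j_k = g_k * (V - params.E_K) / 1000.0
    j_l = params.g_L_max * (V - params.E_L) / 1000.0
    return {
        "V": V, "m": m, "n": n, "h": h,
        "g_Na": g_na, "g_K": g_k,
        "J_Na": j_na, "J_K": j_k, "J_L": j_l, "J_total": j_na + j_k + j_l,
        "flux_Na": flux_na, "flux_K": flux_k, "M_Na": M_na, "M_K": M_k,
    }


def _metadata(model, params, options, dt, protocol_kind, protocol, mem=None) -> dict:
    md = {
        "model": model,
        "dt": dt,
        "protocol_kind": protocol_kind,
        "protocol": asdict(protocol),
        "params": asdict(params),
        "kinetics": asdict(options),
    }
    if mem is not None:
        md["memristor"] = asdict(mem)
    return md


def run_current_clamp(
    model: str,
    params: NeuronParams | None = None,
    mem: MemristorConfig | None = None,
    stim: StimulusSpec | None = None,
    dt: float = 0.005,
    options: KineticsOptions | None = None,
) -> Trace:
    """Integrate the membrane under an injected current waveform.

    The initial condition is the nominal resting potential with gates at
    their steady state there (and the configured initial flux for the
    memristive model).  Returns a densely sampled :class:`Trace`.
    """
    if model not in ("hh", "mhh"):
        raise ValueError(f"model must be 'hh' or 'mhh', got {model!r}")
    params = params or NeuronParams()
    stim = stim or StimulusSpec()
    options = options or params.kinetics_options()
    n_steps = _n_steps(stim.duration, dt)
    t = np.arange(n_steps + 1) * dt

    if model == "hh":
        s0 = initial_hh_state(params, options)
        y0 = (s0.V, s0.gates.m, s0.gates.n, s0.gates.h)

        def deriv(tt: float, y: tuple) -> tuple:
            state = HHState(V=y[0], gates=GatingState(y[1], y[2], y[3]))
            return hh_rhs(state, stimulus_value(stim, tt), params, options)

        Y = _rk4(deriv, y0, dt, n_steps)
        data = _hh_series(*(Y[:, i] for i in range(4)), params)
        md = _metadata("hh", params, options, dt, "current_clamp", stim)
    else:
        mem = mem or MemristorConfig()
        s0 = initial_mhh_state(params, mem, options)
        y0 = (s0.V, s0.gates.m, s0.gates.n, s0.gates.h, s0.flux_Na, s0.flux_K)

        def deriv(tt: float, y: tuple) -> tuple:
            state = MHHState(
                V=y[0], gates=GatingState(y[1], y[2], y[3]), flux_Na=y[4], flux_K=y[5]
            )
            return mhh_rhs(state, stimulus_value(stim, tt), params, mem, options)

        Y = _rk4(deriv, y0, dt, n_steps)
        data = _mhh_series(*(Y[:, i] for i in range(6)), params, mem)
        md = _metadata("mhh", params, options, dt, "current_clamp", stim, mem)

    data["J_ext"] = np.array([stimulus_value(stim, tt) for tt in t])
    return Trace(t=t, data=data, metadata=md)


def run_voltage_clamp(
    model: str,
    params: NeuronParams | None = None,
    mem: MemristorConfig | None = None,
    clamp: ClampSpec | None = None,
    dt: float = 0.005,
    options: KineticsOptions | None = None,
) -> Trace:
    """Hold the membrane at ``V_clamp + V_rest`` and integrate the gates.

    The clamp is an ideal instantaneous step applied at t = 0 to a membrane
    whose gates start at the resting steady state.  The recorded ``J_ext``
    series is the holding current the clamp amplifier must supply, equal to
    the total ionic current at the held potential.
    """
    if model not in ("hh", "mhh"):
        raise ValueError(f"model must be 'hh' or 'mhh', got {model!r}")
    if clamp is None:
        raise ValueError("a ClampSpec is required")
    params = params or NeuronParams()
    options = options or params.kinetics_options()
    n_steps = _n_steps(clamp.duration, dt)
    t = np.arange(n_steps + 1) * dt
    v_held = clamp.V_clamp + params.v_rest

    if model == "hh":
        s0 = initial_hh_state(params, options)
        y0 = (s0.gates.m, s0.gates.n, s0.gates.h)

        def deriv(tt: float, y: tuple) -> tuple:
            state = HHState(V=v_held, gates=GatingState(*y))
            return hh_rhs(state, 0.0, params, options)[1:]

        Y = _rk4(deriv, y0, dt, n_steps)
        V = np.full(n_steps + 1, v_held)
        data = _hh_series(V, Y[:, 0], Y[:, 1], Y[:, 2], params)
        md = _metadata("hh", params, options, dt, "voltage_clamp", clamp)
    else:
        mem = mem or MemristorConfig()
        s0 = initial_mhh_state(params, mem, options)
        y0 = (s0.gates.m, s0.gates.n, s0.gates.h, s0.flux_Na, s0.flux_K)

        def deriv(tt: float, y: tuple) -> tuple:
            state = MHHState(
                V=v_held, gates=GatingState(y[0], y[1], y[2]), flux_Na=y[3], flux_K=y[4]
            )
            return mhh_rhs(state, 0.0, params, mem, options)[1:]

        Y = _rk4(deriv, y0, dt, n_steps)
        V = np.full(n_steps + 1, v_held)
        data = _mhh_series(V, Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3], Y[:, 4], params, mem)
        md = _metadata("mhh", params, options, dt, "voltage_clamp", clamp, mem)

    data["J_ext"] = data["J_total"].copy()
    return Trace(t=t, data=data, metadata=md)
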