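"""Voltage- and temperature-dependent gating kinetics of the squid-axon channels.

The sodium channel is governed by three activation gates (``m``) and one
inactivation gate (``h``); the potassium channel by four activation gates
(``n``).  Each gate relaxes toward a voltage-dependent steady state with a
voltage-dependent time constant,

    dx/dt = (x_inf(V) - x) / tau_x(V),        x in {m, n, h},

where ``x_inf = alpha/(alpha + beta)`` and ``tau_x = 1/(alpha + beta)``.
All transition rates are expressed in 1/ms as functions of the deviation
``v = V_m - V_rest`` (mV) and are scaled by a common temperature factor
``phi = 3**((T - 6.3)/10)`` (a Q10 of 3 referenced to 6.3 degrees C, the
temperature of the original squid-axon measurements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "RateSet",
    "SteadyTau",
    "KineticsOptions",
    "DegenerateKineticsError",
    "temperature_factor",
    "rate_constants",
    "gate_steady_tau",
    "gate_derivative",
    "steady_gates",
]


class DegenerateKineticsError(ValueError):
    """Raised when alpha + beta vanishes for a gate, or tau is nonpositive."""


@dataclass(frozen=True)
class RateSet:
    """The six channel transition rates at one membrane potential, in 1/ms.

    ``alpha_x`` is the closed-to-open rate of gate ``x``; ``beta_x`` the
    open-to-closed rate.  All rates are nonnegative for finite voltage.
    """

    alpha_m: float
    beta_m: float
    alpha_n: float
    beta_n: float
    alpha_h: float
    beta_h: float


@dataclass(frozen=True)
class SteadyTau:
    """Steady-state gate values (dimensionless, in [0, 1]) and time constants (ms)."""

    m_inf: float
    n_inf: float
    h_inf: float
    tau_m: float
    tau_n: float
    tau_h: float


@dataclass(frozen=True)
class KineticsOptions:
    """Evaluation context for the rate functions.

    Parameters
    ----------
    temperature:
        Bath temperature in degrees C.  Enters only through the factor
        ``phi = 3**((T - 6.3)/10)`` that multiplies every rate.
    v_rest:
        Resting potential in mV; the rate formulas use v = V_m - v_rest.
    beta_m_divisor:
        The exponential e-fold (mV) of the m-gate closing rate
        ``beta_m = 4 phi exp(-v/divisor)``.  The classical squid-axon value
        is 18 mV (default); 20 mV is exposed as an alternative convention.
    singularity_epsilon:
        Half-width of the window around the removable singularities of
        alpha_m and alpha_n inside which ``x/(e^x - 1)`` is evaluated by
        its Taylor series.
    """

    temperature: float = 6.3
    v_rest: float = -65.0
    beta_m_divisor: float = 18.0
    singularity_epsilon: float = 1e-7


def temperature_factor(temperature: float) -> float:
    """Q10 = 3 rate scaling referenced to 6.3 degrees C: ``3**((T - 6.3)/10)``."""
    if not math.isfinite(temperature):
        raise ValueError(f"temperature must be finite, got {temperature!r}")
    return 3.0 ** ((temperature - 6.3) / 10.0)


def _xexpm1(x: float, eps: float) -> float:
    # x / (e^x - 1) with its removable singularity at x = 0 filled by the
    # second-order series 1 - x/2 + x^2/12.
    if abs(x) < eps:
        return 1.0 - x / 2.0 + x * x / 12.0
    return x / math.expm1(x)


def rate_constants(v_m: float, options: KineticsOptions | None = None) -> RateSet:
    """All six transition rates at membrane potential ``v_m`` (mV).

    The rates, with v = V_m - V_rest in mV and phi the temperature factor::

        alpha_m = phi (2.5 - 0.1 v) / (e^(2.5 - 0.1 v) - 1)
        beta_m  = 4 phi e^(-v / divisor)
        alpha_n = phi (0.1 - 0.01 v) / (e^(1 - 0.1 v) - 1)
        beta_n  = 0.125 phi e^(-v / 80)
        alpha_h = 0.07 phi e^(-v / 20)
        beta_h  = phi / (e^(3 - 0.1 v) + 1)

    alpha_m and alpha_n have removable singularities at v = 25 and v = 10
    respectively and are continued through them by a Taylor series.
    """
    if options is None:
        options = KineticsOptions()
    if not math.isfinite(v_m):
        raise ValueError(f"membrane potential must be finite, got {v_m!r}")
    v = v_m - options.v_rest
    phi = temperature_factor(options.temperature)
    eps = options.singularity_epsilon
    return RateSet(
        alpha_m=phi * _xexpm1(2.5 - 0.1 * v, eps),
        beta_m=4.0 * phi * math.exp(-v / options.beta_m_divisor),
        alpha_n=0.1 * phi * _xexpm1(1.0 - 0.1 * v, eps),
        beta_n=0.125 * phi * math.exp(-v / 80.0),
        alpha_h=0.07 * phi * math.exp(-v / 20.0),
        beta_h=phi / (math.exp(3.0 - 0.1 * v) + 1.0),
    )


def gate_steady_tau(rates: RateSet) -> SteadyTau:
    """Steady states ``x_inf = a/(a+b)`` and time constants ``tau = 1/(a+b)``."""
    out = {}
    for gate in ("m", "n", "h"):
        a = getattr(rates, f"alpha_{gate}")
        b = getattr(rates, f"beta_{gate}")
        s = a + b
        if s <= 0.0:
            raise DegenerateKineticsError(
                f"alpha_{gate} + beta_{gate} = {s}; steady state undefined"
            )
        out[f"{gate}_inf"] = a / s
        out[f"tau_{gate}"] = 1.0 / s
    return SteadyTau(**out)


def gate_derivative(x: float, x_inf: float, tau: float) -> float:
    """First-order relaxation rate ``(x_inf - x)/tau`` in 1/ms."""
    if tau <= 0.0:
        raise DegenerateKineticsError(f"tau must be positive, got {tau}")
    return (x_inf - x) / tau


def steady_gates(v_m: float, options: KineticsOptions | None = None) -> tuple[float, float, float]:
    """(m_inf, n_inf, h_inf) at a fixed membrane potential — the gate values a
    neuron held at ``v_m`` relaxes to."""
    st = gate_steady_tau(rate_constants(v_m, options))
    return st.m_inf, st.n_inf, st.h_inf
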