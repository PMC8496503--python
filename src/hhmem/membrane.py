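"""Membrane equations of the classical (HH) and memristive (MHH) neuron.

Units follow the classical squid-axon convention throughout: potential in
mV, time in ms, capacitance in uF/cm^2, conductance in mS/cm^2, current
density in mA/cm^2.  Since mS/cm^2 x mV = uA/cm^2, ionic current densities
carry a factor 1/1000 and the membrane equation reads

    dV/dt [mV/ms] = 1000 (J_ext - J_m) / C .

In the memristive variant the Na and K maximal conductances are replaced by
the reciprocal memristance of a flux-controlled memristor per channel:

    g_MNa = m^3 h / M(phi_Na),    g_MK = n^4 / M(phi_K),

with M in Ohm cm^2 (so 1/M is in S/cm^2) following a piecewise-linear,
monotone non-increasing law between a high plateau (nearly closed channel)
and a low plateau (fully available channel).  The flux states integrate the
deviation of the membrane potential from rest, d(phi)/dt = k (V - V_rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from scipy.optimize import brentq

from .kinetics import (
    KineticsOptions,
    gate_steady_tau,
    rate_constants,
    steady_gates,
)

__all__ = [
    "GatingState",
    "NeuronParams",
    "HHState",
    "MemristorConfig",
    "MHHState",
    "CurrentDensities",
    "channel_conductances",
    "ionic_current_densities",
    "hh_rhs",
    "memristance",
    "memductances",
    "mhh_rhs",
    "resting_potential",
    "initial_hh_state",
    "initial_mhh_state",
]


@dataclass(frozen=True)
class GatingState:
    """The three gate variables, each dimensionless in [0, 1]."""

    m: float
    n: float
    h: float


@dataclass(frozen=True)
class NeuronParams:
    """Passive and maximal-conductance parameters of the membrane.

    Defaults are the classical squid-axon constants expressed relative to a
    resting potential of -65 mV: E_Na = 50, E_K = -77, E_L = -54.4 mV and
    maximal conductances 120 / 36 / 0.3 mS/cm^2.  With these values the
    membrane has a stable fixed point at -65 mV under zero stimulus, and
    the classic clamp and pulse experiments are reproduced quantitatively.
    ``printed_variant`` swaps in the rounded reversal potentials E_K = -70,
    E_L = -50 mV sometimes quoted for this model; note that with those the
    resting membrane is not at equilibrium at -65 mV.
    """

    C: float = 1.0
    E_Na: float = 50.0
    E_K: float = -77.0
    E_L: float = -54.4
    g_Na_max: float = 120.0
    g_K_max: float = 36.0
    g_L_max: float = 0.3
    temperature: float = 6.3
    v_rest: float = -65.0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("membrane capacitance C must be positive")
        if min(self.g_Na_max, self.g_K_max, self.g_L_max) < 0:
            raise ValueError("maximal conductances must be nonnegative")

    @classmethod
    def printed_variant(cls, **overrides: float) -> "NeuronParams":
        """Parameters with the rounded reversal potentials E_K=-70, E_L=-50 mV."""
        base = dict(E_K=-70.0, E_L=-50.0)
        base.update(overrides)
        return cls(**base)

    def kinetics_options(self, beta_m_divisor: float = 18.0) -> KineticsOptions:
        return KineticsOptions(
            temperature=self.temperature,
            v_rest=self.v_rest,
            beta_m_divisor=beta_m_divisor,
        )


@dataclass(frozen=True)
class HHState:
    V: float
    gates: GatingState


@dataclass(frozen=True)
class MemristorConfig:
    """Parameters of the flux-controlled memristance law and flux dynamics.

    law_variant
        ``reconstructed_continuous`` (default): M falls linearly from
        ``M_high`` at ``flux_lo`` to the per-channel floor at ``flux_hi``,
        with plateaus outside the window; M(0) is then close to the nominal
        initial memristance of 10,000 Ohm cm^2.  ``as_printed`` uses the
        literal constants of the source law (slope -3.98e8, intercept 1e8,
        breakpoints -0.75/0.25, shared floor 100), clipped to
        [M_low_k, M_high]; that law is internally inconsistent and is kept
        only for reference.
    M_low_na, M_low_k
        Low plateaus per channel, Ohm cm^2.  The sodium floor defaults to
        1/g_Na_max = 1/0.120 Ohm cm^2 so that a fully driven sodium
        memristor recovers the classical maximal sodium conductance; the
        potassium floor keeps the printed 100 Ohm cm^2.
    flux_gain
        k in d(phi)/dt = k (V - V_rest), flux units per mV ms.
    flux_init
        Named initial-flux preset: ``midpoint`` (phi0 = 0, M ~ 10,000,
        the stated initial memristance; default) or ``fig8`` (phi0 =
        flux_lo, M ~ M_high, the stated initial memductance 0.5e-4).
    shared_flux
        Drive both memristors from a single flux state.
    """

    law_variant: str = "reconstructed_continuous"
    M_high: float = 20000.0
    M_low_na: float = 1.0 / 0.120
    M_low_k: float = 100.0
    flux_lo: float = -0.25
    flux_hi: float = 0.25
    flux_gain: float = 0.1
    flux_init: str = "midpoint"
    shared_flux: bool = False
    # as-printed law constants, kept for the reference variant
    printed_slope: float = -3.98e8
    printed_intercept: float = 1.0e8
    printed_flux_lo: float = -0.75
    printed_flux_hi: float = 0.25

    def __post_init__(self) -> None:
        if self.law_variant not in ("reconstructed_continuous", "as_printed"):
            raise ValueError(f"unknown memristance law variant {self.law_variant!r}")
        if self.flux_init not in ("midpoint", "fig8"):
            raise ValueError(f"unknown flux preset {self.flux_init!r}")
        if not (0 < self.M_low_na <= self.M_high and 0 < self.M_low_k <= self.M_high):
            raise ValueError("memristance plateaus must satisfy 0 < M_low <= M_high")

    def initial_flux(self) -> float:
        return 0.0 if self.flux_init == "midpoint" else self.flux_lo


@dataclass(frozen=True)
class MHHState:
    V: float
    gates: GatingState
    flux_Na: float
    flux_K: float


@dataclass(frozen=True)
class CurrentDensities:
    """Per-channel and total membrane current densities, mA/cm^2."""

    J_Na: float
    J_K: float
    J_L: float
    J_m: float


def channel_conductances(
    gates: GatingState, params: NeuronParams
) -> tuple[float, float, float]:
    """(g_Na, g_K, g_L) in mS/cm^2: ``g_Na_max m^3 h``, ``g_K_max n^4``, ``g_L_max``."""
    g_na = params.g_Na_max * gates.m**3 * gates.h
    g_k = params.g_K_max * gates.n**4
    return g_na, g_k, params.g_L_max


def ionic_current_densities(
    V: float, conductances: tuple[float, float, float], params: NeuronParams
) -> CurrentDensities:
    """Ohmic channel currents ``J_x = g_x (V - E_x)`` in mA/cm^2.

    Conductances are in mS/cm^2 and driving forces in mV, so the products
    are in uA/cm^2 and are divided by 1000.
    """
    g_na, g_k, g_l = conductances
    j_na = g_na * (V - params.E_Na) / 1000.0
    j_k = g_k * (V - params.E_K) / 1000.0
    j_l = g_l * (V - params.E_L) / 1000.0
    return CurrentDensities(J_Na=j_na, J_K=j_k, J_L=j_l, J_m=j_na + j_k + j_l)


def _gate_derivs(
    V: float, gates: GatingState, options: KineticsOptions
) -> tuple[float, float, float]:
    r = rate_constants(V, options)
    st = gate_steady_tau(r)
    return (
        (st.m_inf - gates.m) / st.tau_m,
        (st.n_inf - gates.n) / st.tau_n,
        (st.h_inf - gates.h) / st.tau_h,
    )


def hh_rhs(
    state: HHState,
    J_ext: float,
    params: NeuronParams,
    options: KineticsOptions | None = None,
) -> tuple[float, float, float, float]:
    """Time derivative (dV/dt, dm/dt, dn/dt, dh/dt) of the space-clamped membrane.

    ``dV/dt = 1000 (J_ext - J_m) / C`` with J in mA/cm^2 and C in uF/cm^2.
    """
    if options is None:
        options = params.kinetics_options()
    cur = ionic_current_densities(state.V, channel_conductances(state.gates, params), params)
    dv = 1000.0 * (J_ext - cur.J_m) / params.C
    dm, dn, dh = _gate_derivs(state.V, state.gates, options)
    return dv, dm, dn, dh


def memristance(flux: float, config: MemristorConfig, channel: str = "na") -> float:
    """Memristance M(phi) in Ohm cm^2 for the given channel ('na' or 'k').

    Piecewise linear and monotone non-increasing; always within
    [M_low, M_high] for the channel.
    """
    if channel not in ("na", "k"):
        raise ValueError(f"channel must be 'na' or 'k', got {channel!r}")
    m_low = config.M_low_na if channel == "na" else config.M_low_k
    if config.law_variant == "as_printed":
        lo, hi = config.printed_flux_lo, config.printed_flux_hi
        if flux < lo:
            return config.M_high
        if flux < hi:
            val = config.printed_slope * flux + config.printed_intercept
            return min(config.M_high, max(config.M_low_k, val))
        return config.M_low_k
    lo, hi = config.flux_lo, config.flux_hi
    if flux < lo:
        return config.M_high
    if flux < hi:
        frac = (flux - lo) / (hi - lo)
        return config.M_high + frac * (m_low - config.M_high)
    return m_low


def memductances(
    gates: GatingState, M_Na: float, M_K: float
) -> tuple[float, float]:
    """(g_MNa, g_MK) in S/cm^2 (Ohm^-1 cm^-2): ``m^3 h / M_Na`` and ``n^4 / M_K``."""
    if M_Na <= 0 or M_K <= 0:
        raise ValueError(f"memristance must be positive, got M_Na={M_Na}, M_K={M_K}")
    return gates.m**3 * gates.h / M_Na, gates.n**4 / M_K


def mhh_currents(
    state: MHHState, params: NeuronParams, mem: MemristorConfig
) -> CurrentDensities:
    """Channel currents of the memristive membrane, mA/cm^2.

    The memductances are in S/cm^2, so g (V - E) is directly in mA/cm^2;
    the leak remains the classical conductance.
    """
    g_mna, g_mk = memductances(
        state.gates,
        memristance(state.flux_Na, mem, "na"),
        memristance(state.flux_K, mem, "k"),
    )
    j_na = g_mna * (state.V - params.E_Na)
    j_k = g_mk * (state.V - params.E_K)
    j_l = params.g_L_max * (state.V - params.E_L) / 1000.0
    return CurrentDensities(J_Na=j_na, J_K=j_k, J_L=j_l, J_m=j_na + j_k + j_l)


def mhh_rhs(
    state: MHHState,
    J_ext: float,
    params: NeuronParams,
    mem: MemristorConfig,
    options: KineticsOptions | None = None,
) -> tuple[float, float, float, float, float, float]:
    """Derivative (dV, dm, dn, dh, dphi_Na, dphi_K) of the memristive membrane.

    Gate kinetics are identical to the classical model; the flux of each
    memristor integrates the voltage deviation from rest, scaled by the
    flux gain.  With ``shared_flux`` the two flux derivatives coincide (a
    single memristor state drives both channels).
    """
    if options is None:
        options = params.kinetics_options()
    cur = mhh_currents(state, params, mem)
    dv = 1000.0 * (J_ext - cur.J_m) / params.C
    dm, dn, dh = _gate_derivs(state.V, state.gates, options)
    dflux = mem.flux_gain * (state.V - params.v_rest)
    return dv, dm, dn, dh, dflux, dflux


def resting_potential(
    params: NeuronParams, options: KineticsOptions | None = None
) -> float:
    """Zero-stimulus fixed point of the membrane: the V where the total ionic
    current vanishes with all gates at their steady states."""
    if options is None:
        options = params.kinetics_options()

    def total_current(v: float) -> float:
        m, n, h = steady_gates(v, options)
        cur = ionic_current_densities(
            v, channel_conductances(GatingState(m, n, h), params), params
        )
        return cur.J_m

    return brentq(total_current, -90.0, -40.0, xtol=1e-12)


def initial_hh_state(
    params: NeuronParams, options: KineticsOptions | None = None
) -> HHState:
    """Initial condition at the nominal resting potential with gates at the
    steady state of that potential."""
    if options is None:
        options = params.kinetics_options()
    m, n, h = steady_gates(params.v_rest, options)
    return HHState(V=params.v_rest, gates=GatingState(m, n, h))


def initial_mhh_state(
    params: NeuronParams,
    mem: MemristorConfig,
    options: KineticsOptions | None = None,
) -> MHHState:
    hh = initial_hh_state(params, options)
    phi0 = mem.initial_flux()
    return MHHState(V=hh.V, gates=hh.gates, flux_Na=phi0, flux_K=phi0)
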