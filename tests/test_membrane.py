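"""Membrane equations: conductances, current densities, memristance law and
the structural relation between the classical and memristive right-hand sides."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hhmem import (
    GatingState,
    HHState,
    MemristorConfig,
    MHHState,
    NeuronParams,
    channel_conductances,
    hh_rhs,
    initial_hh_state,
    ionic_current_densities,
    memductances,
    memristance,
    mhh_rhs,
    resting_potential,
    steady_gates,
)

P = NeuronParams()


class TestConductances:
    def test_fully_open_channels_reach_maxima(self):
        g = channel_conductances(GatingState(1.0, 1.0, 1.0), P)
        assert g == (120.0, 36.0, 0.3)

    def test_closed_n_gate_zeroes_potassium(self):
        g = channel_conductances(GatingState(0.5, 0.0, 0.5), P)
        assert g[1] == 0.0

    def test_partially_open_potassium(self):
        """36 n^4 at the n reached after a 10 ms clamp step 20 mV above rest."""
        g = channel_conductances(GatingState(0.0, 0.5956498103444454, 0.0), P)
        assert g[1] == pytest.approx(4.531756142990483, rel=1e-9)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            NeuronParams(C=0.0)
        with pytest.raises(ValueError):
            NeuronParams(g_K_max=-1.0)


class TestCurrentDensities:
    def test_zero_driving_force(self):
        cur = ionic_current_densities(P.E_K, (0.0, 36.0, 0.3), P)
        assert cur.J_K == 0.0

    def test_unit_conversion_micro_to_milli(self):
        """g = 0.3 mS/cm^2, driving force 50 mV -> 15 uA/cm^2 = 0.015 mA/cm^2."""
        p = NeuronParams(E_L=-50.0)
        cur = ionic_current_densities(0.0, (0.0, 0.0, 0.3), p)
        assert cur.J_L == pytest.approx(0.015)

    @settings(derandomize=True, max_examples=100)
    @given(
        v=st.floats(min_value=-120, max_value=80),
        m=st.floats(min_value=0, max_value=1),
        n=st.floats(min_value=0, max_value=1),
        h=st.floats(min_value=0, max_value=1),
    )
    def test_total_is_sum_of_components(self, v, m, n, h):
        cur = ionic_current_densities(v, channel_conductances(GatingState(m, n, h), P), P)
        assert cur.J_m == cur.J_Na + cur.J_K + cur.J_L


class TestHHRhs:
    def test_resting_fixed_point(self):
        """At the zero-current fixed point with gates at steady state, every
        derivative vanishes."""
        v_star = resting_potential(P)
        state = HHState(V=v_star, gates=GatingState(*steady_gates(v_star)))
        dv, dm, dn, dh = hh_rhs(state, 0.0, P)
        assert abs(dv) < 1e-6
        assert abs(dm) < 1e-12 and abs(dn) < 1e-12 and abs(dh) < 1e-12

    def test_default_resting_potential_is_minus_65(self):
        """The default reversal potentials put the quiescent membrane at -65 mV."""
        assert resting_potential(P) == pytest.approx(-65.0, abs=0.01)

    def test_pure_capacitor_charging_rate(self):
        """With all conductances off, dV/dt = 1000 J_ext / C."""
        p = NeuronParams(g_Na_max=0.0, g_K_max=0.0, g_L_max=0.0)
        state = HHState(V=-65.0, gates=GatingState(0.5, 0.5, 0.5))
        dv = hh_rhs(state, 0.001, p)[0]
        assert dv == pytest.approx(1.0)

    def test_gates_at_steady_state_are_stationary(self):
        state = initial_hh_state(P)
        _, dm, dn, dh = hh_rhs(state, 0.05, P)
        assert dm == pytest.approx(0.0, abs=1e-14)
        assert dn == pytest.approx(0.0, abs=1e-14)
        assert dh == pytest.approx(0.0, abs=1e-14)


class TestMemristanceLaw:
    def test_plateaus(self):
        cfg = MemristorConfig()
        assert memristance(-1.0, cfg, "na") == 20000.0
        assert memristance(0.5, cfg, "k") == 100.0
        assert memristance(0.5, cfg, "na") == pytest.approx(1.0 / 0.120)

    def test_midpoint_matches_nominal_initial_memristance(self):
        """M(0) sits at the stated initial memristance of ~10,000 Ohm cm^2."""
        cfg = MemristorConfig()
        assert memristance(0.0, cfg, "na") == pytest.approx(10000.0, rel=0.01)
        assert memristance(0.0, cfg, "k") == pytest.approx(10000.0, rel=0.01)

    def test_as_printed_constants(self):
        cfg = MemristorConfig(law_variant="as_printed")
        assert memristance(-1.0, cfg, "k") == 20000.0
        assert memristance(0.5, cfg, "k") == 100.0
        # the printed linear segment is clipped to the plateau interval
        assert memristance(0.0, cfg, "k") == 20000.0

    @settings(derandomize=True, max_examples=200)
    @given(
        flux=st.floats(min_value=-3, max_value=3),
        variant=st.sampled_from(["reconstructed_continuous", "as_printed"]),
        channel=st.sampled_from(["na", "k"]),
    )
    def test_bounded_and_monotone(self, flux, variant, channel):
        cfg = MemristorConfig(law_variant=variant)
        m_low = cfg.M_low_na if (channel == "na" and variant != "as_printed") else cfg.M_low_k
        val = memristance(flux, cfg, channel)
        assert m_low <= val <= cfg.M_high
        assert memristance(flux + 0.01, cfg, channel) <= val + 1e-9


class TestMemductances:
    def test_reciprocal_of_high_plateau(self):
        g_na, g_k = memductances(GatingState(1.0, 1.0, 1.0), 20000.0, 20000.0)
        assert g_na == pytest.approx(0.5e-4)
        assert g_k == pytest.approx(0.5e-4)

    def test_closed_gate(self):
        assert memductances(GatingState(1.0, 0.0, 1.0), 100.0, 100.0)[1] == 0.0

    def test_low_memristance(self):
        assert memductances(GatingState(1.0, 0.0, 1.0), 100.0, 100.0)[0] == pytest.approx(1e-2)

    def test_nonpositive_memristance_rejected(self):
        with pytest.raises(ValueError):
            memductances(GatingState(1, 1, 1), 0.0, 100.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        m=st.floats(min_value=0, max_value=1),
        n=st.floats(min_value=0, max_value=1),
        h=st.floats(min_value=0, max_value=1),
        m_na=st.floats(min_value=1, max_value=20000),
        m_k=st.floats(min_value=1, max_value=20000),
    )
    def test_memductance_times_memristance_is_gate_product(self, m, n, h, m_na, m_k):
        g_na, g_k = memductances(GatingState(m, n, h), m_na, m_k)
        assert g_na * m_na == pytest.approx(m**3 * h, abs=1e-12)
        assert g_k * m_k == pytest.approx(n**4, abs=1e-12)


class TestMHHRhs:
    def test_flux_stationary_at_rest(self):
        state = MHHState(V=-65.0, gates=GatingState(0.1, 0.3, 0.6), flux_Na=0.0, flux_K=0.0)
        d = mhh_rhs(state, 0.0, P, MemristorConfig())
        assert d[4] == 0.0 and d[5] == 0.0

    def test_flux_rate_proportional_to_depolarization(self):
        cfg = MemristorConfig(flux_gain=1e-3)
        state = MHHState(V=35.0, gates=GatingState(0.1, 0.3, 0.6), flux_Na=0.0, flux_K=0.0)
        d = mhh_rhs(state, 0.0, P, cfg)
        assert d[4] == pytest.approx(0.1)

    def test_reduces_to_hh_at_floor_memristances(self):
        """With each memristor pinned at 1/g_max of its channel, the MHH
        voltage and gate derivatives equal the HH ones exactly."""
        cfg = MemristorConfig(
            M_low_na=1.0 / 0.120, M_low_k=1.0 / 0.036, flux_init="midpoint"
        )
        gates = GatingState(0.3, 0.4, 0.5)
        for v in (-65.0, -40.0, 0.0, 30.0):
            hh = hh_rhs(HHState(V=v, gates=gates), 0.02, P)
            mhh = mhh_rhs(
                MHHState(V=v, gates=gates, flux_Na=10.0, flux_K=10.0), 0.02, P, cfg
            )
            assert mhh[0] == pytest.approx(hh[0], rel=1e-12)
            assert mhh[1:4] == pytest.approx(hh[1:4], rel=1e-12)

    def test_scaled_currents_at_high_plateau(self):
        """With both memristances pinned at the 20000 plateau the channel
        currents are the HH ones rescaled by (1/20000)/(g_max/1000)."""
        from hhmem.membrane import mhh_currents

        gates = GatingState(0.3, 0.4, 0.5)
        v = -30.0
        cur_hh = ionic_current_densities(v, channel_conductances(gates, P), P)
        cur_m = mhh_currents(
            MHHState(V=v, gates=gates, flux_Na=-5.0, flux_K=-5.0), P, MemristorConfig()
        )
        assert cur_m.J_Na == pytest.approx(
            cur_hh.J_Na * (1.0 / 20000.0) / (P.g_Na_max / 1000.0), rel=1e-12
        )
        assert cur_m.J_K == pytest.approx(
            cur_hh.J_K * (1.0 / 20000.0) / (P.g_K_max / 1000.0), rel=1e-12
        )
        assert cur_m.J_m == pytest.approx(cur_m.J_Na + cur_m.J_K + cur_m.J_L)
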