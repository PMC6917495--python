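"""Conductance model: filter-cascade oracles, voltage equations, the E-
rectification bound, and the Scaled-EI construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import cont2discrete, lfilter

from t5model.model import (ChannelParams, EIParams, EpEmParams, MembraneFrame,
                           channel_conductance, e_minus_bound, scale_EI_from_EpEm,
                           simulate, spatial_rf, stimulus_drive, voltage_EI,
                           voltage_EpEm)
from t5model.stimuli import make_bar_flash, make_moving_bar

from conftest import model_dsi


def cascade_zoh_reference(tau_r, tau_d, drive, dt):
    """Independent oracle: matrix zero-order-hold discretization of the
    two-filter cascade via scipy.signal.cont2discrete."""
    A = np.array([[-1.0 / tau_r, 0.0], [1.0 / tau_d, -1.0 / tau_d]])
    B = np.array([[1.0 / tau_r], [0.0]])
    C = np.array([[0.0, 1.0]])
    D = np.array([[0.0]])
    (Ad, Bd, Cd, Dd, _) = cont2discrete((A, B, C, D), dt, method="zoh")
    x = np.zeros(2)
    out = np.empty(drive.size)
    for i, u in enumerate(drive):
        out[i] = x[1]
        x = Ad @ x + Bd[:, 0] * u
    return out


class TestSpatialRF:
    def test_gaussian_values(self):
        ch = ChannelParams(10, 50, 1.0, 0.0, 1.0)
        w = spatial_rf(ch, np.array([0.0, 1.0]))
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(np.exp(-0.5))

    def test_zero_amplitude_gives_zero_weights(self):
        ch = ChannelParams(10, 50, 0.0, 0.0, 1.0)
        assert not spatial_rf(ch, np.arange(-3, 4)).any()

    def test_rejects_nonpositive_sigma_and_empty_positions(self):
        with pytest.raises(ValueError):
            ChannelParams(10, 50, 1.0, 0.0, 0.0)
        ch = ChannelParams(10, 50, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            spatial_rf(ch, np.array([]))


class TestStimulusDrive:
    def test_zero_movie_gives_zero_drive(self):
        ch = ChannelParams(10, 50, 1.0, 0.0, 1.0)
        m = make_bar_flash(0, 1, 0.0)
        assert not stimulus_drive(ch, m).any()

    def test_single_and_double_position_sums(self):
        ch = ChannelParams(10, 50, 1.0, 0.0, 1.0)
        m1 = make_bar_flash(0, 1, 160.0, dt_ms=1.0)
        d1 = stimulus_drive(ch, m1)
        assert d1[250] == pytest.approx(1.0)
        m2 = make_bar_flash(0, 2, 160.0, dt_ms=1.0)
        d2 = stimulus_drive(ch, m2)
        assert d2[250] == pytest.approx(1.0 + np.exp(-0.5))


class TestFilterCascade:
    def test_step_response_closed_form(self):
        # k(t) = 1 + (tauR e^{-t/tauR} - tauD e^{-t/tauD})/(tauD - tauR)
        ch = ChannelParams(10.0, 50.0, 1.0, 0.0, 1.0)
        drive = np.ones(1001)
        k = channel_conductance(ch, drive, 1.0, "analytic")
        t = np.arange(1001.0)
        expected = 1 + (10 * np.exp(-t / 10) - 50 * np.exp(-t / 50)) / (50 - 10)
        assert np.allclose(k, expected, atol=1e-10)
        assert k[50] == pytest.approx(0.5418, abs=1e-4)

    def test_steady_state_equals_input(self):
        ch = ChannelParams(5.0, 20.0, 1.0, 0.0, 1.0)
        k = channel_conductance(ch, 3.0 * np.ones(5000), 1.0)
        assert k[-1] == pytest.approx(3.0, rel=1e-6)

    def test_equal_time_constants_alpha_function(self):
        tau = 25.0
        ch = ChannelParams(tau, tau, 1.0, 0.0, 1.0)
        drive = np.ones(801)
        k = channel_conductance(ch, drive, 1.0)
        t = np.arange(801.0)
        expected = 1 - np.exp(-t / tau) * (1 + t / tau)
        assert np.allclose(k, expected, atol=1e-9)

    @given(tau_r=st.floats(2.0, 200.0), tau_d=st.floats(2.0, 200.0))
    @settings(max_examples=20, deadline=None)
    def test_analytic_matches_scipy_zoh(self, tau_r, tau_d):
        rng = np.random.default_rng(0)
        drive = rng.uniform(0, 2, 300)
        ch = ChannelParams(tau_r, tau_d, 1.0, 0.0, 1.0)
        k = channel_conductance(ch, drive, 1.0)
        ref = cascade_zoh_reference(tau_r, tau_d, drive, 1.0)
        assert np.allclose(k, ref, atol=1e-12)

    def test_rk4_matches_analytic_on_step(self):
        ch = ChannelParams(10.0, 50.0, 1.0, 0.0, 1.0)
        drive = np.ones(10001)  # 1 s at dt = 0.1 ms
        k_an = channel_conductance(ch, drive, 0.1, "analytic")
        k_rk = channel_conductance(ch, drive, 0.1, "rk4")
        rel = np.max(np.abs(k_rk - k_an)) / np.max(np.abs(k_an))
        assert rel < 1e-6

    def test_unknown_integrator_rejected(self):
        ch = ChannelParams(10.0, 50.0, 1.0, 0.0, 1.0)
        with pytest.raises(ValueError, match="integrator"):
            channel_conductance(ch, np.ones(10), 1.0, "euler")


class TestVoltageEquations:
    def test_ei_baseline_and_cancellation(self):
        p = EIParams(exc=ChannelParams(10, 50, 1, 0, 1),
                     inh=ChannelParams(10, 50, 1, 0, 1),
                     frame=MembraneFrame())
        z = np.zeros(5)
        assert not voltage_EI(p, z, z).any()
        i = np.array([0.5, 1.0, 2.0])
        e = p.frame.alpha * i
        assert np.allclose(voltage_EI(p, e, i), 0.0)

    def test_ei_direct_substitution(self):
        frame = MembraneFrame.from_alpha(0.8, v_leak_mV=-60.0, v_exc_mV=0.0)
        p = EIParams(exc=ChannelParams(10, 50, 1, 0, 1),
                     inh=ChannelParams(10, 50, 1, 0, 1), frame=frame)
        v = voltage_EI(p, np.array([1.0]), np.array([1.0]))
        assert v[0] == pytest.approx(60.0 * (1 - 0.8) / 3.0)

    def test_epem_zero_input_and_rectification(self):
        p = EpEmParams(e_plus=ChannelParams(10, 50, 1, 0, 1),
                       e_minus=ChannelParams(40, 120, 1, 1, 1),
                       g_e_star=1.0, frame=MembraneFrame())
        z = np.zeros(4)
        assert not voltage_EpEm(p, z, z).any()
        # raw E- far above gE*: clipped at gE*, voltage bounded by the
        # Eq.-12-style ceiling with E+ = 0
        v_clip = voltage_EpEm(p, z, 10.0 * np.ones(4))
        em_bound = e_minus_bound(p.g_e_star, p.frame.alpha)
        v_floor = -p.frame.driving_force_mV * em_bound / (1 - em_bound)
        assert np.allclose(v_clip, v_floor)

    def test_epem_most_negative_voltage_bounded(self):
        p = EpEmParams(e_plus=ChannelParams(10, 50, 3, 0, 2),
                       e_minus=ChannelParams(40, 120, 6, 1.5, 1),
                       g_e_star=1.5, frame=MembraneFrame())
        m = make_bar_flash(2, 4, 160.0)
        v, _ = simulate(p, m)
        em_bound = e_minus_bound(p.g_e_star, p.frame.alpha)
        v_floor = -p.frame.driving_force_mV * em_bound / (1 - em_bound)
        assert v.v_mV.min() >= v_floor - 1e-9


class TestEMinusBound:
    def test_direct_values(self):
        assert e_minus_bound(1.0, 1.0) == pytest.approx(1.0 / 3.0)
        assert e_minus_bound(1.0, 1e12) == pytest.approx(0.5, rel=1e-6)

    @given(g=st.floats(0.05, 10.0), a=st.floats(0.05, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_bound_below_one(self, g, a):
        assert 0 < e_minus_bound(g, a) < 1


class TestSimulate:
    def test_zero_movie_flat_voltage(self, ei_cell):
        m = make_bar_flash(0, 1, 0.0)
        v, g = simulate(ei_cell, m)
        assert not v.v_mV.any()
        assert np.allclose(g.sigma_g, 1.0)

    def test_symmetric_cell_has_zero_dsi(self, moving_bar_pair):
        from t5model.synth import ground_truth_cell
        cell = ground_truth_cell("symmetric_null", rng_seed=7)
        assert model_dsi(cell, *moving_bar_pair) == pytest.approx(0.0, abs=1e-9)

    def test_trailing_inhibition_cell_is_directional(self, ei_cell, moving_bar_pair):
        assert model_dsi(ei_cell, *moving_bar_pair) > 0.1

    def test_ei_total_conductance_at_least_one(self, ei_cell):
        m = make_moving_bar(-4, 4, 2, 80.0)
        _, g = simulate(ei_cell, m)
        assert (g.sigma_g >= 1.0).all()

    def test_ei_voltage_coarse_bound(self, ei_cell):
        m = make_bar_flash(1, 4, 160.0)
        v, _ = simulate(ei_cell, m)
        drive = ei_cell.frame.driving_force_mV
        assert np.all(np.abs(v.v_mV) <= drive * max(1.0, ei_cell.frame.alpha))

    def test_epem_sigma_positive_and_em_rectified(self, epem_cell):
        m = make_moving_bar(4, -4, 4, 160.0)
        _, g = simulate(epem_cell, m)
        assert (g.sigma_g > 0).all()
        assert (g.g_hyp <= epem_cell.g_e_star / epem_cell.tonic_norm + 1e-12).all()


class TestScaledEI:
    def test_delta_g_identical_to_epem(self, epem_cell):
        scaled = scale_EI_from_EpEm(epem_cell)
        m = make_moving_bar(-4, 4, 2, 80.0)
        _, g_epem = simulate(epem_cell, m)
        _, g_scaled = simulate(scaled, m)
        assert np.allclose(g_scaled.delta_g, g_epem.delta_g, atol=1e-12)

    def test_sigma_g_dominates_epem(self, epem_cell):
        scaled = scale_EI_from_EpEm(epem_cell)
        m = make_moving_bar(4, -4, 2, 80.0)
        _, g_epem = simulate(epem_cell, m)
        _, g_scaled = simulate(scaled, m)
        assert (g_scaled.sigma_g >= g_epem.sigma_g - 1e-12).all()

    def test_scaled_ei_more_directional_than_epem(self, epem_cell, moving_bar_pair):
        scaled = scale_EI_from_EpEm(epem_cell)
        assert model_dsi(scaled, *moving_bar_pair) > model_dsi(epem_cell, *moving_bar_pair)

    def test_unrectified_flag_changes_only_hyperpolarizing_arm(self, epem_cell):
        m = make_bar_flash(2, 4, 160.0)
        _, g_rect = simulate(scale_EI_from_EpEm(epem_cell, rectify=True), m)
        _, g_raw = simulate(scale_EI_from_EpEm(epem_cell, rectify=False), m)
        assert np.array_equal(g_rect.g_dep, g_raw.g_dep)
        assert (g_raw.g_hyp >= g_rect.g_hyp - 1e-12).all()


class TestMembraneFrame:
    def test_alpha_default(self):
        assert MembraneFrame().alpha == pytest.approx(0.25)

    def test_from_alpha_roundtrip(self):
        f = MembraneFrame.from_alpha(0.7)
        assert f.alpha == pytest.approx(0.7)

    def test_reversal_ordering_enforced(self):
        with pytest.raises(ValueError):
            MembraneFrame(v_leak_mV=-80.0, v_inh_mV=-75.0)

    def test_epem_baseline_is_leak_reversal(self, epem_cell):
        # gI* = gE*/alpha pins Vb at VL: Eq-4-style numerator vanishes
        g_e, g_i = epem_cell.g_e_star, epem_cell.g_i_star
        assert g_e - epem_cell.frame.alpha * g_i == pytest.approx(0.0, abs=1e-12)
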