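"""Calcium sources and the bistable efficacy SDE."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from sleepsyn.constants import SimpleModelConstants
from sleepsyn.patterns import VoltageTrace, pairing_pattern, spikes_to_voltage
from sleepsyn.plasticity import (PlasticityRuleParams, SynapseState,
                                 nmda_influx_trace, saturating_gate,
                                 simulate_synapse, step_calcium,
                                 step_efficacy, vgcc_activation, CalciumState,
                                 calcium_trace)
from sleepsyn import _kernels


class TestGates:
    def test_saturating_gate_midpoint_and_limits(self):
        assert saturating_gate(20.0) == pytest.approx(0.5)
        assert saturating_gate(200.0) == pytest.approx(1.0, abs=1e-12)
        assert saturating_gate(-200.0) == pytest.approx(0.0, abs=1e-12)
        assert saturating_gate(0.0) == pytest.approx(1.0 / (1.0 + np.exp(10.0)))

    def test_vgcc_midpoint_and_closed_form(self):
        assert vgcc_activation(-20.0) == pytest.approx(0.5)
        assert vgcc_activation(-38.0) == pytest.approx(1.0 / (1.0 + np.e ** 2))

    @pytest.mark.parametrize("fn", [saturating_gate, vgcc_activation])
    def test_monotone_increasing_and_bounded(self, fn):
        grid = np.linspace(-120.0, 80.0, 301)
        vals = np.array([fn(v) for v in grid])
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < 1))

    @pytest.mark.parametrize("fn", [saturating_gate, vgcc_activation])
    def test_nonfinite_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(np.nan)


class TestCalcium:
    def test_pure_decay_at_rest(self, nominal_params):
        # presynaptic neuron at rest: gate ~ 0, c_pre decays as exp(-t/tau)
        state = CalciumState(c_pre=1.0, s_nmda=0.0, x_nmda=0.0)
        dt, n = 0.1, 2000
        for _ in range(n):
            state = step_calcium(state, -65.0, -65.0, nominal_params, dt=dt)
        expected = np.exp(-n * dt / nominal_params.tau_pre)
        assert state.c_pre == pytest.approx(expected, rel=1e-4)

    def test_influx_linear_in_conductance(self):
        pre, _ = pairing_pattern(0.0, 1.0, 3.0)
        v = spikes_to_voltage(pre, dt=0.1)
        c1 = SimpleModelConstants()
        c2 = replace(c1, g_nmda=2.0 * c1.g_nmda)
        u1 = nmda_influx_trace(v, c1)
        u2 = nmda_influx_trace(v, c2)
        np.testing.assert_allclose(u2, 2.0 * u1, rtol=1e-12)

    def test_spike_transient_matches_fine_step_reference(self, nominal_params):
        # one presynaptic spike: integrate the same waveform at dt and dt/10;
        # the spike rise is slowed so the voltage is resolved at both steps
        # and the comparison isolates the integrator error
        from sleepsyn.patterns import VoltageTrace
        from sleepsyn.constants import WaveformConstants
        pre, _ = pairing_pattern(0.0, 1.0, 1.2)
        cs = SimpleModelConstants()
        wf = WaveformConstants(rise_ms=4.0, ahp_ms=6.0, recover_ms=16.0)
        v_fine = spikes_to_voltage(pre, wf, dt=0.01)
        out = {}
        for dt, v in ((0.01, v_fine.v), (0.1, v_fine.v[::10])):
            u = nmda_influx_trace(VoltageTrace(v=v, dt=dt), cs)
            c = _kernels.exp_filter(u, dt, nominal_params.tau_pre, 1.0, 0.0)
            out[dt] = c[int(round(600.0 / dt))]  # 100 ms after the spike
        assert out[0.1] == pytest.approx(out[0.01], rel=1e-3)


class TestEfficacyStep:
    def test_cubic_drift_sign_below_thresholds(self, nominal_params):
        p = replace(nominal_params, sigma=0.0)
        s = SynapseState(rho=0.2)
        for _ in range(200):
            s = step_efficacy(s, 0.0, p, dt=50.0)
        assert s.rho < 0.2  # below rho* the cubic pushes toward 0

    def test_gamma_dominated_fixed_point(self, nominal_params):
        # both thresholds exceeded, amplitudes dominate the cubic:
        # rho -> gamma_p / (gamma_p + gamma_d)
        p = replace(nominal_params, sigma=0.0, gamma_p=300.0, gamma_d=150.0)
        c = p.theta_p + 1.0
        s = SynapseState(rho=0.1)
        for _ in range(4000):
            s = step_efficacy(s, c, p, dt=10.0)
        assert s.rho == pytest.approx(300.0 / 450.0, abs=2e-3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rho0=st.floats(0.0, 1.0),
           gamma_p=st.floats(0.0, 1000.0), gamma_d=st.floats(0.0, 1000.0),
           seed=st.integers(0, 2 ** 16))
    def test_boundary_invariance_without_noise(self, rho0, gamma_p, gamma_d,
                                               seed):
        # with sigma = 0 the boundary fluxes confine rho to [0, 1] for any
        # calcium input and any non-negative amplitudes
        c = np.random.default_rng(seed).uniform(0.0, 3.0, size=500)
        traj = _kernels.simulate_efficacy(
            c, 1.0, 1.5e5, 1.2, 0.7, gamma_p, gamma_d,
            0.0, 3.5, 0.5, rho0, np.random.default_rng(1))
        assert traj.min() >= -1e-12 and traj.max() <= 1.0 + 1e-12

    def test_noise_gated_off_below_thresholds(self, nominal_params):
        # identical trajectories with sigma = 0 and sigma huge while the
        # calcium trace stays below both thresholds
        c = np.full(1000, min(nominal_params.theta_p,
                              nominal_params.theta_d) - 1e-6)
        out = []
        for sigma in (0.0, 1e4):
            traj = _kernels.simulate_efficacy(
                c, 1.0, nominal_params.tau_s, nominal_params.theta_p,
                nominal_params.theta_d, nominal_params.gamma_p,
                nominal_params.gamma_d, sigma, nominal_params.z,
                nominal_params.rho_star, 0.3, np.random.default_rng(5))
            out.append(traj)
        np.testing.assert_array_equal(out[0], out[1])

    def test_invalid_dt_rejected(self, nominal_params):
        with pytest.raises(ValueError):
            step_efficacy(SynapseState(), 0.0, nominal_params, dt=0.0)


class TestSimulateSynapse:
    def test_integrator_convergence_halved_dt(self, pairing_ctx, stdp_sets):
        # sparse pairing so threshold-crossing quantization (~dt per event)
        # stays below the bound and the comparison reflects integrator error
        p = replace(stdp_sets[0], sigma=0.0)
        pre, post = pairing_pattern(20.0, 1.0, 3.0)
        finals = {}
        for dt in (0.1, 0.05):
            vp = spikes_to_voltage(pre, dt=dt)
            vq = spikes_to_voltage(post, dt=dt)
            finals[dt] = simulate_synapse(vp, vq, p, rho0=0.5, seed=0)[-1]
        assert abs(finals[0.1] - finals[0.05]) < 1e-3

    def test_high_frequency_pairing_potentiates_stdp(self, stdp_sets):
        # repeated 60 Hz pairing at +20 ms lag drives the synapse upward
        p = replace(stdp_sets[0], sigma=0.0)
        pre, post = pairing_pattern(20.0, 60.0, 10.0)
        vp = spikes_to_voltage(pre, dt=0.05)
        vq = spikes_to_voltage(post, dt=0.05)
        traj = simulate_synapse(vp, vq, p, rho0=0.5, seed=1)
        assert traj[-1] > 0.5

    def test_mismatched_traces_rejected(self, nominal_params):
        a = VoltageTrace(v=np.zeros(100), dt=0.1)
        b = VoltageTrace(v=np.zeros(50), dt=0.1)
        with pytest.raises(ValueError, match="time base"):
            simulate_synapse(a, b, nominal_params)

    def test_subthreshold_input_leaves_rho_at_rho_star(self, nominal_params):
        p = replace(nominal_params, sigma=0.0, beta_nmda=1e-9, beta_vgcc=1e-9)
        pre, post = pairing_pattern(0.0, 1.0, 2.0)
        vp = spikes_to_voltage(pre, dt=0.1)
        vq = spikes_to_voltage(post, dt=0.1)
        traj = simulate_synapse(vp, vq, p, rho0=p.rho_star, seed=0)
        assert traj[-1] == pytest.approx(p.rho_star)

    def test_deterministic_given_seed(self, nominal_params, pairing_ctx):
        p = pairing_ctx.calibrate(nominal_params)
        pre, post = pairing_pattern(10.0, 1.0, 2.0)
        vp = spikes_to_voltage(pre, dt=0.1)
        vq = spikes_to_voltage(post, dt=0.1)
        a = simulate_synapse(vp, vq, p, seed=42)
        b = simulate_synapse(vp, vq, p, seed=42)
        np.testing.assert_array_equal(a, b)


def test_calcium_trace_requires_matching_time_base(nominal_params):
    a = VoltageTrace(v=np.zeros(10), dt=0.1)
    b = VoltageTrace(v=np.zeros(10), dt=0.2)
    with pytest.raises(ValueError):
        calcium_trace(a, b, nominal_params)
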