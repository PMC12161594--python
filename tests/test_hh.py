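"""Conductance-based network: currents, classification, score, bifurcation."""

import numpy as np
import pytest

from sleepsyn import _kernels
from sleepsyn.constants import HHConstants
from sleepsyn.hh import (HHNetwork, NetworkConfig, NeuronParams, SweepResult,
                         SweepStep, bifurcation_sweep, classify_pattern,
                         detect_spikes, multiplier_grid, null_threshold,
                         run_single_neuron, sample_neuron_params,
                         search_rules_hh, select_matched_pair,
                         single_neuron_bifurcates, sleep_score,
                         sleep_score_from_times, run_plastic_network)
from sleepsyn.plasticity import PlasticityRuleParams


def reference_params(**overrides) -> NeuronParams:
    base = dict(g_l=0.067, g_na=50.0, g_k=10.5, g_a=1.0, g_ks=0.576,
                g_ca=0.43, g_kca=0.57, g_nap=0.0686, g_ar=0.0257,
                g_ampa=0.2, g_nmda=0.2, g_gaba=0.1, tau_ca=150.0)
    base.update(overrides)
    return NeuronParams(**base)


class TestNeuronEquations:
    def test_leak_only_equilibrium(self):
        p = reference_params(g_na=0, g_k=0, g_a=0, g_ks=0, g_ca=0, g_kca=0,
                             g_nap=0, g_ar=0, g_ampa=0, g_nmda=0, g_gaba=0)
        cls, v = run_single_neuron(p, duration_s=3.0, settle_s=2.5,
                                   early_stop=False)
        assert v[-1] == pytest.approx(HHConstants().v_l, abs=0.01)

    def test_steady_state_gate_closed_forms(self):
        tab = _kernels.RATE_TABLES
        idx = lambda v: int(round((v - _kernels.V_TAB_MIN) / _kernels.V_TAB_STEP))
        assert tab[idx(-75.0), 11] == pytest.approx(0.5)      # hAR_inf(-75)
        assert tab[idx(-34.0), 7] == pytest.approx(0.5)       # mKS_inf(-34)
        assert tab[idx(-50.0), 5] == pytest.approx(0.125)     # mA_inf(-50)^3
        assert tab[idx(-20.0), 9] == pytest.approx(0.25)      # mCa_inf(-20)^2
        assert tab[idx(20.0), 12] == pytest.approx(0.5)       # f(20)

    def test_rk4_convergence_against_fine_step(self):
        # sub-threshold configuration: trajectory comparison is meaningful
        p = reference_params(g_na=0.5, g_nap=0.01, g_ampa=0.0, g_nmda=0.0,
                             g_gaba=0.0)
        traces = {}
        for dt in (0.05, 0.005):
            cls, v = run_single_neuron(p, duration_s=2.0, settle_s=1.0,
                                       dt=dt, early_stop=False)
            traces[dt] = np.asarray(v, dtype=float)
        assert np.max(np.abs(traces[0.05] - traces[0.005])) < 0.5

    def test_single_and_network_kernels_agree(self):
        p = reference_params()
        net = HHNetwork(p, single=True)
        res = net.run(0.5, dt=0.05)
        cls, v = run_single_neuron(p, duration_s=0.5, settle_s=0.0, dt=0.05,
                                   early_stop=False)
        np.testing.assert_allclose(res.v_rec[:, 0], v, atol=1e-10)

    def test_zero_conductance_neurons_evolve_independently(self):
        p = reference_params(g_ampa=0.0, g_nmda=0.0, g_gaba=0.0)
        net = HHNetwork(p, config=NetworkConfig(n_neurons=5, seed=1))
        res = net.run(0.3, dt=0.05)
        for j in range(1, 5):
            np.testing.assert_allclose(res.v_rec[:, j], res.v_rec[:, 0],
                                       atol=1e-9)

    def test_gating_variables_stay_bounded(self):
        p = reference_params()
        net = HHNetwork(p, single=True)
        net.run(1.0, dt=0.05)
        gates = np.concatenate([net.N[1:5].ravel(), net.E[:3].ravel(),
                                net.G.ravel()])
        assert np.all(gates >= -1e-9) and np.all(gates <= 1.0 + 1e-9)
        assert net.N[_kernels.ICA].min() >= 0.0
        assert net.E[_kernels.ICASYN].min() >= 0.0


class TestSpikeDetection:
    def test_flat_trace(self):
        count, times = detect_spikes(np.full(1000, -65.0), 1.0)
        assert count == 0 and len(times) == 0

    def test_single_action_potential(self):
        v = np.full(200, -65.0)
        v[100:105] = 20.0
        count, times = detect_spikes(v, 1.0)
        assert count == 1 and len(times) == 1

    def test_sine_periods_counted(self):
        t = np.arange(0, 5000.0, 1.0)
        v = -20.0 + 10.0 * np.sin(2 * np.pi * 4.0 * t / 1000.0)
        count, _ = detect_spikes(v, 1.0)
        assert count == 20  # 4 Hz for 5 s


class TestClassification:
    def test_silent_trace_is_resting(self):
        cls = classify_pattern(np.full(10000, -65.0), 0.5)
        assert cls.label == "Resting"

    @staticmethod
    def make_swo_trace(n_spikes_per_burst, isi_ms, dt=0.5, duration_ms=5000.0):
        """1 Hz Up/Down alternation: depolarized plateau with riding spikes."""
        n = int(duration_ms / dt)
        v = np.full(n, -70.0)
        for start in np.arange(200.0, duration_ms, 1000.0):
            up_len = max(150.0, n_spikes_per_burst * isi_ms + 20.0)
            i0, i1 = int(start / dt), int((start + up_len) / dt)
            v[i0:i1] = -45.0
            for k in range(n_spikes_per_burst):
                i = int((start + 5.0 + isi_ms * k) / dt)
                v[i:i + 2] = 10.0
        return v

    def test_burst_train_is_swo(self):
        # 1 Hz bursts of 10 spikes: rate 10/s, peak 1 Hz, 2*1 <= 10 < 30
        dt = 0.5
        v = self.make_swo_trace(10, 12.0, dt)
        cls = classify_pattern(v, dt)
        assert cls.label == "SWO"
        assert cls.spike_rate == pytest.approx(10.0)
        assert cls.peak_frequency == pytest.approx(1.0, abs=0.21)

    def test_rate_thirty_boundary_goes_to_swo_high(self):
        # 30 spikes/s with low peak frequency: SWO excludes rate 30 (strict <)
        dt = 0.5
        v = self.make_swo_trace(30, 5.0, dt)
        cls = classify_pattern(v, dt)
        assert cls.spike_rate == pytest.approx(30.0)
        assert cls.label == "SWO_high"

    def test_amplitude_guard_excludes(self):
        v = np.full(1000, -65.0)
        v[500] = 250.0
        assert classify_pattern(v, 0.5).label == "EXCLUDED"

    def test_tonic_fast_firing_is_awake(self):
        dt = 0.5
        t = np.arange(0, 5000.0, dt)
        v = -65.0 + 60.0 * (np.sin(2 * np.pi * 8.0 * t / 1000.0) > 0.95)
        cls = classify_pattern(v, dt)
        assert cls.label == "AWAKE"


class TestSleepScore:
    def test_uniform_counts_score_zero(self):
        assert sleep_score(np.full(100, 7)) == 0.0

    def test_single_bin_closed_form(self):
        n = 50
        bins = np.zeros(n)
        bins[13] = 40
        assert sleep_score(bins) == pytest.approx(np.sqrt(n - 1))

    def test_silent_is_missing(self):
        assert np.isnan(sleep_score(np.zeros(10)))

    def test_synchronized_scores_above_desynchronized(self):
        rng = np.random.default_rng(0)
        dur = 5000.0
        desync = [np.sort(rng.uniform(0, dur, 50)) for _ in range(20)]
        sync = [np.sort(np.concatenate(
            [b + rng.uniform(0, 30, 10)
             for b in np.arange(250.0, dur, 1000.0)])) for _ in range(20)]
        assert sleep_score_from_times(sync, dur) \
            > sleep_score_from_times(desync, dur)


class TestNullThreshold:
    def test_median_at_p_half(self):
        thr, _ = null_threshold(n_neurons=10, duration_s=2.5, reps=200,
                                p=0.5, seed=1)
        # p = 0.5 quantile is the ensemble median: far below the p=0.01 tail
        thr_tail, _ = null_threshold(n_neurons=10, duration_s=2.5, reps=200,
                                     p=0.01, seed=1)
        assert thr < thr_tail

    def test_deterministic_under_seed(self):
        a = null_threshold(n_neurons=5, duration_s=2.5, reps=120, seed=3)
        b = null_threshold(n_neurons=5, duration_s=2.5, reps=120, seed=3)
        assert a == b

    def test_threshold_nonincreasing_with_duration(self):
        thr_short, _ = null_threshold(n_neurons=20, duration_s=2.5, reps=400,
                                      seed=5)
        thr_long, _ = null_threshold(n_neurons=20, duration_s=10.0, reps=400,
                                     seed=5)
        assert thr_long <= thr_short + 0.05


class TestSearchAndBifurcation:
    def test_sampled_parameters_within_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = sample_neuron_params(rng)
            for name in ("g_l", "g_na", "g_k", "g_a", "g_ks", "g_ca",
                         "g_kca", "g_nap", "g_ar"):
                assert 1e-2 <= getattr(p, name) <= 1e2
            for name in ("g_ampa", "g_nmda", "g_gaba"):
                assert 1e-3 <= getattr(p, name) <= 1e1
            assert 1e1 <= p.tau_ca <= 1e3

    def test_reference_initial_values_used(self):
        p = reference_params(g_na=0.0, g_nap=0.0, g_ampa=0, g_nmda=0, g_gaba=0)
        cls, v = run_single_neuron(p, duration_s=0.01, settle_s=0.0,
                                   dt=0.01, record_dt_ms=0.01,
                                   early_stop=False)
        assert v[0] == pytest.approx(-45.0)

    @pytest.mark.parametrize("stage,axis,lo,hi,count", [
        ("single", "g_nmda", 1e-2, 1e2, 100),
        ("single", "presyn", 1e-2, 1e1, 100),
        ("network1", "g_nmda", 1e-2, 1e2, 17),
        ("network1", "presyn", 1e-2, 1e1, 16),
        ("network2", "g_nmda", 1e-2, 10 ** 1.5, 36),
        ("network2", "presyn", 1e-2, 10 ** 0.8, 29),
    ])
    def test_multiplier_grids_match_protocol(self, stage, axis, lo,
                                                     hi, count):
        grid = multiplier_grid(stage, axis)
        assert len(grid) == count
        assert grid[0] == pytest.approx(lo)
        assert grid[-1] == pytest.approx(hi)
        assert np.allclose(np.diff(np.log10(grid)),
                           np.diff(np.log10(grid))[0])

    def test_single_neuron_acceptance_rule(self):
        steps = [SweepStep(multiplier=0.1, label="AWAKE", v_min=-55.0),
                 SweepStep(multiplier=1.0, label="SWO", v_min=-70.0)]
        assert single_neuron_bifurcates(SweepResult("g_nmda", "single", steps))
        steps[1].v_min = -58.0  # margin violated: -58 + 5 >= -55
        assert not single_neuron_bifurcates(
            SweepResult("g_nmda", "single", steps))

    def test_network_acceptance_rules_on_synthetic_sweep(self):
        steps = [
            SweepStep(0.1, "network", sleep_score=0.5, frac_wake=0.6,
                      frac_sleep=0.0, mean_rate=5.0),
            SweepStep(0.3, "network", sleep_score=0.9, frac_wake=0.2,
                      frac_sleep=0.1, mean_rate=5.5),   # wake% too low
            SweepStep(1.0, "network", sleep_score=1.5, frac_sleep=0.7,
                      frac_wake=0.0, mean_rate=6.0),
            SweepStep(3.0, "network", sleep_score=1.2, frac_sleep=0.9,
                      frac_wake=0.0, mean_rate=6.2),    # score below 1.3
        ]
        sweep = SweepResult("g_nmda", "network2", steps)
        assert [s.multiplier for s in sweep.accepted_wake_steps()] == [0.1]
        assert [s.multiplier for s in sweep.accepted_sleep_steps()] == [1.0]
        pair = select_matched_pair(sweep)
        assert pair is not None
        assert pair.rate_difference < 2.0

    def test_matched_pair_requires_close_rates(self):
        steps = [
            SweepStep(0.1, "network", sleep_score=0.5, frac_wake=0.6,
                      frac_sleep=0.0, mean_rate=2.0),
            SweepStep(1.0, "network", sleep_score=1.5, frac_sleep=0.7,
                      frac_wake=0.0, mean_rate=9.0),
        ]
        sweep = SweepResult("g_nmda", "network2", steps)
        assert select_matched_pair(sweep) is None  # excluded, |diff| >= 2 Hz

    def test_network_sweep_smoke(self):
        p = reference_params()
        sweep = bifurcation_sweep(p, "g_nmda", "network1", seed=0, dt=0.05,
                                  config=NetworkConfig(n_neurons=10, seed=2),
                                  duration_s=0.5,
                                  multipliers=np.array([0.01, 1.0]))
        assert len(sweep.steps) == 2
        assert all(np.isfinite(s.mean_rate) for s in sweep.steps)


class TestNetworkStructure:
    def test_ei_ratio_and_no_inhibitory_to_inhibitory(self):
        net = HHNetwork(reference_params(), config=NetworkConfig(seed=4))
        assert net.is_exc.sum() == 64 and (~net.is_exc).sum() == 16
        for q in net.i_post:
            assert net.is_exc[q]  # GABA synapses only onto excitatory cells
        for p in net.i_pre:
            assert not net.is_exc[p]
        for p in net.e_pre:
            assert net.is_exc[p]

    def test_conductance_divided_by_mean_synapse_count(self):
        params = reference_params()
        net = HHNetwork(params, config=NetworkConfig(seed=4))
        avg_e = len(net.e_pre) / net.n
        assert net.g_ampa[0] == pytest.approx(params.g_ampa / avg_e)


class TestPlasticCoupling:
    def test_neutral_efficacy_leaves_conductance_unchanged(self):
        # rho pinned at 0.5 -> gAMPA = g_min + 0.5 (g_max - g_min) = original
        p = reference_params()
        rule = PlasticityRuleParams(theta_p=1e9, theta_d=1e8, gamma_p=0.0,
                                    gamma_d=0.0, tau_pre=20.0, tau_post=15.0,
                                    sigma=0.0, tau_s=1e5)
        cfg = NetworkConfig(n_neurons=5, seed=6)
        nets = []
        for couple in (False, True):
            net = HHNetwork(p, config=cfg, rule=rule, seed=0)
            res = net.run(0.3, dt=0.05, plastic=couple, couple_rho=couple)
            nets.append(res.v_rec.copy())
        np.testing.assert_allclose(nets[0], nets[1], atol=1e-9)

    def test_efficacy_extremes_scale_ampa(self):
        # coupling law g_min + rho (g_max - g_min) with g_min/g_max = 0.5/1.5
        # of the original conductance: saturated efficacy -> 1.5x, silent -> 0.5x
        p = reference_params()
        rule = PlasticityRuleParams(theta_p=1e9, theta_d=1e8, gamma_p=0.0,
                                    gamma_d=0.0, tau_pre=20.0, tau_post=15.0,
                                    sigma=0.0, tau_s=1e5)
        cfg = NetworkConfig(n_neurons=4, seed=3)
        traces = {}
        for rho0 in (0.0, 1.0):
            net = HHNetwork(p, config=cfg, rule=rule, seed=0)
            net.rho[:] = rho0
            res = net.run(0.2, dt=0.05, plastic=True, couple_rho=True)
            traces[rho0] = res.v_rec.copy()
        # explicit conductance comparators: 0.5x / 1.5x of the original value
        for rho0, factor in ((0.0, 0.5), (1.0, 1.5)):
            net = HHNetwork(p, config=cfg, seed=0)
            net.g_ampa *= factor
            ref = net.run(0.2, dt=0.05)
            np.testing.assert_allclose(traces[rho0], ref.v_rec, atol=1e-9)

    def test_run_plastic_network_smoke(self):
        p = reference_params()
        rule = PlasticityRuleParams(theta_p=1.2, theta_d=0.7, gamma_p=100.0,
                                    gamma_d=50.0, tau_pre=20.0, tau_post=15.0,
                                    sigma=100.0, tau_s=1e5)
        out = run_plastic_network(p, rule, multiplier=1.0, axis="g_nmda",
                                  config=NetworkConfig(n_neurons=8, seed=1),
                                  duration_s=1.0, skip_s=0.2, dt=0.05, seed=2)
        assert 0.0 <= out["mean_efficacy"] <= 1.0
        assert np.isfinite(out["mean_rate"])


class TestRuleSearchInNetwork:
    def test_accepted_sets_respect_boxes_and_sse(self):
        # synthetic wake-like trace as the template
        from sleepsyn.patterns import PatternSpec, sample_wake_train, \
            spikes_to_voltage
        # sparse tonic trace (~2 Hz): transients stay unitary, the regime
        # in which the lag-duplication protocol separates the rules
        spec = PatternSpec(state="wake", duration_s=4.0, isim=2.3, seed=31)
        pat = sample_wake_train(spec)
        v = spikes_to_voltage(pat, dt=0.1)
        found = search_rules_hh(v.v, 0.1, "STDP", budget=4000, seed=2,
                                n_target=2)
        assert len(found) >= 1
        for params, sse in found:
            assert sse < 0.6
            assert 0.8 <= params.theta_p <= 1.6
            assert 0.5 <= params.theta_d <= 1.0
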