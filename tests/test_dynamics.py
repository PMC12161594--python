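"""Kinase sleep-wake oscillator, Process S and model selection."""

import numpy as np
import pytest
from dataclasses import replace

from sleepsyn.dynamics import (CycleRun, KinaseParams, KinaseState,
                               ProcessSParams, balance_ok, bistable_params,
                               classify_periods, couple_conductance,
                               presyn_calcium, process_s,
                               select_dynamics_models, simulate_kinase,
                               sliding_sleep_scores, step_kinase)
from sleepsyn.plasticity import PlasticityRuleParams


@pytest.fixture
def rule():
    return PlasticityRuleParams(theta_p=1.2, theta_d=0.7, gamma_p=100.0,
                                gamma_d=50.0, tau_pre=20.0, tau_post=15.0,
                                sigma=100.0, tau_s=1e5, beta_vgcc=2.0)


class TestKinaseStep:
    def test_sigmoid_midpoint_fixed_point(self):
        # no coupling, no input: r relaxes to R_inf(0) = 0.5
        p = KinaseParams(w=0.0, b=0.0, I=0.0, alpha=0.0, theta=0.0,
                         epsilon=0.0)
        ks = KinaseState(r=0.1, a=0.0)
        for _ in range(5000):
            ks = step_kinase(ks, 0.0, p, dt=50.0)
        assert ks.r == pytest.approx(0.5, abs=1e-6)

    def test_inhibition_lowers_r_fixed_point(self):
        base = KinaseParams(w=0.0, I=0.5, alpha=0.0, theta=0.0, epsilon=0.0)
        finals = []
        for b in (0.0, 5.0):
            p = replace(base, b=b)
            ks = KinaseState(r=0.5, a=1.0)
            for _ in range(3000):
                ks = replace(step_kinase(ks, 0.0, p, dt=50.0), a=1.0)
            finals.append(ks.r)
        assert finals[1] < finals[0]

    def test_ou_stationary_sd_recovers_epsilon(self):
        p = KinaseParams(theta=1e-3, epsilon=0.08)
        tr = simulate_kinase(p, 4000.0, dt=10.0, ca=0.0, seed=12)
        xi = tr["xi"][2000:]
        # effective sample size ~ T * theta; SE of the SD ~ eps/sqrt(2 n_eff)
        n_eff = len(xi) * 10.0 * p.theta
        se = p.epsilon / np.sqrt(2 * n_eff)
        assert abs(xi.std() - p.epsilon) < 3 * se

    def test_ou_autocorrelation_time(self):
        p = KinaseParams(theta=1e-3, epsilon=0.05)
        tr = simulate_kinase(p, 4000.0, dt=10.0, seed=3)
        xi = tr["xi"][1000:]
        lag = int(1.0 / p.theta / 10.0)  # one autocorrelation time in samples
        rho = np.corrcoef(xi[:-lag], xi[lag:])[0, 1]
        assert rho == pytest.approx(np.exp(-1.0), abs=0.1)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            step_kinase(KinaseState(), 0.0, KinaseParams(), dt=0.0)


class TestRegimes:
    def test_oscillatory_default_alternates(self):
        p = KinaseParams(theta=0.0, epsilon=0.0)
        tr = simulate_kinase(p, 600.0, dt=20.0, ca=0.5)
        r = tr["r"][2000:]
        assert np.sum(np.diff(r > 0.5) != 0) >= 2

    def test_bistable_without_noise_never_switches(self):
        p = bistable_params()
        for r0 in (0.05, 0.95):
            tr = simulate_kinase(p, 400.0, dt=20.0, ca=0.0,
                                 state0=KinaseState(r=r0, a=0.1, xi=0.0))
            assert np.all((tr["r"] > 0.5) == (r0 > 0.5))

    def test_r_leads_a_in_oscillation(self):
        # rising sleep need: r is high when a starts rising (sleep onset)
        p = KinaseParams(theta=0.0, epsilon=0.0)
        tr = simulate_kinase(p, 800.0, dt=20.0, ca=0.5)
        r, a = tr["r"][3000:], tr["a"][3000:]
        sleep_onsets = np.flatnonzero(np.diff((a > 0.5).astype(int)) == 1)
        wake_onsets = np.flatnonzero(np.diff((a > 0.5).astype(int)) == -1)
        if len(sleep_onsets) and len(wake_onsets):
            assert np.mean(r[sleep_onsets]) > np.mean(r[wake_onsets])


class TestCoupling:
    def test_zero_activity_silences_conductance(self):
        p = KinaseParams(coupling_variable="a")
        assert couple_conductance(KinaseState(a=0.0), 3.0, p) == 0.0

    def test_linear_in_coupling_variable(self):
        p = KinaseParams(coupling_variable="a", max_rate=2.0)
        g1 = couple_conductance(KinaseState(a=0.25), 1.0, p)
        g2 = couple_conductance(KinaseState(a=0.5), 1.0, p)
        assert g2 == pytest.approx(2 * g1)

    def test_presyn_calcium_sign_and_linearity(self, rule):
        from sleepsyn.constants import HHConstants
        c = HHConstants()
        assert presyn_calcium(c.v_ca, rule) == pytest.approx(0.0)
        v = -40.0
        val = presyn_calcium(v, rule)
        assert val >= 0.0
        double = presyn_calcium(v, replace(rule, beta_vgcc=2 * rule.beta_vgcc))
        assert double == pytest.approx(2 * val)


class TestProcessS:
    P = ProcessSParams(upper=1.0, lower=0.0, tau_i=60_000.0, tau_d=40_000.0)

    def test_all_wake_saturates_upward(self):
        s = process_s(np.ones(4000, dtype=bool), 500.0, self.P, 0.2)
        assert np.all(np.diff(s) >= -1e-15)
        assert s[-1] == pytest.approx(1.0, abs=1e-6)

    def test_all_sleep_decays_downward(self):
        s = process_s(np.zeros(4000, dtype=bool), 500.0, self.P, 0.8)
        assert np.all(np.diff(s) <= 1e-15)
        assert s[-1] == pytest.approx(0.0, abs=1e-6)

    def test_single_step_closed_form(self):
        s0, dt = 0.3, 500.0
        s = process_s(np.array([True]), dt, self.P, s0)
        assert s[1] == pytest.approx(
            1.0 - (1.0 - s0) * np.exp(-dt / self.P.tau_i), rel=1e-12)

    def test_degenerate_asymptotes_rejected(self):
        with pytest.raises(ValueError):
            ProcessSParams(upper=0.0, lower=1.0)

    def test_bounds_never_violated(self):
        rng = np.random.default_rng(0)
        labels = rng.random(2000) < 0.5
        s = process_s(labels, 500.0, self.P, 0.5)
        assert s.min() >= 0.0 and s.max() <= 1.0


class TestPeriodClassification:
    def test_constant_extremes(self):
        assert classify_periods(np.full(30, 5.0), threshold=1.3).all()
        assert not classify_periods(np.full(30, 0.2), threshold=1.3).any()

    def test_alternating_scores_switch_labels(self):
        scores = np.r_[np.full(30, 0.2), np.full(30, 5.0)]
        labels = classify_periods(scores, threshold=1.3, smooth=10)
        assert not labels[:20].any() and labels[-20:].all()

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            classify_periods(np.ones(5), 1.0, smooth=10)

    def test_sliding_scores_window_count(self):
        bins = np.ones(200)  # 10 s of 50 ms bins
        scores = sliding_sleep_scores(bins)
        assert len(scores) == (200 - 100) // 10 + 1


def _run(ratio: float, corr_sign: float = 1.0) -> CycleRun:
    n = 200
    n_sleep = int(n * ratio / (1 + ratio))
    labels = np.zeros(n, dtype=bool)
    labels[:n_sleep] = True
    t = np.linspace(0, 4 * np.pi, n)
    s = 0.5 + 0.4 * np.sin(t)
    r = 0.5 + corr_sign * 0.4 * np.sin(t)
    return CycleRun(labels=labels, r=r, a=r.copy(), s=s, scores=np.ones(n),
                    rho_mean=np.full(n, 0.5), rho_std=np.zeros(n), dt_ms=500.0)


class TestModelSelection:
    def test_balance_boundaries_half_open(self):
        assert balance_ok(0.7)
        assert not balance_ok(1.3)
        assert balance_ok(1.0)

    def test_filters_and_ranks_by_correlation(self):
        runs = [_run(1.0, 1.0), _run(1.0, -1.0), _run(3.0, 1.0)]
        picked = select_dynamics_models(runs, optimize_variable="r")
        assert [i for i, _ in picked] == [0, 1]  # unbalanced run 2 dropped
        assert picked[0][1] > picked[1][1]

    def test_constant_trace_excluded_with_diagnostic(self):
        run = _run(1.0)
        run.r = np.full_like(run.r, 0.5)
        with pytest.warns(UserWarning, match="constant"):
            picked = select_dynamics_models([run], optimize_variable="r")
        assert picked == []


class TestClosedLoop:
    """Reduced-scale smoke runs of the coupled network + kinase cycle."""

    def _network(self, n=8):
        from sleepsyn.hh import HHNetwork, NetworkConfig, NeuronParams
        params = NeuronParams(g_l=0.067, g_na=50.0, g_k=10.5, g_a=1.0,
                              g_ks=0.576, g_ca=0.43, g_kca=0.57,
                              g_nap=0.0686, g_ar=0.0257, g_ampa=0.2,
                              g_nmda=0.2, g_gaba=0.1, tau_ca=150.0)
        rule = PlasticityRuleParams(theta_p=1.2, theta_d=0.7, gamma_p=100.0,
                                    gamma_d=50.0, tau_pre=20.0, tau_post=15.0,
                                    sigma=100.0, tau_s=1e5)
        net = HHNetwork(params, config=NetworkConfig(n_neurons=n, seed=2),
                        rule=rule, seed=4)
        return net, params, rule

    def test_full_cycle_produces_consistent_report(self):
        from sleepsyn.dynamics import KinaseParams, run_full_cycle
        net, params, rule = self._network()
        kp = KinaseParams(tau_r=2000.0, tau_a=8000.0)
        run = run_full_cycle(net, rule, kp, duration_s=12.0,
                             kinase_dt_ms=50.0, dt=0.05, seed=3,
                             threshold=1.0)
        n_steps = len(run.labels)
        assert len(run.r) == n_steps and len(run.a) == n_steps
        assert len(run.s) == n_steps
        assert np.all((run.s >= 0.0) & (run.s <= 1.0))
        assert np.all((run.r >= -1e-9) & (run.r <= 1.0 + 1e-9))
        assert np.all((run.rho_mean >= 0.0) & (run.rho_mean <= 1.0))
        assert np.isfinite(run.sleep_wake_ratio) or run.sleep_wake_ratio == np.inf

    def test_stimulation_groups_and_ratios(self):
        from sleepsyn.hh import (HHNetwork, NetworkConfig,
                                 stimulation_experiment)
        net, params, rule = self._network()
        out = stimulation_experiment(
            params, rule, config=NetworkConfig(n_neurons=80, seed=5),
            wake_s=0.3, stim_s=0.2, sleep_s=0.3, dt=0.05, seed=6)
        # the reference grouping of the 64 excitatory neurons
        assert out["group1_n"] == 20
        assert out["group2_n"] == 20
        assert out["group3_n"] == 24
        for k in ("group1", "group2", "group3"):
            assert np.isfinite(out[f"{k}_sleep_ratio"])
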