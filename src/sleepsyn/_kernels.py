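"""Numba-compiled inner loops.

Everything here is deliberately free of Python objects: plain float64/float32
arrays in, arrays or scalars out.  Public modules wrap these kernels with
typed, validated interfaces.
"""

from __future__ import annotations

import numpy as np
from numba import njit


# ---------------------------------------------------------------------------
# calcium-source kinetics (simple two-neuron model)
# ---------------------------------------------------------------------------

@njit(cache=True)
def sigmoid_gate(v):
    """Saturating presynaptic gate f(V) = 1/(1+exp(-(V-20)/2))."""
    return 1.0 / (1.0 + np.exp(-(v - 20.0) / 2.0))


@njit(cache=True)
def vgcc_gate(v):
    """Instantaneous VGCC activation mCa_inf(V) = 1/(1+exp(-(V+20)/9))."""
    return 1.0 / (1.0 + np.exp(-(v + 20.0) / 9.0))


@njit(cache=True)
def nmda_gating_trace(v_pre, dt, a_x, tau_x, a_s, tau_s, s0, x0):
    """Second-order NMDAR gating s(t) driven by the presynaptic voltage.

    dx/dt = a_x f(Vpre) - x/tau_x ;  ds/dt = a_s x (1-s) - s/tau_s
    RK4 with Vpre interpolated linearly inside the step.
    """
    n = v_pre.shape[0]
    s_out = np.empty(n)
    s = s0
    x = x0
    s_out[0] = s
    for i in range(n - 1):
        f0 = sigmoid_gate(v_pre[i])
        f1 = sigmoid_gate(v_pre[i + 1])
        # midpoint stage uses f at the midpoint voltage: with piecewise-linear
        # V the three nodes give Simpson-quality quadrature of f(V(t))
        fm = sigmoid_gate(0.5 * (v_pre[i] + v_pre[i + 1]))
        # k1
        dx1 = a_x * f0 - x / tau_x
        ds1 = a_s * x * (1.0 - s) - s / tau_s
        # k2
        x2 = x + 0.5 * dt * dx1
        s2 = s + 0.5 * dt * ds1
        dx2 = a_x * fm - x2 / tau_x
        ds2 = a_s * x2 * (1.0 - s2) - s2 / tau_s
        # k3
        x3 = x + 0.5 * dt * dx2
        s3 = s + 0.5 * dt * ds2
        dx3 = a_x * fm - x3 / tau_x
        ds3 = a_s * x3 * (1.0 - s3) - s3 / tau_s
        # k4
        x4 = x + dt * dx3
        s4 = s + dt * ds3
        dx4 = a_x * f1 - x4 / tau_x
        ds4 = a_s * x4 * (1.0 - s4) - s4 / tau_s
        x += dt * (dx1 + 2.0 * dx2 + 2.0 * dx3 + dx4) / 6.0
        s += dt * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4) / 6.0
        s_out[i + 1] = s
    return s_out


@njit(cache=True)
def exp_filter(u, dt, tau, beta, c0):
    """Exact exponential integrator for dc/dt = beta*u(t) - c/tau.

    The source u is taken piecewise-linear between samples; the linear ODE is
    then integrated exactly over each step.  c is clipped at 0 from below.
    """
    n = u.shape[0]
    out = np.empty(n)
    e = np.exp(-dt / tau)
    # int_0^dt exp(-(dt-s)/tau) ds and the ramp moment
    w_total = tau * (1.0 - e)
    w_ramp = tau - tau * tau * (1.0 - e) / dt
    w0 = w_total - w_ramp
    c = c0
    out[0] = c
    for i in range(n - 1):
        c = c * e + beta * (w0 * u[i] + w_ramp * u[i + 1])
        if c < 0.0:
            c = 0.0
        out[i + 1] = c
    return out


# ---------------------------------------------------------------------------
# efficacy SDE
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rho_drift(rho, gp_on, gd_on, gamma_p, gamma_d, rho_star):
    d = -rho * (1.0 - rho) * (rho_star - rho)
    if gp_on:
        d += gamma_p * (1.0 - rho)
    if gd_on:
        d -= gamma_d * rho
    return d


@njit(cache=True)
def simulate_efficacy(c, dt, tau_s, theta_p, theta_d, gamma_p, gamma_d,
                      sigma, z, rho_star, rho0, rng):
    """One realization of the efficacy SDE driven by a calcium trace.

    Deterministic drift advanced with RK4 (threshold gates frozen at the
    step's calcium value); noise sigma*z*sqrt(#thresholds)*sqrt(dt)*eta is
    added per step, active only while calcium exceeds a threshold.
    """
    n = c.shape[0]
    out = np.empty(n)
    rho = rho0
    out[0] = rho
    sq = np.sqrt(dt)
    for i in range(n - 1):
        ci = c[i]
        gp = ci >= theta_p
        gd = ci >= theta_d
        k1 = _rho_drift(rho, gp, gd, gamma_p, gamma_d, rho_star)
        k2 = _rho_drift(rho + 0.5 * dt * k1 / tau_s, gp, gd, gamma_p, gamma_d, rho_star)
        k3 = _rho_drift(rho + 0.5 * dt * k2 / tau_s, gp, gd, gamma_p, gamma_d, rho_star)
        k4 = _rho_drift(rho + dt * k3 / tau_s, gp, gd, gamma_p, gamma_d, rho_star)
        rho += dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / (6.0 * tau_s)
        if gp or gd:
            nth = 2.0 if (gp and gd) else 1.0
            rho += sigma * z * np.sqrt(nth) * sq * rng.standard_normal() / tau_s
        out[i + 1] = rho
    return out


@njit(cache=True)
def mc_up_fraction(seg_len, seg_onp, seg_ond, dt, tau_s, gamma_p, gamma_d,
                   sigma, z, rho_star, rho0, n_rep, rng):
    """Fraction of noise realizations ending above rho* after the protocol.

    The SDE depends on calcium only through the two threshold gates, so the
    protocol is described by runs of constant gate state (seg_len steps of
    size dt each).  Gated segments are integrated at the full step size with
    per-step noise; sub-threshold segments are noise-free and follow the
    slow autonomous cubic drift, integrated with coarse RK4 steps (<= 10 ms,
    the drift rate is bounded by 1/(16 tau_s) per ms so the coarse-step
    error is negligible).  After the protocol the drift relaxes rho to the
    wells at 0 or 1, so the post-protocol mean efficacy equals the up-well
    probability.
    """
    sq = np.sqrt(dt)
    rho = np.full(n_rep, rho0)
    n_seg = seg_len.shape[0]
    for k in range(n_seg):
        on_p = seg_onp[k]
        on_d = seg_ond[k]
        span = seg_len[k] * dt
        if not on_p and not on_d:
            n_sub = int(span / 10.0) + 1
            h = span / n_sub
            for r in range(n_rep):
                rr = rho[r]
                for _ in range(n_sub):
                    k1 = _rho_drift(rr, False, False, 0.0, 0.0, rho_star)
                    k2 = _rho_drift(rr + 0.5 * h * k1 / tau_s, False, False, 0.0, 0.0, rho_star)
                    k3 = _rho_drift(rr + 0.5 * h * k2 / tau_s, False, False, 0.0, 0.0, rho_star)
                    k4 = _rho_drift(rr + h * k3 / tau_s, False, False, 0.0, 0.0, rho_star)
                    rr += h * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / (6.0 * tau_s)
                rho[r] = rr
        else:
            nth = 2.0 if (on_p and on_d) else 1.0
            amp = sigma * z * np.sqrt(nth) * sq / tau_s
            for _ in range(seg_len[k]):
                for r in range(n_rep):
                    rr = rho[r]
                    k1 = _rho_drift(rr, on_p, on_d, gamma_p, gamma_d, rho_star)
                    k2 = _rho_drift(rr + 0.5 * dt * k1 / tau_s, on_p, on_d, gamma_p, gamma_d, rho_star)
                    k3 = _rho_drift(rr + 0.5 * dt * k2 / tau_s, on_p, on_d, gamma_p, gamma_d, rho_star)
                    k4 = _rho_drift(rr + dt * k3 / tau_s, on_p, on_d, gamma_p, gamma_d, rho_star)
                    rho[r] = rr + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / (6.0 * tau_s) \
                        + amp * rng.standard_normal()
    n_up = 0
    for r in range(n_rep):
        if rho[r] > rho_star:
            n_up += 1
    return n_up / n_rep


# ---------------------------------------------------------------------------
# rule-search evaluation
# ---------------------------------------------------------------------------

@njit(cache=True)
def occupancy_ms(c_pre, c_post, shift, i0, i1, theta_p, theta_d, dt):
    """Above-threshold time (ms) of c_pre[i] + c_post[i-shift] over [i0, i1)."""
    np_cnt = 0
    nd_cnt = 0
    for i in range(i0, i1):
        j = i - shift
        c = c_pre[i]
        if 0 <= j < c_post.shape[0]:
            c += c_post[j]
        if c >= theta_p:
            np_cnt += 1
        if c >= theta_d:
            nd_cnt += 1
    return np_cnt * dt, nd_cnt * dt


@njit(cache=True)
def lag_occupancies(c_pre, c_post, shifts, i0, i1, theta_p, theta_d, dt):
    """Occupancy times for a whole lag grid; returns (n_lags, 2) ms."""
    out = np.empty((shifts.shape[0], 2))
    for k in range(shifts.shape[0]):
        tp, td = occupancy_ms(c_pre, c_post, shifts[k], i0, i1, theta_p, theta_d, dt)
        out[k, 0] = tp
        out[k, 1] = td
    return out


# ---------------------------------------------------------------------------
# simple-model state comparison (many rule sets, shared influx traces)
# ---------------------------------------------------------------------------

@njit(cache=True)
def state_comparison_kernel(u_nmda, u_vgcc, pre_col, post_col,
                            tau_pre, tau_post, beta_n, beta_v,
                            theta_p, theta_d, gamma_p, gamma_d,
                            sigma, z, tau_s, rho_star,
                            rho0, dt, win_start, rng):
    """Efficacy statistics for many rule sets driven by shared influx traces.

    u_nmda: (L, n_nmda) float32 unit-beta NMDAR-source influx, one column per
        neuron that acts presynaptically
    u_vgcc: (L, n_vgcc) float32 unit-beta VGCC-source influx, one column per
        neuron that acts postsynaptically
    pre_col/post_col: per-synapse column indices into the two trace blocks
    returns (mean_eff, cv_eff): per-rule-set time averages over
        [win_start, L) of the across-synapse mean and CV of rho.

    The time loop is outermost so each influx row is read once and shared by
    every rule set (the trace blocks dominate memory traffic).
    """
    L = u_nmda.shape[0]
    n_sets = tau_pre.shape[0]
    n_syn = pre_col.shape[0]
    n_vg = u_vgcc.shape[1]
    sqdt = np.sqrt(dt)

    e_pre = np.empty(n_sets)
    w0_pre = np.empty(n_sets)
    w1_pre = np.empty(n_sets)
    e_post = np.empty(n_sets)
    w0_post = np.empty(n_sets)
    w1_post = np.empty(n_sets)
    amp1 = np.empty(n_sets)
    amp2 = np.empty(n_sets)
    # exact exponential maps of the gated (linear) efficacy drift per
    # threshold combination; the weak cubic term is stepped explicitly
    le_p = np.empty(n_sets)
    le_d = np.empty(n_sets)
    le_pd = np.empty(n_sets)
    winf_pd = np.empty(n_sets)
    for r in range(n_sets):
        ep = np.exp(-dt / tau_pre[r])
        wt = tau_pre[r] * (1.0 - ep)
        wr = tau_pre[r] - tau_pre[r] * tau_pre[r] * (1.0 - ep) / dt
        e_pre[r] = ep
        w0_pre[r] = (wt - wr) * beta_n[r]
        w1_pre[r] = wr * beta_n[r]
        eq = np.exp(-dt / tau_post[r])
        wt = tau_post[r] * (1.0 - eq)
        wr = tau_post[r] - tau_post[r] * tau_post[r] * (1.0 - eq) / dt
        e_post[r] = eq
        w0_post[r] = (wt - wr) * beta_v[r]
        w1_post[r] = wr * beta_v[r]
        amp1[r] = sigma[r] * z * sqdt / tau_s[r]
        amp2[r] = amp1[r] * np.sqrt(2.0)
        le_p[r] = np.exp(-gamma_p[r] * dt / tau_s[r])
        le_d[r] = np.exp(-gamma_d[r] * dt / tau_s[r])
        g_tot = gamma_p[r] + gamma_d[r]
        le_pd[r] = np.exp(-g_tot * dt / tau_s[r])
        winf_pd[r] = gamma_p[r] / g_tot if g_tot > 0 else 0.0

    c_pre = np.zeros((n_sets, n_syn))
    c_post = np.zeros((n_sets, n_vg))
    rho = np.full((n_sets, n_syn), rho0)
    acc_mean = np.zeros(n_sets)
    acc_cv = np.zeros(n_sets)
    n_win = L - win_start

    for i in range(L - 1):
        in_win = (i + 1) >= win_start
        for r in range(n_sets):
            for q in range(n_vg):
                cq = c_post[r, q] * e_post[r] + w0_post[r] * u_vgcc[i, q] \
                    + w1_post[r] * u_vgcc[i + 1, q]
                c_post[r, q] = cq if cq > 0.0 else 0.0
            tp = theta_p[r]
            td = theta_d[r]
            ts = tau_s[r]
            s1 = 0.0
            s2 = 0.0
            for s in range(n_syn):
                cp = c_pre[r, s] * e_pre[r] + w0_pre[r] * u_nmda[i, pre_col[s]] \
                    + w1_pre[r] * u_nmda[i + 1, pre_col[s]]
                if cp < 0.0:
                    cp = 0.0
                c_pre[r, s] = cp
                c = cp + c_post[r, post_col[s]]
                on_p = c >= tp
                on_d = c >= td
                rr = rho[r, s]
                rr -= dt / ts * rr * (1.0 - rr) * (rho_star - rr)
                if on_p and on_d:
                    rr = winf_pd[r] + (rr - winf_pd[r]) * le_pd[r]
                    rr += amp2[r] * rng.standard_normal()
                elif on_p:
                    rr = 1.0 + (rr - 1.0) * le_p[r]
                    rr += amp1[r] * rng.standard_normal()
                elif on_d:
                    rr = rr * le_d[r]
                    rr += amp1[r] * rng.standard_normal()
                rho[r, s] = rr
                if in_win:
                    s1 += rr
                    s2 += rr * rr
            if in_win:
                m = s1 / n_syn
                var = s2 / n_syn - m * m
                if var < 0.0:
                    var = 0.0
                acc_mean[r] += m
                if m != 0.0:
                    acc_cv[r] += np.sqrt(var) / np.abs(m)
    mean_eff = acc_mean / n_win
    cv_eff = acc_cv / n_win
    return mean_eff, cv_eff


# ---------------------------------------------------------------------------
# Hodgkin-Huxley machinery: tabulated voltage-dependent rates
# ---------------------------------------------------------------------------

V_TAB_MIN = -200.0
V_TAB_MAX = 200.0
V_TAB_STEP = 0.05
N_TAB = int(round((V_TAB_MAX - V_TAB_MIN) / V_TAB_STEP)) + 1
# table rows: 0 mNa_inf, 1 alpha_h, 2 beta_h, 3 alpha_n, 4 beta_n, 5 mA_inf^3,
# 6 hA_inf, 7 mKS_inf, 8 1/tau_mKS, 9 mCa_inf^2, 10 mNaP_inf^3, 11 hAR_inf,
# 12 f(V) synaptic gate


def build_rate_tables() -> np.ndarray:
    v = np.linspace(V_TAB_MIN, V_TAB_MAX, N_TAB)
    with np.errstate(over="ignore", invalid="ignore"):
        am = 0.1 * (v + 33.0) / (1.0 - np.exp(-(v + 33.0) / 10.0))
        am = np.where(np.abs(v + 33.0) < 1e-9, 1.0, am)  # removable singularity
        bm = 4.0 * np.exp(-(v + 53.7) / 12.0)
        an = 0.01 * (v + 34.0) / (1.0 - np.exp(-(v + 34.0) / 10.0))
        an = np.where(np.abs(v + 34.0) < 1e-9, 0.1, an)
        tab = np.empty((13, v.size))
        tab[0] = am / (am + bm)
        tab[1] = 0.07 * np.exp(-(v + 50.0) / 10.0)
        tab[2] = 1.0 / (1.0 + np.exp(-(v + 20.0) / 10.0))
        tab[3] = an
        tab[4] = 0.125 * np.exp(-(v + 44.0) / 25.0)
        tab[5] = (1.0 / (1.0 + np.exp(-(v + 50.0) / 2.0))) ** 3
        tab[6] = 1.0 / (1.0 + np.exp((v + 80.0) / 6.0))
        tab[7] = 1.0 / (1.0 + np.exp(-(v + 34.0) / 6.5))
        tab[8] = (np.exp(-(v + 55.0) / 30.0) + np.exp((v + 55.0) / 30.0)) / 8.0
        tab[9] = (1.0 / (1.0 + np.exp(-(v + 20.0) / 9.0))) ** 2
        tab[10] = (1.0 / (1.0 + np.exp(-(v + 55.7) / 7.7))) ** 3
        tab[11] = 1.0 / (1.0 + np.exp((v + 75.0) / 4.0))
        tab[12] = 1.0 / (1.0 + np.exp(-(v - 20.0) / 2.0))
    # transposed layout: one voltage sample reads a contiguous 13-float row
    return np.ascontiguousarray(tab.T)


RATE_TABLES = build_rate_tables()


@njit(cache=True, inline="always")
def _tab_idx(v):
    x = (v - V_TAB_MIN) / V_TAB_STEP
    if x <= 0.0:
        x = 0.0
    elif x >= N_TAB - 1.001:
        x = N_TAB - 1.001
    i = int(x)
    return i, x - i


@njit(cache=True, inline="always")
def _tab(tables, row, v):
    i, f = _tab_idx(v)
    return tables[i, row] * (1.0 - f) + tables[i + 1, row] * f


# ---------------------------------------------------------------------------
# Hodgkin-Huxley machinery
# ---------------------------------------------------------------------------
# Voltage-dependent gating functions are tabulated over [-200, 200] mV and
# linearly interpolated: the integrator spends nearly all its time evaluating
# them, and a 0.05 mV table is accurate to ~1e-7 on these sigmoids.

V_TAB_MIN = -200.0
V_TAB_MAX = 200.0
V_TAB_STEP = 0.05
N_TAB = int(round((V_TAB_MAX - V_TAB_MIN) / V_TAB_STEP)) + 1
# table rows: 0 mNa_inf, 1 alpha_h, 2 beta_h, 3 alpha_n, 4 beta_n, 5 mA_inf^3,
# 6 hA_inf, 7 mKS_inf, 8 1/tau_mKS, 9 mCa_inf^2, 10 mNaP_inf^3, 11 hAR_inf,
# 12 f(V) synaptic gate


def build_rate_tables() -> np.ndarray:
    v = np.linspace(V_TAB_MIN, V_TAB_MAX, N_TAB)
    with np.errstate(over="ignore", invalid="ignore"):
        am = 0.1 * (v + 33.0) / (1.0 - np.exp(-(v + 33.0) / 10.0))
        am = np.where(np.abs(v + 33.0) < 1e-9, 1.0, am)  # removable singularity
        bm = 4.0 * np.exp(-(v + 53.7) / 12.0)
        an = 0.01 * (v + 34.0) / (1.0 - np.exp(-(v + 34.0) / 10.0))
        an = np.where(np.abs(v + 34.0) < 1e-9, 0.1, an)
        tab = np.empty((13, v.size))
        tab[0] = am / (am + bm)
        tab[1] = 0.07 * np.exp(-(v + 50.0) / 10.0)
        tab[2] = 1.0 / (1.0 + np.exp(-(v + 20.0) / 10.0))
        tab[3] = an
        tab[4] = 0.125 * np.exp(-(v + 44.0) / 25.0)
        tab[5] = (1.0 / (1.0 + np.exp(-(v + 50.0) / 2.0))) ** 3
        tab[6] = 1.0 / (1.0 + np.exp((v + 80.0) / 6.0))
        tab[7] = 1.0 / (1.0 + np.exp(-(v + 34.0) / 6.5))
        tab[8] = (np.exp(-(v + 55.0) / 30.0) + np.exp((v + 55.0) / 30.0)) / 8.0
        tab[9] = (1.0 / (1.0 + np.exp(-(v + 20.0) / 9.0))) ** 2
        tab[10] = (1.0 / (1.0 + np.exp(-(v + 55.7) / 7.7))) ** 3
        tab[11] = 1.0 / (1.0 + np.exp((v + 75.0) / 4.0))
        tab[12] = 1.0 / (1.0 + np.exp(-(v - 20.0) / 2.0))
    # transposed layout: one voltage sample reads a contiguous 13-float row
    return np.ascontiguousarray(tab.T)


RATE_TABLES = build_rate_tables()

# index maps for the packed state arrays
IV, IHNA, INK, IHA, IMKS, ICA = 0, 1, 2, 3, 4, 5          # neuron rows
ISA, ISN, IXN, ICASYN = 0, 1, 2, 3                         # excitatory-synapse rows
# constants vector layout
(KCM, KAREA, KVL, KVNA, KVK, KVCA, KVAMPA, KVNMDA, KVGABA, KTAUHA, KKD,
 KALPHACA, KTAUCA, KTAUCASYN, KAAMPA, KTAUAMPA, KASN, KAXN, KTAUSN, KTAUXN,
 KAGABA, KTAUGABA, KBNMDA, KBVGCC, KPHI) = range(25)


@njit(cache=True, inline="always")
def _tab_idx(v):
    x = (v - V_TAB_MIN) / V_TAB_STEP
    if x <= 0.0:
        x = 0.0
    elif x >= N_TAB - 1.001:
        x = N_TAB - 1.001
    i = int(x)
    return i, x - i


@njit(cache=True, inline="always")
def _tab(tables, row, v):
    i, f = _tab_idx(v)
    return tables[i, row] * (1.0 - f) + tables[i + 1, row] * f


@njit(cache=True, inline="always")
def hh_rhs(tables, N, E, G, dN, dE, dG, i_syn,
           g_int, g_ampa_syn, g_nmda_syn, g_gaba_syn,
           e_pre, e_post, i_pre, i_post, cst, i_ext):
    """Time derivatives of the packed network state.

    N: (6, n) neuron state rows V, hNa, nK, hA, mKS, [Ca2+]
    E: (4, me) excitatory-synapse rows sAMPA, sNMDA, xNMDA, [Ca2+]_syn
    G: (1, mi) inhibitory-synapse row sGABA
    Intrinsic current densities (uA/cm2) are converted to nA with the 10*area
    factor; synaptic currents (uS * mV) are nA directly.
    """
    n = N.shape[1]
    me = e_pre.shape[0]
    mi = i_pre.shape[0]
    c_fac = 10.0 * cst[KCM] * cst[KAREA]
    for j in range(n):
        i_syn[j] = 0.0
    for s in range(me):
        q = e_post[s]
        vq = N[IV, q]
        i_syn[q] += g_ampa_syn[s] * E[ISA, s] * (vq - cst[KVAMPA]) \
            + g_nmda_syn[s] * E[ISN, s] * (vq - cst[KVNMDA])
        fpre = _tab(tables, 12, N[IV, e_pre[s]])
        dE[ISA, s] = cst[KAAMPA] * fpre - E[ISA, s] / cst[KTAUAMPA]
        dE[IXN, s] = cst[KAXN] * fpre - E[IXN, s] / cst[KTAUXN]
        dE[ISN, s] = cst[KASN] * E[IXN, s] * (1.0 - E[ISN, s]) - E[ISN, s] / cst[KTAUSN]
    for s in range(mi):
        q = i_post[s]
        i_syn[q] += g_gaba_syn[s] * G[0, s] * (N[IV, q] - cst[KVGABA])
        dG[0, s] = cst[KAGABA] * _tab(tables, 12, N[IV, i_pre[s]]) \
            - G[0, s] / cst[KTAUGABA]
    for j in range(n):
        v = N[IV, j]
        i, f = _tab_idx(v)
        g = 1.0 - f
        lo = tables[i]
        hi = tables[i + 1]
        m_na = lo[0] * g + hi[0] * f
        i_l = g_int[j, 0] * (v - cst[KVL])
        i_na = g_int[j, 1] * m_na * m_na * m_na * N[IHNA, j] * (v - cst[KVNA])
        nk2 = N[INK, j] * N[INK, j]
        i_k = g_int[j, 2] * nk2 * nk2 * (v - cst[KVK])
        i_a = g_int[j, 3] * (lo[5] * g + hi[5] * f) * N[IHA, j] * (v - cst[KVK])
        i_ks = g_int[j, 4] * N[IMKS, j] * (v - cst[KVK])
        i_ca = g_int[j, 5] * (lo[9] * g + hi[9] * f) * (v - cst[KVCA])
        ca = N[ICA, j]
        if ca < 1e-9:
            ca = 1e-9
        ratio = cst[KKD] / ca
        r3 = ratio * ratio * ratio
        m_kca = 1.0 / (1.0 + r3 * np.sqrt(ratio))  # (KD/Ca)^3.5
        i_kca = g_int[j, 6] * m_kca * (v - cst[KVK])
        i_nap = g_int[j, 7] * (lo[10] * g + hi[10] * f) * (v - cst[KVNA])
        i_ar = g_int[j, 8] * (lo[11] * g + hi[11] * f) * (v - cst[KVK])
        i_int = i_l + i_na + i_k + i_a + i_ks + i_ca + i_kca + i_nap + i_ar
        dN[IV, j] = (-10.0 * cst[KAREA] * i_int - i_syn[j] + i_ext[j]) / c_fac
        dN[IHNA, j] = 4.0 * cst[KPHI] * ((lo[1] * g + hi[1] * f) * (1.0 - N[IHNA, j])
                                         - (lo[2] * g + hi[2] * f) * N[IHNA, j])
        dN[INK, j] = 4.0 * cst[KPHI] * ((lo[3] * g + hi[3] * f) * (1.0 - N[INK, j])
                                        - (lo[4] * g + hi[4] * f) * N[INK, j])
        dN[IHA, j] = ((lo[6] * g + hi[6] * f) - N[IHA, j]) / cst[KTAUHA]
        dN[IMKS, j] = ((lo[7] * g + hi[7] * f) - N[IMKS, j]) * (lo[8] * g + hi[8] * f)
        dN[ICA, j] = -cst[KALPHACA] * (10.0 * cst[KAREA] * i_ca) - ca / cst[KTAUCA]
    for s in range(me):
        q = e_post[s]
        v = N[IV, q]
        i_ca_post = g_int[q, 5] * _tab(tables, 9, v) * (v - cst[KVCA])
        inm = g_nmda_syn[s] * E[ISN, s] * (v - cst[KVNMDA])
        dE[ICASYN, s] = -cst[KALPHACA] * (10.0 * cst[KAREA] * i_ca_post * cst[KBVGCC]
                                          + inm * cst[KBNMDA]) \
            - E[ICASYN, s] / cst[KTAUCASYN]
    return 0


@njit(cache=True)
def hh_run(tables, dt, n_steps, record_every, N, E, G, rho,
           g_int, g_ampa_base, g_nmda_syn, g_gaba_syn,
           e_pre, e_post, i_pre, i_post, cst, i_ext,
           plastic, couple_rho,
           theta_p, theta_d, gamma_p, gamma_d, sigma, z, tau_s, rho_star,
           rng, spike_bin_ms, early_stop):
    """Integrate the network with RK4; state arrays are updated in place.

    Returns (v_rec, spike_counts, spike_bins, vmin, vmax, ok,
             rho_mean_trace, casyn_rec):
      v_rec (float32, n_rec x n): voltage every `record_every` steps
      spike_counts: per-neuron count = (-20 mV crossings) / 2
      spike_bins: population upward -20 mV crossings per spike_bin_ms window
      ok: False when the solution left [-200, 200] mV (excluded set)
    If `plastic`, every excitatory synapse's efficacy follows the calcium
    SDE on its synaptic Ca2+ compartment; with `couple_rho` the AMPAR
    conductance is live-updated as g_base * (0.5 + rho).
    """
    n = N.shape[1]
    me = e_pre.shape[0]
    mi = i_pre.shape[0]
    n_rec = n_steps // record_every + 1
    v_rec = np.empty((n_rec, n), dtype=np.float32)
    rho_mean_trace = np.empty(n_rec, dtype=np.float32)
    rho_std_trace = np.empty(n_rec, dtype=np.float32)
    casyn_rec = np.empty(n_rec, dtype=np.float32)
    n_bins = int(n_steps * dt / spike_bin_ms) + 1
    spike_bins = np.zeros(n_bins, dtype=np.int64)
    crossings = np.zeros(n, dtype=np.int64)
    vmin = np.full(n, 1e30)
    vmax = np.full(n, -1e30)
    above = np.empty(n, dtype=np.bool_)
    for j in range(n):
        above[j] = N[IV, j] > -20.0

    # preallocated RK4 workspace
    Nt = np.empty_like(N); dN = np.empty_like(N); aN = np.empty_like(N)
    Et = np.empty_like(E); dE = np.empty_like(E); aE = np.empty_like(E)
    Gt = np.empty_like(G); dG = np.empty_like(G); aG = np.empty_like(G)
    i_syn = np.empty(n)
    g_ampa_syn = np.empty(me)

    sqdt = np.sqrt(dt)
    ok = True
    irec = 0
    quiet_ref = N[IV, 0]
    quiet_steps = 0
    for i in range(n_steps + 1):
        if i % record_every == 0 and irec < n_rec:
            for j in range(n):
                v_rec[irec, j] = N[IV, j]
            rm = 0.0
            r2 = 0.0
            for s in range(me):
                rm += rho[s]
                r2 += rho[s] * rho[s]
            if me > 0:
                rm /= me
                var = r2 / me - rm * rm
                rho_mean_trace[irec] = rm
                rho_std_trace[irec] = np.sqrt(var) if var > 0.0 else 0.0
                casyn_rec[irec] = E[ICASYN, 0]
            else:
                rho_mean_trace[irec] = 0.0
                rho_std_trace[irec] = 0.0
                casyn_rec[irec] = 0.0
            irec += 1
        if i == n_steps or not ok:
            break
        for s in range(me):
            if couple_rho:
                g_ampa_syn[s] = g_ampa_base[s] * (0.5 + rho[s])
            else:
                g_ampa_syn[s] = g_ampa_base[s]
        # RK4
        hh_rhs(tables, N, E, G, dN, dE, dG, i_syn, g_int, g_ampa_syn,
               g_nmda_syn, g_gaba_syn, e_pre, e_post, i_pre, i_post, cst, i_ext)
        for a in range(N.shape[0]):
            for j in range(n):
                aN[a, j] = dN[a, j]
                Nt[a, j] = N[a, j] + 0.5 * dt * dN[a, j]
        for a in range(E.shape[0]):
            for s in range(me):
                aE[a, s] = dE[a, s]
                Et[a, s] = E[a, s] + 0.5 * dt * dE[a, s]
        for s in range(mi):
            aG[0, s] = dG[0, s]
            Gt[0, s] = G[0, s] + 0.5 * dt * dG[0, s]
        hh_rhs(tables, Nt, Et, Gt, dN, dE, dG, i_syn, g_int, g_ampa_syn,
               g_nmda_syn, g_gaba_syn, e_pre, e_post, i_pre, i_post, cst, i_ext)
        for a in range(N.shape[0]):
            for j in range(n):
                aN[a, j] += 2.0 * dN[a, j]
                Nt[a, j] = N[a, j] + 0.5 * dt * dN[a, j]
        for a in range(E.shape[0]):
            for s in range(me):
                aE[a, s] += 2.0 * dE[a, s]
                Et[a, s] = E[a, s] + 0.5 * dt * dE[a, s]
        for s in range(mi):
            aG[0, s] += 2.0 * dG[0, s]
            Gt[0, s] = G[0, s] + 0.5 * dt * dG[0, s]
        hh_rhs(tables, Nt, Et, Gt, dN, dE, dG, i_syn, g_int, g_ampa_syn,
               g_nmda_syn, g_gaba_syn, e_pre, e_post, i_pre, i_post, cst, i_ext)
        for a in range(N.shape[0]):
            for j in range(n):
                aN[a, j] += 2.0 * dN[a, j]
                Nt[a, j] = N[a, j] + dt * dN[a, j]
        for a in range(E.shape[0]):
            for s in range(me):
                aE[a, s] += 2.0 * dE[a, s]
                Et[a, s] = E[a, s] + dt * dE[a, s]
        for s in range(mi):
            aG[0, s] += 2.0 * dG[0, s]
            Gt[0, s] = G[0, s] + dt * dG[0, s]
        hh_rhs(tables, Nt, Et, Gt, dN, dE, dG, i_syn, g_int, g_ampa_syn,
               g_nmda_syn, g_gaba_syn, e_pre, e_post, i_pre, i_post, cst, i_ext)
        for a in range(N.shape[0]):
            for j in range(n):
                N[a, j] += dt * (aN[a, j] + dN[a, j]) / 6.0
        for a in range(E.shape[0]):
            for s in range(me):
                E[a, s] += dt * (aE[a, s] + dE[a, s]) / 6.0
        for s in range(mi):
            G[0, s] += dt * (aG[0, s] + dG[0, s]) / 6.0
        for j in range(n):
            if N[ICA, j] < 0.0:
                N[ICA, j] = 0.0
            if not np.isfinite(N[IV, j]) or N[IV, j] > 200.0 or N[IV, j] < -200.0:
                ok = False
        for s in range(me):
            if E[ICASYN, s] < 0.0:
                E[ICASYN, s] = 0.0

        if plastic:
            for s in range(me):
                c = E[ICASYN, s]
                on_p = c >= theta_p
                on_d = c >= theta_d
                rr = rho[s]
                k1 = _rho_drift(rr, on_p, on_d, gamma_p, gamma_d, rho_star)
                k2 = _rho_drift(rr + 0.5 * dt * k1 / tau_s, on_p, on_d,
                                gamma_p, gamma_d, rho_star)
                k3 = _rho_drift(rr + 0.5 * dt * k2 / tau_s, on_p, on_d,
                                gamma_p, gamma_d, rho_star)
                k4 = _rho_drift(rr + dt * k3 / tau_s, on_p, on_d,
                                gamma_p, gamma_d, rho_star)
                rr += dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / (6.0 * tau_s)
                if on_p or on_d:
                    nth = 2.0 if (on_p and on_d) else 1.0
                    rr += sigma * z * np.sqrt(nth) * sqdt * rng.standard_normal() / tau_s
                rho[s] = rr

        t_ms = (i + 1) * dt
        for j in range(n):
            v = N[IV, j]
            if v < vmin[j]:
                vmin[j] = v
            if v > vmax[j]:
                vmax[j] = v
            now_above = v > -20.0
            if now_above != above[j]:
                crossings[j] += 1
                if now_above:
                    b = int(t_ms / spike_bin_ms)
                    if b < n_bins:
                        spike_bins[b] += 1
                above[j] = now_above
        if early_stop and n == 1:
            # terminate quiescent single-neuron runs early
            if abs(N[IV, 0] - quiet_ref) < 1e-3:
                quiet_steps += 1
            else:
                quiet_steps = 0
                quiet_ref = N[IV, 0]
            if quiet_steps * dt > 500.0 and crossings[0] == 0 and t_ms > 1500.0:
                for k in range(irec, n_rec):
                    v_rec[k, 0] = N[IV, 0]
                    rho_mean_trace[k] = rho_mean_trace[irec - 1]
                    rho_std_trace[k] = rho_std_trace[irec - 1]
                    casyn_rec[k] = casyn_rec[irec - 1]
                irec = n_rec
                break
    if not ok and irec < n_rec:
        for k in range(irec, n_rec):
            for j in range(n):
                v_rec[k, j] = v_rec[irec - 1, j] if irec > 0 else N[IV, j]
            rho_mean_trace[k] = rho_mean_trace[irec - 1] if irec > 0 else 0.0
            rho_std_trace[k] = rho_std_trace[irec - 1] if irec > 0 else 0.0
            casyn_rec[k] = casyn_rec[irec - 1] if irec > 0 else 0.0
    spike_counts = crossings // 2
    return (v_rec, spike_counts, spike_bins, vmin, vmax, ok,
            rho_mean_trace, rho_std_trace, casyn_rec)


@njit(cache=True, inline="always")
def _hh1_deriv(tables, v, hna, nk, ha, mks, ca, sa, sn, xn, sg, casyn,
               gl, gna, gk, ga, gks, gca, gkca, gnap, gar,
               g_ampa, g_nmda, g_gaba, cst, i_ext):
    i, f = _tab_idx(v)
    g = 1.0 - f
    lo = tables[i]
    hi = tables[i + 1]
    fv = lo[12] * g + hi[12] * f  # self-synapse gate f(V)
    m_na = lo[0] * g + hi[0] * f
    i_l = gl * (v - cst[KVL])
    i_na = gna * m_na * m_na * m_na * hna * (v - cst[KVNA])
    nk2 = nk * nk
    i_k = gk * nk2 * nk2 * (v - cst[KVK])
    i_a = ga * (lo[5] * g + hi[5] * f) * ha * (v - cst[KVK])
    i_ks = gks * mks * (v - cst[KVK])
    i_ca = gca * (lo[9] * g + hi[9] * f) * (v - cst[KVCA])
    cc = ca if ca > 1e-9 else 1e-9
    ratio = cst[KKD] / cc
    r3 = ratio * ratio * ratio
    m_kca = 1.0 / (1.0 + r3 * np.sqrt(ratio))
    i_kca = gkca * m_kca * (v - cst[KVK])
    i_nap = gnap * (lo[10] * g + hi[10] * f) * (v - cst[KVNA])
    i_ar = gar * (lo[11] * g + hi[11] * f) * (v - cst[KVK])
    i_int = i_l + i_na + i_k + i_a + i_ks + i_ca + i_kca + i_nap + i_ar
    i_syn = g_ampa * sa * (v - cst[KVAMPA]) + g_nmda * sn * (v - cst[KVNMDA]) \
        + g_gaba * sg * (v - cst[KVGABA])
    c_fac = 10.0 * cst[KCM] * cst[KAREA]
    dv = (-10.0 * cst[KAREA] * i_int - i_syn + i_ext) / c_fac
    dhna = 4.0 * cst[KPHI] * ((lo[1] * g + hi[1] * f) * (1.0 - hna)
                              - (lo[2] * g + hi[2] * f) * hna)
    dnk = 4.0 * cst[KPHI] * ((lo[3] * g + hi[3] * f) * (1.0 - nk)
                             - (lo[4] * g + hi[4] * f) * nk)
    dha = ((lo[6] * g + hi[6] * f) - ha) / cst[KTAUHA]
    dmks = ((lo[7] * g + hi[7] * f) - mks) * (lo[8] * g + hi[8] * f)
    dca = -cst[KALPHACA] * (10.0 * cst[KAREA] * i_ca) - cc / cst[KTAUCA]
    dsa = cst[KAAMPA] * fv - sa / cst[KTAUAMPA]
    dxn = cst[KAXN] * fv - xn / cst[KTAUXN]
    dsn = cst[KASN] * xn * (1.0 - sn) - sn / cst[KTAUSN]
    dsg = cst[KAGABA] * fv - sg / cst[KTAUGABA]
    inm = g_nmda * sn * (v - cst[KVNMDA])
    dcasyn = -cst[KALPHACA] * (10.0 * cst[KAREA] * i_ca * cst[KBVGCC]
                               + inm * cst[KBNMDA]) - casyn / cst[KTAUCASYN]
    return (dv, dhna, dnk, dha, dmks, dca, dsa, dsn, dxn, dsg, dcasyn)


@njit(cache=True)
def hh_single_run(tables, dt, n_steps, record_every, state,
                  gl, gna, gk, ga, gks, gca, gkca, gnap, gar,
                  g_ampa, g_nmda, g_gaba, cst, i_ext, early_stop):
    """Specialized all-scalar integrator for the self-connected neuron.

    `state` is the 11-element vector (V, hNa, nK, hA, mKS, Ca, sAMPA,
    sNMDA, xNMDA, sGABA, Ca_syn), updated in place.  Returns
    (v_rec, casyn_rec, crossings, vmin, vmax, ok).  Same equations as the
    network kernel (cross-checked by tests), roughly an order of magnitude
    faster for n = 1.
    """
    v = state[0]; hna = state[1]; nk = state[2]; ha = state[3]
    mks = state[4]; ca = state[5]; sa = state[6]; sn = state[7]
    xn = state[8]; sg = state[9]; casyn = state[10]
    n_rec = n_steps // record_every + 1
    v_rec = np.empty(n_rec, dtype=np.float32)
    casyn_rec = np.empty(n_rec, dtype=np.float32)
    crossings = 0
    vmin = v
    vmax = v
    above = v > -20.0
    ok = True
    irec = 0
    quiet_ref = v
    quiet_steps = 0
    for i in range(n_steps + 1):
        if i % record_every == 0 and irec < n_rec:
            v_rec[irec] = v
            casyn_rec[irec] = casyn
            irec += 1
        if i == n_steps:
            break
        d1 = _hh1_deriv(tables, v, hna, nk, ha, mks, ca, sa, sn, xn, sg, casyn,
                        gl, gna, gk, ga, gks, gca, gkca, gnap, gar,
                        g_ampa, g_nmda, g_gaba, cst, i_ext)
        h = 0.5 * dt
        d2 = _hh1_deriv(tables, v + h * d1[0], hna + h * d1[1], nk + h * d1[2],
                        ha + h * d1[3], mks + h * d1[4], ca + h * d1[5],
                        sa + h * d1[6], sn + h * d1[7], xn + h * d1[8],
                        sg + h * d1[9], casyn + h * d1[10],
                        gl, gna, gk, ga, gks, gca, gkca, gnap, gar,
                        g_ampa, g_nmda, g_gaba, cst, i_ext)
        d3 = _hh1_deriv(tables, v + h * d2[0], hna + h * d2[1], nk + h * d2[2],
                        ha + h * d2[3], mks + h * d2[4], ca + h * d2[5],
                        sa + h * d2[6], sn + h * d2[7], xn + h * d2[8],
                        sg + h * d2[9], casyn + h * d2[10],
                        gl, gna, gk, ga, gks, gca, gkca, gnap, gar,
                        g_ampa, g_nmda, g_gaba, cst, i_ext)
        d4 = _hh1_deriv(tables, v + dt * d3[0], hna + dt * d3[1], nk + dt * d3[2],
                        ha + dt * d3[3], mks + dt * d3[4], ca + dt * d3[5],
                        sa + dt * d3[6], sn + dt * d3[7], xn + dt * d3[8],
                        sg + dt * d3[9], casyn + dt * d3[10],
                        gl, gna, gk, ga, gks, gca, gkca, gnap, gar,
                        g_ampa, g_nmda, g_gaba, cst, i_ext)
        w = dt / 6.0
        v += w * (d1[0] + 2.0 * d2[0] + 2.0 * d3[0] + d4[0])
        hna += w * (d1[1] + 2.0 * d2[1] + 2.0 * d3[1] + d4[1])
        nk += w * (d1[2] + 2.0 * d2[2] + 2.0 * d3[2] + d4[2])
        ha += w * (d1[3] + 2.0 * d2[3] + 2.0 * d3[3] + d4[3])
        mks += w * (d1[4] + 2.0 * d2[4] + 2.0 * d3[4] + d4[4])
        ca += w * (d1[5] + 2.0 * d2[5] + 2.0 * d3[5] + d4[5])
        sa += w * (d1[6] + 2.0 * d2[6] + 2.0 * d3[6] + d4[6])
        sn += w * (d1[7] + 2.0 * d2[7] + 2.0 * d3[7] + d4[7])
        xn += w * (d1[8] + 2.0 * d2[8] + 2.0 * d3[8] + d4[8])
        sg += w * (d1[9] + 2.0 * d2[9] + 2.0 * d3[9] + d4[9])
        casyn += w * (d1[10] + 2.0 * d2[10] + 2.0 * d3[10] + d4[10])
        if ca < 0.0:
            ca = 0.0
        if casyn < 0.0:
            casyn = 0.0
        if not np.isfinite(v) or v > 200.0 or v < -200.0:
            ok = False
            break
        if v < vmin:
            vmin = v
        if v > vmax:
            vmax = v
        now_above = v > -20.0
        if now_above != above:
            crossings += 1
            above = now_above
        if early_stop:
            if abs(v - quiet_ref) < 1e-3:
                quiet_steps += 1
            else:
                quiet_steps = 0
                quiet_ref = v
            if quiet_steps * dt > 400.0 and crossings == 0 \
                    and (i + 1) * dt > 800.0:
                for k in range(irec, n_rec):
                    v_rec[k] = v
                    casyn_rec[k] = casyn
                irec = n_rec
                break
    if not ok:
        for k in range(irec, n_rec):
            v_rec[k] = v_rec[irec - 1] if irec > 0 else np.float32(v)
            casyn_rec[k] = casyn_rec[irec - 1] if irec > 0 else np.float32(casyn)
    state[0] = v; state[1] = hna; state[2] = nk; state[3] = ha
    state[4] = mks; state[5] = ca; state[6] = sa; state[7] = sn
    state[8] = xn; state[9] = sg; state[10] = casyn
    return v_rec, casyn_rec, crossings, vmin, vmax, ok
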