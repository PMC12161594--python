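"""Learning-rule classification by spike-timing pairing protocol.

A candidate plasticity parameter set is classified by the synaptic-change
curve it produces under a 1 Hz, 60 s pre/post pairing protocol evaluated on
a lag grid from -160 to +160 ms in 10 ms steps (lag > 0: post after pre).
The pipeline per candidate is:

1. calibrate_scaling  -- scale factors beta_nmda/beta_vgcc such that the
   unitary transient amplitudes are C_pre = 0.7 uM and C_post = 1.4 uM,
   measured in the 2-3 s steady-state window of the protocol;
2. balance_depression_amplitude -- update gamma_d so the potentiation and
   depression rates gamma_p*alpha_p and gamma_d*alpha_d are equal at a
   +100 ms lag (no net change for clearly separated spike pairs), then
   re-run the calibration;
3. analytic change per lag from the threshold occupancies (closed form of
   the linearized protocol dynamics, see `analytic_change`);
4. sum of squared errors between (change - 1) and a piecewise Gaussian
   target; the set is accepted when SSE < threshold (strict).

Because calcium is independent of the efficacy and the protocol is
periodic, occupancies are measured in the 2-3 s window and multiplied by 60
to obtain the 60 s totals, exactly as a full-length integration would give
once the calcium transients have reached their periodic steady state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtr

from . import _kernels
from .constants import SimpleModelConstants, WaveformConstants
from .patterns import VoltageTrace, pairing_pattern, spikes_to_voltage
from .plasticity import (PlasticityRuleParams, RULE_LABELS, nmda_influx_trace,
                         vgcc_influx_trace)

LAG_GRID_MS = np.arange(-160.0, 170.0, 10.0)
BALANCE_LAG_MS = 100.0
#: default Gaussian-target condition of the rule search and its SSE
#: acceptance threshold (the strong-window condition; see docs)
DEFAULT_TARGET_AMPLITUDE = 0.9
DEFAULT_TARGET_TAU = 30.0
DEFAULT_SSE_THRESHOLD = 0.45
TARGET_AMP_PRE = 0.7   # uM, calibrated C_pre transient amplitude
TARGET_AMP_POST = 1.4  # uM, calibrated C_post transient amplitude

#: default uniform sampling boxes for the rule search.  The threshold boxes
#: are the ones used for the network-model search; the remaining ranges are
#: package defaults in the spirit of the two-threshold calcium model
#: (amplitudes far above the cubic scale, tens-of-ms calcium decays,
#: minutes-scale efficacy time constant).
DEFAULT_RANGES: Dict[str, Tuple[float, float]] = {
    "theta_p": (0.8, 1.6),
    "theta_d": (0.5, 1.0),
    "gamma_p": (30.0, 600.0),
    "tau_pre": (5.0, 50.0),
    "tau_post": (5.0, 50.0),
    "sigma": (200.0, 900.0),
    "tau_s": (1.0e5, 5.0e5),
}


class CalibrationError(RuntimeError):
    """Degenerate parameter set: a calcium transient has zero amplitude."""


class BalanceError(RuntimeError):
    """Degenerate parameter set: no threshold occupancy at the balance lag."""


@dataclass
class RuleTarget:
    """Piecewise Gaussian target curve for one learning rule."""

    a_lr: float            # amplitude of the lag >= 0 branch
    b_lr: float            # amplitude of the lag < 0 branch, |a| == |b|
    tau_lr: float          # ms, Gaussian width
    rule_label: str

    def __post_init__(self):
        if abs(abs(self.a_lr) - abs(self.b_lr)) > 1e-12:
            raise ValueError("|a_lr| must equal |b_lr|")
        if self.tau_lr <= 0:
            raise ValueError("tau_lr must be positive")

    def values(self, lags: np.ndarray) -> np.ndarray:
        amp = np.where(lags >= 0, self.a_lr, self.b_lr)
        return amp * np.exp(-(lags / self.tau_lr) ** 2)


def default_target(rule_label: str,
                   amplitude: float = DEFAULT_TARGET_AMPLITUDE,
                   tau_lr: float = DEFAULT_TARGET_TAU) -> RuleTarget:
    """The four learning-rule targets: sign pattern by label."""
    signs = {"Hebbian": (1, 1), "STDP": (1, -1),
             "AntiHebbian": (-1, -1), "AntiSTDP": (-1, 1)}
    if rule_label not in signs:
        raise ValueError(f"unknown rule label {rule_label!r}")
    sa, sb = signs[rule_label]
    return RuleTarget(a_lr=sa * amplitude, b_lr=sb * amplitude,
                      tau_lr=tau_lr, rule_label=rule_label)


@dataclass
class StdpCurve:
    lags: np.ndarray      # ms, strictly increasing
    change: np.ndarray    # after/before efficacy ratio per lag
    alpha_p: Optional[np.ndarray] = None
    alpha_d: Optional[np.ndarray] = None


@dataclass
class OccupancyFractions:
    alpha_p: float
    alpha_d: float


def occupancy_fractions(c_trace: np.ndarray, theta: float,
                        window: Tuple[float, float], dt: float) -> float:
    """Fraction of (t0, t1) the calcium trace spends at or above theta."""
    t0, t1 = window
    i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
    if i1 <= i0 or i0 < 0 or i1 > len(c_trace):
        raise ValueError("window must be non-empty and inside the trace")
    seg = c_trace[i0:i1]
    return float(np.count_nonzero(seg >= theta)) / (i1 - i0)


class PairingContext:
    """Precomputed influx traces of the 1 Hz pairing protocol.

    The NMDAR-source influx depends only on the presynaptic train and the
    VGCC-source influx only on the postsynaptic one, so a single pair of
    unit-beta influx templates serves every candidate parameter set; a lag
    simply shifts the postsynaptic template.
    """

    def __init__(self, constants: Optional[SimpleModelConstants] = None,
                 waveform: Optional[WaveformConstants] = None,
                 dt: float = 0.1, rate_hz: float = 1.0,
                 sim_seconds: float = 3.0,
                 window: Tuple[float, float] = (2000.0, 3000.0),
                 protocol_seconds: float = 60.0):
        self.constants = constants or SimpleModelConstants()
        self.waveform = waveform or WaveformConstants()
        self.dt = dt
        self.rate_hz = rate_hz
        self.protocol_ms = protocol_seconds * 1000.0
        pre, post0 = pairing_pattern(0.0, rate_hz, sim_seconds)
        v_pre = spikes_to_voltage(pre, self.waveform, dt)
        v_post0 = spikes_to_voltage(post0, self.waveform, dt)
        self.u_pre = nmda_influx_trace(v_pre, self.constants)
        self.u_post0 = vgcc_influx_trace(v_post0, self.constants)
        self.i0 = int(round(window[0] / dt))
        self.i1 = int(round(window[1] / dt))
        self.window_ms = window[1] - window[0]
        self.n_pairs = protocol_seconds * rate_hz
        self.lags = LAG_GRID_MS.copy()
        self.shifts = np.round(self.lags / dt).astype(np.int64)

    # -- per-candidate pieces -------------------------------------------------

    def component_traces(self, params: PlasticityRuleParams
                         ) -> Tuple[np.ndarray, np.ndarray]:
        c_pre = _kernels.exp_filter(self.u_pre, self.dt, params.tau_pre,
                                    params.beta_nmda, 0.0)
        c_post = _kernels.exp_filter(self.u_post0, self.dt, params.tau_post,
                                     params.beta_vgcc, 0.0)
        return c_pre, c_post

    def calibrate(self, params: PlasticityRuleParams) -> PlasticityRuleParams:
        base = replace(params, beta_nmda=1.0, beta_vgcc=1.0)
        c_pre, c_post = self.component_traces(base)
        amp_pre = float(c_pre[self.i0:self.i1].max())
        amp_post = float(c_post[self.i0:self.i1].max())
        if amp_pre <= 0 or amp_post <= 0:
            raise CalibrationError("zero-amplitude calcium transient")
        return replace(params, beta_nmda=TARGET_AMP_PRE / amp_pre,
                       beta_vgcc=TARGET_AMP_POST / amp_post)

    def occupancy_ms(self, c_pre: np.ndarray, c_post: np.ndarray,
                     lag_ms: float, params: PlasticityRuleParams
                     ) -> Tuple[float, float]:
        shift = int(round(lag_ms / self.dt))
        tp, td = _kernels.occupancy_ms(c_pre, c_post, shift, self.i0, self.i1,
                                       params.theta_p, params.theta_d, self.dt)
        return tp, td

    def balance(self, params: PlasticityRuleParams) -> PlasticityRuleParams:
        c_pre, c_post = self.component_traces(params)
        tp, td = self.occupancy_ms(c_pre, c_post, BALANCE_LAG_MS, params)
        if tp == 0.0 and td == 0.0:
            raise BalanceError("no threshold occupancy at the balance lag")
        if td == 0.0:
            raise BalanceError("depression threshold never crossed at the "
                               "balance lag; rates cannot be balanced")
        gamma_d = params.gamma_p * tp / td
        balanced = replace(params, gamma_d=gamma_d)
        # scaling factors are recomputed after the amplitude update (they do
        # not depend on gamma, so this is a consistency re-run)
        return self.calibrate(balanced)

    def curve(self, params: PlasticityRuleParams, rho0: float = 0.5) -> StdpCurve:
        c_pre, c_post = self.component_traces(params)
        occ = _kernels.lag_occupancies(c_pre, c_post, self.shifts,
                                       self.i0, self.i1,
                                       params.theta_p, params.theta_d, self.dt)
        scale = self.n_pairs / (self.n_pairs * 1000.0 / self.rate_hz)
        alpha_p = occ[:, 0] * scale  # occupancy ms per pair -> fraction of T
        alpha_d = occ[:, 1] * scale
        change = np.array([
            analytic_change(ap, ad, params, self.protocol_ms / 1000.0, rho0)
            for ap, ad in zip(alpha_p, alpha_d)])
        return StdpCurve(lags=self.lags.copy(), change=change,
                         alpha_p=alpha_p, alpha_d=alpha_d)

    def tiled_calcium(self, params: PlasticityRuleParams, lag_ms: float
                      ) -> np.ndarray:
        """Full-protocol calcium trace built from the periodic window."""
        c_pre, c_post = self.component_traces(params)
        shift = int(round(lag_ms / self.dt))
        n = len(c_pre)
        c3 = c_pre.copy()
        j0 = max(0, shift)
        j1 = min(n, n + shift)
        c3[j0:j1] += c_post[j0 - shift:j1 - shift]
        cwin = c3[self.i0:self.i1]
        reps = int(self.n_pairs) - int(round(n * self.dt * self.rate_hz / 1000.0))
        return np.concatenate([c3, np.tile(cwin, max(reps, 0))])


def calibrate_scaling(params: PlasticityRuleParams,
                      ctx: Optional[PairingContext] = None) -> PlasticityRuleParams:
    """Set beta_nmda/beta_vgcc so transient amplitudes are 0.7 / 1.4 uM."""
    ctx = ctx or PairingContext()
    return ctx.calibrate(params)


def balance_depression_amplitude(params: PlasticityRuleParams,
                                 ctx: Optional[PairingContext] = None
                                 ) -> PlasticityRuleParams:
    """Update gamma_d so gamma_p*alpha_p == gamma_d*alpha_d at +100 ms lag."""
    ctx = ctx or PairingContext()
    return ctx.balance(params)


def analytic_change(alpha_p: float, alpha_d: float,
                    params: PlasticityRuleParams, T: float,
                    rho0: float = 0.5) -> float:
    """Closed-form change ratio of the linearized protocol dynamics.

    While thresholds are crossed the efficacy is an Ornstein-Uhlenbeck
    process with protocol-averaged drift rate (Gp+Gd)/tau_s toward
    Gp/(Gp+Gd) (Gx = gamma_x * alpha_x) and squared diffusion
    (sigma*z/tau_s)^2 (alpha_p+alpha_d); afterwards the double-well drift
    relaxes rho to 0 or 1, so the mean post-protocol efficacy equals the
    probability of ending above rho*.  Returns that mean divided by rho0.
    """
    if not 0 < rho0 <= 1:
        raise ValueError("rho0 must lie in (0, 1]")
    if alpha_p == 0.0 and alpha_d == 0.0:
        return 1.0
    T_ms = T * 1000.0
    gp = params.gamma_p * alpha_p
    gd = params.gamma_d * alpha_d
    g = gp + gd
    s2_rate = (params.sigma * params.z / params.tau_s) ** 2 * (alpha_p + alpha_d)
    if g > 0:
        rho_inf = gp / g
        decay = np.exp(-g * T_ms / params.tau_s)
        rho_bar = rho_inf + (rho0 - rho_inf) * decay
        var = s2_rate * params.tau_s / (2.0 * g) * (-np.expm1(-2.0 * g * T_ms / params.tau_s))
    else:
        rho_bar = rho0
        var = s2_rate * T_ms
    if var <= 0:
        p_up = 1.0 if rho_bar > params.rho_star else (0.5 if rho_bar == params.rho_star else 0.0)
    else:
        p_up = float(ndtr((rho_bar - params.rho_star) / np.sqrt(var)))
    return p_up / rho0


def stdp_curve(params: PlasticityRuleParams,
               ctx: Optional[PairingContext] = None,
               rho0: float = 0.5) -> StdpCurve:
    """Change-ratio curve on the standard lag grid (calibrated, balanced set)."""
    ctx = ctx or PairingContext()
    return ctx.curve(params, rho0)


def rule_fit(curve: StdpCurve, target: RuleTarget) -> float:
    """Sum of squared errors between (change - 1) and the Gaussian target."""
    if len(curve.lags) != len(target.values(curve.lags)):
        raise ValueError("curve and target must share the lag grid")
    resid = (curve.change - 1.0) - target.values(curve.lags)
    return float(np.dot(resid, resid))


def monte_carlo_change(params: PlasticityRuleParams, lag_ms: float,
                       n_rep: int = 200, seed: int = 0,
                       ctx: Optional[PairingContext] = None,
                       rho0: float = 0.5) -> float:
    """Simulated change ratio: noise realizations of the full protocol.

    Independent oracle for `analytic_change`: integrates the efficacy SDE
    against the actual protocol calcium trace and assigns each realization
    to its post-protocol well.
    """
    ctx = ctx or PairingContext()
    c = ctx.tiled_calcium(params, lag_ms)
    # runs of constant threshold-gate state: the SDE sees calcium only
    # through the gates, so this is an exact reformulation of the protocol
    code = (c >= params.theta_p).astype(np.int8) * 2 \
        + (c >= params.theta_d).astype(np.int8)
    change_at = np.flatnonzero(np.diff(code)) + 1
    bounds = np.concatenate(([0], change_at, [len(code)]))
    seg_len = np.diff(bounds).astype(np.int64)
    seg_code = code[bounds[:-1]]
    rng = np.random.default_rng(seed)
    frac_up = _kernels.mc_up_fraction(
        seg_len, (seg_code >= 2).astype(np.bool_),
        (seg_code % 2 == 1).astype(np.bool_), ctx.dt, params.tau_s,
        params.gamma_p, params.gamma_d, params.sigma, params.z,
        params.rho_star, rho0, n_rep, rng)
    return float(frac_up) / rho0


def sample_candidate(rng: np.random.Generator, rule_label: str,
                     ranges: Optional[Dict[str, Tuple[float, float]]] = None
                     ) -> PlasticityRuleParams:
    """Draw one parameter set from the uniform boxes for a rule family.

    Hebbian/STDP are searched in the theta_p > theta_d region and the
    anti-rules in theta_p < theta_d (the boxes swap roles).
    """
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    u = lambda k: float(rng.uniform(*r[k]))
    anti = rule_label in ("AntiHebbian", "AntiSTDP")
    # the "theta_p" box is the upper-threshold box, "theta_d" the lower one;
    # the anti-rules swap which threshold lives in which box and the ordering
    # constraint (theta_p > theta_d, or < for anti) is enforced by rejection
    while True:
        theta_hi = float(rng.uniform(*r["theta_p"]))
        theta_lo = float(rng.uniform(*r["theta_d"]))
        if theta_hi > theta_lo:
            break
    theta_p, theta_d = (theta_hi, theta_lo) if not anti else (theta_lo, theta_hi)
    return PlasticityRuleParams(
        theta_p=theta_p, theta_d=theta_d, gamma_p=u("gamma_p"),
        gamma_d=u("gamma_p"), tau_pre=u("tau_pre"), tau_post=u("tau_post"),
        sigma=u("sigma"), tau_s=u("tau_s"), rule_label=rule_label)


def evaluate_candidate(params: PlasticityRuleParams, target: RuleTarget,
                       ctx: PairingContext, rho0: float = 0.5
                       ) -> Tuple[Optional[PlasticityRuleParams], float,
                                  Optional[StdpCurve]]:
    """Calibrate, balance and score one candidate; None when degenerate."""
    try:
        p = ctx.calibrate(params)
        p = ctx.balance(p)
    except (CalibrationError, BalanceError):
        return None, np.inf, None
    curve = ctx.curve(p, rho0)
    return p, rule_fit(curve, target), curve


def search_rules(rule_label: str, n_target: int, seed: int,
                 budget: int = 100_000,
                 ranges: Optional[Dict[str, Tuple[float, float]]] = None,
                 target: Optional[RuleTarget] = None,
                 sse_threshold: float = DEFAULT_SSE_THRESHOLD,
                 ctx: Optional[PairingContext] = None,
                 keep_curves: bool = False):
    """Random search for parameter sets expressing one learning rule.

    Samples up to `budget` candidates, keeps those with SSE < threshold and
    stops once `n_target` acceptances are collected.  Returns
    (accepted params list sorted ascending by SSE, SSE array, curves or None).
    """
    if rule_label not in RULE_LABELS:
        raise ValueError(f"unknown rule label {rule_label!r}")
    ctx = ctx or PairingContext()
    target = target or default_target(rule_label)
    rng = np.random.default_rng(seed)
    accepted: List[PlasticityRuleParams] = []
    sses: List[float] = []
    curves: List[StdpCurve] = []
    for _ in range(budget):
        cand = sample_candidate(rng, rule_label, ranges)
        p, sse, curve = evaluate_candidate(cand, target, ctx)
        if p is not None and sse < sse_threshold:
            accepted.append(p)
            sses.append(sse)
            if keep_curves:
                curves.append(curve)
            if len(accepted) >= n_target:
                break
    if not accepted:
        warnings.warn(f"rule search for {rule_label} exhausted its budget "
                      f"({budget}) with no acceptances")
    order = np.argsort(sses)
    accepted = [accepted[i] for i in order]
    sses_arr = np.asarray(sses)[order]
    curves = [curves[i] for i in order] if keep_curves else None
    return accepted, sses_arr, curves
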