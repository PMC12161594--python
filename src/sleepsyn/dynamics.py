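"""Two-variable kinase model of spontaneous sleep-wake alternation.

The state (r, a) tracks the fractions of two phosphorylated kinase (CaMKII)
states.  r is use-dependent -- activated by calcium and by itself -- and
activates a; a inhibits r and couples back onto the network (e.g. NMDAR
conductance), which closes the homeostatic loop:

    tau_r dr/dt = -r + R_inf(w r + alpha Ca - b a + I + xi)
    tau_a da/dt = -a + A_inf(r - beta Ca - d)
    d xi       = -theta xi dt + epsilon sqrt(2 theta) dW

R_inf(x) = 1/(1+exp(-c x)), A_inf(x) = 1/(1+exp(-e x)).  The input noise xi
is an Ornstein-Uhlenbeck process with autocorrelation time 1/theta and
stationary SD epsilon, advanced with the exact discretization.  Depending
on parameters the system is a relaxation oscillator (spontaneous sleep-wake
alternation) or bistable (state switches only under sufficient noise).

Sleep need (Process S) is the classic exponential homeostat: saturating
toward the upper asymptote during wake, decaying toward the lower one
during sleep.  Candidate models are selected by sleep/wake balance
(0.7 <= sleep/wake < 1.3) and by the Pearson correlation between r (or a)
and Process S.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import HHConstants
from .plasticity import PlasticityRuleParams, vgcc_activation


@dataclass
class KinaseParams:
    tau_r: float = 10_000.0    # ms
    tau_a: float = 60_000.0    # ms
    w: float = 3.0             # auto-activation of r
    alpha: float = 0.15        # Ca2+ activation of r (per uM)
    b: float = 3.2             # inhibition of r by a
    beta: float = 0.0          # Ca2+ inhibition of a (per uM)
    I: float = -0.30           # constant input
    c: float = 4.0             # R_inf slope
    d: float = 0.55            # A_inf threshold on r
    e: float = 8.0             # A_inf slope
    theta: float = 1e-4        # 1/ms, OU rate (10 s autocorrelation)
    epsilon: float = 0.05      # OU stationary SD
    max_rate: float = 2.0      # conductance coupling gain
    coupling_variable: str = "a"   # which state scales the conductance

    def __post_init__(self):
        if self.tau_r <= 0 or self.tau_a <= 0:
            raise ValueError("time constants must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.coupling_variable not in ("r", "a"):
            raise ValueError("coupling_variable must be 'r' or 'a'")


def bistable_params(**overrides) -> KinaseParams:
    """A bistable configuration: without noise the state never switches."""
    base = KinaseParams(b=0.0, I=-1.5, theta=0.0, epsilon=0.0)
    return replace(base, **overrides)


@dataclass
class KinaseState:
    r: float = 0.1
    a: float = 0.1
    xi: float = 0.0


@dataclass
class ProcessSParams:
    upper: float = 1.0     # UA
    lower: float = 0.0     # LA
    tau_i: float = 60_000.0   # ms, rise during wake
    tau_d: float = 40_000.0   # ms, decay during sleep

    def __post_init__(self):
        if self.upper <= self.lower:
            raise ValueError("upper asymptote must exceed the lower one")


def r_inf(x: float, c: float = 4.0) -> float:
    return 1.0 / (1.0 + np.exp(-c * x))


def a_inf(x: float, e: float = 8.0) -> float:
    return 1.0 / (1.0 + np.exp(-e * x))


def step_kinase(ks: KinaseState, ca: float, p: KinaseParams, dt: float,
                rng: Optional[np.random.Generator] = None) -> KinaseState:
    """One update: exact OU step for xi, Euler relaxation for (r, a)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if p.theta > 0 and rng is not None:
        decay = np.exp(-p.theta * dt)
        xi = ks.xi * decay + p.epsilon * np.sqrt(1.0 - decay * decay) \
            * rng.standard_normal()
    elif p.theta > 0:
        xi = ks.xi * np.exp(-p.theta * dt)
    else:
        xi = ks.xi
    r_target = r_inf(p.w * ks.r + p.alpha * ca - p.b * ks.a + p.I + xi, p.c)
    a_target = a_inf(ks.r - p.beta * ca - p.d, p.e)
    r = ks.r + dt / p.tau_r * (r_target - ks.r)
    a = ks.a + dt / p.tau_a * (a_target - ks.a)
    return KinaseState(r=r, a=a, xi=xi)


def simulate_kinase(p: KinaseParams, duration_s: float, dt: float = 10.0,
                    ca: float | np.ndarray = 0.0, seed: int = 0,
                    state0: Optional[KinaseState] = None
                    ) -> Dict[str, np.ndarray]:
    """Standalone (r, a, xi) trajectories with a prescribed calcium input."""
    n = int(round(duration_s * 1000.0 / dt))
    ca_arr = np.broadcast_to(np.asarray(ca, dtype=float), (n,))
    rng = np.random.default_rng(seed)
    ks = state0 or KinaseState()
    out_r = np.empty(n + 1)
    out_a = np.empty(n + 1)
    out_xi = np.empty(n + 1)
    out_r[0], out_a[0], out_xi[0] = ks.r, ks.a, ks.xi
    for i in range(n):
        ks = step_kinase(ks, float(ca_arr[i]), p, dt, rng)
        out_r[i + 1], out_a[i + 1], out_xi[i + 1] = ks.r, ks.a, ks.xi
    return {"r": out_r, "a": out_a, "xi": out_xi, "dt_ms": np.array([dt])}


def couple_conductance(ks: KinaseState, g_original: float,
                       p: KinaseParams) -> float:
    """Multiplicative coupling g = g_original * max_rate * (a or r)."""
    if g_original < 0:
        raise ValueError("conductance must be non-negative")
    var = ks.a if p.coupling_variable == "a" else ks.r
    return g_original * p.max_rate * var


def presyn_calcium(v_pre: float, params: PlasticityRuleParams,
                   constants: Optional[HHConstants] = None,
                   g_ca: float = 1.0) -> float:
    """Instantaneous VGCC-mediated presynaptic calcium proxy.

    The defining relation carries no time derivative; it is implemented as an
    algebraic map of the presynaptic potential:
    -alpha_Ca * A * g_Ca * mCa_inf(V)^2 * (V - V_Ca) * beta_vgcc.
    """
    if not np.isfinite(v_pre):
        raise ValueError("membrane potential must be finite")
    c = constants or HHConstants()
    m = vgcc_activation(v_pre)
    i_ca = g_ca * m * m * (v_pre - c.v_ca)
    return -c.alpha_ca * (10.0 * c.area * i_ca) * params.beta_vgcc


def process_s(state_is_wake: np.ndarray, dt: float, p: ProcessSParams,
              s0: float) -> np.ndarray:
    """Exponential sleep-need homeostat along a wake/sleep label sequence.

    S_{t+1} = UA - (UA - S_t) exp(-dt/tau_i) during wake,
    S_{t+1} = LA + (S_t - LA) exp(-dt/tau_d) during sleep.
    """
    if not p.lower <= s0 <= p.upper:
        raise ValueError("S0 must lie between the asymptotes")
    wake = np.asarray(state_is_wake, dtype=bool)
    ei = np.exp(-dt / p.tau_i)
    ed = np.exp(-dt / p.tau_d)
    out = np.empty(len(wake) + 1)
    out[0] = s0
    s = s0
    for i, w in enumerate(wake):
        s = p.upper - (p.upper - s) * ei if w else p.lower + (s - p.lower) * ed
        out[i + 1] = s
    return out


def sliding_sleep_scores(spike_bins: np.ndarray, bin_ms: float = 50.0,
                         window_ms: float = 5000.0,
                         step_ms: float = 500.0) -> np.ndarray:
    """Sleep scores in sliding windows over a 50-ms-binned population count."""
    per_win = int(round(window_ms / bin_ms))
    step = int(round(step_ms / bin_ms))
    bins = np.asarray(spike_bins, dtype=float)
    if len(bins) < per_win:
        raise ValueError("run shorter than one scoring window")
    out = []
    for start in range(0, len(bins) - per_win + 1, step):
        seg = bins[start:start + per_win]
        m = seg.mean()
        out.append(seg.std() / m if m > 0 else np.nan)
    return np.asarray(out)


def classify_periods(scores: np.ndarray, threshold: float,
                     smooth: int = 10) -> np.ndarray:
    """Sleep (True) / wake (False) labels from smoothed sliding sleep scores.

    Moving averages over `smooth` consecutive scores are compared with the
    null-ensemble threshold; the label sequence has the same length as the
    input (edges use the partial average).
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < smooth:
        raise ValueError("run shorter than the smoothing span")
    kernel = np.ones(smooth) / smooth
    padded = np.convolve(s, kernel, mode="same")
    # renormalize edge averages for the partial windows
    norm = np.convolve(np.ones_like(s), kernel, mode="same")
    smoothed = padded / norm
    return smoothed > threshold


@dataclass
class CycleRun:
    """Outputs of one coupled network + kinase + Process S simulation."""

    labels: np.ndarray        # sleep True / wake False per kinase step
    r: np.ndarray
    a: np.ndarray
    s: np.ndarray             # Process S
    scores: np.ndarray        # sliding sleep scores
    rho_mean: np.ndarray      # mean efficacy per kinase step
    rho_std: np.ndarray
    dt_ms: float
    meta: Dict[str, float] = field(default_factory=dict)

    @property
    def sleep_wake_ratio(self) -> float:
        n_sleep = int(np.sum(self.labels))
        n_wake = len(self.labels) - n_sleep
        return np.inf if n_wake == 0 else n_sleep / n_wake


def balance_ok(ratio: float) -> bool:
    """Half-open sleep/wake balance acceptance: 0.7 <= ratio < 1.3."""
    return 0.7 <= ratio < 1.3


def select_dynamics_models(runs: Sequence[CycleRun],
                           optimize_variable: str = "r"
                           ) -> List[Tuple[int, float]]:
    """Balance-filtered runs ranked by corr(optimize_variable, Process S).

    Returns (index, correlation) pairs sorted descending; runs with a
    constant trace (undefined correlation) are excluded with a warning.
    """
    if optimize_variable not in ("r", "a"):
        raise ValueError("optimize_variable must be 'r' or 'a'")
    out = []
    for i, run in enumerate(runs):
        if not balance_ok(run.sleep_wake_ratio):
            continue
        x = getattr(run, optimize_variable)
        s = run.s[:len(x)]
        x = x[:len(s)]
        if np.std(x) == 0 or np.std(s) == 0:
            warnings.warn(f"run {i}: constant trace, correlation undefined")
            continue
        out.append((i, float(np.corrcoef(x, s)[0, 1])))
    return sorted(out, key=lambda t: -t[1])


def run_full_cycle(network, rule: PlasticityRuleParams, kp: KinaseParams,
                   duration_s: float = 300.0, kinase_dt_ms: float = 50.0,
                   dt: float = 0.05, seed: int = 0,
                   coupling_axis: str = "g_nmda",
                   ca_source: str = "synaptic",
                   threshold: float = 1.3,
                   sp: Optional[ProcessSParams] = None,
                   beta_nmda: float = 1.0, beta_vgcc: float = 1.0,
                   state0: Optional[KinaseState] = None,
                   s0: float = 0.5) -> CycleRun:
    """Closed-loop sleep-wake cycle: network <-> kinase <-> Process S.

    The conductance-based network (an `hh.HHNetwork`) is integrated in
    segments of `kinase_dt_ms`; between segments the kinase state advances
    one step driven by the chosen calcium compartment (averaged over the
    segment) and the coupled conductance is rescaled by max_rate * (a or r).
    Sleep scores are computed in 5-s sliding windows over the population
    spike counts, smoothed, thresholded into sleep/wake labels, and Process
    S is accumulated along the label sequence.
    """
    from . import _kernels
    sp = sp or ProcessSParams()
    rng = np.random.default_rng(seed)
    ks = state0 or KinaseState()
    n_seg = int(round(duration_s * 1000.0 / kinase_dt_ms))
    r_tr = np.empty(n_seg)
    a_tr = np.empty(n_seg)
    rho_m = np.empty(n_seg)
    rho_s = np.empty(n_seg)
    bins_all = []
    for k in range(n_seg):
        mult = kp.max_rate * (ks.a if kp.coupling_variable == "a" else ks.r)
        res = network.run(kinase_dt_ms / 1000.0, dt=dt,
                          multiplier=max(mult, 1e-9), axis=coupling_axis,
                          beta_nmda=beta_nmda, beta_vgcc=beta_vgcc,
                          plastic=True, couple_rho=True)
        bins_all.append(res.spike_bins[:max(1, int(kinase_dt_ms / 50.0))])
        rho_m[k] = res.rho_mean[-1]
        rho_s[k] = res.rho_std[-1]
        if ca_source == "synaptic":
            ca = float(np.mean(network.E[_kernels.ICASYN]))
        elif ca_source == "intracellular":
            ca = float(np.mean(network.N[_kernels.ICA]))
        elif ca_source == "presynaptic":
            v = network.N[_kernels.IV]
            ca = float(np.mean([presyn_calcium(float(x), rule) for x in v]))
        else:
            raise ValueError(f"unknown ca_source {ca_source!r}")
        ks = step_kinase(ks, ca, kp, kinase_dt_ms, rng)
        r_tr[k] = ks.r
        a_tr[k] = ks.a
    bins = np.concatenate(bins_all)
    scores = sliding_sleep_scores(bins)
    labels_scored = classify_periods(scores, threshold)
    # map the 500-ms score grid onto the kinase step grid
    idx = np.minimum((np.arange(n_seg) * kinase_dt_ms / 500.0).astype(int),
                     len(labels_scored) - 1)
    labels = labels_scored[idx]
    s = process_s(~labels, kinase_dt_ms, sp, s0)
    return CycleRun(labels=labels, r=r_tr, a=a_tr, s=s[1:], scores=scores,
                    rho_mean=rho_m, rho_std=rho_s, dt_ms=kinase_dt_ms)
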