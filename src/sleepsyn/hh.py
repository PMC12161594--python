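"""Conductance-based cortical network: slow-wave oscillation machinery.

A single "averaged" neuron carries nine intrinsic currents (leak, transient
Na+, delayed-rectifier K+, A-type K+, slowly inactivating K+, high-threshold
Ca2+, Ca2+-dependent K+, persistent Na+, inwardly rectifying K+), three
receptor currents (AMPA, second-order NMDA, GABA-A) fed back through
self-synapses, and two Ca2+ compartments (cell body driving the KCa current,
synapse driving plasticity).  Networks of 80 neurons (E:I 4:1, no I-to-I
connections, ~2 synapses of each kind per neuron) alternate between
desynchronized wake-like firing and synchronized slow-wave (Up/Down)
firing depending on channel or receptor conductances; bifurcation sweeps
locate both regimes and the sleep score (CV of population spike counts in
50 ms windows) quantifies synchronization.

Parameter search, the two-stage bifurcation analysis, the plastic network
runs (AMPAR conductance live-coupled to synaptic efficacy) and the
wake-stimulation protocol all live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from ._kernels import RATE_TABLES
from .constants import HHConstants
from .patterns import isim_for_wake_rate, sample_wake_train, PatternSpec
from .plasticity import PlasticityRuleParams

INTRINSIC_NAMES = ("g_l", "g_na", "g_k", "g_a", "g_ks", "g_ca", "g_kca",
                   "g_nap", "g_ar")
SYNAPTIC_NAMES = ("g_ampa", "g_nmda", "g_gaba")
#: log10 sampling bounds: intrinsic mS/cm2, synaptic uS, tau_ca ms
INTRINSIC_BOUNDS = (-2.0, 2.0)
SYNAPTIC_BOUNDS = (-3.0, 1.0)
TAU_CA_BOUNDS = (1.0, 3.0)

#: reference initial values for search and bifurcation runs
INIT_SINGLE = {"v": -45.0, "h_na": 0.045, "n_k": 0.54, "h_a": 0.045,
               "m_ks": 0.34, "ca": 1.0, "s_ampa": 0.01, "s_nmda": 0.01,
               "x_nmda": 0.01, "s_gaba": 0.01}


@dataclass
class NeuronParams:
    """Free conductance parameters of one model neuron / network."""

    g_l: float
    g_na: float
    g_k: float
    g_a: float
    g_ks: float
    g_ca: float
    g_kca: float
    g_nap: float
    g_ar: float
    g_ampa: float
    g_nmda: float
    g_gaba: float
    tau_ca: float  # ms, cell-body Ca2+ clearance

    def __post_init__(self):
        for name in INTRINSIC_NAMES + SYNAPTIC_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_ca <= 0:
            raise ValueError("tau_ca must be positive")

    def intrinsic_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in INTRINSIC_NAMES])


def sample_neuron_params(rng: np.random.Generator) -> NeuronParams:
    """Log-uniform draw over the stated decade ranges."""
    vals = {n: 10.0 ** rng.uniform(*INTRINSIC_BOUNDS) for n in INTRINSIC_NAMES}
    vals.update({n: 10.0 ** rng.uniform(*SYNAPTIC_BOUNDS) for n in SYNAPTIC_NAMES})
    return NeuronParams(tau_ca=10.0 ** rng.uniform(*TAU_CA_BOUNDS), **vals)


@dataclass
class NetworkConfig:
    n_neurons: int = 80
    ei_ratio: float = 4.0          # excitatory : inhibitory
    syn_count_mean: float = 2.0    # lognormal synapse-count distribution
    syn_count_sd: float = 0.01
    seed: int = 0

    @property
    def n_exc(self) -> int:
        return int(round(self.n_neurons * self.ei_ratio / (self.ei_ratio + 1)))


@dataclass
class PatternClass:
    label: str                     # Resting | SWO | SWO_high | AWAKE | AWAKE_high | EXCLUDED
    spike_rate: float              # spikes / s in the analysis window
    peak_frequency: float          # Hz
    v_min: float
    v_max: float


@dataclass
class SimResult:
    """Recorded output of one integration segment."""

    v_rec: np.ndarray              # (n_rec, n) float32
    dt_rec: float                  # ms between records
    spike_counts: np.ndarray       # per neuron, crossings/2
    spike_bins: np.ndarray         # population counts per 50 ms bin
    v_min: np.ndarray
    v_max: np.ndarray
    ok: bool
    rho_mean: np.ndarray
    rho_std: np.ndarray
    ca_syn: np.ndarray
    duration_ms: float

    @property
    def mean_rate(self) -> float:
        return float(np.sum(self.spike_counts)) * 1000.0 \
            / (self.v_rec.shape[1] * self.duration_ms)


class HHNetwork:
    """Stateful network simulator (state persists across run segments)."""

    def __init__(self, params: NeuronParams,
                 config: Optional[NetworkConfig] = None,
                 constants: Optional[HHConstants] = None,
                 rule: Optional[PlasticityRuleParams] = None,
                 single: bool = False, seed: int = 0):
        self.params = params
        self.constants = constants or HHConstants()
        self.config = config or NetworkConfig()
        self.rule = rule
        self.single = single
        self.rng = np.random.default_rng(seed)
        if single:
            self._build_single()
        else:
            self._build_network()
        self._init_state()

    # -- construction ----------------------------------------------------

    def _build_single(self):
        self.n = 1
        self.e_pre = np.array([0], dtype=np.int64)
        self.e_post = np.array([0], dtype=np.int64)
        self.i_pre = np.array([0], dtype=np.int64)
        self.i_post = np.array([0], dtype=np.int64)
        self.g_ampa = np.array([self.params.g_ampa])
        self.g_nmda = np.array([self.params.g_nmda])
        self.g_gaba = np.array([self.params.g_gaba])
        self.is_exc = np.array([True])

    def _build_network(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = cfg.n_neurons
        n_e = cfg.n_exc
        self.n = n
        self.is_exc = np.arange(n) < n_e
        exc = np.arange(n_e)
        inh = np.arange(n_e, n)
        # per-neuron synapse counts ~ lognormal(mean, sd), rounded, >= 1
        m, s = cfg.syn_count_mean, cfg.syn_count_sd
        sig2 = np.log1p((s / m) ** 2)
        mu = np.log(m) - sig2 / 2.0
        counts_e = np.maximum(1, np.round(
            rng.lognormal(mu, np.sqrt(sig2), n)).astype(int))
        counts_i = np.maximum(1, np.round(
            rng.lognormal(mu, np.sqrt(sig2), n)).astype(int))
        e_pre, e_post, i_pre, i_post = [], [], [], []
        for j in range(n):
            srcs = exc[exc != j]
            for p in rng.choice(srcs, size=counts_e[j], replace=True):
                e_pre.append(int(p))
                e_post.append(j)
            if self.is_exc[j]:  # no inhibitory synapses onto inhibitory cells
                for p in rng.choice(inh, size=counts_i[j], replace=True):
                    i_pre.append(int(p))
                    i_post.append(j)
        self.e_pre = np.array(e_pre, dtype=np.int64)
        self.e_post = np.array(e_post, dtype=np.int64)
        self.i_pre = np.array(i_pre, dtype=np.int64)
        self.i_post = np.array(i_post, dtype=np.int64)
        # conductances divided by the average synapse count per neuron
        avg_e = len(e_pre) / n
        avg_i = max(len(i_pre) / n_e, 1e-12)
        self.g_ampa = np.full(len(e_pre), self.params.g_ampa / avg_e)
        self.g_nmda = np.full(len(e_pre), self.params.g_nmda / avg_e)
        self.g_gaba = np.full(len(i_pre), self.params.g_gaba / avg_i)

    def _init_state(self, randomize: bool = False):
        n, me, mi = self.n, len(self.e_pre), len(self.i_pre)
        iv = INIT_SINGLE
        self.N = np.empty((6, n))
        self.N[_kernels.IV] = iv["v"]
        self.N[_kernels.IHNA] = iv["h_na"]
        self.N[_kernels.INK] = iv["n_k"]
        self.N[_kernels.IHA] = iv["h_a"]
        self.N[_kernels.IMKS] = iv["m_ks"]
        self.N[_kernels.ICA] = iv["ca"]
        if randomize:
            # network initial conditions are randomly assigned within
            # physiological ranges for V and the fast gates
            self.N[_kernels.IV] = self.rng.uniform(-80.0, -50.0, n)
            self.N[_kernels.IHNA] = self.rng.uniform(0.0, 1.0, n)
            self.N[_kernels.INK] = self.rng.uniform(0.0, 1.0, n)
            self.N[_kernels.IHA] = self.rng.uniform(0.0, 1.0, n)
            self.N[_kernels.IMKS] = self.rng.uniform(0.0, 1.0, n)
        self.E = np.empty((4, me))
        self.E[_kernels.ISA] = iv["s_ampa"]
        self.E[_kernels.ISN] = iv["s_nmda"]
        self.E[_kernels.IXN] = iv["x_nmda"]
        self.E[_kernels.ICASYN] = 0.0
        self.G = np.full((1, mi), iv["s_gaba"])
        self.rho = np.full(me, 0.5)

    def constants_vector(self, beta_nmda: float = 1.0, beta_vgcc: float = 1.0,
                         presyn_scale: float = 1.0) -> np.ndarray:
        c = self.constants
        cst = np.zeros(25)
        cst[_kernels.KCM] = c.c_m
        cst[_kernels.KAREA] = c.area
        cst[_kernels.KVL] = c.v_l
        cst[_kernels.KVNA] = c.v_na
        cst[_kernels.KVK] = c.v_k
        cst[_kernels.KVCA] = c.v_ca
        cst[_kernels.KVAMPA] = c.v_ampa
        cst[_kernels.KVNMDA] = c.v_nmda
        cst[_kernels.KVGABA] = c.v_gaba
        cst[_kernels.KTAUHA] = c.tau_h_a
        cst[_kernels.KKD] = c.k_d
        cst[_kernels.KALPHACA] = c.alpha_ca
        cst[_kernels.KTAUCA] = self.params.tau_ca
        cst[_kernels.KTAUCASYN] = c.tau_ca_syn
        cst[_kernels.KAAMPA] = c.a_ampa * presyn_scale
        cst[_kernels.KTAUAMPA] = c.tau_ampa
        cst[_kernels.KASN] = c.a_s_nmda
        cst[_kernels.KAXN] = c.a_x_nmda * presyn_scale
        cst[_kernels.KTAUSN] = c.tau_s_nmda
        cst[_kernels.KTAUXN] = c.tau_x_nmda
        cst[_kernels.KAGABA] = c.a_gaba * presyn_scale
        cst[_kernels.KTAUGABA] = c.tau_gaba
        cst[_kernels.KBNMDA] = beta_nmda
        cst[_kernels.KBVGCC] = beta_vgcc
        cst[_kernels.KPHI] = c.phi
        return cst

    def run(self, duration_s: float, dt: float = 0.05,
            record_dt_ms: float = 0.5, multiplier: float = 1.0,
            axis: Optional[str] = None,
            beta_nmda: float = 1.0, beta_vgcc: float = 1.0,
            plastic: bool = False, couple_rho: bool = False,
            theta_p: float = 1.0, theta_d: float = 0.5,
            i_ext: Optional[np.ndarray] = None,
            early_stop: bool = False) -> SimResult:
        """Integrate one segment; the network state carries over."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        presyn_scale = 1.0
        g_int = np.tile(self.params.intrinsic_array(), (self.n, 1))
        g_ampa = self.g_ampa.copy()
        g_nmda = self.g_nmda.copy()
        g_gaba = self.g_gaba.copy()
        if axis is not None and multiplier != 1.0:
            if axis == "presyn":
                presyn_scale = multiplier
            elif axis in INTRINSIC_NAMES:
                g_int[:, INTRINSIC_NAMES.index(axis)] *= multiplier
            elif axis == "g_ampa":
                g_ampa *= multiplier
            elif axis == "g_nmda":
                g_nmda *= multiplier
            elif axis == "g_gaba":
                g_gaba *= multiplier
            else:
                raise ValueError(f"unknown bifurcation axis {axis!r}")
        cst = self.constants_vector(beta_nmda, beta_vgcc, presyn_scale)
        n_steps = int(round(duration_s * 1000.0 / dt))
        record_every = max(1, int(round(record_dt_ms / dt)))
        rule = self.rule
        if plastic and rule is None:
            raise ValueError("plastic run requires a rule parameter set")
        r = rule or PlasticityRuleParams(theta_p=1.0, theta_d=0.5, gamma_p=0,
                                         gamma_d=0, tau_pre=1, tau_post=1,
                                         sigma=0, tau_s=1)
        if i_ext is None:
            i_ext = np.zeros(self.n)
        out = _kernels.hh_run(
            RATE_TABLES, dt, n_steps, record_every,
            self.N, self.E, self.G, self.rho,
            g_int, g_ampa, g_nmda, g_gaba,
            self.e_pre, self.e_post, self.i_pre, self.i_post, cst,
            np.asarray(i_ext, dtype=float),
            plastic, couple_rho,
            theta_p if rule is None else r.theta_p,
            theta_d if rule is None else r.theta_d,
            r.gamma_p, r.gamma_d, r.sigma, r.z, r.tau_s, r.rho_star,
            self.rng, 50.0, early_stop)
        (v_rec, counts, bins, vmin, vmax, ok, rho_mean, rho_std, casyn) = out
        return SimResult(v_rec=v_rec, dt_rec=record_every * dt,
                         spike_counts=counts, spike_bins=bins,
                         v_min=vmin, v_max=vmax, ok=ok,
                         rho_mean=rho_mean, rho_std=rho_std, ca_syn=casyn,
                         duration_ms=n_steps * dt)


# ---------------------------------------------------------------------------
# analysis operations
# ---------------------------------------------------------------------------

def detect_spikes(v: np.ndarray, dt: float,
                  threshold: float = -20.0) -> Tuple[int, np.ndarray]:
    """Spike count = (threshold crossings)/2; times at upward crossings."""
    v = np.asarray(v, dtype=float)
    above = v > threshold
    flips = np.flatnonzero(np.diff(above.astype(np.int8)))
    upward = flips[~above[flips]]
    return len(flips) // 2, (upward + 1) * dt


def peak_frequency(v: np.ndarray, dt_ms: float) -> float:
    """Dominant frequency (Hz) of the mean-subtracted voltage spectrum."""
    v = np.asarray(v, dtype=float)
    spec = np.abs(np.fft.rfft(v - v.mean()))
    if len(spec) < 2:
        return 0.0
    freqs = np.fft.rfftfreq(len(v), d=dt_ms / 1000.0)
    return float(freqs[1:][np.argmax(spec[1:])])


def classify_pattern(v: np.ndarray, dt_ms: float,
                     ok: bool = True) -> PatternClass:
    """Classify a voltage trace into the six firing-pattern categories.

    The decision rules operate on the spike rate (crossings/2 per second),
    the spectral peak frequency and the voltage extrema; amplitude guards
    (beyond +-200 mV) and integration failures map to EXCLUDED.  A literal
    gap in the decision rules (e.g. sub-0.6 Hz firing with a detectable
    sub-threshold rhythm) also falls to EXCLUDED.
    """
    v = np.asarray(v, dtype=float)
    vmax, vmin = float(v.max()), float(v.min())
    if not ok or vmax > 200.0 or vmin < -200.0 or not np.isfinite(v).all():
        return PatternClass("EXCLUDED", np.nan, np.nan, vmin, vmax)
    count, _ = detect_spikes(v, dt_ms)
    seconds = len(v) * dt_ms / 1000.0
    rate = count / seconds
    peak = peak_frequency(v, dt_ms)
    if rate < 0.6 and peak <= 0.5 and (vmax < -30.0 or vmin > -30.0):
        label = "Resting"
    elif peak >= 0.5 and 2.0 * peak <= rate < 30.0:
        label = "SWO"
    elif peak >= 0.5 and rate >= 2.0 * peak and rate >= 30.0:
        label = "SWO_high"
    elif peak >= 0.5 and rate <= 2.0 * peak and rate < 30.0:
        label = "AWAKE"
    elif peak >= 0.5 and 30.0 < rate <= 2.0 * peak and rate < 100.0:
        label = "AWAKE_high"
    else:
        label = "EXCLUDED"
    return PatternClass(label, rate, peak, vmin, vmax)


def sleep_score(spike_bins: np.ndarray) -> float:
    """CV of population spike counts per 50 ms window (NaN if silent)."""
    bins = np.asarray(spike_bins, dtype=float)
    m = bins.mean()
    if m == 0:
        return np.nan
    return float(bins.std() / m)


def sleep_score_from_times(spike_times_ms: Sequence[np.ndarray],
                           duration_ms: float, window_ms: float = 50.0) -> float:
    """Sleep score from per-neuron spike-time arrays."""
    n_bins = int(duration_ms / window_ms)
    if n_bins < 1:
        raise ValueError("duration must cover at least one window")
    counts = np.zeros(n_bins)
    for t in spike_times_ms:
        idx = (np.asarray(t) / window_ms).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1)
    return sleep_score(counts)


def null_threshold(n_neurons: int = 80, duration_s: float = 5.0,
                   rate_range: Tuple[float, float] = (0.5, 15.0),
                   reps: int = 10_000, p: float = 0.01,
                   seed: int = 0) -> Tuple[float, Tuple[float, float]]:
    """Sleep-score threshold from an ensemble of desynchronized trains.

    Each replicate draws per-neuron wake-like lognormal-ISI trains with
    mean rates uniform in `rate_range`; the threshold is the (1-p) quantile
    of the resulting scores.  Returns (threshold, 95% CI of the quantile
    from order statistics).
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    # analytic rate -> ISIM inversion, tabulated once
    rates_tab = np.linspace(rate_range[0], rate_range[1], 64)
    isim_tab = np.array([isim_for_wake_rate(r) for r in rates_tab])
    scores = np.empty(reps)
    for k in range(reps):
        rates = rng.uniform(*rate_range, n_neurons)
        isims = np.interp(rates, rates_tab, isim_tab)
        times = []
        for m in isims:
            spec = PatternSpec(state="wake", duration_s=duration_s, isim=m)
            times.append(sample_wake_train(spec, rng).spikes[0])
        scores[k] = sleep_score_from_times(times, duration_s * 1000.0)
    scores = np.sort(scores[np.isfinite(scores)])
    n = len(scores)
    q = 1.0 - p
    thr = float(np.quantile(scores, q))
    # order-statistic CI of the quantile
    se = np.sqrt(n * q * (1 - q))
    lo = scores[max(0, min(n - 1, int(n * q - 1.96 * se)))]
    hi = scores[max(0, min(n - 1, int(n * q + 1.96 * se)))]
    return thr, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# parameter search and bifurcation
# ---------------------------------------------------------------------------

def run_single_neuron(params: NeuronParams, duration_s: float = 6.0,
                      settle_s: float = 1.0, dt: float = 0.05,
                      multiplier: float = 1.0, axis: Optional[str] = None,
                      constants: Optional[HHConstants] = None,
                      early_stop: bool = True, record_dt_ms: float = 0.5,
                      beta_nmda: float = 1.0, beta_vgcc: float = 1.0
                      ) -> Tuple[PatternClass, np.ndarray]:
    """Simulate the self-connected averaged neuron and classify it.

    The first `settle_s` seconds are integrated but excluded from analysis.
    Uses the specialized scalar kernel (an order of magnitude faster than
    the network integrator at n = 1; both paths are equation-identical and
    cross-checked by tests).  Returns (classification, analysed V trace).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    g = {n: getattr(params, n) for n in INTRINSIC_NAMES + SYNAPTIC_NAMES}
    presyn_scale = 1.0
    if axis is not None and multiplier != 1.0:
        if axis == "presyn":
            presyn_scale = multiplier
        elif axis in g:
            g[axis] = g[axis] * multiplier
        else:
            raise ValueError(f"unknown bifurcation axis {axis!r}")
    helper = HHNetwork.__new__(HHNetwork)
    helper.constants = constants or HHConstants()
    helper.params = params
    cst = HHNetwork.constants_vector(helper, beta_nmda, beta_vgcc, presyn_scale)
    iv = INIT_SINGLE
    state = np.array([iv["v"], iv["h_na"], iv["n_k"], iv["h_a"], iv["m_ks"],
                      iv["ca"], iv["s_ampa"], iv["s_nmda"], iv["x_nmda"],
                      iv["s_gaba"], 0.0])
    record_every = max(1, int(round(record_dt_ms / dt)))
    args = (g["g_l"], g["g_na"], g["g_k"], g["g_a"], g["g_ks"], g["g_ca"],
            g["g_kca"], g["g_nap"], g["g_ar"],
            g["g_ampa"], g["g_nmda"], g["g_gaba"], cst, 0.0)
    n_settle = int(round(settle_s * 1000.0 / dt))
    if n_settle > 0:
        _kernels.hh_single_run(RATE_TABLES, dt, n_settle, n_settle, state,
                               *args, early_stop)
    n_steps = int(round((duration_s - settle_s) * 1000.0 / dt))
    v_rec, casyn, crossings, vmin, vmax, ok = _kernels.hh_single_run(
        RATE_TABLES, dt, n_steps, record_every, state, *args, early_stop)
    cls = classify_pattern(v_rec, record_every * dt, ok=ok)
    return cls, v_rec


def search_swo(n_samples: int, seed: int, duration_s: float = 6.0,
               dt: float = 0.05,
               constants: Optional[HHConstants] = None
               ) -> List[Tuple[NeuronParams, PatternClass]]:
    """Random conductance search for slow-wave-oscillation regimes."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    hits = []
    for _ in range(n_samples):
        params = sample_neuron_params(rng)
        try:
            cls, _ = run_single_neuron(params, duration_s=duration_s, dt=dt,
                                       constants=constants)
        except Exception:
            continue
        if cls.label in ("SWO", "SWO_high"):
            hits.append((params, cls))
    return hits


def multiplier_grid(stage: str, axis: str) -> np.ndarray:
    """Log-uniform multiplier grids of the two-stage bifurcation protocol."""
    presyn = axis == "presyn"
    if stage == "single":
        return np.logspace(-2.0, 1.0 if presyn else 2.0, 100)
    if stage == "network1":
        return np.logspace(-2.0, 1.0, 16) if presyn \
            else np.logspace(-2.0, 2.0, 17)
    if stage == "network2":
        return np.logspace(-2.0, 0.8, 29) if presyn \
            else np.logspace(-2.0, 1.5, 36)
    raise ValueError(f"unknown stage {stage!r}")


@dataclass
class SweepStep:
    multiplier: float
    label: str = ""
    sleep_score: float = np.nan
    frac_sleep: float = np.nan     # fraction of neurons classified sleep-like
    frac_wake: float = np.nan
    mean_rate: float = np.nan      # spikes/s per neuron
    v_min: float = np.nan


@dataclass
class SweepResult:
    axis: str
    stage: str
    steps: List[SweepStep]

    def accepted_wake_steps(self) -> List[SweepStep]:
        return [s for s in self.steps
                if s.sleep_score < 1.0 and s.frac_wake > 0.30]

    def accepted_sleep_steps(self) -> List[SweepStep]:
        return [s for s in self.steps
                if s.sleep_score >= 1.3 and s.frac_sleep > 0.30]


def bifurcation_sweep(params: NeuronParams, axis: str, stage: str,
                      seed: int = 0, dt: float = 0.05,
                      config: Optional[NetworkConfig] = None,
                      constants: Optional[HHConstants] = None,
                      duration_s: Optional[float] = None,
                      multipliers: Optional[np.ndarray] = None) -> SweepResult:
    """Classify the model along a log-spaced conductance multiplier grid.

    stage "single": the self-connected neuron, 6 s per step, labels only;
    stages "network1"/"network2": the 80-neuron network for 2.5 s / 5 s per
    step, recording the sleep score, sleep/wake neuron fractions and mean
    firing rate of each step.
    """
    mults = multiplier_grid(stage, axis) if multipliers is None else multipliers
    steps = []
    if stage == "single":
        dur = duration_s or 6.0
        for m in mults:
            cls, res = run_single_neuron(params, duration_s=dur, dt=dt,
                                         multiplier=m, axis=axis,
                                         constants=constants)
            steps.append(SweepStep(multiplier=m, label=cls.label,
                                   mean_rate=cls.spike_rate,
                                   v_min=cls.v_min))
        return SweepResult(axis=axis, stage=stage, steps=steps)
    dur = duration_s or (2.5 if stage == "network1" else 5.0)
    for m in mults:
        net = HHNetwork(params, config=config, constants=constants, seed=seed)
        net._init_state(randomize=True)
        res = net.run(dur, dt=dt, multiplier=m, axis=axis)
        labels = [classify_pattern(res.v_rec[:, j], res.dt_rec, ok=res.ok).label
                  for j in range(net.n)]
        n_sleep = sum(l in ("SWO", "SWO_high") for l in labels)
        n_wake = sum(l in ("AWAKE", "AWAKE_high") for l in labels)
        steps.append(SweepStep(
            multiplier=m, label="network",
            sleep_score=sleep_score(res.spike_bins),
            frac_sleep=n_sleep / net.n, frac_wake=n_wake / net.n,
            mean_rate=res.mean_rate, v_min=float(res.v_min.min())))
    return SweepResult(axis=axis, stage=stage, steps=steps)


def single_neuron_bifurcates(sweep: SweepResult,
                             margin_mv: float = 5.0) -> bool:
    """AWAKE-to-SWO transition with the minimum-voltage margin criterion.

    Requires an SWO step and an AWAKE step along the sweep with
    min-V(SWO) + 5 mV < min-V(AWAKE).
    """
    swo = [s for s in sweep.steps if s.label in ("SWO", "SWO_high")]
    awake = [s for s in sweep.steps if s.label in ("AWAKE", "AWAKE_high")]
    if not swo or not awake:
        return False
    return min(s.v_min for s in swo) + margin_mv < min(a.v_min for a in awake)


@dataclass
class MatchedPair:
    wake: SweepStep
    sleep: SweepStep

    @property
    def rate_difference(self) -> float:
        return abs(self.wake.mean_rate - self.sleep.mean_rate)


def select_matched_pair(sweep: SweepResult,
                        max_rate_diff: float = 2.0) -> Optional[MatchedPair]:
    """Representative wake/sleep step pair with |rate difference| < 2 Hz."""
    best = None
    for w in sweep.accepted_wake_steps():
        for s in sweep.accepted_sleep_steps():
            d = abs(w.mean_rate - s.mean_rate)
            if d < max_rate_diff and (best is None or d < best.rate_difference):
                best = MatchedPair(wake=w, sleep=s)
    return best


# ---------------------------------------------------------------------------
# learning rules inside the network model
# ---------------------------------------------------------------------------

HH_THETA_BOXES = {
    "STDP": {"theta_p": (0.8, 1.6), "theta_d": (0.5, 1.0)},
    "AntiSTDP": {"theta_p": (0.5, 1.0), "theta_d": (0.8, 1.6)},
    "Hebbian": {"theta_p": (0.8, 1.6), "theta_d": (0.5, 1.0)},
    "AntiHebbian": {"theta_p": (0.5, 1.0), "theta_d": (0.8, 1.6)},
}


def representative_trace(res: SimResult, seconds: float = 4.0
                         ) -> Tuple[np.ndarray, int]:
    """Pick the neuron with minimum CV of 1-s firing rates; return its trace.

    The stable tonic firer is the cleanest template for the lag-duplication
    protocol of the in-network rule search.
    """
    n = res.v_rec.shape[1]
    dur_s = res.duration_ms / 1000.0
    n_sec = int(dur_s)
    best, best_cv = 0, np.inf
    for j in range(n):
        count, times = detect_spikes(res.v_rec[:, j], res.dt_rec)
        per_sec = np.histogram(times, bins=n_sec,
                               range=(0, n_sec * 1000.0))[0]
        m = per_sec.mean()
        cv = per_sec.std() / m if m > 0 else np.inf
        if cv < best_cv:
            best, best_cv = j, cv
    n_keep = int(seconds * 1000.0 / res.dt_rec)
    return np.asarray(res.v_rec[:n_keep, best], dtype=float), best


def search_rules_hh(v_wake: np.ndarray, dt: float, rule_label: str,
                    budget: int, seed: int, n_target: int = 1,
                    sse_threshold: float = 0.6,
                    constants=None) -> List[Tuple[PlasticityRuleParams, float]]:
    """Rule search driven by a network wake-state voltage trace.

    The 4-s trace is duplicated with a lag per grid point; the NMDAR
    calcium current uses the conductance-model form g s (Vpost - VCa).
    Occupancies are measured over seconds 1-4 and multiplied by 20 for the
    60-s totals.  Thresholds are drawn from the network-search boxes and
    accepted sets satisfy SSE < 0.6.
    """
    from .rules import (PairingContext, default_target, rule_fit, StdpCurve,
                        analytic_change, sample_candidate, LAG_GRID_MS)
    from .constants import SimpleModelConstants
    from .patterns import VoltageTrace
    from .plasticity import nmda_influx_trace, vgcc_influx_trace

    from dataclasses import replace as _replace

    sconst = constants or SimpleModelConstants()
    trace = VoltageTrace(v=np.asarray(v_wake, dtype=float), dt=dt)
    u_pre = nmda_influx_trace(trace, sconst, v_post=trace)  # Vpost driving force
    u_post = vgcc_influx_trace(trace, sconst)
    i0 = int(round(1000.0 / dt))
    i1 = int(round(min(4000.0, len(trace.v) * dt - 1) / dt))
    shifts = np.round(LAG_GRID_MS / dt).astype(np.int64)
    balance_shift = int(round(100.0 / dt))
    T = 60.0
    total_ms = T * 1000.0
    rng = np.random.default_rng(seed)
    target = default_target(rule_label)
    boxes = HH_THETA_BOXES[rule_label]
    accepted = []
    for _ in range(budget):
        cand = sample_candidate(rng, rule_label, ranges=boxes)
        # calibrate the source amplitudes on the trace itself (the network
        # analogue of the pairing-protocol calibration), then balance the
        # depression amplitude at the +100 ms lag as in the simple model
        c_pre_u = _kernels.exp_filter(u_pre, dt, cand.tau_pre, 1.0, 0.0)
        c_post_u = _kernels.exp_filter(u_post, dt, cand.tau_post, 1.0, 0.0)
        amp_pre = float(c_pre_u[i0:i1].max())
        amp_post = float(c_post_u[i0:i1].max())
        if amp_pre <= 0 or amp_post <= 0:
            continue
        c_pre = c_pre_u * (0.7 / amp_pre)
        c_post = c_post_u * (1.4 / amp_post)
        tp_ms, td_ms = _kernels.occupancy_ms(
            c_pre, c_post, balance_shift, i0, i1,
            cand.theta_p, cand.theta_d, dt)
        if td_ms == 0.0:
            continue
        cand = _replace(cand, gamma_d=cand.gamma_p * tp_ms / td_ms,
                        beta_nmda=0.7 / amp_pre, beta_vgcc=1.4 / amp_post)
        occ = _kernels.lag_occupancies(c_pre, c_post, shifts, i0, i1,
                                       cand.theta_p, cand.theta_d, dt)
        alpha = occ * 20.0 / total_ms
        change = np.array([analytic_change(ap, ad, cand, T, 0.5)
                           for ap, ad in alpha])
        curve = StdpCurve(lags=LAG_GRID_MS.copy(), change=change)
        sse = rule_fit(curve, target)
        if sse < sse_threshold:
            accepted.append((cand, sse))
            if len(accepted) >= n_target:
                break
    if not accepted:
        warnings.warn(f"in-network rule search for {rule_label} exhausted "
                      f"its budget ({budget})")
    return sorted(accepted, key=lambda t: t[1])


def calibrate_network_scaling(net_factory, wake_multiplier: float, axis: str,
                              duration_s: float = 10.0, dt: float = 0.05
                              ) -> Tuple[float, float, float]:
    """Network scaling: beta_nmda = 1, beta_vgcc from 2*MC_pre = MC_post.

    Runs the wake-like state twice without learning rules, once with only
    the NMDAR source and once with only the VGCC source active, measures
    the mean synaptic calcium transient amplitudes MC_pre and MC_post, and
    returns (beta_nmda, beta_vgcc, MC_pre).  Thresholds are normalized
    elsewhere as theta' = theta * MC_pre / 0.7.
    """
    amps = {}
    for name, (bn, bv) in (("pre", (1.0, 0.0)), ("post", (0.0, 1.0))):
        net = net_factory()
        res = net.run(duration_s, dt=dt, multiplier=wake_multiplier, axis=axis,
                      beta_nmda=bn, beta_vgcc=bv)
        trace = np.asarray(res.ca_syn, dtype=float)
        # mean amplitude: average of the per-250 ms local maxima
        n_bins = max(1, int(len(trace) * res.dt_rec / 250.0))
        chunks = np.array_split(trace, n_bins)
        amps[name] = float(np.mean([c.max() for c in chunks]))
    mc_pre = amps["pre"]
    if mc_pre <= 0 or amps["post"] <= 0:
        raise RuntimeError("degenerate calcium transients during calibration")
    beta_vgcc = 2.0 * mc_pre / amps["post"]
    return 1.0, beta_vgcc, mc_pre


def run_plastic_network(params: NeuronParams, rule: PlasticityRuleParams,
                        multiplier: float, axis: str,
                        config: Optional[NetworkConfig] = None,
                        constants: Optional[HHConstants] = None,
                        duration_s: float = 60.0, skip_s: float = 10.0,
                        dt: float = 0.05, seed: int = 0,
                        beta_nmda: float = 1.0, beta_vgcc: float = 1.0,
                        mc_pre: Optional[float] = None) -> Dict[str, float]:
    """Efficacy statistics of the network in one state multiplier.

    AMPAR conductance is live-updated as g_min + rho (g_max - g_min) with
    g_min/g_max = 0.5/1.5 of the original value; all excitatory synapses
    share the rule, rho starts at 0.5 and the mean/CV are averaged over
    [skip_s, duration_s].  Thresholds are normalized by MC_pre/0.7 when
    `mc_pre` is given.
    """
    r = rule
    if mc_pre is not None:
        scale = mc_pre / 0.7
        r = replace(rule, theta_p=rule.theta_p * scale,
                    theta_d=rule.theta_d * scale)
    net = HHNetwork(params, config=config, constants=constants, rule=r,
                    seed=seed)
    net._init_state(randomize=True)
    res = net.run(duration_s, dt=dt, multiplier=multiplier, axis=axis,
                  beta_nmda=beta_nmda, beta_vgcc=beta_vgcc,
                  plastic=True, couple_rho=True)
    i0 = int(skip_s * 1000.0 / res.dt_rec)
    mean_rho = float(np.mean(res.rho_mean[i0:]))
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(res.rho_mean[i0:] != 0,
                      res.rho_std[i0:] / res.rho_mean[i0:], np.nan)
    return {"mean_efficacy": mean_rho,
            "cv_efficacy": float(np.nanmean(cv)),
            "mean_rate": res.mean_rate,
            "sleep_score": sleep_score(res.spike_bins),
            "ok": res.ok}


def stimulation_experiment(params: NeuronParams, rule: PlasticityRuleParams,
                           wake_multiplier: float = 10 ** -0.4,
                           sleep_multiplier: float = 10 ** -0.1,
                           axis: str = "g_ca",
                           config: Optional[NetworkConfig] = None,
                           constants: Optional[HHConstants] = None,
                           wake_s: float = 10.0, stim_s: float = 15.0,
                           sleep_s: float = 20.0, stim_rate_hz: float = 20.0,
                           stim_amp_na: float = 1.0, dt: float = 0.05,
                           seed: int = 0,
                           beta_nmda: float = 1.0, beta_vgcc: float = 1.0
                           ) -> Dict[str, float]:
    """Wake -> 20 Hz stimulation of groups 1+2 -> sleep; group-wise ratios.

    Excitatory neurons are split by index into groups of 20/20/24; groups 1
    and 2 receive pulsed depolarizing current during the stimulation phase.
    Returns the per-group mean-efficacy ratio of after-sleep to before-sleep.
    """
    cfg = config or NetworkConfig()
    net = HHNetwork(params, config=cfg, constants=constants, rule=rule,
                    seed=seed)
    net._init_state(randomize=True)
    n_e = cfg.n_exc
    if n_e < 64:
        g1 = np.arange(0, n_e // 3)
        g2 = np.arange(n_e // 3, 2 * n_e // 3)
        g3 = np.arange(2 * n_e // 3, n_e)
    else:
        g1, g2, g3 = np.arange(20), np.arange(20, 40), np.arange(40, 64)
    groups = {"group1": g1, "group2": g2, "group3": g3}
    stim_mask = np.zeros(net.n)
    stim_mask[np.concatenate([g1, g2])] = 1.0

    def group_means():
        sums = {k: [] for k in groups}
        for s_idx in range(len(net.e_pre)):
            post = net.e_post[s_idx]
            for k, idx in groups.items():
                if post in idx:
                    sums[k].append(net.rho[s_idx])
        return {k: float(np.mean(v)) if v else np.nan
                for k, v in sums.items()}

    common = dict(dt=dt, axis=axis, plastic=True, couple_rho=True,
                  beta_nmda=beta_nmda, beta_vgcc=beta_vgcc)
    net.run(wake_s, multiplier=wake_multiplier, **common)
    before_stim = group_means()
    # pulsed stimulation: on/off duty cycle at stim_rate_hz
    period_ms = 1000.0 / stim_rate_hz
    on_ms = min(5.0, period_ms / 2)
    n_cycles = int(stim_s * 1000.0 / period_ms)
    for _ in range(n_cycles):
        net.run(on_ms / 1000.0, multiplier=wake_multiplier,
                i_ext=stim_mask * stim_amp_na, **common)
        net.run((period_ms - on_ms) / 1000.0, multiplier=wake_multiplier,
                **common)
    before_sleep = group_means()
    net.run(sleep_s, multiplier=sleep_multiplier, **common)
    after_sleep = group_means()
    out = {}
    for k in groups:
        out[f"{k}_n"] = len(groups[k])
        out[f"{k}_before_stim"] = before_stim[k]
        out[f"{k}_before_sleep"] = before_sleep[k]
        out[f"{k}_after_sleep"] = after_sleep[k]
        out[f"{k}_sleep_ratio"] = after_sleep[k] / before_sleep[k]
    return out
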