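"""Fixed-firing-pattern efficacy experiments.

Firing patterns are given and do not change under simulation: pre/post
voltage waveforms are synthesized from matched-rate sleep-like and wake-like
spike trains, every synapse integrates the calcium-plasticity model against
them, and the per-state efficacy statistics (time-averaged mean and
across-synapse CV over the last minutes of the run) are compared between
states.  Mean firing rates are matched between states before comparison --
the sleep generator by its mean Down-state duration (or ISI), the wake
generator by its mean ISI.

The headline contrasts: under Hebbian/STDP rules the synchronized bursty
sleep-like pattern strengthens synapses while the desynchronized wake-like
pattern weakens them at the same mean rate (wake inhibition, sleep
excitation); the anti-rules reverse the direction (synaptic homeostasis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .constants import SimpleModelConstants, WaveformConstants
from .patterns import (PatternSpec, SpikePattern, VoltageTrace, match_rate,
                       sample_pattern, spikes_to_voltage)
from .plasticity import (PlasticityRuleParams, nmda_influx_trace,
                         vgcc_influx_trace)

#: default sleep-like generator shape used by the fixed-rate experiments:
#: half-second Up states (UPM = 2.7 log10 ms) with ~30 ms within-Up ISIs
#: (ISIM = 1.5); the Down-state duration is the rate-matching knob.
DEFAULT_SLEEP_UPM = 2.7
DEFAULT_SLEEP_ISIM = 1.5
#: alternative configuration with the two values' roles swapped
#: (the source annotations are ambiguous; both readings are supported).
ALT_SLEEP_UPM = 1.5
ALT_SLEEP_ISIM = 2.7


@dataclass
class Topology:
    """Directed pre -> post synapse list over a pool of neurons."""

    n_neurons: int
    edges: List[Tuple[int, int]]
    kind: str

    def __post_init__(self):
        for p, q in self.edges:
            if p == q:
                raise ValueError("self-edges are not allowed")

    @property
    def n_synapses(self) -> int:
        return len(self.edges)


def build_topology(kind: str, seed: Optional[int] = None) -> Topology:
    """The three experiment topologies.

    fan_in_10 / fan_in_96: N presynaptic neurons onto one postsynaptic
    neuron (the last index).  random_p12: 10 neurons, every ordered pair
    connected with probability 0.12.
    """
    if kind in ("fan_in_10", "fan_in_96"):
        n_pre = 10 if kind == "fan_in_10" else 96
        edges = [(i, n_pre) for i in range(n_pre)]
        return Topology(n_neurons=n_pre + 1, edges=edges, kind=kind)
    if kind == "random_p12":
        rng = np.random.default_rng(seed)
        n = 10
        edges = [(i, j) for i in range(n) for j in range(n)
                 if i != j and rng.random() < 0.12]
        return Topology(n_neurons=n, edges=edges, kind=kind)
    raise ValueError(f"unknown topology kind {kind!r}")


@dataclass
class ExperimentConfig:
    """One matched-rate state-comparison experiment."""

    duration_min: float = 6.0
    window_min: float = 2.0          # averaged tail of the run
    rho0: float = 0.5
    dt: float = 0.05                 # ms
    rate_tolerance: float = 0.02
    sleep_upm: float = DEFAULT_SLEEP_UPM
    sleep_isim: float = DEFAULT_SLEEP_ISIM
    sleep_downm: float = 3.0
    constants: SimpleModelConstants = field(default_factory=SimpleModelConstants)
    waveform: WaveformConstants = field(default_factory=WaveformConstants)

    def __post_init__(self):
        if self.duration_min < self.window_min:
            raise ValueError("duration must cover the averaging window")


@dataclass
class EfficacyReport:
    """Per-rule-set efficacy statistics for a sleep/wake state pair."""

    rate_hz: float
    rule_label: str
    mean_sleep: np.ndarray
    mean_wake: np.ndarray
    cv_sleep: np.ndarray
    cv_wake: np.ndarray
    sleep_spec: Optional[PatternSpec] = None
    wake_spec: Optional[PatternSpec] = None

    def frame(self) -> pd.DataFrame:
        rows = []
        for state in ("sleep", "wake"):
            m = getattr(self, f"mean_{state}")
            c = getattr(self, f"cv_{state}")
            for i in range(len(m)):
                rows.append({"rule": self.rule_label, "rate_hz": self.rate_hz,
                             "state": state, "set_index": i,
                             "mean_efficacy": m[i], "cv_efficacy": c[i]})
        return pd.DataFrame(rows)


def matched_specs(rate_hz: float, cfg: ExperimentConfig,
                  sleep_knob: str = "DOWNM") -> Tuple[PatternSpec, PatternSpec]:
    """Sleep and wake generator specs matched to the same mean rate."""
    sleep = PatternSpec(state="sleep", duration_s=cfg.duration_min * 60.0,
                        isim=cfg.sleep_isim, upm=cfg.sleep_upm,
                        downm=cfg.sleep_downm)
    sleep = match_rate(sleep, rate_hz, knob=sleep_knob,
                       tolerance=cfg.rate_tolerance)
    wake = PatternSpec(state="wake", duration_s=cfg.duration_min * 60.0,
                       isim=3.0)
    wake = match_rate(wake, rate_hz, knob="ISIM", tolerance=cfg.rate_tolerance)
    return sleep, wake


def up_state_rate(pattern: SpikePattern) -> float:
    """Empirical mean firing rate inside Up states, Hz."""
    total_up = float(np.sum(pattern.up_intervals[:, 1]
                            - pattern.up_intervals[:, 0]))
    if total_up <= 0:
        return 0.0
    n = sum(len(s) for s in pattern.spikes)
    return 1000.0 * n / (pattern.n_neurons * total_up)


def match_up_rate(spec: PatternSpec, target_rate: float,
                  tolerance: float = 0.02, probe_duration_s: float = 600.0,
                  probe_seed: int = 24_601, max_iter: int = 60) -> PatternSpec:
    """Bisect ISIM until the sleep within-Up firing rate matches target."""
    lo, hi = 0.2, 4.8

    def rate_at(isim: float) -> float:
        probe = replace(spec, isim=isim, duration_s=probe_duration_s)
        pat = sample_pattern(probe, np.random.default_rng(probe_seed))
        return up_state_rate(pat)

    r_lo, r_hi = rate_at(lo), rate_at(hi)
    if not (r_hi <= target_rate <= r_lo):
        raise ValueError(f"Up-state rate {target_rate} Hz unreachable: "
                         f"bracket [{r_hi:.3g}, {r_lo:.3g}] Hz")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate_at(mid)
        if abs(r - target_rate) <= tolerance * target_rate:
            return replace(spec, isim=mid)
        if r > target_rate:
            lo = mid
        else:
            hi = mid
    return replace(spec, isim=0.5 * (lo + hi))


def _influx_blocks(patterns: SpikePattern, topology: Topology,
                   cfg: ExperimentConfig) -> Tuple[np.ndarray, np.ndarray,
                                                   np.ndarray, np.ndarray]:
    """Unit-beta influx trace blocks for the neurons a topology uses."""
    pre_neurons = sorted({p for p, _ in topology.edges})
    post_neurons = sorted({q for _, q in topology.edges})
    pre_map = {n: i for i, n in enumerate(pre_neurons)}
    post_map = {n: i for i, n in enumerate(post_neurons)}
    L = int(round(patterns.duration_ms / cfg.dt)) + 1
    u_nmda = np.empty((L, len(pre_neurons)), dtype=np.float32)
    u_vgcc = np.empty((L, len(post_neurons)), dtype=np.float32)
    for n in pre_neurons:
        v = spikes_to_voltage(patterns, cfg.waveform, cfg.dt, neuron=n)
        u_nmda[:, pre_map[n]] = nmda_influx_trace(v, cfg.constants)
    for n in post_neurons:
        v = spikes_to_voltage(patterns, cfg.waveform, cfg.dt, neuron=n)
        u_vgcc[:, post_map[n]] = vgcc_influx_trace(v, cfg.constants)
    pre_col = np.array([pre_map[p] for p, _ in topology.edges], dtype=np.int64)
    post_col = np.array([post_map[q] for _, q in topology.edges], dtype=np.int64)
    return u_nmda, u_vgcc, pre_col, post_col


def _params_arrays(rule_sets: Sequence[PlasticityRuleParams]):
    get = lambda a: np.array([getattr(p, a) for p in rule_sets])
    return (get("tau_pre"), get("tau_post"), get("beta_nmda"), get("beta_vgcc"),
            get("theta_p"), get("theta_d"), get("gamma_p"), get("gamma_d"),
            get("sigma"), get("tau_s"))


def run_state_efficacy(pattern: SpikePattern, topology: Topology,
                       rule_sets: Sequence[PlasticityRuleParams],
                       cfg: ExperimentConfig,
                       rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Efficacy mean/CV per rule set for one generated pattern ensemble."""
    u_nmda, u_vgcc, pre_col, post_col = _influx_blocks(pattern, topology, cfg)
    (tau_pre, tau_post, beta_n, beta_v, theta_p, theta_d,
     gamma_p, gamma_d, sigma, tau_s) = _params_arrays(rule_sets)
    L = u_nmda.shape[0]
    win_start = L - int(round(cfg.window_min * 60_000.0 / cfg.dt))
    z = rule_sets[0].z
    rho_star = rule_sets[0].rho_star
    mean_eff, cv_eff = _kernels.state_comparison_kernel(
        u_nmda, u_vgcc, pre_col, post_col,
        tau_pre, tau_post, beta_n, beta_v, theta_p, theta_d,
        gamma_p, gamma_d, sigma, z, tau_s, rho_star,
        cfg.rho0, cfg.dt, win_start, rng)
    return mean_eff, cv_eff


def run_state_comparison(rule_sets: Sequence[PlasticityRuleParams],
                         topology: Topology, rate_hz: float, seed: int,
                         cfg: Optional[ExperimentConfig] = None,
                         sleep_spec: Optional[PatternSpec] = None,
                         wake_spec: Optional[PatternSpec] = None
                         ) -> EfficacyReport:
    """Matched-rate sleep vs wake efficacy comparison for many rule sets."""
    cfg = cfg or ExperimentConfig()
    if not rule_sets:
        raise ValueError("need at least one rule parameter set")
    if sleep_spec is None or wake_spec is None:
        sleep_spec, wake_spec = matched_specs(rate_hz, cfg)
    ss = np.random.SeedSequence((seed, int(round(rate_hz * 1000))))
    seeds = ss.spawn(4)
    out = {}
    for state, spec, gen_seed, sde_seed in (
            ("sleep", sleep_spec, seeds[0], seeds[1]),
            ("wake", wake_spec, seeds[2], seeds[3])):
        pattern = sample_pattern(spec, np.random.default_rng(gen_seed),
                                 n_neurons=topology.n_neurons)
        mean_eff, cv_eff = run_state_efficacy(
            pattern, topology, rule_sets, cfg, np.random.default_rng(sde_seed))
        out[state] = (mean_eff, cv_eff)
    label = rule_sets[0].rule_label
    return EfficacyReport(rate_hz=rate_hz, rule_label=label,
                          mean_sleep=out["sleep"][0], mean_wake=out["wake"][0],
                          cv_sleep=out["sleep"][1], cv_wake=out["wake"][1],
                          sleep_spec=sleep_spec, wake_spec=wake_spec)


def up_rate_specs(rate_hz: float, cfg: ExperimentConfig
                  ) -> Tuple[PatternSpec, PatternSpec]:
    """Generator specs of the Up-state-rate design (cacheable per rate).

    The sleep-like generator keeps its Up/Down durations (UPM 2.7,
    DOWNM 3.0 by default) and its within-Up ISI is tuned so the Up-state
    rate equals ``rate_hz``; the wake generator is matched to the same
    ``rate_hz`` as its overall mean rate, so wake fires more on average.
    """
    sleep = PatternSpec(state="sleep", duration_s=cfg.duration_min * 60.0,
                        isim=2.0, upm=cfg.sleep_upm, downm=cfg.sleep_downm)
    sleep = match_up_rate(sleep, rate_hz, tolerance=cfg.rate_tolerance)
    wake = PatternSpec(state="wake", duration_s=cfg.duration_min * 60.0, isim=3.0)
    wake = match_rate(wake, rate_hz, knob="ISIM", tolerance=cfg.rate_tolerance)
    return sleep, wake


def run_up_rate_comparison(rule_sets: Sequence[PlasticityRuleParams],
                           topology: Topology, rate_hz: float, seed: int,
                           cfg: Optional[ExperimentConfig] = None,
                           sleep_spec: Optional[PatternSpec] = None,
                           wake_spec: Optional[PatternSpec] = None
                           ) -> EfficacyReport:
    """Comparison with the wake rate set to the sleep Up-state rate."""
    cfg = cfg or ExperimentConfig()
    if sleep_spec is None or wake_spec is None:
        sleep_spec, wake_spec = up_rate_specs(rate_hz, cfg)
    return run_state_comparison(rule_sets, topology, rate_hz, seed, cfg,
                                sleep_spec=sleep_spec, wake_spec=wake_spec)


def sweep_rates(rule_sets: Sequence[PlasticityRuleParams], topology: Topology,
                rates: Sequence[float], seed: int,
                cfg: Optional[ExperimentConfig] = None,
                design: str = "matched") -> pd.DataFrame:
    """Long-format table of state comparisons over a rate grid.

    design="matched": equal mean rates in both states (Down-duration knob);
    design="up_rate": wake rate equals the sleep Up-state rate.
    Per-rate failures are recorded as missing rows, not raised.
    """
    cfg = cfg or ExperimentConfig()
    frames = []
    runner = {"matched": run_state_comparison,
              "up_rate": run_up_rate_comparison}[design]
    for rate in rates:
        try:
            rep = runner(rule_sets, topology, rate, seed, cfg)
        except Exception as exc:  # per-rate failures are not fatal
            warnings.warn(f"rate {rate} Hz failed: {exc}")
            continue
        df = rep.frame()
        df["median_diff"] = (np.median(rep.mean_sleep)
                             - np.median(rep.mean_wake))
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["rule", "rate_hz", "state", "set_index",
                                     "mean_efficacy", "cv_efficacy",
                                     "median_diff"])
    return pd.concat(frames, ignore_index=True)
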