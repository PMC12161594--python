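"""Sleep-like and wake-like spike-train synthesis and voltage conversion.

Wake-like activity is tonic: inter-spike intervals (ISIs) are drawn from a
lognormal distribution.  Sleep-like activity alternates between depolarized
Up states (bursty firing) and silent hyperpolarized Down states; Up and Down
durations and within-Up ISIs are all lognormal.  Distribution means are the
free parameters ISIM/UPM/DOWNM -- decadic logs of the mean ISI and state
durations in milliseconds -- and the corresponding log10 SDs follow fixed
linear regressions estimated from in vivo cortical recordings:

    SD_up       = 0.35 * UPM   - 0.70
    SD_down     = 0.25 * DOWNM - 0.35
    SD_isi_up   = -0.20 * ISIM + 0.95     (ISIs inside sleep Up states)
    SD_isi_wake = 0.03 * ISIM  + 0.65     (wake ISIs)
    DOWNM       = -0.70 * UPM  + 4.00     (coupling used where configured)

"Mean" and "SD" parameterize log10 of the sampled quantity directly.

Up/Down interval sequences are shared across the neurons of one generated
ensemble (a population-wide slow oscillation); within-Up spike times are
drawn independently per neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from .constants import WaveformConstants

LN10 = np.log(10.0)

_SD_COEFFS = {
    "up": (0.35, -0.70),
    "down": (0.25, -0.35),
    "isi_sleep_up": (-0.20, 0.95),
    "isi_wake": (0.03, 0.65),
}

# knob bounds used by match_rate (log10 ms)
_KNOB_BOUNDS = {"DOWNM": (1.0, 6.0), "ISIM": (0.2, 4.8)}


@dataclass
class PatternSpec:
    """Parameters of one sleep-like or wake-like spike-train generator."""

    state: str                      # "sleep" | "wake"
    duration_s: float
    isim: float                     # log10 mean ISI (ms)
    upm: Optional[float] = None     # log10 mean Up duration (ms); sleep only
    downm: Optional[float] = None   # log10 mean Down duration (ms); sleep only
    seed: Optional[int] = None

    def __post_init__(self):
        if self.state not in ("sleep", "wake"):
            raise ValueError(f"state must be 'sleep' or 'wake', got {self.state!r}")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.state == "sleep" and (self.upm is None or self.downm is None):
            raise ValueError("sleep spec requires upm and downm")


@dataclass
class SpikePattern:
    """Per-neuron spike timestamps plus Up-interval annotations."""

    spikes: List[np.ndarray]            # sorted times, ms
    duration_ms: float
    up_intervals: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2)))  # (k, 2) ms; empty for wake
    state: str = "wake"

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    @property
    def mean_rate(self) -> float:
        """Population-mean firing rate in Hz."""
        total = sum(len(s) for s in self.spikes)
        return 1000.0 * total / (self.n_neurons * self.duration_ms)


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane potential, mV."""

    v: np.ndarray
    dt: float  # ms

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.v)) * self.dt


def sd_from_mean(kind: str, log10_mean: float) -> float:
    """log10 SD from log10 mean via the fixed linear regressions."""
    if not np.isfinite(log10_mean):
        raise ValueError("log10_mean must be finite")
    try:
        a, b = _SD_COEFFS[kind]
    except KeyError:
        raise ValueError(f"unknown kind {kind!r}; expected one of {sorted(_SD_COEFFS)}")
    return a * log10_mean + b


def downm_from_upm(upm: float) -> float:
    """Mean Down-state duration regression: DOWNM = -0.7 * UPM + 4.0."""
    return -0.7 * upm + 4.0


def _sample_log10_normal(rng: np.random.Generator, mean: float, sd: float,
                         size: int) -> np.ndarray:
    return 10.0 ** rng.normal(mean, max(sd, 0.0), size)


def _draw_isis_until(rng: np.random.Generator, mean: float, sd: float,
                     span_ms: float) -> np.ndarray:
    """Cumulative lognormal ISIs filling ``span_ms``; returns spike offsets."""
    mean_isi = 10.0 ** mean * np.exp((max(sd, 0.0) * LN10) ** 2 / 2.0)
    out = []
    t = 0.0
    chunk = max(16, int(span_ms / max(mean_isi, 1e-9) * 1.5) + 8)
    while t < span_ms:
        isis = _sample_log10_normal(rng, mean, sd, chunk)
        times = t + np.cumsum(isis)
        keep = times < span_ms
        out.append(times[keep])
        if keep.all():
            t = times[-1]
        else:
            break
    return np.concatenate(out) if out else np.empty(0)


def sample_wake_train(spec: PatternSpec, rng: Optional[np.random.Generator] = None,
                      n_neurons: int = 1) -> SpikePattern:
    """Tonic wake-like trains: cumulative lognormal ISIs."""
    if spec.state != "wake":
        raise ValueError("spec.state must be 'wake'")
    rng = _resolve_rng(spec, rng)
    sd = sd_from_mean("isi_wake", spec.isim)
    dur = spec.duration_s * 1000.0
    spikes = [_draw_isis_until(rng, spec.isim, sd, dur) for _ in range(n_neurons)]
    return SpikePattern(spikes=spikes, duration_ms=dur, state="wake")


def sample_up_down_intervals(spec: PatternSpec,
                             rng: np.random.Generator) -> np.ndarray:
    """One alternating Down/Up sequence covering the spec duration.

    Returns the Up intervals as an (k, 2) array in ms.  The sequence starts
    with a Down state so traces begin at baseline.
    """
    dur = spec.duration_s * 1000.0
    sd_up = sd_from_mean("up", spec.upm)
    sd_down = sd_from_mean("down", spec.downm)
    ups = []
    t = 0.0
    while t < dur:
        t += float(_sample_log10_normal(rng, spec.downm, sd_down, 1)[0])
        if t >= dur:
            break
        up_len = float(_sample_log10_normal(rng, spec.upm, sd_up, 1)[0])
        ups.append((t, min(t + up_len, dur)))
        t += up_len
    return np.asarray(ups).reshape(-1, 2)


def sample_sleep_train(spec: PatternSpec, rng: Optional[np.random.Generator] = None,
                       n_neurons: int = 1,
                       up_intervals: Optional[np.ndarray] = None) -> SpikePattern:
    """Sleep-like trains: spikes only inside (shared) Up intervals."""
    if spec.state != "sleep":
        raise ValueError("spec.state must be 'sleep'")
    rng = _resolve_rng(spec, rng)
    if up_intervals is None:
        up_intervals = sample_up_down_intervals(spec, rng)
    sd_isi = sd_from_mean("isi_sleep_up", spec.isim)
    dur = spec.duration_s * 1000.0
    spikes = []
    for _ in range(n_neurons):
        per_up = [start + _draw_isis_until(rng, spec.isim, sd_isi, end - start)
                  for start, end in up_intervals]
        spikes.append(np.concatenate(per_up) if per_up else np.empty(0))
    return SpikePattern(spikes=spikes, duration_ms=dur,
                        up_intervals=up_intervals, state="sleep")


def sample_pattern(spec: PatternSpec, rng: Optional[np.random.Generator] = None,
                   n_neurons: int = 1) -> SpikePattern:
    if spec.state == "wake":
        return sample_wake_train(spec, rng, n_neurons)
    return sample_sleep_train(spec, rng, n_neurons)


def _resolve_rng(spec: PatternSpec,
                 rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    if spec.seed is None:
        raise ValueError("either pass an rng or set spec.seed")
    return np.random.default_rng(spec.seed)


def mean_isi_ms(log10_mean: float, kind: str) -> float:
    """Expected ISI (ms) of the lognormal with log10 mean/SD regression."""
    sd = sd_from_mean(kind, log10_mean)
    return 10.0 ** log10_mean * np.exp((sd * LN10) ** 2 / 2.0)


def isim_for_wake_rate(rate_hz: float) -> float:
    """Invert the wake mean-rate relation rate = 1000 / E[ISI] for ISIM."""
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    lo, hi = _KNOB_BOUNDS["ISIM"]
    f = lambda m: mean_isi_ms(m, "isi_wake") - 1000.0 / rate_hz
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"rate {rate_hz} Hz outside the wake generator range")
    return brentq(f, lo, hi, xtol=1e-10)


def _empirical_rate(spec: PatternSpec, probe_seed: int, probe_duration_s: float) -> float:
    probe = replace(spec, duration_s=probe_duration_s, seed=None)
    rng = np.random.default_rng(probe_seed)
    pat = sample_pattern(probe, rng, n_neurons=1)
    return pat.mean_rate


def match_rate(spec: PatternSpec, target_rate: float, knob: str = "DOWNM",
               tolerance: float = 0.02, probe_duration_s: float = 600.0,
               probe_seed: int = 987_654, max_iter: int = 60) -> PatternSpec:
    """Bisect a generator knob until the long-run mean rate matches target.

    ``knob`` is "DOWNM" (sleep; longer Down states lower the rate) or "ISIM"
    (either state; longer ISIs lower the rate).  The empirical rate is
    measured on a fixed-seed probe train so the objective is a deterministic,
    monotone-decreasing function of the knob.
    """
    if knob not in _KNOB_BOUNDS:
        raise ValueError(f"knob must be one of {sorted(_KNOB_BOUNDS)}")
    if knob == "DOWNM" and spec.state != "sleep":
        raise ValueError("DOWNM knob applies to sleep specs only")
    lo, hi = _KNOB_BOUNDS[knob]
    attr = "downm" if knob == "DOWNM" else "isim"

    def rate_at(value: float) -> float:
        return _empirical_rate(replace(spec, **{attr: value}), probe_seed,
                               probe_duration_s)

    r_lo, r_hi = rate_at(lo), rate_at(hi)
    # rate decreases with the knob: r_lo is the highest achievable rate
    if not (r_hi <= target_rate <= r_lo):
        raise ValueError(
            f"target {target_rate} Hz unreachable with {knob} in [{lo}, {hi}]: "
            f"bracketing rates [{r_hi:.4g}, {r_lo:.4g}] Hz")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate_at(mid)
        if abs(r - target_rate) <= tolerance * target_rate:
            return replace(spec, **{attr: mid})
        if r > target_rate:
            lo = mid
        else:
            hi = mid
    return replace(spec, **{attr: 0.5 * (lo + hi)})


def spikes_to_voltage(pattern: SpikePattern, wf: Optional[WaveformConstants] = None,
                      dt: float = 0.1, neuron: int = 0) -> VoltageTrace:
    """Piecewise-linear membrane-potential waveform for one neuron.

    Each spike timestamp coincides with a voltage peak.  Between spikes the
    trace sits at the Up-state potential inside sleep Up intervals and at the
    Down/baseline potential otherwise.  When consecutive spikes are closer
    than the anchor window, the anchor offsets are compressed proportionally
    so peak times are preserved.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    wf = wf or WaveformConstants()
    n = int(round(pattern.duration_ms / dt)) + 1
    v = np.full(n, wf.baseline)
    for start, end in pattern.up_intervals:
        i0, i1 = int(round(start / dt)), int(round(end / dt))
        v[i0:i1 + 1] = wf.up_level

    times = np.sort(pattern.spikes[neuron])
    if times.size == 0:
        return VoltageTrace(v=v, dt=dt)
    gaps_prev = np.diff(times, prepend=-np.inf)
    gaps_next = np.diff(times, append=np.inf)
    for t, gp, gn in zip(times, gaps_prev, gaps_next):
        # compress anchors so adjacent spike windows never overlap
        f_pre = min(1.0, 0.5 * gp / wf.rise_ms) if np.isfinite(gp) else 1.0
        f_post = min(1.0, 0.5 * gn / wf.recover_ms) if np.isfinite(gn) else 1.0
        ip = int(round(t / dt))
        if ip < 0 or ip >= n:
            continue
        i0 = max(0, int(np.ceil((t - wf.rise_ms * f_pre) / dt)))
        i1 = min(n - 1, int(np.floor((t + wf.recover_ms * f_post) / dt)))
        anchors_t = np.array([t - wf.rise_ms * f_pre, t,
                              t + wf.ahp_ms * f_post, t + wf.recover_ms * f_post])
        anchors_v = np.array([v[i0], wf.peak, wf.ahp, v[i1]])
        idx = np.arange(i0, i1 + 1)
        v[idx] = np.interp(idx * dt, anchors_t, anchors_v)
        v[ip] = wf.peak  # peak exactly at the snapped timestamp
    return VoltageTrace(v=v, dt=dt)


def pairing_pattern(lag_ms: float, rate_hz: float, duration_s: float,
                    start_ms: float = 500.0) -> Tuple[SpikePattern, SpikePattern]:
    """Regular pre/post pairing protocol: pre at ``rate_hz``, post shifted by lag.

    lag > 0 means the post-synaptic neuron fires after the pre-synaptic one.
    Returns (pre, post) single-neuron patterns on a shared time base.
    """
    period = 1000.0 / rate_hz
    dur = duration_s * 1000.0
    pre = np.arange(start_ms, dur - 1.0, period)
    post = pre + lag_ms
    post = post[(post > 0) & (post < dur - 1.0)]
    return (SpikePattern([pre], dur), SpikePattern([post], dur))
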