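# sleepsyn

Simulation toolkit for synaptic dynamics across the sleep–wake cycle: do
cortical synapses strengthen during wakefulness and weaken during NREM
sleep (the synaptic homeostasis picture, SHY), or the other way around
(wake inhibition / sleep excitation, WISE)?  `sleepsyn` implements the
modeling chain needed to ask that question quantitatively:

* a **calcium-based bistable plasticity model** — synaptic efficacy ρ obeys

  `τ_s dρ/dt = −ρ(1−ρ)(ρ*−ρ) + γ_p(1−ρ)·H[c−θ_p] − γ_d·ρ·H[c−θ_d] + noise`

  with postsynaptic calcium `c = C_pre + C_post` summing an NMDAR source
  (second-order gating of the presynaptic potential) and a VGCC source
  (instantaneous voltage-gated activation), and weight `w = w0 + ρ(w1−w0)`;
* a **learning-rule taxonomy**: random parameter sets are calibrated
  (unitary transients 0.7 / 1.4 µM), balanced (no net change for ±100 ms
  spike pairs) and classified as Hebbian, STDP, Anti-Hebbian or Anti-STDP
  by fitting their 1 Hz pairing-protocol change-versus-lag curves to
  piecewise Gaussian targets;
* a **sleep/wake spike-pattern generator**: tonic lognormal-ISI wake
  trains, and Up/Down-alternating sleep trains with lognormal state
  durations whose log₁₀ mean–SD relations follow fixed regressions from in
  vivo cortical recordings, plus rate matching and conversion to
  piecewise-linear membrane-voltage waveforms;
* **fixed-pattern experiments** comparing time-averaged efficacy between
  matched-rate sleep-like and wake-like inputs across topologies
  (10 or 96 presynaptic neurons onto one, or random 12% connectivity);
* a **conductance-based cortical network** (nine intrinsic + three
  receptor currents, two Ca²⁺ compartments, 80 neurons at 4:1 E:I) with
  slow-wave-oscillation parameter search, two-stage bifurcation analysis,
  a population-synchrony "sleep score", and AMPAR conductance live-coupled
  to synaptic efficacy;
* a **two-variable kinase (CaMKII) sleep–wake oscillator** with
  Ornstein–Uhlenbeck input noise, Process S sleep-need tracking and
  balance/correlation model selection;
* the **comparison statistics** used throughout: a seeded Gibbs-sampled
  Bayesian difference of group means with 95% credible intervals, and
  Student/Welch t tests.

The headline result reproduced by the test suite: at equal mean firing
rates, synchronized bursty sleep-like firing strengthens synapses under
Hebbian/STDP rules while desynchronized wake-like firing weakens them
(WISE); the anti-rules reverse the direction (SHY); and when wake fires as
fast as the sleep Up states, the direction flips from WISE at low rates to
SHY at high rates.

## Worked example

Search for spike-timing-dependent plasticity parameter sets, then compare
synaptic efficacy between matched 1 Hz sleep-like and wake-like firing:

```python
import numpy as np
from sleepsyn.rules import search_rules
from sleepsyn.simple import ExperimentConfig, build_topology, run_state_comparison
from sleepsyn.stats import bayes_diff_means

stdp, sse, _ = search_rules("STDP", n_target=40, seed=7, budget=40_000)
print(f"accepted {len(stdp)} STDP sets, best SSE {sse[0]:.3f}")

topo = build_topology("fan_in_10")          # 10 presynaptic -> 1 postsynaptic
cfg = ExperimentConfig(duration_min=6.0, window_min=2.0, dt=0.1)
rep = run_state_comparison(stdp, topo, rate_hz=1.0, seed=11, cfg=cfg)
res = bayes_diff_means(rep.mean_sleep, rep.mean_wake, seed=1)
print(f"median efficacy: sleep {np.median(rep.mean_sleep):.3f} "
      f"wake {np.median(rep.mean_wake):.3f}")
print(f"mean difference {res.diff_mean:+.3f}, "
      f"95% CI [{res.ci_low:+.3f}, {res.ci_high:+.3f}] -> {res.verdict}")
```

prints

```
accepted 40 STDP sets, best SSE 0.070
median efficacy: sleep 0.643 wake 0.499
mean difference +0.144, 95% CI [+0.120, +0.167] -> WISE
```

Every synapse starts at ρ = 0.5; after six minutes of matched 1 Hz input
the sleep-like state has pushed the median synapse toward the upper well
while the wake-like state left it near or below the midpoint, and the
credible interval of the mean difference excludes zero from above — the
WISE regime.  Running the same comparison with Anti-STDP sets flips the
interval to strictly negative (SHY).

The same operations are exposed on the command line:

```bash
sleepsyn search-rules --rule stdp --n 50 --seed 7 --out rules.csv
sleepsyn run-simple --rules rules.csv --rates 0.5,1,2 --seed 11 --dt 0.1
sleepsyn gen-patterns --state sleep --rate 1.0 --upm 2.7 --duration 360 --seed 3
sleepsyn search-swo --n 2000 --seed 1
```

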