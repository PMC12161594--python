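"""Fixed model constants and key-value configuration files.

All constants live in small frozen dataclasses so that a simulation is fully
specified by (constants, parameter set, inputs, seed).  The defaults are the
package's reference configuration: the calcium-source kinetics follow the
two-threshold calcium-plasticity literature (NMDAR second-order gating, VGCC
instantaneous activation, no Mg2+ block) and the conductance-based constants
follow the averaged-neuron family of cortical slow-oscillation models.

Absolute scales of the calcium sources are irrelevant in the simple model:
the beta_nmda/beta_vgcc scaling factors are always re-calibrated so that the
mean unitary transient amplitudes are 0.7 uM (NMDAR source) and 1.4 uM (VGCC
source).  Only the transient *shapes* (rise/decay kinetics) matter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union


@dataclass(frozen=True)
class SimpleModelConstants:
    """Fixed constants of the two-neuron (simple) plasticity model."""

    v_rest: float = -65.0     # mV, resting potential entering the NMDAR driving force
    v_ca: float = 120.0       # mV, Ca2+ reversal potential
    g_nmda: float = 1.0       # uS, NMDAR conductance (scale absorbed by beta_nmda)
    g_ca: float = 1.0         # uS, VGCC conductance (scale absorbed by beta_vgcc)
    alpha_ca: float = 0.1     # uM per (nA ms), current-to-concentration factor
    area: float = 1.0         # relative membrane area factor for the VGCC current
    a_x_nmda: float = 0.5     # 1/ms, NMDAR x-gate activation rate
    tau_x_nmda: float = 2.0   # ms, NMDAR x-gate decay
    a_s_nmda: float = 0.5     # 1/ms, NMDAR s-gate activation rate
    tau_s_nmda: float = 10.0  # ms, NMDAR s-gate decay
    z_noise: float = 3.5      # noise coefficient z of the efficacy SDE


@dataclass(frozen=True)
class WaveformConstants:
    """Spike-train to membrane-voltage conversion parameters.

    A spike is drawn as linear segments through (t-rise_ms, local level),
    (t, peak), (t+ahp_ms, ahp), (t+recover_ms, local level) so the timestamp
    always coincides with the voltage peak.  "Local level" is the Up-state
    potential inside sleep Up intervals and the Down/baseline potential
    otherwise.  The Up-Down difference defaults to 15 mV.
    """

    peak: float = 30.0        # mV, spike peak
    ahp: float = -70.0        # mV, after-hyperpolarization trough
    baseline: float = -65.0   # mV, Down-state / wake baseline potential
    up_down_diff: float = 15.0  # mV, Up-state minus Down-state potential
    rise_ms: float = 1.0      # ms before peak where depolarization starts
    ahp_ms: float = 2.0       # ms after peak where the AHP trough sits
    recover_ms: float = 8.0   # ms after peak where the trace is back at level

    @property
    def up_level(self) -> float:
        return self.baseline + self.up_down_diff


@dataclass(frozen=True)
class HHConstants:
    """Fixed constants of the conductance-based (averaged neuron) model.

    Conductances themselves are free parameters of the search and are not
    listed here.  Intrinsic current densities are in uA/cm2 and multiplied
    by 10*area to obtain nA; synaptic currents (g in uS, V in mV) are in nA
    directly.
    """

    c_m: float = 1.0          # uF/cm2, specific capacitance
    area: float = 0.02        # mm2, membrane area
    v_l: float = -60.95       # mV, leak reversal
    v_na: float = 55.0        # mV
    v_k: float = -100.0       # mV
    v_ca: float = 120.0       # mV
    v_ampa: float = 0.0       # mV
    v_nmda: float = 0.0       # mV
    v_gaba: float = -70.0     # mV
    tau_h_a: float = 15.0     # ms, A-current inactivation time constant
    k_d: float = 30.0         # uM, Ca2+ half-activation of the KCa current
    alpha_ca: float = 0.2     # uM/(nA ms), Ca2+ influx factor; places burst
                              # Ca2+ at the KCa half-activation scale
    phi: float = 1.0          # temperature factor
    # synaptic kinetics
    a_ampa: float = 0.5       # 1/ms
    tau_ampa: float = 5.0     # ms
    a_s_nmda: float = 0.5     # 1/ms
    a_x_nmda: float = 0.5     # 1/ms
    tau_s_nmda: float = 100.0  # ms
    tau_x_nmda: float = 2.0   # ms
    a_gaba: float = 0.5       # 1/ms
    tau_gaba: float = 10.0    # ms
    tau_ca_syn: float = 15.0  # ms, synaptic Ca2+ compartment time constant


def save_config(obj, path: Union[str, Path]) -> None:
    """Write a constants dataclass as a plain ``key = value`` text file."""
    lines = [f"{f.name} = {getattr(obj, f.name)!r}" for f in dataclasses.fields(obj)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(cls, path: Union[str, Path]):
    """Read a ``key = value`` text file back into dataclass ``cls``."""
    values = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if not key:
            raise ValueError(f"malformed config line: {raw!r}")
        values[key] = eval(val.strip(), {"__builtins__": {}})  # literals only
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**values)
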