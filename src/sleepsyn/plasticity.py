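"""Calcium-based synaptic plasticity: the bistable efficacy model.

The synaptic efficacy rho follows a double-well stochastic differential
equation driven by the postsynaptic calcium concentration c(t):

    tau_s drho/dt = -rho(1-rho)(rho*-rho) + gamma_p (1-rho) H[c-theta_p]
                    - gamma_d rho H[c-theta_d] + Noise(t)

with H the Heaviside step.  Calcium is the sum of an NMDAR-sourced component
C_pre (second-order receptor gating driven by the presynaptic voltage) and a
VGCC-sourced component C_post (instantaneous voltage-gated activation of the
postsynaptic membrane); no Mg2+ block is applied.  The noise term is
sigma * z * sqrt(H[c-theta_d] + H[c-theta_p]) * sqrt(dt) * eta per step --
Gaussian, active only while calcium exceeds at least one threshold -- with
z = 3.5 calibrated against the closed-form protocol solution.

With sigma = 0 the flux at the boundaries keeps rho in [0, 1]: at rho = 0
the drift is gamma_p H[...] >= 0 and at rho = 1 it is -gamma_d H[...] <= 0.
Synaptic weight is the affine map w = w0 + rho (w1 - w0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .constants import SimpleModelConstants
from .patterns import VoltageTrace

RULE_LABELS = ("Hebbian", "STDP", "AntiHebbian", "AntiSTDP")


@dataclass
class PlasticityRuleParams:
    """One synaptic learning-rule instance (thresholds in uM, taus in ms)."""

    theta_p: float
    theta_d: float
    gamma_p: float
    gamma_d: float
    tau_pre: float
    tau_post: float
    sigma: float
    tau_s: float
    rho_star: float = 0.5
    z: float = 3.5
    beta_nmda: float = 1.0
    beta_vgcc: float = 1.0
    rule_label: str = "STDP"

    def __post_init__(self):
        if min(self.tau_pre, self.tau_post, self.tau_s) <= 0:
            raise ValueError("time constants must be positive")
        if self.gamma_p < 0 or self.gamma_d < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.theta_p <= 0 or self.theta_d <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.rho_star < 1:
            raise ValueError("rho_star must lie in (0, 1)")
        if self.rule_label not in RULE_LABELS:
            raise ValueError(f"rule_label must be one of {RULE_LABELS}")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CalciumState:
    c_pre: float = 0.0
    c_post: float = 0.0
    s_nmda: float = 0.0
    x_nmda: float = 0.0


@dataclass
class SynapseState:
    rho: float = 0.5
    w0: float = 0.0
    w1: float = 1.0

    @property
    def weight(self) -> float:
        return self.w0 + self.rho * (self.w1 - self.w0)


def saturating_gate(v: float) -> float:
    """Presynaptic release gate f(V) = 1/[1+exp(-(V-20)/2)], in (0, 1)."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    out = 1.0 / (1.0 + np.exp(-(v - 20.0) / 2.0))
    return float(out) if out.ndim == 0 else out


def vgcc_activation(v: float) -> float:
    """Steady-state VGCC activation mCa_inf(V) = 1/[1+exp(-(V+20)/9)]."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    out = 1.0 / (1.0 + np.exp(-(v + 20.0) / 9.0))
    return float(out) if out.ndim == 0 else out


def nmda_influx_trace(v_pre: VoltageTrace, constants: SimpleModelConstants,
                      v_post: Optional[VoltageTrace] = None) -> np.ndarray:
    """Unit-beta NMDAR calcium influx -alpha_Ca * I_Ca_NMDA per time step.

    In the simple model the driving force is fixed at (V_rest - V_Ca); when a
    postsynaptic trace is supplied the conductance-model variant
    I = g s (V_post - V_Ca) is used instead.
    """
    s = _kernels.nmda_gating_trace(
        np.ascontiguousarray(v_pre.v, dtype=float), v_pre.dt,
        constants.a_x_nmda, constants.tau_x_nmda,
        constants.a_s_nmda, constants.tau_s_nmda, 0.0, 0.0)
    if v_post is None:
        drive = constants.v_ca - constants.v_rest
        return constants.alpha_ca * constants.g_nmda * drive * s
    return constants.alpha_ca * constants.g_nmda * s * (constants.v_ca - v_post.v)


def vgcc_influx_trace(v_post: VoltageTrace,
                      constants: SimpleModelConstants) -> np.ndarray:
    """Unit-beta VGCC calcium influx -alpha_Ca * A * I_Ca_VGCC per step."""
    m = vgcc_activation(v_post.v)
    return (constants.alpha_ca * constants.area * constants.g_ca
            * m * m * (constants.v_ca - v_post.v))


def calcium_trace(v_pre: VoltageTrace, v_post: VoltageTrace,
                  params: PlasticityRuleParams,
                  constants: Optional[SimpleModelConstants] = None,
                  hh_nmda: bool = False) -> np.ndarray:
    """Total postsynaptic calcium c(t) = C_pre + C_post for a trace pair."""
    if len(v_pre.v) != len(v_post.v) or v_pre.dt != v_post.dt:
        raise ValueError("pre/post traces must share the time base")
    constants = constants or SimpleModelConstants()
    u_pre = nmda_influx_trace(v_pre, constants, v_post if hh_nmda else None)
    u_post = vgcc_influx_trace(v_post, constants)
    c_pre = _kernels.exp_filter(u_pre, v_pre.dt, params.tau_pre,
                                params.beta_nmda, 0.0)
    c_post = _kernels.exp_filter(u_post, v_post.dt, params.tau_post,
                                 params.beta_vgcc, 0.0)
    return c_pre + c_post


def step_calcium(state: CalciumState, v_pre: float, v_post: float,
                 params: PlasticityRuleParams,
                 constants: Optional[SimpleModelConstants] = None,
                 dt: float = 0.1, hh_nmda: bool = False) -> CalciumState:
    """Advance the calcium sources by one RK4 step (voltages held constant).

    The kernel path used in simulations integrates whole traces; this
    single-step form exists for stepping experiments and tests.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.isfinite(v_pre) and np.isfinite(v_post)):
        raise ValueError("membrane potentials must be finite")
    constants = constants or SimpleModelConstants()
    f = saturating_gate(v_pre)
    drive = (v_post - constants.v_ca) if hh_nmda else (constants.v_rest - constants.v_ca)

    def deriv(c_pre, c_post, s, x):
        i_nmda = constants.g_nmda * s * drive
        m = vgcc_activation(v_post)
        i_vgcc = constants.g_ca * m * m * (v_post - constants.v_ca)
        dcp = (-constants.alpha_ca * i_nmda * params.beta_nmda
               - c_pre / params.tau_pre)
        dcq = (-constants.alpha_ca * constants.area * i_vgcc * params.beta_vgcc
               - c_post / params.tau_post)
        ds = constants.a_s_nmda * x * (1.0 - s) - s / constants.tau_s_nmda
        dx = constants.a_x_nmda * f - x / constants.tau_x_nmda
        return np.array([dcp, dcq, ds, dx])

    y = np.array([state.c_pre, state.c_post, state.s_nmda, state.x_nmda])
    k1 = deriv(*y)
    k2 = deriv(*(y + 0.5 * dt * k1))
    k3 = deriv(*(y + 0.5 * dt * k2))
    k4 = deriv(*(y + dt * k3))
    y = y + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    y[:2] = np.maximum(y[:2], 0.0)  # concentrations stay non-negative
    return CalciumState(c_pre=y[0], c_post=y[1], s_nmda=y[2], x_nmda=y[3])


def step_efficacy(s: SynapseState, c: float, params: PlasticityRuleParams,
                  dt: float, rng: Optional[np.random.Generator] = None) -> SynapseState:
    """One Euler-Maruyama-style update of rho (RK4 drift + gated noise)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = rng or np.random.default_rng(0)
    traj = _kernels.simulate_efficacy(
        np.array([c, c]), dt, params.tau_s, params.theta_p, params.theta_d,
        params.gamma_p, params.gamma_d, params.sigma, params.z,
        params.rho_star, s.rho, rng)
    return replace(s, rho=float(traj[-1]))


def simulate_synapse(v_pre: VoltageTrace, v_post: VoltageTrace,
                     params: PlasticityRuleParams, rho0: float = 0.5,
                     seed: Optional[int] = None,
                     constants: Optional[SimpleModelConstants] = None,
                     rng: Optional[np.random.Generator] = None,
                     hh_nmda: bool = False) -> np.ndarray:
    """Full efficacy trajectory rho(t) for one pre/post voltage-trace pair."""
    if not 0 <= rho0 <= 1:
        raise ValueError("rho0 must lie in [0, 1]")
    c = calcium_trace(v_pre, v_post, params, constants, hh_nmda=hh_nmda)
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    return _kernels.simulate_efficacy(
        c, v_pre.dt, params.tau_s, params.theta_p, params.theta_d,
        params.gamma_p, params.gamma_d, params.sigma, params.z,
        params.rho_star, rho0, rng)
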