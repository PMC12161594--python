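"""Shared fixtures: searched rule sets and the pairing-protocol context.

The searches are session-scoped because several test modules (and the
acceptance tests) consume the same accepted parameter sets.
"""

from __future__ import annotations

import numpy as np
import pytest

from sleepsyn.plasticity import PlasticityRuleParams
from sleepsyn.rules import PairingContext, search_rules


@pytest.fixture(scope="session")
def pairing_ctx() -> PairingContext:
    return PairingContext()


@pytest.fixture(scope="session")
def stdp_sets(pairing_ctx):
    """100 accepted STDP parameter sets (ascending SSE)."""
    accepted, sse, _ = search_rules("STDP", n_target=100, seed=101,
                                    budget=60_000, ctx=pairing_ctx)
    assert len(accepted) >= 100
    return accepted


@pytest.fixture(scope="session")
def antistdp_sets(pairing_ctx):
    """100 accepted Anti-STDP parameter sets (ascending SSE)."""
    accepted, sse, _ = search_rules("AntiSTDP", n_target=100, seed=102,
                                    budget=100_000, ctx=pairing_ctx)
    assert len(accepted) >= 100
    return accepted


@pytest.fixture(scope="session")
def stdp_curves(pairing_ctx, stdp_sets):
    return [pairing_ctx.curve(p) for p in stdp_sets[:5]]


@pytest.fixture()
def nominal_params() -> PlasticityRuleParams:
    """A hand-picked mid-range parameter set (uncalibrated)."""
    return PlasticityRuleParams(theta_p=1.2, theta_d=0.7, gamma_p=300.0,
                                gamma_d=150.0, tau_pre=20.0, tau_post=15.0,
                                sigma=400.0, tau_s=1.5e5)
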