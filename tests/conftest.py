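"""Shared fixtures: simulated cells are expensive, so families are session-scoped."""

import numpy as np
import pytest

from vipcinq.synth import NeuronModelParams, simulate_family
from vipcinq.synth.protocols import firing_protocol, rin_protocol, sag_protocol


@pytest.fixture(scope="session")
def vip_params() -> NeuronModelParams:
    """Default noise-free VIP-like cell (AdEx + H-current)."""
    return NeuronModelParams()


@pytest.fixture(scope="session")
def passive_params(vip_params) -> NeuronModelParams:
    """Pure RC membrane: spiking, adaptation and H-current disabled."""
    return vip_params.passive()


@pytest.fixture(scope="session")
def wt_families(vip_params):
    """The three noise-free stimulus families of one default cell at 50 kHz."""
    return (
        simulate_family(vip_params, rin_protocol(), 50.0, 11),
        simulate_family(vip_params, firing_protocol(), 50.0, 12),
        simulate_family(vip_params, sag_protocol(), 50.0, 13),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
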