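"""Standard current-step protocols for VIP+ interneuron characterization.

Three stimulus families drive the intrinsic-feature pipeline:

* input-resistance family: -50 to +20 pA in 10 pA steps (8 sweeps),
* firing family: 800 ms depolarizing steps spanning 25-500 pA (13 levels),
* sag/rebound family: -50 to -250 pA in 50 pA steps (5 sweeps).

The 13 firing levels are 25-300 pA in 25 pA increments plus a 500 pA top
step; the fine 25 pA spacing at the bottom resolves rheobase and guarantees
a sweep 50 pA above it for spike-shape analysis.
"""

from __future__ import annotations

import numpy as np

from .neuron import StimulusDescriptor

#: Depolarizing step amplitudes (pA) of the firing protocol, 13 levels.
FIRING_LEVELS_PA: tuple[float, ...] = tuple(float(a) for a in range(25, 301, 25)) + (500.0,)


def rin_protocol(
    onset_ms: float = 200.0, duration_ms: float = 500.0, baseline_pa: float = 0.0
) -> list[StimulusDescriptor]:
    """-50 to +20 pA in 10 pA steps: the voltage-current (Rin) family."""
    return [
        StimulusDescriptor(float(a), onset_ms, duration_ms, baseline_pa)
        for a in np.arange(-50.0, 20.0 + 1e-9, 10.0)
    ]


def firing_protocol(
    onset_ms: float = 200.0,
    duration_ms: float = 800.0,
    baseline_pa: float = 0.0,
    levels_pa: tuple[float, ...] = FIRING_LEVELS_PA,
) -> list[StimulusDescriptor]:
    """800 ms depolarizing steps used for firing curve, rheobase and AP shape."""
    return [StimulusDescriptor(float(a), onset_ms, duration_ms, baseline_pa) for a in levels_pa]


def sag_protocol(
    onset_ms: float = 200.0, duration_ms: float = 800.0, baseline_pa: float = 0.0
) -> list[StimulusDescriptor]:
    """-50 to -250 pA in 50 pA steps: the sag/rebound family."""
    return [
        StimulusDescriptor(float(a), onset_ms, duration_ms, baseline_pa)
        for a in np.arange(-50.0, -250.0 - 1e-9, -50.0)
    ]
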