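"""Genotype effects expressed as parameter multipliers.

The three experimental groups are wildtype (WT), conditional heterozygote
(cHet) and conditional knockout (cKO) of *Tsc1* in VIP+ interneurons.  Group
differences are emulated by scaling generator parameters.  The default
multipliers are illustrative, chosen only to reproduce the qualitative effect
directions reported for the mutants (lower input resistance, larger rebound,
higher firing output, broader spikes, larger sEPSCs, attenuated
developmental cell loss); they are not fitted to data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

from .neuron import NeuronModelParams

GENOTYPES = ("WT", "cHet", "cKO")


@dataclass(frozen=True)
class GenotypeEffect:
    """A label plus a feature-name -> scale-factor map.

    Keys naming :class:`NeuronModelParams` fields scale the membrane model;
    other keys (e.g. ``epsc_amplitude``, ``colabel_rate``) are consumed by the
    generator that owns them.  A WT effect has an empty map (all factors 1).
    """

    label: str
    multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label == "WT" and any(v != 1.0 for v in self.multipliers.values()):
            raise ValueError("WT multipliers must all be 1")

    def apply_to_params(self, params: NeuronModelParams) -> NeuronModelParams:
        """Scale the membrane-model fields named in the multiplier map.

        Note that scaling a negative voltage (e.g. the intrinsic threshold)
        by a factor > 1 makes it more negative, i.e. more excitable.
        """
        names = {f.name for f in fields(NeuronModelParams)}
        updates = {
            k: getattr(params, k) * v for k, v in self.multipliers.items() if k in names
        }
        return replace(params, **updates) if updates else params

    def factor(self, key: str, default: float = 1.0) -> float:
        return float(self.multipliers.get(key, default))


#: Illustrative default effects reproducing the reported directions only.
DEFAULT_EFFECTS: dict[str, GenotypeEffect] = {
    "WT": GenotypeEffect("WT", {}),
    "cHet": GenotypeEffect(
        "cHet",
        {
            "spike_threshold_slope_factor": 1.25,  # broader spikes
            "adaptation_increment": 0.75,  # weaker adaptation
            "epsc_amplitude": 1.1,
        },
    ),
    "cKO": GenotypeEffect(
        "cKO",
        {
            "leak_conductance": 1.75,  # lower Rin
            "h_current_max_conductance": 1.5,  # larger rebound
            "spike_threshold_slope_factor": 1.5,  # broader spikes
            "adaptation_increment": 0.5,  # weaker adaptation, higher firing output
            "intrinsic_threshold": 1.05,  # more negative threshold -> excitable
            "epsc_amplitude": 1.4,  # larger sEPSC amplitude and AUC
            "colabel_rate": 0.4,  # reduced apoptosis marker fraction
        },
    ),
}
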