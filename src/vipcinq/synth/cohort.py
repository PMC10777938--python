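"""Synthetic developmental cohorts: per-animal cell densities and apoptosis
marker co-label counts across postnatal ages and genotypes.

The default trajectories emulate the qualitative developmental pattern of
tdTomato+ VIP-lineage interneuron density: a rise to a plateau between P7 and
P15 followed by a monotonic decline through P35 in WT and cHet animals, and a
flat trajectory from P7 through P35 in the cKO (apoptotic elimination
attenuated).  Co-label counts (e.g. cleaved caspase-3+ among tdTomato+
cells) are binomial per animal.  All trajectory values are free generator
parameters, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_AGES = (3, 7, 15, 25, 35, 50)

#: Mean density trajectories (cells/mm^2 per postnatal day).
DEFAULT_TRAJECTORIES: dict[str, dict[int, float]] = {
    "WT": {3: 90.0, 7: 160.0, 15: 170.0, 25: 110.0, 35: 85.0, 50: 80.0},
    "cHet": {3: 90.0, 7: 160.0, 15: 170.0, 25: 112.0, 35: 87.0, 50: 82.0},
    "cKO": {3: 90.0, 7: 165.0, 15: 170.0, 25: 168.0, 35: 165.0, 50: 150.0},
}

#: Fraction of marked cells co-labelled for the apoptosis marker.
DEFAULT_COLABEL_RATES = {"WT": 0.002, "cHet": 0.002, "cKO": 0.0008}


@dataclass
class CohortSpec:
    ages: tuple[int, ...] = DEFAULT_AGES
    genotypes: tuple[str, ...] = ("WT", "cHet", "cKO")
    n_animals: int = 8
    trajectories: dict[str, dict[int, float]] = field(
        default_factory=lambda: {g: dict(t) for g, t in DEFAULT_TRAJECTORIES.items()}
    )
    density_sd: float = 20.0
    colabel_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COLABEL_RATES)
    )
    cells_per_animal: int = 3000

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.density_sd < 0:
            raise ValueError("density_sd must be >= 0")
        for g in self.genotypes:
            rate = self.colabel_rates.get(g, 0.0)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"colabel_rate for {g} must be in [0, 1]")
            for age in self.ages:
                if self.trajectories[g][age] <= 0:
                    raise ValueError("trajectory densities must be > 0")


def simulate_cohort(
    spec: CohortSpec,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one cohort table.

    Per animal and age: density ~ Normal(trajectory mean, density_sd),
    truncated at 0 by redrawing, and colabel_count ~ Binomial(
    cells_per_animal, colabel_rate).  Columns: animal_id, genotype, age,
    density_per_mm2, cells_counted, colabel_count.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in spec.genotypes:
        for a in range(spec.n_animals):
            animal = f"{g}_{a:02d}"
            for age in spec.ages:
                mu = spec.trajectories[g][age]
                if spec.density_sd > 0:
                    density = rng.normal(mu, spec.density_sd)
                    while density < 0:  # truncate at zero by redraw
                        density = rng.normal(mu, spec.density_sd)
                else:
                    density = mu
                colabel = rng.binomial(spec.cells_per_animal, spec.colabel_rates.get(g, 0.0))
                rows.append(
                    {
                        "animal_id": animal,
                        "genotype": g,
                        "age": age,
                        "density_per_mm2": float(density),
                        "cells_counted": spec.cells_per_animal,
                        "colabel_count": int(colabel),
                    }
                )
    return pd.DataFrame(rows)
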