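"""Cell-density, co-label and developmental-trajectory computations.

Cell tables are pandas DataFrames with columns ``animal_id``, ``section_id``,
``x_um``, ``y_um`` and ``markers`` (semicolon-separated label string, e.g.
``"tdTomato;cC3"``).  Boxes and layer bins are half-open ``[lo, hi)`` so
boundary assignment is deterministic and counts are additive under
splitting; a cell sitting exactly on a layer boundary goes to the deeper
bin.  The animal (not the section) is the statistical unit: sections are
averaged within animal before group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import one_way_anova_tukey

UM2_PER_MM2 = 1e6


@dataclass(frozen=True)
class CountBox:
    """A counting box with optional laminar subdivision.

    ``layer_edges`` are y-offsets from the box origin (depth increases with
    y), strictly increasing, starting at 0 and ending at ``height_um``;
    ``layer_labels`` name the ``len(layer_edges) - 1`` strips.
    """

    x0_um: float
    y0_um: float
    width_um: float
    height_um: float
    layer_edges: tuple[float, ...] = ()
    layer_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("box width and height must be > 0")
        if self.layer_edges:
            edges = np.asarray(self.layer_edges)
            if np.any(np.diff(edges) <= 0):
                raise ValueError("layer edges must be strictly increasing")
            if len(self.layer_labels) != len(self.layer_edges) - 1:
                raise ValueError("need one label per layer strip")

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / UM2_PER_MM2


def has_marker(cells: pd.DataFrame, marker: str) -> pd.Series:
    """Boolean mask of cells carrying a marker label."""
    return cells["markers"].map(lambda m: marker in str(m).split(";"))


def in_box(cells: pd.DataFrame, box: CountBox) -> pd.Series:
    """Half-open membership: [x0, x0+w) x [y0, y0+h)."""
    return (
        (cells["x_um"] >= box.x0_um)
        & (cells["x_um"] < box.x0_um + box.width_um)
        & (cells["y_um"] >= box.y0_um)
        & (cells["y_um"] < box.y0_um + box.height_um)
    )


def density_in_box(cells: pd.DataFrame, box: CountBox) -> float:
    """Cells per mm^2: half-open box count divided by box area."""
    if box.area_mm2 <= 0:
        raise ValueError("box area must be > 0")
    return float(in_box(cells, box).sum() / box.area_mm2)


def laminar_distribution(cells: pd.DataFrame, box: CountBox) -> pd.DataFrame:
    """Per-layer densities within a subdivided box.

    Returns one row per layer with count and density (cells/mm^2), plus an
    ``outside`` row tallying in-box cells falling outside all layer bins
    (possible when the edges do not span the full box height).
    """
    if not box.layer_edges:
        raise ValueError("box has no layer subdivision")
    inside = cells[in_box(cells, box)]
    depth = inside["y_um"] - box.y0_um
    edges = np.asarray(box.layer_edges, dtype=np.float64)
    rows = []
    assigned = pd.Series(False, index=inside.index)
    for i, label in enumerate(box.layer_labels):
        lo, hi = edges[i], edges[i + 1]
        mask = (depth >= lo) & (depth < hi)
        assigned |= mask
        strip_area = box.width_um * (hi - lo) / UM2_PER_MM2
        rows.append(
            {
                "layer": label,
                "count": int(mask.sum()),
                "density_per_mm2": float(mask.sum() / strip_area),
            }
        )
    rows.append(
        {
            "layer": "outside",
            "count": int((~assigned).sum()),
            "density_per_mm2": np.nan,
        }
    )
    return pd.DataFrame(rows)


def filter_every_nth_section(cells: pd.DataFrame, n: int = 5, offset: int = 0) -> pd.DataFrame:
    """Keep every n-th section (systematic sampling of a rostro-caudal series)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return cells[cells["section_id"].astype(int) % n == offset]


def colabel_fraction(
    cells: pd.DataFrame, marker_a: str, marker_b: str
) -> pd.DataFrame:
    """Per-animal co-label fraction ``|a and b| / |a|`` with raw counts.

    Returns one row per animal with ``n_a``, ``n_ab`` and ``fraction``.
    Raises when no cell carries ``marker_a`` at all.
    """
    a = has_marker(cells, marker_a)
    if not a.any():
        raise ValueError(f"no cells carry marker {marker_a!r}")
    b = has_marker(cells, marker_b)
    df = cells.assign(_a=a, _ab=a & b)
    out = (
        df.groupby("animal_id", sort=True)
        .agg(n_a=("_a", "sum"), n_ab=("_ab", "sum"))
        .reset_index()
    )
    out["fraction"] = out["n_ab"] / out["n_a"]
    return out


@dataclass
class TrajectoryResult:
    """Group means/sems and pairwise contrasts of a developmental cohort."""

    group_summary: pd.DataFrame  # genotype, age, n, mean, sem
    age_contrasts: pd.DataFrame  # age, pair, mean_diff, p_tukey
    earliest_divergence_age: int | None
    within_genotype_changes: pd.DataFrame  # genotype, age_from, age_to, change


def trajectory_contrast(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    value_col: str = "density_per_mm2",
) -> TrajectoryResult:
    """Developmental trajectory comparison across genotypes.

    Computes per (genotype, age) means and standard errors; at each age runs
    a one-way ANOVA with Tukey post-test across genotypes; and reports
    within-genotype age-to-age changes of the group mean.  An age is flagged
    as divergent when its omnibus ANOVA is significant after a Bonferroni
    correction across the ages tested (controlling the cohort-wise false
    flag rate at ``alpha``) and at least one Tukey pair falls below
    ``alpha``; the earliest such age is reported.  Groups with fewer than
    two animals are excluded with a warning.
    """
    ages = sorted(cohort["age"].unique())
    genotypes = sorted(cohort["genotype"].unique())
    if len(ages) < 2 or len(genotypes) < 2:
        raise ValueError("need >= 2 ages and >= 2 genotypes")
    summary = (
        cohort.groupby(["genotype", "age"])[value_col]
        .agg(n="count", mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    contrast_rows = []
    per_age: list[tuple[int, object]] = []
    for age in ages:
        sub = cohort[cohort["age"] == age]
        groups = {}
        for g in genotypes:
            vals = sub.loc[sub["genotype"] == g, value_col].to_numpy()
            if len(vals) < 2:
                warnings.warn(
                    f"group {g} at age {age} has n={len(vals)} < 2; excluded"
                )
                continue
            groups[g] = vals
        if len(groups) < 2:
            continue
        res = one_way_anova_tukey(groups, alpha=alpha)
        per_age.append((int(age), res))
        for pair in res.pairs:
            contrast_rows.append(
                {
                    "age": age,
                    "pair": f"{pair.group_a} vs {pair.group_b}",
                    "mean_diff": pair.mean_diff,
                    "p_omnibus": res.p_value,
                    "p_tukey": pair.p_adjusted,
                }
            )
    earliest: int | None = None
    n_tested = len(per_age)
    for age, res in per_age:
        omnibus_ok = res.p_value < alpha / max(n_tested, 1)
        pair_ok = any(p.p_adjusted < alpha for p in res.pairs)
        if omnibus_ok and pair_ok:
            earliest = age
            break
    change_rows = []
    for g in genotypes:
        gsum = summary[summary["genotype"] == g].sort_values("age")
        means = gsum["mean"].to_numpy()
        gages = gsum["age"].to_numpy()
        for i in range(len(gages) - 1):
            change_rows.append(
                {
                    "genotype": g,
                    "age_from": int(gages[i]),
                    "age_to": int(gages[i + 1]),
                    "change": float(means[i + 1] - means[i]),
                }
            )
    return TrajectoryResult(
        group_summary=summary,
        age_contrasts=pd.DataFrame(contrast_rows),
        earliest_divergence_age=earliest,
        within_genotype_changes=pd.DataFrame(change_rows),
    )
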