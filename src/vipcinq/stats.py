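"""The study's statistical protocol: assumption checks, one-way ANOVA with
Tukey's post-test, and two-way (genotype x current) fixed-effects ANOVA.

The one-way decomposition and the Tukey-Kramer standard error are assembled
explicitly from sums of squares and the studentized-range distribution;
distributional machinery (Shapiro-Wilk, Levene, F and studentized-range
distributions) comes from scipy, and the two-way table from a statsmodels
OLS fit.  The two-way model treats every observation as independent
(fixed-effects, no repeated-measures structure), which with g genotypes and
c current levels gives an interaction with (g-1)(c-1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    mean_diff: float
    p_adjusted: float


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairs: list[PairwiseResult] = field(default_factory=list)
    ss_between: float = 0.0
    ss_within: float = 0.0

    def to_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p_value,
            "pairs": [
                {
                    "a": p.group_a,
                    "b": p.group_b,
                    "mean_diff": p.mean_diff,
                    "p_tukey": p.p_adjusted,
                }
                for p in self.pairs
            ],
        }


@dataclass
class GroupAssumption:
    group: str
    statistic: float | None
    p_value: float | None
    testable: bool
    passed: bool | None


@dataclass
class AssumptionReport:
    normality: list[GroupAssumption]
    levene_statistic: float | None
    levene_p: float | None
    homogeneity_testable: bool
    homogeneity_passed: bool | None
    alpha: float


def _as_groups(data: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {str(k): np.asarray(v, dtype=np.float64) for k, v in data.items()}


def check_assumptions(
    data: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AssumptionReport:
    """Shapiro-Wilk normality per group and Levene homogeneity across groups.

    Levene is run with ``center='mean'`` (the classic test).  Groups with
    n < 3, and degenerate (zero-variance) configurations, are flagged
    untestable rather than failed.
    """
    groups = _as_groups(data)
    normality = []
    for name, vals in groups.items():
        if len(vals) < 3 or np.ptp(vals) == 0:
            normality.append(GroupAssumption(name, None, None, False, None))
            continue
        stat, p = sps.shapiro(vals)
        normality.append(GroupAssumption(name, float(stat), float(p), True, p >= alpha))
    arrays = list(groups.values())
    if len(arrays) >= 2 and all(len(a) >= 2 for a in arrays) and any(
        np.ptp(a) > 0 for a in arrays
    ):
        stat, p = sps.levene(*arrays, center="mean")
        report = AssumptionReport(
            normality, float(stat), float(p), True, bool(p >= alpha), alpha
        )
    else:
        report = AssumptionReport(normality, None, None, False, None, alpha)
    return report


def one_way_anova(data: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA from the explicit SS decomposition.

    Identical groups (zero between-group SS) report F = 0, p = 1; zero
    within-group SS with nonzero between-group SS reports F = inf, p = 0.
    """
    groups = _as_groups(data)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    if ss_between == 0:
        f_stat, p = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(sps.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
    )


def tukey_pairs(
    data: Mapping[str, Sequence[float]], anova: AnovaResult | None = None
) -> list[PairwiseResult]:
    """Tukey HSD adjusted p-values via the studentized-range distribution.

    Unbalanced groups use the Tukey-Kramer standard error
    ``sqrt(MSW/2 * (1/n_i + 1/n_j))``.  With zero within-group variance,
    pairs with equal means get p = 1 and differing means p = 0.
    """
    groups = _as_groups(data)
    if anova is None:
        anova = one_way_anova(groups)
    k = len(groups)
    msw = anova.ss_within / anova.df_within if anova.df_within > 0 else 0.0
    names = list(groups)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = groups[names[i]], groups[names[j]]
            diff = float(a.mean() - b.mean())
            if msw == 0:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, anova.df_within))
            out.append(PairwiseResult(names[i], names[j], diff, min(max(p_adj, 0.0), 1.0)))
    return out


def one_way_anova_tukey(
    data: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA followed by Tukey's post-test (the default protocol)."""
    res = one_way_anova(data)
    res.pairs = tukey_pairs(data, res)
    return res


@dataclass
class TwoWayAnovaResult:
    table: pd.DataFrame  # rows: factor_a, factor_b, interaction, residual
    interaction_f: float
    interaction_df: int
    residual_df: int
    interaction_p: float


def two_way_anova(
    data: pd.DataFrame,
    value_col: str,
    factor_a: str,
    factor_b: str,
) -> TwoWayAnovaResult:
    """Two-factor fixed-effects ANOVA with interaction.

    Requires a complete factorial layout (every factor-level combination
    represented); an empty cell raises, naming the cell.  With ``g`` levels
    of factor A and ``c`` of factor B the interaction has (g-1)(c-1) df.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    levels_a = data[factor_a].unique()
    levels_b = data[factor_b].unique()
    counts = data.groupby([factor_a, factor_b]).size()
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in counts.index:
                raise ValueError(f"empty cell: {factor_a}={a!r}, {factor_b}={b!r}")
    df = data.rename(columns={value_col: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = smf.ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    inter = "C(_fa):C(_fb)"
    interaction_f = float(table.loc[inter, "F"])
    interaction_df = int(table.loc[inter, "df"])
    residual_df = int(table.loc["Residual", "df"])
    interaction_p = float(table.loc[inter, "PR(>F)"])
    ss_total = float(table["sum_sq"].sum())
    ss_inter = float(table.loc[inter, "sum_sq"])
    # additive-by-construction data: interaction (and possibly residual) SS
    # vanish up to rounding; report F = 0 rather than 0/0 noise
    if np.isnan(interaction_f) or ss_inter <= 1e-10 * max(ss_total, 1e-300):
        interaction_f, interaction_p = 0.0, 1.0
    table = table.rename(
        index={"C(_fa)": factor_a, "C(_fb)": factor_b, inter: f"{factor_a}:{factor_b}"}
    )
    return TwoWayAnovaResult(
        table=table,
        interaction_f=interaction_f,
        interaction_df=interaction_df,
        residual_df=residual_df,
        interaction_p=interaction_p,
    )
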