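"""Classical statistics for the factorial nutrition experiment.

Fixed-effects factorial ANOVA with interactions (Type I sums of squares on
the balanced design, where Type I and Type III coincide), Tukey HSD post-hoc
comparisons summarized as a compact letter display, Kolmogorov-Smirnov and
Levene distributional checks, and F-distribution critical values used by the
neurofuzzy model-quality gate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import MultiComparison

__all__ = [
    "StatConfig",
    "DegenerateResponseError",
    "factorial_anova",
    "tukey_hsd_letters",
    "f_critical",
    "distribution_checks",
]


@dataclass(frozen=True)
class StatConfig:
    """Significance levels: alpha_anova for the factorial stage (post-hoc
    letters included), alpha_model for the model f-critical gate."""

    alpha_anova: float = 0.01
    alpha_model: float = 0.05

    def __post_init__(self) -> None:
        for alpha in (self.alpha_anova, self.alpha_model):
            if not 0 < alpha < 1:
                raise ValueError(f"alpha must be in (0, 1), got {alpha}")


class DegenerateResponseError(ValueError):
    """The response is constant; no variance decomposition exists."""


def factorial_anova(
    table: pd.DataFrame,
    response: str,
    factors: Sequence[str] = ("genotype", "medium", "subculture"),
    interactions: bool = True,
) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA table for one response.

    Returns one row per term (main effects, interactions if requested, and
    the residual) with sum of squares, df, mean square, F and p-value.
    """
    if response not in table.columns:
        raise KeyError(f"response column {response!r} missing")
    y = table[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateResponseError(f"response {response!r} is constant")
    for factor in factors:
        if table[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    terms = [f'C(Q("{f}"))' for f in factors]
    cells = int(np.prod([table[f].nunique() for f in factors]))
    if interactions and len(table) > cells:
        formula = f'Q("{response}") ~ ' + " * ".join(terms)
    elif interactions and len(factors) > 1:
        # no replicates: the full crossing is saturated, so the highest-order
        # interaction is not testable and becomes the residual
        formula = f'Q("{response}") ~ (' + " + ".join(terms) + ")**2"
    else:
        formula = f'Q("{response}") ~ ' + " + ".join(terms)
    fitted = smf.ols(formula, data=table).fit()
    if fitted.df_resid < 1:
        raise ValueError("saturated design: no residual degrees of freedom")
    anova = sm.stats.anova_lm(fitted, typ=1)

    def clean(term: str) -> str:
        out = term
        for factor in factors:
            out = out.replace(f'C(Q("{factor}"))', factor)
        return out.replace(":", " x ")

    anova = anova.rename(index=clean)
    anova = anova.rename(
        columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p_value"}
    )
    anova["mean_sq"] = anova["sum_sq"] / anova["df"]
    return anova[["sum_sq", "df", "mean_sq", "F", "p_value"]]


def _compact_letters(groups: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Greedy insert-absorb compact letter display.

    ``groups`` are ordered by descending mean; ``distinct`` holds unordered
    pairs judged significantly different.  Starting from a single letter
    covering every group, each significant pair splits the letter sets that
    still contain both members; redundant sets are absorbed.  Two groups then
    share a letter iff they were never judged different.
    """
    letter_sets: list[set[str]] = [set(groups)]
    for a, b in sorted(distinct):
        updated: list[set[str]] = []
        for s in letter_sets:
            if a in s and b in s:
                updated.extend((s - {a}, s - {b}))
            else:
                updated.append(s)
        # absorb sets contained in another, keeping first-occurrence order
        unique = []
        for s in updated:
            if s and s not in unique:
                unique.append(s)
        letter_sets = [s for s in unique if not any(s < other for other in unique)]
    # order letters by their highest-mean member for readable output
    rank = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    assignment = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                assignment[g] += letter
    return assignment


def tukey_hsd_letters(
    table: pd.DataFrame,
    response: str,
    grouping: str,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Tukey HSD post-hoc comparison summarized as letters per group.

    Groups sharing no letter differ at level ``alpha``; letters are assigned
    in order of decreasing group mean.  A single group gets letter ``a``.
    """
    sub = table[[grouping, response]].dropna()
    means = sub.groupby(grouping, sort=False)[response].mean().sort_values(ascending=False)
    groups = [str(g) for g in means.index]
    if len(groups) == 1:
        return pd.DataFrame({"group": groups, "mean": means.to_numpy(), "letters": ["a"]})
    comparison = MultiComparison(
        sub[response].to_numpy(dtype=float), sub[grouping].astype(str).to_numpy()
    )
    result = comparison.tukeyhsd(alpha=alpha)
    distinct = {
        (str(a), str(b))
        for (a, b), reject in zip(
            ((r[0], r[1]) for r in result.summary().data[1:]), result.reject
        )
        if reject
    }
    letters = _compact_letters(groups, distinct)
    return pd.DataFrame(
        {"group": groups, "mean": means.to_numpy(), "letters": [letters[g] for g in groups]}
    )


def f_critical(alpha: float, df1: int, df2: int) -> float:
    """Upper-``alpha`` quantile of the F(df1, df2) distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(sps.f.ppf(1.0 - alpha, df1, df2))


def distribution_checks(
    table: pd.DataFrame,
    response: str,
    grouping: str = "medium",
) -> dict:
    """Normality (KS on standardized residuals) and homoscedasticity (Levene).

    Residuals are taken about group means; the KS test compares their
    standardized values with N(0, 1), and Levene's test compares spread
    across the ``grouping`` levels.
    """
    sub = table[[grouping, response]].dropna()
    if len(sub) < 3:
        raise ValueError("at least 3 observations are required")
    groups = [g[response].to_numpy(dtype=float) for _, g in sub.groupby(grouping)]
    if len(groups) < 2:
        raise ValueError("Levene's test needs >= 2 groups")
    resid = np.concatenate([g - g.mean() for g in groups])
    sd = resid.std(ddof=1)
    if sd == 0:
        return {
            "degenerate": True,
            "ks_statistic": np.nan, "ks_p": np.nan,
            "levene_statistic": np.nan, "levene_p": np.nan,
        }
    ks_stat, ks_p = sps.kstest(resid / sd, "norm")
    lev_stat, lev_p = sps.levene(*groups)
    return {
        "degenerate": False,
        "ks_statistic": float(ks_stat), "ks_p": float(ks_p),
        "levene_statistic": float(lev_stat), "levene_p": float(lev_p),
    }
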