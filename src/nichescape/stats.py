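"""Group comparisons on per-animal (or per-well) summary values.

The animal is the experimental unit throughout: per-animal means enter the
tests, never pooled cells.  Two groups are compared with a Welch t test;
more groups with one-way ANOVA; two crossed factors with two-way ANOVA.
Post hoc pairwise comparisons are Welch t tests with Holm–Šídák adjustment,
two-sided, α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = ["StatsResult", "compare_groups"]


@dataclass
class StatsResult:
    """Outcome of one omnibus test plus its post hoc table."""

    test: str
    factors: list[str]
    statistic: float
    df: tuple
    p_value: float
    post_hoc: pd.DataFrame | None = None  # comparison, statistic, p_raw, p_adj, method
    anova_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def _posthoc_pairwise(df: pd.DataFrame, value: str, group: str) -> pd.DataFrame:
    """All pairwise Welch t tests with Holm–Šídák adjusted p-values."""
    levels = list(pd.unique(df[group]))
    rows = []
    for a, b in combinations(levels, 2):
        xa = df.loc[df[group] == a, value].to_numpy(float)
        xb = df.loc[df[group] == b, value].to_numpy(float)
        t, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append({"comparison": f"{a} vs {b}", "statistic": float(t),
                     "p_raw": float(p)})
    tab = pd.DataFrame(rows)
    if len(tab):
        tab["p_adj"] = multipletests(tab["p_raw"], method="holm-sidak")[1]
        tab["method"] = "Welch t, Holm-Sidak"
    return tab


def compare_groups(per_animal: pd.DataFrame, value: str = "value",
                   factors: list[str] | str = "group") -> StatsResult:
    """Compare per-animal summary values across groups.

    Parameters
    ----------
    per_animal:
        One row per animal (or well), with the response in column ``value``
        and grouping columns named in ``factors``.
    factors:
        One factor: Welch t for two levels, one-way ANOVA for more.
        Two factors: two-way ANOVA with interaction.

    Degenerate input with zero variance in every group returns statistic 0
    and p = 1 rather than NaN.
    """
    if isinstance(factors, str):
        factors = [factors]
    if not 1 <= len(factors) <= 2:
        raise ValueError("one or two factors supported")
    df = per_animal.dropna(subset=[value] + factors).copy()
    for f in factors:
        counts = df.groupby(f, observed=True)[value].size()
        if (counts < 2).any() or len(counts) < 2:
            raise ValueError(f"need >=2 animals in each level of {f!r}")

    if len(factors) == 1:
        f = factors[0]
        levels = list(pd.unique(df[f]))
        groups = [df.loc[df[f] == g, value].to_numpy(float) for g in levels]
        if len(levels) == 2:
            if all(np.ptp(g) == 0 for g in groups) and groups[0].mean() == groups[1].mean():
                return StatsResult("welch_t", factors, 0.0,
                                   (len(df) - 2,), 1.0,
                                   post_hoc=_maybe_empty_posthoc())
            t, p = sps.ttest_ind(groups[0], groups[1], equal_var=False)
            nu = _welch_df(groups[0], groups[1])
            return StatsResult("welch_t", factors, float(t), (nu,), float(p))
        fstat, p = sps.f_oneway(*groups)
        dfb, dfw = len(levels) - 1, len(df) - len(levels)
        ph = _posthoc_pairwise(df, value, f)
        return StatsResult("one_way_anova", factors, float(fstat), (dfb, dfw),
                           float(p), post_hoc=ph)

    # two-way ANOVA with interaction; main effect of the first factor is the
    # headline statistic, the full table is attached.
    d = df.rename(columns={value: "_y", factors[0]: "_f1", factors[1]: "_f2"})
    model = smf.ols("_y ~ C(_f1) * C(_f2)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(_f1)"]
    ph = _posthoc_pairwise(df, value, factors[0])
    return StatsResult(
        "two_way_anova", factors, float(row["F"]),
        (int(row["df"]), int(table.loc["Residual", "df"])),
        float(row["PR(>F)"]), post_hoc=ph, anova_table=table,
    )


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return float(len(a) + len(b) - 2)
    return float((va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1)))


def _maybe_empty_posthoc() -> pd.DataFrame:
    return pd.DataFrame(columns=["comparison", "statistic", "p_raw", "p_adj", "method"])
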