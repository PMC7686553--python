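"""Group-comparison layer: two-sample tests and two-way ANOVA reporting.

All p-values are two-sided.  The Mann-Whitney U test switches to the exact
null distribution for small samples (both n <= 8) without ties and to the
tie-corrected normal approximation otherwise.  Unbalanced two-way layouts
use Type-III sums of squares with sum-to-zero contrasts; pairwise cell
comparisons are Welch t-tests with Bonferroni adjustment (raw p times the
number of comparisons, capped at 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["compare_two", "two_way_anova_bonferroni", "TwoWayAnovaResult", "mean_sem"]

EXACT_MW_MAX_N = 8


def compare_two(
    values_a, values_b, test: str = "t_welch"
) -> tuple[float, float]:
    """Two-sided two-group comparison; returns (statistic, p).

    ``t_welch``: unpaired t-test with Welch correction; fails loudly when
    both groups are constant (degenerate variance).  ``mannwhitney``:
    Mann-Whitney U (statistic is U of the first group).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if test == "t_welch":
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError(
                "degenerate variance: both groups are constant, Welch t undefined"
            )
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "mannwhitney":
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        small = max(len(a), len(b)) <= EXACT_MW_MAX_N
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


@dataclass
class TwoWayAnovaResult:
    anova_table: pd.DataFrame  # main effects, interaction (Type III)
    pairwise: pd.DataFrame  # cell-wise comparisons with adjusted p
    cell_means: pd.DataFrame


def two_way_anova_bonferroni(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "group",
    factor_b: str = "level",
) -> TwoWayAnovaResult:
    """Two-way ANOVA followed by Bonferroni-adjusted pairwise cell tests.

    Every factor-level cell must hold at least two observations.  The
    pairwise table compares all cell pairs with Welch t-tests; adjusted
    p = raw p x number of comparisons, capped at 1 (a single comparison is
    returned unadjusted).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table[[value, factor_a, factor_b]].copy()
    df.columns = ["value", "fa", "fb"]
    counts = df.groupby(["fa", "fb"], observed=True).size()
    n_cells = df["fa"].nunique() * df["fb"].nunique()
    if len(counts) < n_cells or (counts < 2).any():
        raise ValueError("every factor cell needs >= 2 observations")
    model = smf.ols("value ~ C(fa, Sum) * C(fb, Sum)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=3)

    cells = {
        key: grp["value"].to_numpy() for key, grp in df.groupby(["fa", "fb"], observed=True)
    }
    pairs = list(combinations(sorted(cells), 2))
    m = len(pairs)
    rows = []
    for ka, kb in pairs:
        res = stats.ttest_ind(cells[ka], cells[kb], equal_var=False)
        raw = float(res.pvalue)
        rows.append(
            {
                "cell_a": "/".join(map(str, ka)),
                "cell_b": "/".join(map(str, kb)),
                "t": float(res.statistic),
                "p_raw": raw,
                "p_adjusted": raw if m == 1 else min(1.0, raw * m),
            }
        )
    means = (
        df.groupby(["fa", "fb"], observed=True)["value"]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    return TwoWayAnovaResult(
        anova_table=anova, pairwise=pd.DataFrame(rows), cell_means=means
    )


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean."""
    v = np.asarray(values, float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
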