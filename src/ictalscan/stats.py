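"""Group statistics: pooled two-sample t tests and two-way fixed-effects ANOVA.

Conventions follow the analysis they support: significance at α = 0.05,
summaries reported as mean ± SEM, no multiple-testing correction.  The t
test is the classical pooled-variance two-sample test with
``df = n_a + n_b − 2``; both one- and two-tailed p-values are reported
because published rodent-EEG work mixes the two conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "StatResult",
    "TwoWayAnovaResult",
    "GroupSummary",
    "t_two_sample",
    "anova_two_way",
    "group_summary",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    df: float
    p: float
    tails: int = 2
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


@dataclass(frozen=True)
class GroupSummary:
    """mean ± SEM of one group's observations."""

    label: str
    mean_s: float
    sem_s: float
    n: int


def group_summary(label: str, values) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError(f"group {label!r} has no observations")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(label, float(v.mean()), sem, int(v.size))


def t_two_sample(a, b, tails: int = 2) -> StatResult:
    """Pooled-variance two-sample t test.

    ``tails=1`` halves the two-sided p (the directional convention for the
    observed sign of t).  Two identical constant samples give t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 \
            and a.mean() == b.mean():
        return StatResult("t_two_sample", 0.0, df, 1.0, tails)
    t, p2 = sp_stats.ttest_ind(a, b, equal_var=True)
    p = float(p2) / 2 if tails == 1 else float(p2)
    return StatResult("t_two_sample", float(t), float(df), p, tails)


@dataclass(frozen=True)
class TwoWayAnovaResult:
    factor_a: StatResult
    factor_b: StatResult
    interaction: StatResult | None   # None when untestable (1 obs/cell)

    @property
    def interaction_testable(self) -> bool:
        return self.interaction is not None


def anova_two_way(values, factor_a, factor_b) -> TwoWayAnovaResult:
    """Two-way fixed-effects ANOVA with interaction.

    Each factor needs ≥ 2 levels and every cell ≥ 1 observation (empty
    cells raise, naming the cell).  With exactly one observation per cell
    the interaction is untestable: the additive model is fit instead and
    the interaction entry is ``None``.
    """
    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "A": np.asarray(factor_a).astype(str),
        "B": np.asarray(factor_b).astype(str),
    })
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    counts = df.groupby(["A", "B"], sort=True).size()
    for a in df["A"].unique():
        for b in df["B"].unique():
            if (a, b) not in counts.index:
                raise ValueError(f"empty design cell (A={a!r}, B={b!r})")

    with_interaction = int(counts.max()) > 1
    formula = "y ~ C(A) * C(B)" if with_interaction else "y ~ C(A) + C(B)"
    fit = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)

    def row(name: str) -> StatResult:
        r = table.loc[name]
        return StatResult("anova_two_way", float(r["F"]),
                          float(r["df"]), float(r["PR(>F)"]))

    inter = row("C(A):C(B)") if with_interaction else None
    return TwoWayAnovaResult(row("C(A)"), row("C(B)"), inter)
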