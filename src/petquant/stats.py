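"""Group comparisons for regional uptake readouts.

Two tests cover the study design: a one-way ANOVA contrasting regions at
baseline, and a one-factor repeated-measures comparison (two conditions:
baseline vs drug) for treatment effects.  With exactly two conditions the
repeated-measures F statistic equals the square of the paired t statistic,
which is how it is computed here.  Tests are two-sided; no multiplicity
correction is applied by default (an optional Holm adjustment is available
for multi-region tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError


@dataclass(frozen=True)
class StatsResult:
    test_name: str
    statistic: float
    df: tuple                 # (numerator, denominator) degrees of freedom
    p_value: float
    effect: Optional[float] = None   # percent change, for paired contrasts

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "effect_percent": self.effect,
        }


def one_way_anova(groups: dict) -> StatsResult:
    """Classical one-way ANOVA across labeled groups.

    F = MS_between / MS_within with df (k−1, N−k); p from the F distribution.
    """
    if len(groups) < 2:
        raise ParameterError("one-way ANOVA needs at least 2 groups")
    arrays = []
    for name, vals in groups.items():
        a = np.asarray(vals, dtype=float)
        if a.size < 2:
            raise ParameterError(f"group {name!r} needs at least 2 values")
        arrays.append(a)
    f_stat, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    return StatsResult(
        test_name="one_way_anova",
        statistic=float(f_stat),
        df=(k - 1, n_total - k),
        p_value=float(p),
    )


def percent_change(baseline_mean: float, post_mean: float) -> float:
    """100·(post − baseline)/baseline; negative means reduction."""
    if baseline_mean == 0:
        raise ParameterError("percent change is undefined for a zero baseline")
    return 100.0 * (post_mean - baseline_mean) / baseline_mean


def repeated_measures_compare(baseline, post) -> StatsResult:
    """Two-condition repeated-measures comparison of paired subject values.

    Computes the one-factor repeated-measures F for conditions {baseline,
    post}, which for two conditions equals the squared paired t statistic;
    df = (1, n−1).  The effect is the percent change of the condition means.
    """
    b = np.asarray(baseline, dtype=float)
    p_ = np.asarray(post, dtype=float)
    if b.shape != p_.shape or b.ndim != 1:
        raise ParameterError("baseline and post must be equal-length 1-D paired vectors")
    n = b.size
    if n < 2:
        raise ParameterError("need at least 2 paired subjects")
    t_stat, p_val = sps.ttest_rel(p_, b)
    if np.isnan(t_stat):        # zero within-pair variance, identical conditions
        t_stat, p_val = 0.0, 1.0
    return StatsResult(
        test_name="repeated_measures_two_condition",
        statistic=float(t_stat) ** 2,
        df=(1, n - 1),
        p_value=float(p_val),
        effect=percent_change(float(b.mean()), float(p_.mean())),
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def summarize_cohort(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Mean ± SEM per region (and condition, if present).

    *table* is long-format with columns ``subject``, ``region``, optionally
    ``condition``, and the value column.  SEM = SD/√n (ddof = 1); with a
    single subject it is undefined and reported as NaN.
    """
    if len(table) < 1:
        raise ParameterError("cannot summarize an empty table")
    keys = [c for c in ("region", "condition") if c in table.columns]
    if not keys:
        raise ParameterError("table must have a 'region' column")

    def _agg(grp):
        vals = grp[value_col].to_numpy(dtype=float)
        n = vals.size
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return pd.Series({"mean": float(vals.mean()), "sem": sem, "n": n})

    out = table.groupby(keys, sort=True).apply(_agg, include_groups=False).reset_index()
    out["n"] = out["n"].astype(int)
    return out
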