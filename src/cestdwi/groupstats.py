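"""Group comparisons: one-way ANOVA with Tukey HSD post hoc and star labels.

The marshaling (group means, pooled within-group variance, Tukey-Kramer q
statistics for unequal cell sizes) and the star assignment are owned here;
only the F and studentized-range distribution functions are delegated to
scipy. Star boundaries are strict: *** p < 0.001, ** p < 0.01, * p < 0.05,
else ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range

__all__ = ["ComparisonResult", "anova_tukey", "stars"]


@dataclass
class ComparisonResult:
    measure: str
    levels: list[str]
    anova_F: float
    anova_p: float
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    # pairs columns: level_a, level_b, meandiff, p_tukey, stars


def stars(p: float) -> str:
    """Significance annotation with strict threshold inequalities."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_tukey(
    values: np.ndarray | pd.Series,
    levels: np.ndarray | pd.Series,
    measure: str = "value",
    alpha: float = 0.05,
) -> ComparisonResult:
    """One-way ANOVA over the given factor levels plus all-pairs Tukey HSD.

    Levels with fewer than 2 observations are excluded with a warning; at
    least two usable levels are required.
    """
    values = np.asarray(values, dtype=float)
    levels = np.asarray(levels).astype(str)
    if values.shape != levels.shape:
        raise ValueError("values and levels must align")
    keep_levels = []
    groups = []
    for lev in pd.unique(levels):
        v = values[levels == lev]
        if v.size < 2:
            warnings.warn(f"level {lev!r} has <2 observations; excluded")
            continue
        keep_levels.append(lev)
        groups.append(v)
    if len(groups) < 2:
        raise ValueError("need at least two levels with >=2 observations")
    F, p = sps.f_oneway(*groups)
    k = len(groups)
    ns = np.array([g.size for g in groups])
    means = np.array([g.mean() for g in groups])
    dof = int(ns.sum() - k)
    mse = sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / dof
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            if mse == 0:
                p_pair = 1.0 if diff == 0 else 0.0
            else:
                # Tukey-Kramer standard error for unequal cell sizes
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p_pair = float(np.clip(studentized_range.sf(q, k, dof), 0, 1))
            rows.append({"level_a": keep_levels[i], "level_b": keep_levels[j],
                         "meandiff": diff, "p_tukey": p_pair,
                         "stars": stars(p_pair)})
    pairs = pd.DataFrame(rows)
    return ComparisonResult(measure=measure, levels=list(keep_levels),
                            anova_F=float(F), anova_p=float(p), pairs=pairs)
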