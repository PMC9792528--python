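"""Textbook test statistics used by the cohort analysis.

Implements the two-tailed paired Student's t-test and one-way ANOVA with
Tukey's HSD post-hoc comparisons from their defining formulas (p-values via
scipy's t, F and studentized-range distributions).  Results carry the
conventional star annotation at the 0.05 / 0.01 / 0.001 levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "significance_stars",
    "paired_t_test",
    "one_way_anova_tukey",
]

_STAR_LEVELS = (0.05, 0.01, 0.001)


def significance_stars(p: float) -> str:
    """'' / '*' / '**' / '***' at thresholds 0.05, 0.01 and 0.001."""
    return "*" * sum(p < a for a in _STAR_LEVELS)


@dataclass(frozen=True)
class GroupComparison:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    df: tuple[float, ...]
    stars: str = field(init=False)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        object.__setattr__(self, "stars", significance_stars(self.p_value))


def paired_t_test(x, y, labels: tuple[str, str] = ("x", "y")) -> GroupComparison:
    """Two-tailed paired Student's t-test.

    t = mean(d) / (sd(d) / sqrt(n)) with d = x - y and df = n - 1.  If every
    difference is zero the statistic is defined as 0 with p = 1 and the
    result flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if np.all(d == 0):
            return GroupComparison("paired t", labels, 0.0, 1.0, (n - 1,), degenerate=True)
        # identical nonzero differences: infinite t, p -> 0
        return GroupComparison(
            "paired t", labels, float(np.sign(d.mean()) * np.inf), 0.0, (n - 1,),
            degenerate=True,
        )
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return GroupComparison("paired t", labels, t, p, (n - 1,))


def one_way_anova_tukey(
    groups: dict[str, "np.ndarray"],
) -> tuple[GroupComparison, list[GroupComparison]]:
    """One-way ANOVA F-test followed by Tukey's HSD pairwise comparisons.

    F partitions the total sum of squares into between- and within-group
    components; each Tukey comparison uses the studentized-range statistic
    q_ij = |mean_i - mean_j| / sqrt(MSW / 2 * (1/n_i + 1/n_j)) with k groups
    and N - k error degrees of freedom (the Tukey-Kramer form for unequal
    group sizes).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    data = [np.asarray(groups[g], dtype=float) for g in names]
    ns = np.array([len(a) for a in data])
    if np.any(ns < 2):
        raise ValueError("every group needs at least 2 observations")
    k = len(names)
    N = int(ns.sum())
    means = np.array([a.mean() for a in data])
    grand = float(np.concatenate(data).mean())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((a - m) ** 2) for a, m in zip(data, means)))
    dfb, dfw = k - 1, N - k
    msw = ssw / dfw
    degenerate = msw == 0.0
    if degenerate:
        f_stat, p = (0.0, 1.0) if ssb == 0.0 else (np.inf, 0.0)
    else:
        f_stat = (ssb / dfb) / msw
        p = float(sps.f.sf(f_stat, dfb, dfw))
    anova = GroupComparison(
        "one-way ANOVA", tuple(names), float(f_stat), p, (dfb, dfw),
        degenerate=degenerate,
    )

    pairwise = []
    for i in range(k):
        for j in range(i + 1, k):
            if degenerate:
                same = means[i] == means[j]
                q, pq = (0.0, 1.0) if same else (np.inf, 0.0)
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = float(abs(means[i] - means[j]) / se)
                pq = float(sps.studentized_range.sf(q, k, dfw))
            pairwise.append(
                GroupComparison(
                    "Tukey HSD", (names[i], names[j]), q, min(max(pq, 0.0), 1.0),
                    (k, dfw), degenerate=degenerate,
                )
            )
    return anova, pairwise
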