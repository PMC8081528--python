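"""Group-comparison statistics and reporting conventions.

Two groups are compared with a classical pooled-variance two-tailed
Student's t-test (unpaired by default, paired where the design is
paired); three or more groups with one-way ANOVA followed by Dunnett's
many-to-one multiple-comparison test against a shared control. Error
bars are mean +/- SD by default, with SEM as an option, and p-values map
to the usual star labels (NS for p > 0.05 through **** for p <= 1e-4).

Conventions for degenerate inputs: two zero-variance groups with equal
means give t = 0, p = 1; with unequal means the difference is infinitely
many pooled SDs, so p = 0. A paired design whose differences are a
nonzero constant has an undefined t and raises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "unpaired_t_test",
    "paired_t_test",
    "anova_dunnett",
    "stars",
    "summarize",
]

_STAR_LEVELS = ((0.05, "NS"), (0.01, "*"), (0.001, "**"), (0.0001, "***"))


def stars(p: float) -> str:
    """Map a p-value to the star label scheme.

    The legend's inequalities are strict (NS: p>0.05, *: p<0.05, ...),
    so boundary values fall to the less significant label: p exactly
    0.05 is NS, p exactly 0.01 is "*".
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    for cut, label in _STAR_LEVELS:
        if p >= cut:
            return label
    return "****"


def summarize(values: Sequence[float], mode: str = "SD") -> tuple[float, float]:
    """Mean and dispersion (sample SD with n-1 denominator, or SEM).

    A single value has an undefined dispersion, returned as NaN.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if mode not in ("SD", "SEM"):
        raise ValueError("mode must be 'SD' or 'SEM'")
    mean = float(v.mean())
    if v.size < 2:
        return mean, float("nan")
    sd = float(v.std(ddof=1))
    return mean, (sd if mode == "SD" else sd / math.sqrt(v.size))


@dataclass(frozen=True)
class GroupComparisonResult:
    """Outcome of one group comparison, ready for tabular reporting.

    ``p_values`` holds one entry per comparison: a single entry for a
    t-test, one per non-control group for ANOVA + Dunnett (adjusted).
    ``comparisons`` names each entry as (group, control/other).
    """

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    means: tuple[float, ...]
    dispersions: tuple[float, ...]
    dispersion_mode: str
    test: str
    statistic: float
    p_values: tuple[float, ...]
    stars: tuple[str, ...]
    comparisons: tuple[tuple[str, str], ...]


def _result(groups, samples, test, statistic, p_values, comparisons, mode="SD"):
    summ = [summarize(s, mode) for s in samples]
    return GroupComparisonResult(
        groups=tuple(groups),
        n_per_group=tuple(len(s) for s in samples),
        means=tuple(m for m, _ in summ),
        dispersions=tuple(d for _, d in summ),
        dispersion_mode=mode,
        test=test,
        statistic=float(statistic),
        p_values=tuple(float(p) for p in p_values),
        stars=tuple(stars(min(max(p, 0.0), 1.0)) for p in p_values),
        comparisons=tuple(comparisons),
    )


def unpaired_t_test(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    dispersion_mode: str = "SD",
    welch: bool = False,
) -> GroupComparisonResult:
    """Two-sample two-tailed t-test, pooled-variance (classical Student).

    ``welch=True`` switches to the unequal-variance form.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if welch:
        t, p = sps.ttest_ind(a, b, equal_var=False)
    else:
        n1, n2 = a.size, b.size
        s1, s2 = a.var(ddof=1), b.var(ddof=1)
        sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
        diff = a.mean() - b.mean()
        if sp2 == 0.0:
            t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
            p = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            p = 2.0 * sps.t.sf(abs(t), n1 + n2 - 2)
    return _result(
        labels, [a, b], "unpaired_t", t, [p], [(labels[0], labels[1])], dispersion_mode
    )


def paired_t_test(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
    dispersion_mode: str = "SD",
) -> GroupComparisonResult:
    """Paired two-tailed t-test: one-sample t on the differences."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired test needs n >= 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            t, p = 0.0, 1.0
        else:
            raise ValueError(
                "zero-variance nonzero differences: paired t statistic undefined"
            )
    else:
        t = d.mean() / (sd / math.sqrt(d.size))
        p = 2.0 * sps.t.sf(abs(t), d.size - 1)
    return _result(
        labels, [a, b], "paired_t", t, [p], [(labels[0], labels[1])], dispersion_mode
    )


def anova_dunnett(
    groups: Sequence[Sequence[float]],
    control_index: int = 0,
    labels: Sequence[str] | None = None,
    dispersion_mode: str = "SD",
    seed: int = 0,
) -> GroupComparisonResult:
    """One-way ANOVA plus Dunnett's many-to-one comparisons vs the control.

    Adjusted two-sided p-values come from the multivariate-t
    distribution of the Dunnett statistics (quasi Monte Carlo
    integration, seeded for reproducibility); they are valid for
    unbalanced designs. The reported ``statistic`` is the ANOVA F.
    """
    samples = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if not (0 <= control_index < len(samples)):
        raise ValueError("control_index out of range")
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(samples))]
    labels = list(labels)

    if all(np.all(s == samples[0][0]) for s in samples):
        # identical constant data: no variance anywhere, no differences
        f = 0.0
        pvals = [1.0] * (len(samples) - 1)
    else:
        f, _ = sps.f_oneway(*samples)
        treat = [s for i, s in enumerate(samples) if i != control_index]
        res = sps.dunnett(
            *treat,
            control=samples[control_index],
            alternative="two-sided",
            rng=np.random.default_rng(seed),
        )
        pvals = list(res.pvalue)
    comparisons = [
        (labels[i], labels[control_index])
        for i in range(len(samples))
        if i != control_index
    ]
    return _result(labels, samples, "anova_dunnett", f, pvals, comparisons, dispersion_mode)
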