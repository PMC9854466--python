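"""Rank-based tests shared by the analysis modules.

All comparisons in the pipeline are non-parametric: activity magnitudes,
contact rates and subgroup counts are skewed, bounded or integer-valued, so
location differences are tested on ranks (Kruskal–Wallis across groups,
Wilcoxon signed-rank / Mann–Whitney for two samples, Spearman for
monotone association). Ties are handled by midranks throughout (scipy's
convention).

Degenerate inputs — every value identical, or every paired difference zero —
carry no evidence against the null; scipy raises on them, and here they are
mapped to ``statistic = 0, p = 1`` instead, which is the convention the rest
of the pipeline relies on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "kruskal_groups",
    "rank_test_2sample",
    "spearman_corr",
]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test or correlation.

    Attributes
    ----------
    name : str
        Which procedure produced it (e.g. ``"kruskal"``, ``"wilcoxon-paired"``).
    statistic : float
        The test statistic (H, W, U or r depending on ``name``).
    p_value : float
        Two-sided unless noted in ``extra["alternative"]``.
    n : dict
        Per-group sample sizes.
    extra : dict
        Procedure-specific fields (df, alternative, ...).
    """

    name: str
    statistic: float
    p_value: float
    n: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def _as_groups(groups) -> dict:
    if isinstance(groups, dict):
        out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        out = {f"group{i}": np.asarray(v, dtype=float) for i, v in enumerate(groups)}
    for label, vals in out.items():
        if vals.size == 0:
            raise ValueError(f"group {label!r} is empty")
        if np.isnan(vals).any():
            raise ValueError(f"group {label!r} contains NaN")
    return out


def kruskal_groups(groups) -> StatResult:
    """Kruskal–Wallis rank test across >=2 groups (2 groups allowed).

    ``groups`` is a mapping label -> values, or a sequence of arrays.
    """
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    arrays = list(gs.values())
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # no rank information at all
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.kruskal(*arrays)
    return StatResult(
        name="kruskal",
        statistic=float(stat),
        p_value=float(p),
        n={k: int(v.size) for k, v in gs.items()},
        extra={"df": len(gs) - 1},
    )


def rank_test_2sample(x, y, paired: bool, alternative: str = "two-sided") -> StatResult:
    """Two-sample rank test: Wilcoxon signed-rank if paired, Mann–Whitney U else.

    ``paired=True`` requires equal lengths (same individuals or windows on
    both sides). All-zero paired differences give ``p = 1`` by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    if paired:
        if x.size != y.size:
            raise ValueError(f"paired test with unequal lengths: {x.size} vs {y.size}")
        diffs = x - y
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(x, y, alternative=alternative, method="auto")
        name = "wilcoxon-paired"
    else:
        stat, p = sps.mannwhitneyu(x, y, alternative=alternative)
        name = "mannwhitney"
    return StatResult(
        name=name,
        statistic=float(stat),
        p_value=float(p),
        n={"x": int(x.size), "y": int(y.size)},
        extra={"alternative": alternative},
    )


def spearman_corr(x, y) -> StatResult:
    """Spearman rank correlation with two-sided p-value.

    Raises on constant input — a rank correlation is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector: rank correlation undefined")
    r, p = sps.spearmanr(x, y)
    n = int(x.size)
    # S statistic: sum of squared rank differences, the classic companion to r
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    s = float(np.sum((rx - ry) ** 2))
    return StatResult(
        name="spearman",
        statistic=float(r),
        p_value=float(p),
        n={"pairs": n},
        extra={"S": s},
    )
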