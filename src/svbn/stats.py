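"""Nonparametric group comparison: Mann-Whitney U with Bonferroni correction.

The U statistic counts, over all cross-group pairs, how often an observation
from the first group exceeds one from the second, ties counted one half —
the same quantity that, divided by ``n1 * n2``, equals the ROC AUC of the
pooled values against group membership (an identity the test suite checks
against :func:`svbn.cutoffs.roc_auc`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["GroupComparison", "StatsError", "mann_whitney_u", "bonferroni_adjust"]

#: exact permutation p-values are used when n1*n2 is at most this and the
#: pooled sample is tie-free; otherwise the normal approximation with tie
#: and continuity correction
EXACT_PRODUCT_LIMIT = 400


class StatsError(Exception):
    """Invalid input to a statistical routine."""


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples."""

    u_statistic: float
    n1: int
    n2: int
    p_value: float
    p_adjusted: float | None
    method: str  # "exact" | "normal-approximation"


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparison:
    """Two-sided Mann-Whitney U test; U counts a-over-b wins with ties 1/2.

    The exact null distribution is enumerated when ``n1 * n2 <=
    EXACT_PRODUCT_LIMIT`` and the pooled values are tie-free; otherwise the
    normal approximation with tie correction and continuity correction is
    used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == pooled.size
    use_exact = tie_free and a.size * b.size <= EXACT_PRODUCT_LIMIT
    method = "exact" if use_exact else "asymptotic"
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        u_statistic=float(res.statistic),
        n1=int(a.size),
        n2=int(b.size),
        p_value=float(min(res.pvalue, 1.0)),
        p_adjusted=None,
        method="exact" if use_exact else "normal-approximation",
    )


def bonferroni_adjust(p_values: Sequence[float]) -> list[float]:
    """Multiply each p by the family size, capping at 1; order preserved."""
    ps = list(p_values)
    m = len(ps)
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise StatsError(f"p-value {p!r} outside (0, 1]")
    return [min(1.0, m * p) for p in ps]
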