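"""Two-group distribution comparisons (two-sided Mann–Whitney).

Used to contrast C-tail properties between C_cyt and C_ext proteins among
posttranslationally inserting cohorts: C_ext tails are expected to be
shorter and less hydrophilic.  The test is exact for small, tie-free
samples and switches to the normal approximation with tie correction
otherwise.  No multiple-testing correction is applied; comparisons are
reported per panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .ctail import ORIENT_CCYT, ORIENT_CEXT, ROUTE_POST, TailProfile

EXACT_MAX_N = 8  # use the exact null when min(n) <= this and there are no ties


@dataclass
class GroupComparison:
    group_a_label: str
    group_b_label: str
    n_a: int
    n_b: int
    U_statistic: float
    p_two_sided: float
    median_a: float
    median_b: float
    direction: str  # label of the group with the larger median ("tie" if equal)
    metric: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_sided <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("both groups must be non-empty")


def mann_whitney_two_sided(
    x: Sequence[float],
    y: Sequence[float],
    label_x: str = "x",
    label_y: str = "y",
    metric: str = "",
    exact_max_n: int = EXACT_MAX_N,
) -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two samples.

    U is the rank-sum statistic of ``x`` with midrank ties.  The exact null
    distribution is used when ``min(n) <= exact_max_n`` and the pooled
    sample is tie-free; otherwise the normal approximation with tie
    correction applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = (
        "exact" if (min(x.size, y.size) <= exact_max_n and not has_ties)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    med_x, med_y = float(np.median(x)), float(np.median(y))
    if med_x > med_y:
        direction = label_x
    elif med_y > med_x:
        direction = label_y
    else:
        direction = "tie"
    return GroupComparison(
        group_a_label=label_x,
        group_b_label=label_y,
        n_a=int(x.size),
        n_b=int(y.size),
        U_statistic=float(res.statistic),
        p_two_sided=float(min(res.pvalue, 1.0)),
        median_a=med_x,
        median_b=med_y,
        direction=direction,
        metric=metric,
    )


_METRICS = {
    "tail_len": lambda p: p.tail_len,
    "tail_dg": lambda p: p.tail_dg,
    "penultimate_loop_dg": lambda p: p.penultimate_loop_dg,
    "n_tail_dg": lambda p: p.n_tail_dg,
}


def compare_by_orientation(
    profiles: Iterable[TailProfile], metric: str = "tail_dg"
) -> GroupComparison:
    """Compare a C-tail metric between C_cyt and C_ext posttranslational proteins.

    Restricts to ``route == posttranslational``, splits by orientation and
    runs the two-sided Mann–Whitney test.  Raises ``ValueError`` naming the
    empty group when one orientation is absent.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    get = _METRICS[metric]
    post = [p for p in profiles if p.route == ROUTE_POST]
    ccyt = [get(p) for p in post if p.orientation == ORIENT_CCYT]
    cext = [get(p) for p in post if p.orientation == ORIENT_CEXT]
    for label, vals in ((ORIENT_CCYT, ccyt), (ORIENT_CEXT, cext)):
        if not vals:
            raise ValueError(
                f"no posttranslational proteins in group {label}; "
                "cannot compare orientations"
            )
    return mann_whitney_two_sided(
        ccyt, cext, label_x=ORIENT_CCYT, label_y=ORIENT_CEXT, metric=metric
    )
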