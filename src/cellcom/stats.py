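"""Group comparison statistics: two-sided Mann–Whitney U with the
significance-star convention used throughout the reporting.

The exact null distribution is used for small samples without ties
(combined n <= 30); otherwise the normal approximation with continuity
and tie correction.  No multiple-testing correction is applied by
default; Benjamini–Hochberg can be switched on where many comparisons
are reported together.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .model import DomainError, StudyGroup

#: Star ladder: (threshold, label); p >= 0.05 renders as "-".
STAR_THRESHOLDS = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


def significance_stars(p: float) -> str:
    """Map a p-value to its significance stars ('-' if not significant)."""
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"p-value out of range: {p}")
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "-"


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    metric: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    stars: str
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p-value out of range: {self.p_value}")


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    *,
    metric: str = "",
    name_a: str = "a",
    name_b: str = "b",
) -> ComparisonResult:
    """Two-sided Mann–Whitney U comparison of two groups of metric values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DomainError(
            f"each group needs >= 2 values (got {a.size} and {b.size})"
        )
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 30 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(
        group_a=name_a,
        group_b=name_b,
        metric=metric,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=float(res.statistic),
        p_value=p,
        stars=significance_stars(p),
        method=method,
    )


def random_split_control(
    group: StudyGroup, seed: int | np.random.SeedSequence
) -> dict[str, ComparisonResult]:
    """Randomly halve a group and compare the halves on both metrics.

    A homogeneous group should come out non-significant at roughly the
    nominal rate; the split is deterministic for a given seed.
    """
    from .metrics import metric_values

    if len(group) < 4:
        raise DomainError("random_split_control needs >= 4 cells")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(group))
    half = len(group) // 2
    ga = StudyGroup(f"{group.name}/split-a", [group.cells[i] for i in order[:half]])
    gb = StudyGroup(f"{group.name}/split-b", [group.cells[i] for i in order[half:]])
    return {
        metric: compare_groups(
            metric_values(ga, metric),
            metric_values(gb, metric),
            metric=metric,
            name_a=ga.name,
            name_b=gb.name,
        )
        for metric in ("reference", "spread")
    }


def adjust_benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional reporting aid)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
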