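"""Male gonad morphometry: proportion-of-body statistics by age group.

Virgin males are measured (body length and gonad length, µm) at intervals
after emergence from the root; the statistic of interest is the gonad length
as a percentage of body length, which declines with age.  Groups are
compared pairwise with the exact Mann–Whitney test and annotated with a
compact letter display; per-group distributions are summarised as box plots
with 1.5×IQR whiskers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import (
    BoxSummary,
    GroupComparison,
    LetterAssignment,
    box_summary,
    compact_letter_display,
    mann_whitney_u,
)

__all__ = [
    "MorphometryRecord",
    "GroupAnalysis",
    "gonad_proportion",
    "analyze_groups",
    "records_to_frame",
]

METRICS = ("proportion", "body_length", "gonad_length")


@dataclass(frozen=True)
class MorphometryRecord:
    """One worm: age group (days post-emergence) and lengths in µm."""

    worm_id: str
    dpe_group: str
    body_length_um: float
    gonad_length_um: float

    def __post_init__(self) -> None:
        if not self.dpe_group:
            raise ValueError("dpe_group label must be non-empty")
        if not (0.0 < self.gonad_length_um <= self.body_length_um):
            raise ValueError(
                f"worm {self.worm_id!r}: need 0 < gonad ({self.gonad_length_um}) "
                f"<= body ({self.body_length_um})"
            )


def gonad_proportion(rec: MorphometryRecord) -> float:
    """Gonad length as a percentage of body length."""
    return 100.0 * rec.gonad_length_um / rec.body_length_um


@dataclass(frozen=True)
class GroupAnalysis:
    metric: str
    alpha: float
    groups: tuple[str, ...]
    n_per_group: dict[str, int]
    summaries: dict[str, BoxSummary]
    pairwise_p: pd.DataFrame
    comparisons: dict[tuple[str, str], GroupComparison]
    letters: LetterAssignment


def _metric_values(records: Sequence[MorphometryRecord], metric: str) -> dict[str, np.ndarray]:
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    getter = {
        "proportion": gonad_proportion,
        "body_length": lambda r: r.body_length_um,
        "gonad_length": lambda r: r.gonad_length_um,
    }[metric]
    by_group: dict[str, list[float]] = {}
    for r in records:  # preserves first-appearance group order
        by_group.setdefault(r.dpe_group, []).append(getter(r))
    return {g: np.array(v) for g, v in by_group.items()}


def analyze_groups(
    records: Sequence[MorphometryRecord],
    metric: str = "proportion",
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> GroupAnalysis:
    """Per-group box summaries, exact pairwise Mann–Whitney p-values, and
    letter groups for the chosen metric.

    Groups with fewer than 2 records are excluded with a warning.  Letters
    use raw p-values by default; ``bonferroni=True`` multiplies each pairwise
    p by the number of pairs before lettering.
    """
    values = _metric_values(records, metric)
    dropped = [g for g, v in values.items() if v.size < 2]
    if dropped:
        warnings.warn(f"groups excluded with < 2 records: {dropped}")
        values = {g: v for g, v in values.items() if v.size >= 2}
    groups = tuple(values)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with >= 2 records each")

    k = len(groups)
    pmat = np.ones((k, k))
    comparisons: dict[tuple[str, str], GroupComparison] = {}
    for i in range(k):
        for j in range(i + 1, k):
            cmp = mann_whitney_u(values[groups[i]], values[groups[j]])
            comparisons[(groups[i], groups[j])] = cmp
            pmat[i, j] = pmat[j, i] = cmp.p_value
    n_pairs = k * (k - 1) // 2
    letter_p = np.minimum(pmat * n_pairs, 1.0) if bonferroni else pmat
    letters = compact_letter_display(letter_p, alpha=alpha, labels=groups)
    return GroupAnalysis(
        metric=metric,
        alpha=alpha,
        groups=groups,
        n_per_group={g: int(values[g].size) for g in groups},
        summaries={g: box_summary(values[g]) for g in groups},
        pairwise_p=pd.DataFrame(pmat, index=groups, columns=groups),
        comparisons=comparisons,
        letters=letters,
    )


def records_to_frame(records: Sequence[MorphometryRecord]) -> pd.DataFrame:
    """Long-format table with the derived proportion column."""
    return pd.DataFrame(
        {
            "worm_id": [r.worm_id for r in records],
            "dpe_group": [r.dpe_group for r in records],
            "body_length_um": [r.body_length_um for r in records],
            "gonad_length_um": [r.gonad_length_um for r in records],
            "proportion_pct": [gonad_proportion(r) for r in records],
        }
    )
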