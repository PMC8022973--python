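"""Nonparametric statistics shared by the quantification pipelines.

The central piece is a Mann–Whitney *U* test whose small-sample path is the
full permutation null: every assignment of the pooled observations into two
groups of the observed sizes is considered, with midranks for ties.  Larger
samples fall back to the normal approximation with tie and continuity
corrections.  On top of it sit a compact letter display (the lowercase-letter
annotation used on grouped box plots) and Tukey-style box-plot summaries with
1.5×IQR whiskers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "LetterAssignment",
    "BoxSummary",
    "mann_whitney_u",
    "compact_letter_display",
    "box_summary",
]

#: switch to the normal approximation above this pooled sample size
EXACT_MAX_N = 20
#: and above this many distinct group assignments
EXACT_MAX_ARRANGEMENTS = 1_000_000

_EPS = 1e-9  # half-integer U comparisons under midranks


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group Mann–Whitney comparison.

    ``u_statistic`` counts rank wins for the first sample ``x`` (pairs where
    x beats y, plus half for ties), so 0 ≤ U ≤ n1·n2.  ``fold_change`` is the
    ratio of arithmetic means mean(x)/mean(y), or None when the denominator
    is zero.
    """

    u_statistic: float
    p_value: float
    n1: int
    n2: int
    method: str
    alternative: str = "two_sided"
    fold_change: float | None = None

    def __post_init__(self) -> None:
        if not (-_EPS <= self.u_statistic <= self.n1 * self.n2 + _EPS):
            raise ValueError("U outside [0, n1*n2]")
        if not (0.0 < self.p_value <= 1.0 + _EPS):
            raise ValueError("p-value outside (0, 1]")


@dataclass(frozen=True)
class LetterAssignment:
    """Lowercase letters per group: groups sharing no letter differ at `alpha`."""

    letters: Mapping[str, str]
    alpha: float

    def __getitem__(self, group: str) -> str:
        return self.letters[group]

    def differ(self, g1: str, g2: str) -> bool:
        """True iff the two groups share no letter (significant difference)."""
        return not (set(self.letters[g1]) & set(self.letters[g2]))


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def _validate_sample(arr, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"sample {name!r} contains non-finite values")
    return a


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Exact null counts of U over all C(n1+n2, n1) tie-free arrangements.

    Standard recurrence N(n1, n2; u) = N(n1-1, n2; u-n2) + N(n1, n2-1; u);
    identical to enumerating every arrangement, but cacheable.
    """
    # table[i][j] = counts array over u = 0..i*j
    table: list[list[np.ndarray]] = [
        [np.ones(1, dtype=float) for _ in range(n2 + 1)] for _ in range(n1 + 1)
    ]
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            out = np.zeros(i * j + 1)
            a = table[i - 1][j]  # shifted by j
            out[j : j + a.size] += a
            b = table[i][j - 1]
            out[: b.size] += b
            table[i][j] = out
    return table[n1][n2]


def _exact_tail_probs(x: np.ndarray, y: np.ndarray, u_obs: float) -> tuple[float, float]:
    """(P[U ≤ u_obs], P[U ≥ u_obs]) under the full permutation null."""
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties:
        counts = _u_null_counts(n1, n2)
        total = counts.sum()
        u_vals = np.arange(counts.size, dtype=float)
    else:
        ranks = sps.rankdata(pooled)
        idx = np.fromiter(
            itertools.chain.from_iterable(
                itertools.combinations(range(n1 + n2), n1)
            ),
            dtype=np.intp,
        ).reshape(-1, n1)
        u_vals = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
        counts = np.ones(u_vals.size)
        total = float(u_vals.size)
    p_le = counts[u_vals <= u_obs + _EPS].sum() / total
    p_ge = counts[u_vals >= u_obs - _EPS].sum() / total
    return float(p_le), float(p_ge)


def _approx_tail_probs(
    n1: int, n2: int, u_obs: float, pooled: np.ndarray
) -> tuple[float, float]:
    """Normal approximation with tie correction and 0.5 continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all observations identical
        return 1.0, 1.0
    sd = np.sqrt(var)
    p_le = float(sps.norm.cdf((u_obs + 0.5 - mu) / sd))
    p_ge = float(sps.norm.sf((u_obs - 0.5 - mu) / sd))
    return min(p_le, 1.0), min(p_ge, 1.0)


def mann_whitney_u(
    x,
    y,
    alternative: str = "two_sided",
    method: str = "auto",
) -> GroupComparison:
    """Independent two-group Mann–Whitney U test.

    Parameters
    ----------
    x, y:
        The two samples.  ``u_statistic`` counts rank wins for ``x``.
    alternative:
        ``"two_sided"`` or ``"greater"``.  ``"greater"`` tests the
        alternative that ``y`` is stochastically greater than ``x``
        (small U of ``x``), the orientation used for treated-above-control
        detection with the control passed first.
    method:
        ``"auto"`` (exact when the pooled size is at most ``EXACT_MAX_N``
        and the arrangement count at most ``EXACT_MAX_ARRANGEMENTS``),
        ``"exact"``, or ``"normal_approximation"``.

    Two-sided p is ``min(1, 2 * smaller one-sided tail)``.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    xa = _validate_sample(x, "x")
    ya = _validate_sample(y, "y")
    n1, n2 = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    if np.ptp(pooled) == 0:
        warnings.warn(
            "all values identical across both groups; p = 1", stacklevel=2
        )
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    if method == "auto":
        exact_ok = (n1 + n2) <= EXACT_MAX_N and comb(n1 + n2, n1) <= EXACT_MAX_ARRANGEMENTS
        method = "exact" if exact_ok else "normal_approximation"
    if method == "exact":
        p_le, p_ge = _exact_tail_probs(xa, ya, u_obs)
    elif method == "normal_approximation":
        p_le, p_ge = _approx_tail_probs(n1, n2, u_obs, pooled)
    else:
        raise ValueError(f"unknown method {method!r}")

    if alternative == "greater":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    p = min(1.0, max(p, np.finfo(float).tiny))

    mean_y = float(ya.mean())
    fold = float(xa.mean()) / mean_y if mean_y != 0 else None
    return GroupComparison(
        u_statistic=u_obs,
        p_value=p,
        n1=n1,
        n2=n2,
        method=method,
        alternative=alternative,
        fold_change=fold,
    )


def _as_p_matrix(pairwise_p, labels: Sequence[str] | None):
    """Coerce to (k×k ndarray, labels), validating symmetry."""
    try:  # pandas DataFrame carries its own labels
        import pandas as pd

        if isinstance(pairwise_p, pd.DataFrame):
            if labels is None:
                labels = [str(c) for c in pairwise_p.columns]
            pairwise_p = pairwise_p.to_numpy(dtype=float)
    except ImportError:  # pragma: no cover
        pass
    p = np.asarray(pairwise_p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] < 2:
        raise ValueError("pairwise_p must be a square matrix over k >= 2 groups")
    k = p.shape[0]
    off = ~np.eye(k, dtype=bool)
    if np.any((p[off] < 0) | (p[off] > 1)):
        raise ValueError("off-diagonal p-values must lie in [0, 1]")
    if not np.allclose(np.where(off, p, 0.0), np.where(off, p.T, 0.0), equal_nan=True):
        raise ValueError("pairwise p-value matrix is not symmetric")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length does not match matrix size")
    return p, list(labels)


def _letter_symbols(n: int) -> list[str]:
    letters = [chr(ord("a") + i) for i in range(26)]
    while len(letters) < n:  # beyond 'z': aa, ab, ...
        m = len(letters)
        letters.append(letters[m // 26 - 1] + letters[m % 26])
    return letters[:n]


def compact_letter_display(
    pairwise_p, alpha: float = 0.05, labels: Sequence[str] | None = None
) -> LetterAssignment:
    """Assign lowercase letters to groups by insert-and-absorb.

    Start from a single letter column containing every group; for each
    significant pair (p < alpha) still sharing a column, duplicate that
    column, strike one group from each copy, and absorb columns that became
    subsets of another.  The result satisfies: two groups share a letter iff
    their pairwise p ≥ alpha.
    """
    p, labels = _as_p_matrix(pairwise_p, labels)
    k = p.shape[0]
    sig_pairs = [
        (i, j) for i in range(k) for j in range(i + 1, k) if p[i, j] < alpha
    ]
    columns: list[set[int]] = [set(range(k))]
    for i, j in sig_pairs:
        new_columns: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_columns.append(col - {i})
                new_columns.append(col - {j})
            else:
                new_columns.append(col)
        # absorption: drop any column contained in another
        columns = [
            c
            for idx, c in enumerate(new_columns)
            if not any(
                c < other or (c == other and idx > jdx)
                for jdx, other in enumerate(new_columns)
            )
        ]
    columns.sort(key=lambda c: (min(c), sorted(c)))
    symbols = _letter_symbols(len(columns))
    letters = {
        labels[g]: "".join(
            sym for sym, col in zip(symbols, columns) if g in col
        )
        for g in range(k)
    }
    return LetterAssignment(letters=letters, alpha=alpha)


def box_summary(x) -> BoxSummary:
    """Five-number box-plot summary with 1.5×IQR whiskers.

    Quartiles use linear interpolation of order statistics; whiskers extend
    to the most extreme observations within 1.5×IQR of the quartiles and
    everything beyond is listed as an outlier.
    """
    a = _validate_sample(x, "x")
    q1, med, q3 = np.percentile(a, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = a[(a >= lo) & (a <= hi)]
    # quartiles are interpolated, hence always within the data range
    lower, upper = float(inside.min()), float(inside.max())
    outliers = tuple(float(v) for v in np.sort(a[(a < lo) | (a > hi)]))
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_whisker=lower,
        upper_whisker=upper,
        outliers=outliers,
    )
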