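"""Luciferase luminescence decay kinetics.

Each plate-reader well yields an intensity time series sampled on a uniform
grid (176 s by default).  The signal is modelled as a baseline plus a single
exponentially decaying component expressed in base 2,

    Intensity(t) = a + b * 2^(c * t),

so that the decaying component halves every −1/c seconds; c < 0 for a
decaying well.  Parameters are estimated per well by damped (Levenberg–
Marquardt) least squares from the fixed starting point (a, b, c) =
(1000, 1000, −1e−4), with ±1 decade restarts on c if the first attempt does
not converge.  Treated and control half-lives are compared with the exact
Mann–Whitney test, and a per-time-point one-sided test across wells
estimates how long treated wells stay detectable above the background
luminescence of control wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .stats import GroupComparison, mann_whitney_u

__all__ = [
    "DEFAULT_START",
    "LuminescenceSeries",
    "DecayFit",
    "DetectionWindow",
    "model_intensity",
    "fit_decay",
    "half_life",
    "compare_half_lives",
    "detection_window",
    "LuminescenceDecayModel",
]

#: published nls starting point (a, b, c); time in seconds
DEFAULT_START: tuple[float, float, float] = (1000.0, 1000.0, -1e-4)


@dataclass(frozen=True)
class LuminescenceSeries:
    """One well's time course; times in seconds from the first read."""

    well_id: str
    group: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.size != y.size or t.size < 4:
            raise ValueError("series needs >= 4 matched (time, intensity) points")
        if t[0] != 0.0:
            raise ValueError("times must start at 0 (seconds from first read)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(y < 0) or not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class DecayFit:
    """Per-well least-squares fit of a + b·2^(c·t)."""

    a: float
    b: float
    c: float
    half_life_s: float  # -1/c; negative when the well is not decaying
    rss: float
    converged: bool
    non_decaying: bool = False

    @property
    def usable(self) -> bool:
        """Eligible for the half-life comparison."""
        return self.converged and not self.non_decaying and np.isfinite(self.half_life_s)


@dataclass(frozen=True)
class DetectionWindow:
    """How long treated wells stay significantly above control wells.

    ``conservative_end`` ends the contiguous run of significant time points
    starting at t = 0; ``liberal_end`` is the last significant time point
    anywhere.  Both are 0 when nothing is significant.
    """

    conservative_end: float
    liberal_end: float
    alpha: float
    times: np.ndarray
    p_values: np.ndarray

    def __post_init__(self) -> None:
        if self.conservative_end > self.liberal_end:
            raise ValueError("conservative_end must not exceed liberal_end")


def model_intensity(t, a: float, b: float, c: float):
    """Evaluate a + b·2^(c·t)."""
    return a + b * np.exp2(c * np.asarray(t, dtype=float))


def _flagged_fit(a: float, b: float, c: float, rss: float) -> DecayFit:
    hl = -1.0 / c if c != 0 and np.isfinite(c) else np.nan
    return DecayFit(a=a, b=b, c=c, half_life_s=hl, rss=rss, converged=False,
                    non_decaying=bool(np.isfinite(c) and c > 0))


def fit_decay(
    series: LuminescenceSeries,
    start: tuple[float, float, float] = DEFAULT_START,
) -> DecayFit:
    """Least-squares fit of the decay model to one well.

    Non-convergent or degenerate series (e.g. constant wells, where c is
    unidentifiable) come back with ``converged=False`` rather than raising.
    Wells fitted with c > 0 are flagged ``non_decaying``.
    """
    t = series.times
    y = series.intensities
    scale = max(float(np.abs(y).max()), 1.0)
    if np.ptp(y) == 0.0:  # constant series: b = 0 true, c unidentifiable
        a = float(y[0])
        return _flagged_fit(a, 0.0, np.nan, 0.0)

    def residual(p: np.ndarray) -> np.ndarray:
        return model_intensity(t, *p) - y

    best = None
    for c_factor in (1.0, 10.0, 0.1):
        p0 = np.array([start[0], start[1], start[2] * c_factor], dtype=float)
        try:
            res = least_squares(residual, p0, method="lm", ftol=1e-10, xtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        if res.success and np.all(np.isfinite(res.x)):
            best = res
            break
    if best is None or not np.all(np.isfinite(best.x)):
        return _flagged_fit(*map(float, start), rss=float(np.inf))
    a, b, c = map(float, best.x)
    rss = float(2.0 * best.cost)
    converged = bool(best.success)
    if abs(b) <= 1e-10 * scale or c == 0.0:  # amplitude vanished: c unidentifiable
        return _flagged_fit(a, b, np.nan, rss)
    hl = -1.0 / c
    fit = DecayFit(a=a, b=b, c=c, half_life_s=hl, rss=rss,
                   converged=converged, non_decaying=c > 0)
    if fit.non_decaying:
        warnings.warn(f"well {series.well_id!r}: fitted c > 0 (non-decaying)")
    return fit


def half_life(fit: DecayFit) -> float:
    """−1/c in seconds; NaN when c is 0/undefined, negative when c > 0."""
    if fit.c == 0 or not np.isfinite(fit.c):
        warnings.warn("half-life undefined for c = 0")
        return np.nan
    return -1.0 / fit.c


def compare_half_lives(
    treated_fits: Sequence[DecayFit], control_fits: Sequence[DecayFit]
) -> GroupComparison:
    """Two-sided Mann–Whitney on usable per-well half-lives.

    Non-converged or non-decaying wells are excluded (with a warning); the
    returned group sizes count the wells actually used.
    """

    def usable(fits, label):
        hl = [f.half_life_s for f in fits if f.usable]
        dropped = len(fits) - len(hl)
        if dropped:
            warnings.warn(f"{dropped} {label} well(s) excluded from half-life comparison")
        return hl

    t = usable(treated_fits, "treated")
    c = usable(control_fits, "control")
    if len(t) < 2 or len(c) < 2:
        raise ValueError("need >= 2 usable fits per group for the half-life comparison")
    return mann_whitney_u(t, c, alternative="two_sided")


def detection_window(
    treated: Sequence[LuminescenceSeries],
    control: Sequence[LuminescenceSeries],
    alpha: float = 0.05,
) -> DetectionWindow:
    """Per-time-point one-sided Mann–Whitney (treated > control) across wells.

    Returns the end of the initial contiguous run of significance from t = 0
    (conservative) and the last significant time point anywhere (liberal).
    """
    if len(treated) < 3 or len(control) < 3:
        raise ValueError("detection window needs >= 3 wells per group")
    grid = treated[0].times
    for s in list(treated) + list(control):
        if not np.array_equal(s.times, grid):
            raise ValueError(f"well {s.well_id!r} is not on the shared time grid")
    t_mat = np.stack([s.intensities for s in treated])  # wells × times
    c_mat = np.stack([s.intensities for s in control])
    p = np.array(
        [
            mann_whitney_u(c_mat[:, k], t_mat[:, k], alternative="greater").p_value
            for k in range(grid.size)
        ]
    )
    sig = p < alpha
    if not sig.any():
        return DetectionWindow(0.0, 0.0, alpha, grid, p)
    liberal = float(grid[np.nonzero(sig)[0][-1]])
    if sig[0]:
        first_gap = np.argmin(sig)  # index of first False, or 0 if all True
        end_idx = grid.size - 1 if sig.all() else first_gap - 1
        conservative = float(grid[end_idx])
    else:
        conservative = 0.0
    return DetectionWindow(conservative, liberal, alpha, grid, p)


class LuminescenceDecayModel(BaseEstimator, RegressorMixin):
    """sklearn-style regressor for the baseline-plus-2^(c·t) decay model.

    ``fit(X, y)`` takes times in seconds (1-D or a single column) and
    intensities; fitted attributes are ``a_``, ``b_``, ``c_``,
    ``half_life_s_``, ``rss_``, ``converged_``, ``non_decaying_``.
    """

    def __init__(
        self,
        start_a: float = DEFAULT_START[0],
        start_b: float = DEFAULT_START[1],
        start_c: float = DEFAULT_START[2],
    ):
        self.start_a = start_a
        self.start_b = start_b
        self.start_c = start_c

    @staticmethod
    def _times(X) -> np.ndarray:
        t = np.asarray(X, dtype=float)
        if t.ndim == 2 and t.shape[1] == 1:
            t = t[:, 0]
        if t.ndim != 1:
            raise ValueError("X must be 1-D times or a single column")
        return t

    def fit(self, X, y) -> "LuminescenceDecayModel":
        t = self._times(X)
        series = LuminescenceSeries("", "", t, np.asarray(y, dtype=float))
        f = fit_decay(series, start=(self.start_a, self.start_b, self.start_c))
        self.fit_ = f
        self.a_, self.b_, self.c_ = f.a, f.b, f.c
        self.half_life_s_ = f.half_life_s
        self.rss_ = f.rss
        self.converged_ = f.converged
        self.non_decaying_ = f.non_decaying
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "fit_"):
            raise ValueError("LuminescenceDecayModel is not fitted")
        return np.asarray(model_intensity(self._times(X), self.a_, self.b_, self.c_))
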