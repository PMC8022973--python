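"""Shared fixtures and independent brute-force oracles.

The oracles deliberately re-derive results from first principles (pair
counting, explicit enumeration, per-pixel Python loops) so they share no
code path with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


# ---------------------------------------------------------------- Mann-Whitney


def _pair_u(xs, ys) -> float:
    """U for xs by direct pair counting (wins + half-ties)."""
    u = 0.0
    for a in xs:
        for b in ys:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def mwu_enumeration_oracle(x, y, alternative="two_sided"):
    """(U, p) by literal enumeration of every group assignment."""
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y
    u_obs = _pair_u(x, y)
    le = ge = total = 0
    idx_all = set(range(len(pooled)))
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx_all - set(comb)]
        u = _pair_u(xs, ys)
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    if alternative == "greater":
        p = le / total
    else:
        p = min(1.0, 2.0 * min(le, ge) / total)
    return u_obs, p


# ------------------------------------------------------------ pixel pipeline


def brute_force_score(img, box, cfg) -> int:
    """Pure-Python per-pixel re-implementation of the scoring pipeline.

    crop -> invert -> brightness -> contrast -> intensity (round half away
    from zero + clamp after each stage) -> strict threshold count.
    """

    def clamp(v):
        return min(255.0, max(0.0, v))

    def rha(v):
        return math.copysign(math.floor(abs(v) + 0.5), v)

    count = 0
    for r in range(box.y0, box.y1):
        for c in range(box.x0, box.x1):
            p = 255.0 - float(img[r, c])
            p = clamp(rha(p + 255.0 * cfg.brightness_pct / 100.0))
            p = clamp(rha(127.5 + (p - 127.5) * (1.0 + cfg.contrast_pct / 100.0)))
            p = clamp(rha(p * (1.0 + cfg.intensity_pct / 100.0)))
            if abs(p - cfg.background_gray) > cfg.variance:
                count += 1
    return count


# -------------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
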