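"""Synthetic assay data with known ground truth.

Three generators emulate the statistical structure of the three readouts so
every pipeline stage can be verified end to end without micrographs or
plate-reader exports:

- worm micrographs: a dark canvas with a sinusoidal-tube worm, brighter gut
  stripe (endogenous autofluorescence), optional diffuse body-wide reporter
  increment, and Gaussian read noise — together with exact body/gut masks;
- luminescence plates: wells following a + b·2^(c·t) on the 176 s grid with
  additive Gaussian noise clamped at zero;
- morphometry tables: body length and gonad proportion drawn from truncated
  normals per age group, gonad length derived from the two.

All generators are pure functions of (parameters, seed); per-entity noise
streams are derived from (seed, stream_key, entity_index), so adding wells
or worms never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .luminescence import LuminescenceSeries, model_intensity
from .morphometry import MorphometryRecord

__all__ = [
    "ImageSimParams",
    "WormImageTruth",
    "DEFAULT_MORPHOMETRY_GROUPS",
    "generate_worm_image",
    "generate_luminescence",
    "generate_morphometry",
]


@dataclass(frozen=True)
class ImageSimParams:
    """Geometry and intensity parameters of one synthetic worm micrograph.

    Gray levels are 8-bit; ``body_level`` is the absolute body gray (its
    autofluorescence floor), the gut stripe adds ``gut_extra`` on top, and
    ``reporter_extra`` is the diffuse body-wide increment present only in
    treated worms.  The worm is a tube of width ``body_width`` around a
    sinusoidal midline.
    """

    height: int = 120
    width: int = 200
    background_level: int = 10
    body_level: int = 40
    gut_extra: int = 60
    reporter_extra: int = 0
    noise_sd: float = 3.0
    body_width: int = 14
    midline_amplitude: float = 25.0
    midline_frequency: float = 1.5  # full sine cycles across the canvas

    def __post_init__(self) -> None:
        for name in ("background_level", "body_level", "gut_extra", "reporter_extra"):
            if not 0 <= getattr(self, name) <= 255:
                raise ValueError(f"{name} outside [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.height < 3 or self.width < 3 or self.body_width < 2:
            raise ValueError("canvas/body too small")
        if self.midline_amplitude + self.body_width / 2.0 >= self.height / 2.0:
            raise ValueError("worm does not fit the canvas vertically")


@dataclass(frozen=True)
class WormImageTruth:
    image: np.ndarray
    body_mask: np.ndarray
    gut_mask: np.ndarray
    params: ImageSimParams
    seed: int

    def __post_init__(self) -> None:
        if self.body_mask.shape != self.image.shape or self.gut_mask.shape != self.image.shape:
            raise ValueError("masks must match the image shape")
        if np.any(self.gut_mask & ~self.body_mask):
            raise ValueError("gut mask must be a subset of the body mask")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def midline_y(params: ImageSimParams, phase: float, cols: np.ndarray) -> np.ndarray:
    """Row coordinate of the worm midline per column."""
    h, w = params.height, params.width
    x = cols / max(w - 1, 1)
    return (h - 1) / 2.0 + params.midline_amplitude * np.sin(
        2.0 * np.pi * params.midline_frequency * x + phase
    )


def generate_worm_image(
    params: ImageSimParams = ImageSimParams(), seed: int = 0, stream_key: int = 0
) -> WormImageTruth:
    """One synthetic worm micrograph with exact ground-truth masks.

    The worm body is the set of pixels within ``body_width/2`` rows of the
    sinusoidal midline (random phase); the gut is the central stripe within
    half that distance.  Pixel values are level sums plus rounded, clamped
    Gaussian noise.  Deterministic given (params, seed, stream_key).
    """
    rng = _rng(seed, stream_key)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    rows = np.arange(params.height)[:, None]
    cols = np.arange(params.width)[None, :]
    mid = midline_y(params, phase, cols.astype(float))
    dist = np.abs(rows - mid)
    body_mask = dist <= params.body_width / 2.0
    gut_mask = dist <= params.body_width / 4.0

    img = np.full((params.height, params.width), float(params.background_level))
    img[body_mask] = params.body_level + params.reporter_extra
    img[gut_mask] += params.gut_extra
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return WormImageTruth(img, body_mask, gut_mask, params, seed)


def generate_luminescence(
    a: float = 1000.0,
    b: float = 1000.0,
    c: float = -1e-4,
    noise_sd: float = 40.0,
    interval_s: float = 176.0,
    duration_h: float = 48.84,
    n_wells: int = 8,
    group_label: str = "treated",
    seed: int = 0,
    stream_key: int = 0,
) -> list[LuminescenceSeries]:
    """Plate-reader wells following a + b·2^(c·t) plus Gaussian noise.

    Times run 0, interval, … up to the duration (the defaults give 1000
    reads per well).  Noise is independent per well, drawn from the
    (seed, stream_key, well_index) stream, and intensities are clamped at 0.
    """
    if interval_s <= 0 or duration_h <= 0:
        raise ValueError("interval and duration must be positive")
    n_points = int(np.floor(duration_h * 3600.0 / interval_s)) + 1
    times = np.arange(n_points) * interval_s
    clean = model_intensity(times, a, b, c)
    wells = []
    for i in range(n_wells):
        rng = _rng(seed, stream_key, i)
        y = clean + rng.normal(0.0, noise_sd, size=times.size) if noise_sd > 0 else clean.copy()
        wells.append(
            LuminescenceSeries(
                well_id=f"{group_label}-{i + 1:02d}",
                group=group_label,
                times=times,
                intensities=np.maximum(y, 0.0),
            )
        )
    return wells


@dataclass(frozen=True)
class MorphometryGroupSpec:
    label: str
    mean_body_um: float
    sd_body_um: float
    mean_proportion_pct: float
    sd_proportion_pct: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 < self.mean_proportion_pct < 100.0:
            raise ValueError("mean proportion must lie in (0, 100)")


#: Default age-group structure: the proportion statistic falls 65 → 55 → 45 %
#: (sd 5) across 0–1, 2–3 and 5–6 days post-emergence at n = 8 per group; the
#: 2–3 dpe centre (55 %) is an interpolation, not a measured value.  Body
#: lengths drift upward modestly against a large between-animal sd, so the
#: individual body- and gonad-length contrasts stay mostly sub-threshold at
#: these group sizes while the proportion contrast is overwhelming.
DEFAULT_MORPHOMETRY_GROUPS: tuple[MorphometryGroupSpec, ...] = (
    MorphometryGroupSpec("0-1", 1050.0, 300.0, 65.0, 5.0, 8),
    MorphometryGroupSpec("2-3", 1150.0, 300.0, 55.0, 5.0, 8),
    MorphometryGroupSpec("5-6", 1250.0, 300.0, 45.0, 5.0, 8),
)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) restricted to (low, high] by redrawing."""
    if sd == 0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    for _ in range(1000):
        bad = (out <= low) | (out > high)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("truncated normal rejection sampling did not terminate")


def generate_morphometry(
    group_specs: Sequence[MorphometryGroupSpec] | None = None,
    seed: int = 0,
) -> list[MorphometryRecord]:
    """Per-worm morphometry records from per-group truncated normals.

    Body length ~ N(mean_body, sd_body) truncated > 0; proportion ~
    N(mean_prop, sd_prop) truncated to (0, 100]; gonad length is their
    product / 100.  Each group draws from its own (seed, group_index)
    stream.
    """
    specs = tuple(group_specs) if group_specs is not None else DEFAULT_MORPHOMETRY_GROUPS
    records: list[MorphometryRecord] = []
    for gi, spec in enumerate(specs):
        for wi in range(spec.n):  # one stream per worm: growing n leaves earlier worms intact
            rng = _rng(seed, gi, wi)
            body = _truncated_normal(rng, spec.mean_body_um, spec.sd_body_um, 0.0, np.inf, 1)[0]
            prop = _truncated_normal(
                rng, spec.mean_proportion_pct, spec.sd_proportion_pct, 0.0, 100.0, 1
            )[0]
            records.append(
                MorphometryRecord(
                    worm_id=f"{spec.label}-{wi + 1:02d}",
                    dpe_group=spec.label,
                    body_length_um=float(body),
                    gonad_length_um=float(body * prop / 100.0),
                )
            )
    return records
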