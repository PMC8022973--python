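"""Pixel-threshold scoring of per-worm fluorescence micrographs.

Reporter expression in soaked juveniles is read out from single 2-D
grayscale confocal sections, one per worm.  Each worm is cropped, the image
inverted (fluorescence becomes dark-on-light), brightness/contrast/intensity
adjusted with fixed percentages, and the score is the number of pixels whose
gray value deviates from a reference background gray by strictly more than a
"shade variance" tolerance.  Because endogenous gut autofluorescence is
present in every animal, the variance threshold is calibrated on control
worms so that their bright-pixel fraction is negligible; reporter signal
spread through the body then shows up as counted pixels outside the gut.

Defaults follow the published protocol: brightness −17%, contrast +71%,
intensity −27%, background gray 0xD1 (209).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .stats import GroupComparison, mann_whitney_u

__all__ = [
    "BoundingBox",
    "QuantConfig",
    "FluorescenceScore",
    "as_gray_image",
    "crop",
    "invert",
    "adjust_bci",
    "estimate_background",
    "count_bright_pixels",
    "score_worm",
    "calibrate_variance",
    "compare_fluorescence",
    "FluorescenceScorer",
]

MID_GRAY = 127.5  # pivot of the linear contrast stage


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [x0, x1) × [y0, y1), origin top-left, 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate bounding box {self}")
        if min(self.x0, self.y0) < 0:
            raise ValueError(f"negative bounding-box corner {self}")

    @classmethod
    def full(cls, img: np.ndarray) -> "BoundingBox":
        h, w = img.shape
        return cls(0, 0, w, h)


@dataclass(frozen=True)
class QuantConfig:
    """All scoring parameters.

    Percentages are signed; brightness adds ``255·B/100`` to every pixel,
    contrast scales about mid-gray by ``1 + C/100``, intensity multiplies by
    ``1 + I/100``.  ``background_gray`` is the reference gray value and
    ``variance`` the integer tolerance around it (pixels deviating strictly
    more are counted).
    """

    brightness_pct: float = -17.0
    contrast_pct: float = 71.0
    intensity_pct: float = -27.0
    background_gray: int = 0xD1  # 209
    variance: int = 40

    def __post_init__(self) -> None:
        for name in ("brightness_pct", "contrast_pct", "intensity_pct"):
            v = getattr(self, name)
            if not -100.0 <= v <= 500.0:
                raise ValueError(f"{name}={v} outside [-100, 500]")
        if not 0 <= int(self.background_gray) <= 255:
            raise ValueError("background_gray outside [0, 255]")
        if not 0 <= int(self.variance) <= 255:
            raise ValueError("variance outside [0, 255]")


@dataclass(frozen=True)
class FluorescenceScore:
    worm_id: str
    bright_pixel_count: int
    total_pixels: int
    config: QuantConfig

    def __post_init__(self) -> None:
        if not 0 <= self.bright_pixel_count <= self.total_pixels:
            raise ValueError("bright_pixel_count outside [0, total_pixels]")

    @property
    def bright_fraction(self) -> float:
        return self.bright_pixel_count / self.total_pixels


def as_gray_image(arr) -> np.ndarray:
    """Validate/coerce to an 8-bit single-channel image.

    Color input is collapsed by luminance averaging (with a warning); values
    must already lie in [0, 255].
    """
    a = np.asarray(arr)
    if a.ndim == 3 and a.shape[2] in (3, 4):
        warnings.warn("color image converted to grayscale by channel averaging")
        a = a[:, :, :3].mean(axis=2)
        a = np.floor(a + 0.5)
    if a.ndim != 2 or a.shape[0] < 1 or a.shape[1] < 1:
        raise ValueError("image must be a 2-D array with at least one pixel")
    if a.dtype != np.uint8:
        if np.any((a < 0) | (a > 255)) or not np.allclose(a, np.round(a)):
            raise ValueError("gray values must be integers in [0, 255]")
        a = a.astype(np.uint8)
    return a


def crop(img: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Extract the sub-image under ``box``; no resampling."""
    img = as_gray_image(img)
    h, w = img.shape
    if box.x1 > w or box.y1 > h:
        raise ValueError(f"bounding box {box} exceeds image of size {w}x{h}")
    return img[box.y0 : box.y1, box.x0 : box.x1].copy()


def invert(img: np.ndarray) -> np.ndarray:
    """Invert the grayscale: p -> 255 - p."""
    return (255 - as_gray_image(img)).astype(np.uint8)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _clamp8(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 255.0)


def adjust_bci(img: np.ndarray, cfg: QuantConfig) -> np.ndarray:
    """Apply brightness, then contrast, then intensity.

    Each stage rounds half away from zero and clamps to [0, 255] before the
    next:

    - brightness: p' = p + 255·B/100
    - contrast:   p'' = 127.5 + (p' − 127.5)·(1 + C/100)
    - intensity:  p''' = p''·(1 + I/100)
    """
    p = as_gray_image(img).astype(float)
    p = _clamp8(_round_half_away(p + 255.0 * cfg.brightness_pct / 100.0))
    p = _clamp8(_round_half_away(MID_GRAY + (p - MID_GRAY) * (1.0 + cfg.contrast_pct / 100.0)))
    p = _clamp8(_round_half_away(p * (1.0 + cfg.intensity_pct / 100.0)))
    return p.astype(np.uint8)


def estimate_background(img: np.ndarray) -> int:
    """Modal gray value of the image; ties broken toward the lighter value."""
    counts = np.bincount(as_gray_image(img).ravel(), minlength=256)
    # reversed argmax picks the largest index among maxima
    return int(255 - np.argmax(counts[::-1]))


def count_bright_pixels(img: np.ndarray, background_gray: int, variance: int) -> int:
    """Count pixels deviating from the background gray by strictly more than
    ``variance`` shades."""
    a = as_gray_image(img).astype(int)
    return int(np.count_nonzero(np.abs(a - int(background_gray)) > int(variance)))


def process_worm(img: np.ndarray, box: BoundingBox, cfg: QuantConfig) -> np.ndarray:
    """crop → invert → adjust, i.e. the image actually thresholded."""
    return adjust_bci(invert(crop(img, box)), cfg)


def score_worm(
    img: np.ndarray,
    box: BoundingBox | None = None,
    cfg: QuantConfig = QuantConfig(),
    worm_id: str = "",
) -> FluorescenceScore:
    """Full per-worm pipeline: crop → invert → adjust → count."""
    img = as_gray_image(img)
    if box is None:
        box = BoundingBox.full(img)
    processed = process_worm(img, box, cfg)
    n = count_bright_pixels(processed, cfg.background_gray, cfg.variance)
    return FluorescenceScore(
        worm_id=worm_id,
        bright_pixel_count=n,
        total_pixels=int(processed.size),
        config=cfg,
    )


def _deviation_survival(img: np.ndarray, background_gray: int) -> np.ndarray:
    """fraction of pixels with |p − bg| > v, for v = 0..255."""
    dev = np.abs(as_gray_image(img).astype(int) - int(background_gray))
    hist = np.bincount(dev.ravel(), minlength=257)[:257]
    exceed = hist[::-1].cumsum()[::-1]  # exceed[v] = #pixels with dev >= v
    return exceed[1:] / dev.size  # index v -> #dev > v


def calibrate_variance(
    control_images: Sequence[np.ndarray],
    background_gray: int | None = None,
    target_quantile: float = 0.5,
    target_fraction: float = 0.01,
) -> int:
    """Smallest variance v such that the ``target_quantile`` of control
    bright-pixel fractions is at most ``target_fraction``.

    ``control_images`` are *processed* (inverted + adjusted) control worms.
    With ``background_gray=None`` each image is referenced to its own modal
    gray.  Returns 255 with a warning if no v attains the target.
    """
    if len(control_images) == 0:
        raise ValueError("variance calibration requires control images")
    if len(control_images) < 3:
        warnings.warn("fewer than 3 control images; calibration may be unstable")
    fracs = np.stack(
        [
            _deviation_survival(
                im, estimate_background(im) if background_gray is None else background_gray
            )
            for im in control_images
        ]
    )  # (n_images, 256)
    q = np.quantile(fracs, target_quantile, axis=0)
    ok = np.nonzero(q <= target_fraction)[0]
    if ok.size == 0:  # unreachable for target_fraction >= 0, kept defensively
        warnings.warn("calibration target unattainable; returning variance 255")
        return 255
    return int(ok[0])


def compare_fluorescence(
    treated: Iterable[FluorescenceScore | int],
    control: Iterable[FluorescenceScore | int],
    fold_method: str = "mean",
) -> GroupComparison:
    """Treated-vs-control comparison of bright-pixel counts.

    Two-sided Mann–Whitney p; fold change is the ratio of arithmetic means
    (treated/control) by default, or of medians with ``fold_method="median"``.
    A zero-control denominator yields ``fold_change=None``.
    """

    def counts(scores) -> np.ndarray:
        return np.array(
            [s.bright_pixel_count if isinstance(s, FluorescenceScore) else s for s in scores],
            dtype=float,
        )

    t, c = counts(treated), counts(control)
    cmp = mann_whitney_u(t, c, alternative="two_sided")
    if fold_method == "median":
        denom = float(np.median(c))
        fold = float(np.median(t)) / denom if denom != 0 else None
        cmp = replace(cmp, fold_change=fold)
    elif fold_method != "mean":
        raise ValueError(f"unknown fold_method {fold_method!r}")
    if cmp.fold_change is None:
        warnings.warn("control mean is zero; fold change undefined")
    return cmp


class FluorescenceScorer(BaseEstimator, TransformerMixin):
    """Estimator wrapper for the per-worm pixel scoring pipeline.

    ``fit`` calibrates what the protocol leaves empirical — the background
    gray (modal gray of processed controls) and the shade-variance threshold
    — on a batch of control images; ``transform`` returns bright-pixel
    counts.  Set ``background_gray``/``variance`` explicitly to skip
    calibration.

    Parameters
    ----------
    brightness_pct, contrast_pct, intensity_pct : float
        Signed adjustment percentages applied after inversion.
    background_gray : int or None
        Reference gray; None means estimate from the control batch.
    variance : int or None
        Shade tolerance; None means calibrate on the control batch.
    target_quantile, target_fraction : float
        Calibration target: the quantile of control bright-pixel fractions
        pushed at or below the fraction.
    """

    def __init__(
        self,
        brightness_pct: float = -17.0,
        contrast_pct: float = 71.0,
        intensity_pct: float = -27.0,
        background_gray: int | None = None,
        variance: int | None = None,
        target_quantile: float = 0.5,
        target_fraction: float = 0.01,
    ):
        self.brightness_pct = brightness_pct
        self.contrast_pct = contrast_pct
        self.intensity_pct = intensity_pct
        self.background_gray = background_gray
        self.variance = variance
        self.target_quantile = target_quantile
        self.target_fraction = target_fraction

    def _partial_config(self) -> QuantConfig:
        return QuantConfig(
            brightness_pct=self.brightness_pct,
            contrast_pct=self.contrast_pct,
            intensity_pct=self.intensity_pct,
            background_gray=self.background_gray if self.background_gray is not None else 0,
            variance=self.variance if self.variance is not None else 0,
        )

    def fit(self, X: Sequence[np.ndarray], y=None) -> "FluorescenceScorer":
        """Calibrate on control images (raw; inverted/adjusted internally)."""
        cfg = self._partial_config()
        if (self.background_gray is None or self.variance is None) and len(X) == 0:
            raise ValueError("calibration requires control images")
        processed = [adjust_bci(invert(as_gray_image(im)), cfg) for im in X]
        if self.background_gray is None:
            pooled = np.concatenate([p.ravel() for p in processed])
            self.background_gray_ = estimate_background(pooled.reshape(1, -1))
        else:
            self.background_gray_ = int(self.background_gray)
        if self.variance is None:
            self.variance_ = calibrate_variance(
                processed,
                background_gray=self.background_gray_,
                target_quantile=self.target_quantile,
                target_fraction=self.target_fraction,
            )
        else:
            self.variance_ = int(self.variance)
        self.config_ = replace(
            cfg, background_gray=self.background_gray_, variance=self.variance_
        )
        return self

    def transform(self, X: Sequence[np.ndarray]) -> np.ndarray:
        """Bright-pixel count per image (full-frame boxes)."""
        if not hasattr(self, "config_"):
            raise ValueError("FluorescenceScorer is not fitted")
        return np.array(
            [score_worm(im, cfg=self.config_).bright_pixel_count for im in X],
            dtype=int,
        )

    def score_records(
        self, images: Sequence[np.ndarray], boxes: Sequence[BoundingBox], ids: Sequence[str]
    ) -> list[FluorescenceScore]:
        if not hasattr(self, "config_"):
            raise ValueError("FluorescenceScorer is not fitted")
        return [
            score_worm(im, box, self.config_, worm_id=i)
            for im, box, i in zip(images, boxes, ids)
        ]
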