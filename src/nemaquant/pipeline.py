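"""End-to-end reproducible runs: simulate → quantify → compare.

``run_pipeline`` executes the three assay pipelines (fluorescence images,
luminescence plate, morphometry table) from a single ``RunConfig``, writing
every artifact plus the resolved configuration beside the outputs.  All
files are staged in a temporary directory and moved into place only when
every stage succeeded, so a failed run leaves no partial outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as nio
from .fluorescence import FluorescenceScorer, compare_fluorescence
from .luminescence import compare_half_lives, detection_window, fit_decay
from .morphometry import analyze_groups
from .simulate import (
    ImageSimParams,
    generate_luminescence,
    generate_morphometry,
    generate_worm_image,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("nemaquant")


def _default_images() -> dict:
    return {
        "n_treated": 20,
        "n_control": 20,
        "reporter_extra": 80,
        "noise_sd": 3.0,
        "target_fraction": 0.01,
    }


def _default_plate() -> dict:
    return {
        "treated": {"a": 1000.0, "b": 1000.0, "c": -1e-4},
        "control": {"a": 1000.0, "b": 200.0, "c": -3e-4},
        "noise_sd": 40.0,
        "n_wells": 8,
        "alpha": 0.05,
    }


def _default_morphometry() -> dict:
    return {"metric": "proportion", "alpha": 0.05}


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run; JSON round-trippable."""

    seed: int = 1
    outdir: str = "nemaquant-run"
    log_level: str = "INFO"
    images: dict = field(default_factory=_default_images)
    plate: dict = field(default_factory=_default_plate)
    morphometry: dict = field(default_factory=_default_morphometry)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        base = cls()
        merged = {}
        for f in dataclasses.fields(cls):
            default = getattr(base, f.name)
            value = d.get(f.name, default)
            if isinstance(default, dict) and isinstance(value, dict):
                bad = set(value) - set(default)
                if bad:
                    raise ValueError(f"unknown config key(s) under {f.name!r}: {sorted(bad)}")
                value = {**default, **value}
            merged[f.name] = value
        return cls(**merged)


def _comparison_dict(cmp) -> dict:
    return {
        "u_statistic": cmp.u_statistic,
        "p_value": cmp.p_value,
        "n1": cmp.n1,
        "n2": cmp.n2,
        "method": cmp.method,
        "fold_change": cmp.fold_change,
    }


def _stage_images(cfg: RunConfig, out: Path) -> None:
    p = cfg.images
    treated_params = ImageSimParams(reporter_extra=int(p["reporter_extra"]), noise_sd=p["noise_sd"])
    control_params = ImageSimParams(reporter_extra=0, noise_sd=p["noise_sd"])
    entries, images, groups = [], [], []
    for group, params, n, key in (
        ("treated", treated_params, int(p["n_treated"]), 0),
        ("control", control_params, int(p["n_control"]), 1),
    ):
        for i in range(n):
            truth = generate_worm_image(params, seed=cfg.seed, stream_key=key * 10_000 + i)
            fname = f"{group}_{i + 1:02d}.png"
            nio.write_image(out / "images" / fname, truth.image)
            from .fluorescence import BoundingBox

            entries.append(
                nio.ManifestEntry(
                    f"{group}-{i + 1:02d}", f"images/{fname}", group, BoundingBox.full(truth.image)
                )
            )
            images.append(truth.image)
            groups.append(group)
    nio.write_manifest(out / "manifest.csv", entries)

    controls = [im for im, g in zip(images, groups) if g == "control"]
    scorer = FluorescenceScorer(target_fraction=p["target_fraction"]).fit(controls)
    scores = scorer.score_records(
        images, [e.box for e in entries], [e.worm_id for e in entries]
    )
    nio.write_scores_csv(out / "scores.csv", scores, groups)
    cmp = compare_fluorescence(
        [s for s, g in zip(scores, groups) if g == "treated"],
        [s for s, g in zip(scores, groups) if g == "control"],
    )
    nio.write_json(
        out / "fluorescence_comparison.json",
        {
            **_comparison_dict(cmp),
            "variance": scorer.variance_,
            "background_gray": scorer.background_gray_,
        },
    )
    log.info(
        "fluorescence: fold=%.3g p=%.3g (variance=%d, background=%d)",
        cmp.fold_change, cmp.p_value, scorer.variance_, scorer.background_gray_,
    )


def _stage_plate(cfg: RunConfig, out: Path) -> None:
    p = cfg.plate
    groups = {
        "treated": generate_luminescence(
            **p["treated"], noise_sd=p["noise_sd"], n_wells=int(p["n_wells"]),
            group_label="treated", seed=cfg.seed, stream_key=0,
        ),
        "control": generate_luminescence(
            **p["control"], noise_sd=p["noise_sd"], n_wells=int(p["n_wells"]),
            group_label="control", seed=cfg.seed, stream_key=1,
        ),
    }
    series = groups["treated"] + groups["control"]
    nio.write_plate_csv(out / "plate.csv", series)
    fits = {g: [fit_decay(s) for s in ss] for g, ss in groups.items()}
    nio.write_fits_csv(
        out / "fits.csv",
        fits["treated"] + fits["control"],
        [s.well_id for s in series],
        [s.group for s in series],
    )
    cmp = compare_half_lives(fits["treated"], fits["control"])
    nio.write_json(out / "half_life_comparison.json", _comparison_dict(cmp))
    win = detection_window(groups["treated"], groups["control"], alpha=p["alpha"])
    nio.write_json(
        out / "detection_window.json",
        {
            "conservative_end_s": win.conservative_end,
            "conservative_end_h": win.conservative_end / 3600.0,
            "liberal_end_s": win.liberal_end,
            "liberal_end_h": win.liberal_end / 3600.0,
            "alpha": win.alpha,
        },
    )
    log.info(
        "luminescence: half-life p=%.3g; window conservative=%.2f h liberal=%.2f h",
        cmp.p_value, win.conservative_end / 3600.0, win.liberal_end / 3600.0,
    )


def _stage_morphometry(cfg: RunConfig, out: Path) -> None:
    p = cfg.morphometry
    records = generate_morphometry(seed=cfg.seed)
    nio.write_morphometry_csv(out / "morphometry.csv", records)
    analysis = analyze_groups(records, metric=p["metric"], alpha=p["alpha"])
    rows = []
    for g in analysis.groups:
        s = analysis.summaries[g]
        rows.append(
            {
                "group": g,
                "n": analysis.n_per_group[g],
                "median": s.median,
                "q1": s.q1,
                "q3": s.q3,
                "iqr": s.iqr,
                "lower_whisker": s.lower_whisker,
                "upper_whisker": s.upper_whisker,
                "letter": analysis.letters[g],
            }
        )
    import pandas as pd

    with nio.atomic_write(out / "morphometry_summary.csv") as fh:
        pd.DataFrame(rows).to_csv(fh, index=False)
    with nio.atomic_write(out / "morphometry_pmatrix.csv") as fh:
        analysis.pairwise_p.to_csv(fh)
    log.info(
        "morphometry (%s): letters %s",
        p["metric"], {g: analysis.letters[g] for g in analysis.groups},
    )


def run_pipeline(config: RunConfig) -> int:
    """Run all stages; returns 0 on success, raising on any stage failure.

    Outputs appear in ``config.outdir`` only if every stage succeeded.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("nemaquant run: seed=%d numpy=%s", config.seed, np.__version__)
    target = Path(config.outdir)
    target.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".nemaquant-", dir=target.parent))
    try:
        _stage_images(config, staging)
        _stage_plate(config, staging)
        _stage_morphometry(config, staging)
        nio.write_json(staging / "run_config.json", config.to_dict())
        for item in staging.iterdir():
            dest = target / item.name
            if dest.is_dir():
                shutil.rmtree(dest)
            os.replace(item, dest)
    finally:
        shutil.rmtree(staging, ignore_errors=True)
    log.info("outputs written to %s", target)
    return 0
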