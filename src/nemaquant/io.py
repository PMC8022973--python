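"""Readers and writers for the pipeline's on-disk formats.

All tables are plain CSV with fixed column orders:

- image manifest:      worm_id, file, group, x0, y0, x1, y1
- plate (long format): well, group, time_s, intensity
- morphometry:         worm_id, dpe_group, body_length_um, gonad_length_um
- per-worm scores:     worm_id, group, bright_pixel_count, total_pixels,
                       variance, background_gray
- per-well fits:       well, group, a, b, c, half_life_s, rss, converged

Images are 8-bit grayscale PNG (TIFF accepted); 16-bit input is rescaled to
8-bit with a warning.  Coordinates are 0-based and half-open.  Writers go
through a temp-file-then-rename so partial files never appear.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .fluorescence import BoundingBox, FluorescenceScore, as_gray_image
from .luminescence import DecayFit, LuminescenceSeries
from .morphometry import MorphometryRecord

__all__ = [
    "SchemaError",
    "ManifestEntry",
    "atomic_write",
    "read_image",
    "write_image",
    "read_manifest",
    "write_manifest",
    "read_plate_csv",
    "write_plate_csv",
    "read_morphometry_csv",
    "write_morphometry_csv",
    "write_scores_csv",
    "write_fits_csv",
    "write_json",
]


class SchemaError(ValueError):
    """An input table does not match the documented schema."""


@dataclass(frozen=True)
class ManifestEntry:
    worm_id: str
    file: str
    group: str
    box: BoundingBox


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image, coercing to 8-bit."""
    arr = iio.imread(path)
    if arr.dtype == np.uint16:
        warnings.warn(f"{path}: 16-bit image rescaled to 8-bit")
        arr = (arr.astype(float) / 257.0).round().astype(np.uint8)
    return as_gray_image(arr)


def write_image(path: str | Path, img: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, as_gray_image(img))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Parse and validate an image manifest."""
    df = pd.read_csv(path, dtype={"worm_id": str, "file": str, "group": str})
    _require_columns(df, ["worm_id", "file", "group", "x0", "y0", "x1", "y1"], "manifest")
    dupes = df["worm_id"][df["worm_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"manifest: duplicate worm_id(s) {sorted(set(dupes))}")
    entries = []
    for i, row in df.iterrows():
        try:
            box = BoundingBox(int(row.x0), int(row.y0), int(row.x1), int(row.y1))
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"manifest row {i} (worm {row.worm_id!r}): {exc}") from exc
        entries.append(ManifestEntry(str(row.worm_id), str(row.file), str(row.group), box))
    return entries


def write_manifest(path: str | Path, entries: Sequence[ManifestEntry]) -> None:
    df = pd.DataFrame(
        [
            {
                "worm_id": e.worm_id,
                "file": e.file,
                "group": e.group,
                "x0": e.box.x0,
                "y0": e.box.y0,
                "x1": e.box.x1,
                "y1": e.box.y1,
            }
            for e in entries
        ],
        columns=["worm_id", "file", "group", "x0", "y0", "x1", "y1"],
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def read_plate_csv(path: str | Path) -> list[LuminescenceSeries]:
    """Long-format plate file → one series per well (input row order kept)."""
    df = pd.read_csv(path, dtype={"well": str, "group": str})
    _require_columns(df, ["well", "group", "time_s", "intensity"], "plate")
    series = []
    for well, sub in df.groupby("well", sort=False):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise SchemaError(f"plate: well {well!r} maps to several groups {list(groups)}")
        series.append(
            LuminescenceSeries(
                well_id=str(well),
                group=str(groups[0]),
                times=sub["time_s"].to_numpy(float),
                intensities=sub["intensity"].to_numpy(float),
            )
        )
    return series


def write_plate_csv(path: str | Path, series: Sequence[LuminescenceSeries]) -> None:
    frames = [
        pd.DataFrame(
            {
                "well": s.well_id,
                "group": s.group,
                "time_s": s.times,
                "intensity": s.intensities,
            }
        )
        for s in series
    ]
    with atomic_write(path) as fh:
        pd.concat(frames, ignore_index=True).to_csv(fh, index=False)


def read_morphometry_csv(path: str | Path) -> list[MorphometryRecord]:
    df = pd.read_csv(path, dtype={"worm_id": str, "dpe_group": str})
    _require_columns(
        df, ["worm_id", "dpe_group", "body_length_um", "gonad_length_um"], "morphometry"
    )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                MorphometryRecord(
                    str(row.worm_id),
                    str(row.dpe_group),
                    float(row.body_length_um),
                    float(row.gonad_length_um),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"morphometry row {i}: {exc}") from exc
    return records


def write_morphometry_csv(path: str | Path, records: Sequence[MorphometryRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "worm_id": r.worm_id,
                "dpe_group": r.dpe_group,
                "body_length_um": r.body_length_um,
                "gonad_length_um": r.gonad_length_um,
            }
            for r in records
        ],
        columns=["worm_id", "dpe_group", "body_length_um", "gonad_length_um"],
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def write_scores_csv(
    path: str | Path, scores: Sequence[FluorescenceScore], groups: Sequence[str]
) -> None:
    df = pd.DataFrame(
        [
            {
                "worm_id": s.worm_id,
                "group": g,
                "bright_pixel_count": s.bright_pixel_count,
                "total_pixels": s.total_pixels,
                "variance": s.config.variance,
                "background_gray": s.config.background_gray,
            }
            for s, g in zip(scores, groups)
        ],
        columns=[
            "worm_id",
            "group",
            "bright_pixel_count",
            "total_pixels",
            "variance",
            "background_gray",
        ],
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def write_fits_csv(
    path: str | Path, fits: Sequence[DecayFit], wells: Sequence[str], groups: Sequence[str]
) -> None:
    df = pd.DataFrame(
        [
            {
                "well": w,
                "group": g,
                "a": f.a,
                "b": f.b,
                "c": f.c,
                "half_life_s": f.half_life_s,
                "rss": f.rss,
                "converged": f.converged,
            }
            for f, w, g in zip(fits, wells, groups)
        ],
        columns=["well", "group", "a", "b", "c", "half_life_s", "rss", "converged"],
    )
    with atomic_write(path) as fh:
        df.to_csv(fh, index=False)


def write_json(path: str | Path, obj) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
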