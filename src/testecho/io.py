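"""Readers and writers: cohort CSV, frame/mask PNGs, sidecar metadata, config.

Frames are stored as 8-bit grayscale PNG with masks as 0/255 single-channel
PNGs and a plain ``key: value`` sidecar; colour-Doppler overlays are RGB
PNGs in which any non-grey pixel is flow.  The cohort table is a plain CSV
with one header row; missing semen values are empty cells.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .echotexture import UltrasoundFrame
from .synthetic import COLUMNS

MASK_NAMES = ("parenchyma", "mediastinum", "capsule")

#: cohort columns that must parse as numbers (empty cell = missing)
_NUMERIC = [c for c in COLUMNS if c not in ("dog_id", "testis_side",
                                            "frame_path")]


class SchemaError(ValueError):
    """Cohort CSV does not match the documented column layout."""


@dataclasses.dataclass
class RunConfig:
    """Round-trippable run configuration for the CLI subcommands."""

    seed: int = 0
    dogs: int = 8
    weeks: tuple = tuple(range(4, 41, 2))
    image_size: int = 256
    mm_per_pixel: float = 0.15
    min_pixels: int = 4
    distinct_pixels: int = 10
    course_elongation: float = 4.0
    version: str = "0.1.0"

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["weeks"] = list(data["weeks"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "weeks" in data:
            data["weeks"] = tuple(data["weeks"])
        return cls(**data)


# ---------------------------------------------------------------------------
# cohort tables

def write_cohort(df: pd.DataFrame, path) -> None:
    """Write the cohort table as CSV; missing values become empty cells."""
    df.to_csv(path, index=False, na_rep="")


def read_cohort(path, required=COLUMNS) -> pd.DataFrame:
    """Read a cohort CSV, validating the documented header.

    Unknown extra columns are preserved untouched; a missing required
    column raises :class:`SchemaError` naming it, and non-numeric cells in
    numeric columns raise a ValueError naming the column.
    """
    df = pd.read_csv(path, dtype={"dog_id": str, "testis_side": str,
                                  "frame_path": str},
                     keep_default_na=True)
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"cohort CSV is missing column {col!r}")
    for col in _NUMERIC:
        if col in df.columns:
            try:
                df[col] = pd.to_numeric(df[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"non-numeric cell in column {col!r}") from exc
    if "frame_path" in df.columns:
        df["frame_path"] = df["frame_path"].fillna("")
    return df


# ---------------------------------------------------------------------------
# frames

def frame_stem(dog_id: str, week, side: str) -> str:
    return f"{dog_id}_w{int(week):02d}_{side}"


def write_frame(frame: UltrasoundFrame, directory, stem: Optional[str] = None,
                overlay: Optional[np.ndarray] = None, seed=None) -> Path:
    """Write pixels, masks, optional Doppler overlay, and the sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if stem is None:
        stem = frame_stem(frame.dog_id, frame.week, frame.side)
    iio.imwrite(directory / f"{stem}.png", frame.pixels)
    for name in MASK_NAMES:
        mask = frame.masks.get(name)
        if mask is not None:
            iio.imwrite(directory / f"{stem}.mask_{name}.png",
                        (mask.astype(np.uint8) * 255))
    if overlay is not None:
        rgb = np.repeat(frame.pixels[..., None], 3, axis=2)
        rgb[overlay] = (220, 40, 40)
        iio.imwrite(directory / f"{stem}.doppler.png", rgb)
    meta = {
        "mm_per_pixel": frame.mm_per_pixel, "week": frame.week,
        "dog_id": frame.dog_id, "side": frame.side,
        "seed": seed if seed is not None else "",
        "flags": ";".join(frame.flags),
    }
    lines = [f"{k}: {v}" for k, v in meta.items()]
    (directory / f"{stem}.meta.txt").write_text("\n".join(lines) + "\n")
    return directory / f"{stem}.png"


def read_frame(path) -> UltrasoundFrame:
    """Read a frame PNG plus its mask and sidecar companions."""
    path = Path(path)
    stem = path.stem
    pixels = iio.imread(path)
    if pixels.ndim == 3:
        pixels = pixels[..., 0]
    masks = {}
    for name in MASK_NAMES:
        mpath = path.with_name(f"{stem}.mask_{name}.png")
        if mpath.exists():
            masks[name] = iio.imread(mpath) > 127
    meta = {}
    mfile = path.with_name(f"{stem}.meta.txt")
    if mfile.exists():
        for line in mfile.read_text().splitlines():
            if ": " in line:
                k, v = line.split(": ", 1)
                meta[k.strip()] = v.strip()
            elif line.endswith(":"):
                meta[line[:-1].strip()] = ""
    flags = tuple(f for f in meta.get("flags", "").split(";") if f)
    return UltrasoundFrame(
        pixels=pixels.astype(np.uint8),
        mm_per_pixel=float(meta.get("mm_per_pixel", 0.15) or 0.15),
        masks=masks,
        week=float(meta["week"]) if meta.get("week") else None,
        dog_id=meta.get("dog_id") or None,
        side=meta.get("side") or None,
        flags=flags,
    )


def read_doppler_overlay(path) -> np.ndarray:
    """Boolean flow mask from an RGB overlay PNG (non-grey pixels = flow)."""
    rgb = iio.imread(path)
    if rgb.ndim == 2:
        return rgb > 127
    r, g, b = rgb[..., 0].astype(int), rgb[..., 1].astype(int), rgb[..., 2].astype(int)
    return (np.abs(r - g) + np.abs(g - b)) > 0
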