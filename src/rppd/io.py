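"""Readers, writers and overlay rendering shared by the CLI and scripts.

Coordinates in all exports are 0-based, row-major (row, col), with half-open
extents ``[top, bottom) x [left, right)`` in the slide frame.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import FocusPointRegion

TIER_COLORS: Dict[str, Tuple[int, int, int]] = {
    "red": (220, 30, 30),
    "blue": (40, 60, 220),
    "green": (30, 160, 60),
    "black": (0, 0, 0),
    "accepted": (230, 140, 0),
}

REGION_COLUMNS = [
    "partition",
    "tier",
    "density",
    "top",
    "left",
    "bottom",
    "right",
    "tissue_count",
    "background_count",
]


def read_image(path) -> np.ndarray:
    """Read a TIFF or PNG image as a uint8 array, dropping any alpha channel."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image)
    else:
        iio.imwrite(path, image)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (tissue = 255)."""
    write_image(path, (np.asarray(mask).astype(np.uint8)) * 255)


def read_mask(path) -> np.ndarray:
    img = read_image(path)
    if img.ndim == 3:
        img = img[:, :, 0]
    return img > 127


def regions_to_frame(regions: Sequence[FocusPointRegion]) -> pd.DataFrame:
    rows = [
        {
            "partition": r.partition_index,
            "tier": r.tier,
            "density": r.box.density,
            "top": r.slide_top,
            "left": r.slide_left,
            "bottom": r.slide_bottom,
            "right": r.slide_right,
            "tissue_count": r.box.tissue_count,
            "background_count": r.box.background_count,
        }
        for r in regions
    ]
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def write_regions_csv(path, regions: Sequence[FocusPointRegion]) -> None:
    regions_to_frame(regions).to_csv(path, index=False, float_format="%.6f")


def write_regions_json(path, regions: Sequence[FocusPointRegion]) -> None:
    frame = regions_to_frame(regions)
    payload = {"n_regions": int(len(frame)), "regions": frame.to_dict(orient="records")}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def render_overlay(
    image: np.ndarray,
    regions: Sequence[FocusPointRegion],
    thickness: int = 3,
) -> np.ndarray:
    """Draw tier-colored rectangle outlines over a copy of the image."""
    image = np.asarray(image)
    if image.ndim == 2:
        canvas = np.stack([image] * 3, axis=-1).astype(np.uint8)
    else:
        canvas = image.astype(np.uint8).copy()
    h, w = canvas.shape[:2]
    for region in regions:
        color = TIER_COLORS.get(region.tier, (255, 0, 255))
        t, l, b, r = region.slide_extent
        t, l = max(0, t), max(0, l)
        b, r = min(h, b), min(w, r)
        k = thickness
        canvas[t : min(b, t + k), l:r] = color
        canvas[max(t, b - k) : b, l:r] = color
        canvas[t:b, l : min(r, l + k)] = color
        canvas[t:b, max(l, r - k) : r] = color
    return canvas


def write_manifest(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
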