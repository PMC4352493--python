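"""Preprocessing: partitioning, grayscale, CLAHE and Otsu tissue segmentation.

A whole-slide thumbnail is divided into a small grid of partitions (six by
default) and each partition is segmented independently: grayscale conversion,
contrast-limited adaptive histogram equalization, then Otsu thresholding.
Per-partition thresholding matters because camera-captured thumbnails carry
uneven illumination, so no single global threshold separates stain from
background across the whole slide.  Stained tissue is dark, hence tissue =
pixels at or below the Otsu threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from skimage import color, exposure, filters

from .config import RppdConfig
from .errors import DegenerateImageError


@dataclass(frozen=True)
class Partition:
    """A rectangular sub-view of a slide with its origin in slide coordinates.

    ``index`` is the 1-based partition number in row-major order.
    """

    pixels: np.ndarray
    origin_row: int
    origin_col: int
    index: int

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def partition_image(image: np.ndarray, rows: int, cols: int) -> List[Partition]:
    """Tile ``image`` into ``rows x cols`` partitions in row-major order.

    Partitions tile the image exactly: when a dimension is not divisible the
    last partition in that dimension absorbs the remainder.  The returned
    ``pixels`` are views into the original array.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D or 3-D image, got ndim={image.ndim}")
    if rows < 1 or cols < 1:
        raise ValueError(f"rows and cols must be >= 1, got {rows}x{cols}")
    height, width = image.shape[0], image.shape[1]
    if height < rows or width < cols:
        raise ValueError(
            f"image of shape {height}x{width} cannot be split into {rows}x{cols} partitions"
        )
    row_edges = [i * (height // rows) for i in range(rows)] + [height]
    col_edges = [j * (width // cols) for j in range(cols)] + [width]
    parts: List[Partition] = []
    index = 1
    for i in range(rows):
        for j in range(cols):
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            parts.append(Partition(image[r0:r1, c0:c1], r0, c0, index))
            index += 1
    return parts


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit luminance (standard luma weighting)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image of shape (H, W, 3), got {image.shape}")
    gray = color.rgb2gray(image)  # float in [0, 1]
    return np.round(gray * 255.0).astype(np.uint8)


def clahe_equalize(
    gray: np.ndarray,
    tile_grid: Tuple[int, int] = (8, 8),
    clip_limit: float = 0.01,
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    The image is processed in ``tile_grid`` local tiles; ``clip_limit`` is the
    fraction-of-histogram clipping bound.  A constant image is returned
    unchanged (there is no contrast to enhance).
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {gray.shape}")
    t_rows, t_cols = tile_grid
    if t_rows < 1 or t_cols < 1:
        raise ValueError(f"tile grid must be >= 1x1, got {tile_grid}")
    if t_rows > gray.shape[0] or t_cols > gray.shape[1]:
        raise ValueError(
            f"tile grid {tile_grid} larger than image of shape {gray.shape}"
        )
    if gray.min() == gray.max():
        return gray.copy()
    kernel = (max(1, gray.shape[0] // t_rows), max(1, gray.shape[1] // t_cols))
    out = exposure.equalize_adapthist(gray, kernel_size=kernel, clip_limit=clip_limit)
    return np.round(out * 255.0).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> Tuple[int, np.ndarray]:
    """Otsu threshold and the dark-side (tissue) mask.

    Returns the gray level ``t`` minimizing the weighted within-class variance
    of the two classes ``gray <= t`` / ``gray > t``, together with the boolean
    tissue mask ``gray <= t`` (stained tissue is dark).
    """
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {gray.shape}")
    if gray.min() == gray.max():
        raise DegenerateImageError("constant image: no threshold separates two classes")
    thresh = filters.threshold_otsu(gray)
    mask = gray <= thresh
    return int(thresh), mask


def segment_partition(
    rgb_partition: np.ndarray,
    tile_grid: Tuple[int, int] = (8, 8),
    clip_limit: float = 0.01,
) -> np.ndarray:
    """Grayscale -> CLAHE -> Otsu for one RGB partition.

    A degenerate (constant) partition yields an all-background mask.
    """
    gray = to_grayscale(rgb_partition)
    equalized = clahe_equalize(gray, tile_grid=tile_grid, clip_limit=clip_limit)
    try:
        _, mask = otsu_threshold(equalized)
    except DegenerateImageError:
        return np.zeros(gray.shape, dtype=bool)
    return mask


def preprocess_slide(
    image: np.ndarray,
    config: Optional[RppdConfig] = None,
) -> Tuple[List[Partition], List[np.ndarray]]:
    """Partition an RGB slide and segment each partition.

    Returns the partitions of the RGB image and the per-partition boolean
    tissue masks, in the same (row-major) order.
    """
    config = config or RppdConfig()
    rows, cols = config.partition_grid(np.asarray(image).shape)
    parts = partition_image(image, rows, cols)
    masks = [
        segment_partition(p.pixels, tile_grid=config.clahe_tiles, clip_limit=config.clahe_clip)
        for p in parts
    ]
    return parts, masks


def reassemble_masks(parts: List[Partition], masks: List[np.ndarray], shape: Tuple[int, int]) -> np.ndarray:
    """Stitch per-partition masks back into a whole-slide mask."""
    out = np.zeros(shape, dtype=bool)
    for part, mask in zip(parts, masks):
        h, w = mask.shape
        out[part.origin_row : part.origin_row + h, part.origin_col : part.origin_col + w] = mask
    return out
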