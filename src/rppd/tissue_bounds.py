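"""Tissue localization: bound the whole tissue section in one box.

Before a slide is digitised at full resolution, the scanner only needs the
rectangle that actually contains tissue.  The density search is run with
small boxes (40 px) and a low acceptance threshold (``T_r`` = 10%, untiered)
over the un-partitioned mask; the single maximal axis-aligned box enclosing
every accepted small box is the scan region.  A result that misses more than
a small fraction of the true tissue counts as a localization error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .config import RppdConfig
from .core import FocusPointRegion, RppdResult, run_rppd


@dataclass
class BoundingResult:
    """Accepted small boxes plus their maximal enclosing rectangle."""

    small_boxes: List[FocusPointRegion]
    enclosing_box: Optional[Tuple[int, int, int, int]]  # (top, left, bottom, right)
    tissue_coverage: float
    mask_shape: Tuple[int, int]
    rppd_result: RppdResult

    @property
    def found(self) -> bool:
        return self.enclosing_box is not None


def enclosing_box_of(regions: List[FocusPointRegion]) -> Optional[Tuple[int, int, int, int]]:
    """Componentwise min/max of the region extents; None when empty."""
    if not regions:
        return None
    return (
        min(r.slide_top for r in regions),
        min(r.slide_left for r in regions),
        max(r.slide_bottom for r in regions),
        max(r.slide_right for r in regions),
    )


def run_tissue_bounding(
    mask: np.ndarray,
    config: Optional[RppdConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> BoundingResult:
    """Run the small-box search and enclose all accepted boxes.

    ``tissue_coverage`` is the fraction of the mask's tissue pixels inside
    the enclosing box (0 when no box was accepted — the caller treats that as
    a localization error).
    """
    mask = np.asarray(mask).astype(bool)
    config = config or RppdConfig.for_tissue_bounding()
    result = run_rppd(mask, config, rng)
    enclosing = enclosing_box_of(result.regions)
    total = int(mask.sum())
    if enclosing is None or total == 0:
        coverage = 0.0
    else:
        t, l, b, r = enclosing
        coverage = float(mask[t:b, l:r].sum()) / total
    return BoundingResult(
        small_boxes=result.regions,
        enclosing_box=enclosing,
        tissue_coverage=coverage,
        mask_shape=mask.shape,
        rppd_result=result,
    )


def judge_bounding(
    result: BoundingResult,
    truth_mask: np.ndarray,
    miss_tolerance: float = 0.05,
) -> str:
    """"correct" or "localization_error" against the true tissue mask.

    The result is an error iff the fraction of true tissue pixels falling
    outside the enclosing box exceeds ``miss_tolerance`` (or no box was
    found while tissue exists).  An empty truth is trivially correct.
    """
    truth_mask = np.asarray(truth_mask).astype(bool)
    if truth_mask.shape != tuple(result.mask_shape):
        raise ValueError(
            f"truth mask shape {truth_mask.shape} != input shape {result.mask_shape}"
        )
    total = int(truth_mask.sum())
    if total == 0:
        return "correct"
    if result.enclosing_box is None:
        return "localization_error"
    t, l, b, r = result.enclosing_box
    inside = int(truth_mask[t:b, l:r].sum())
    missed = (total - inside) / total
    return "correct" if missed <= miss_tolerance else "localization_error"
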