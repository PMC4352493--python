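"""The random-patch probabilistic density (RPPD) search.

The algorithm operates on a binary tissue mask of one partition.  All tissue
pixel coordinates form the array Omega (here :class:`TissueIndex`).  Each
iteration draws a uniform random tissue pixel ``F_i`` from Omega, centers a
``box_size`` square candidate box on it, and scores the box by its tissue
density ``D_i = tissue / (tissue + background)`` over the (clipped) box area.
Three outcomes are possible:

* accept (``D_i >= T_r``): the box becomes a focus-point region, its tissue
  pixels are consumed from Omega, and the failure counter resets.  The
  density also assigns a priority tier (red >= 0.75 > blue >= 0.50 > green >=
  0.30 > black >= 0.15, half-open at the upper end).
* discard (``D_i < discard_threshold``): the pixels are insignificant debris;
  they are consumed but no region is recorded, and a failure is counted.
* reject (otherwise): a failure is counted; nothing is consumed.

The search stops when the remaining tissue drops below
``T_min = t_min_fraction * box_size**2`` (even a perfect box could no longer
reach the lowest tier) or when ``max_failures`` consecutive failures occur
without an acceptance.  Because Omega only shrinks and a run of failures is
bounded, termination is guaranteed.  Clusters are found adaptively: no number
of regions is specified in advance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .config import UNTIERED_LABEL, RppdConfig
from .errors import EmptyTissueIndexError
from .preprocess import Partition

Coord = Tuple[int, int]


class TissueIndex:
    """The mutable set Omega of tissue-pixel coordinates of one partition.

    Supports uniform random draws over the remaining members and bulk removal
    of all members inside an axis-aligned box.  The size never increases after
    construction.

    Implementation: a boolean "alive" raster plus a flat coordinate array used
    for sampling with rejection; the array is compacted lazily once more than
    half of its entries are dead, which keeps both draw and removal cheap.
    """

    def __init__(self, mask: np.ndarray):
        mask = np.asarray(mask)
        if mask.ndim != 2:
            raise ValueError(f"expected a 2-D binary mask, got shape {mask.shape}")
        self.alive = mask.astype(bool).copy()
        self.shape = self.alive.shape
        self._coords = np.argwhere(self.alive)
        self.initial_count = int(len(self._coords))
        self.n_alive = self.initial_count

    def __len__(self) -> int:
        return self.n_alive

    def __contains__(self, coord: Coord) -> bool:
        r, c = coord
        return bool(self.alive[r, c])

    def coordinates(self) -> np.ndarray:
        """The remaining members as an (n, 2) array of (row, col)."""
        return np.argwhere(self.alive)

    def sample(self, rng: np.random.Generator) -> Coord:
        """Draw one member uniformly at random from the remaining set."""
        if self.n_alive == 0:
            raise EmptyTissueIndexError("cannot sample from an empty tissue index")
        while True:
            i = int(rng.integers(len(self._coords)))
            r, c = self._coords[i]
            if self.alive[r, c]:
                return int(r), int(c)
            if len(self._coords) > 2 * self.n_alive:
                self._coords = np.argwhere(self.alive)

    def remove_box(self, top: int, bottom: int, left: int, right: int) -> int:
        """Remove every member inside ``[top, bottom) x [left, right)``.

        Returns the number of members removed; members outside the extent are
        untouched.
        """
        window = self.alive[top:bottom, left:right]
        removed = int(window.sum())
        window[:] = False
        self.n_alive -= removed
        return removed


@dataclass(frozen=True)
class CandidateBox:
    """A candidate focus-point box with its density score.

    The extent is half-open, ``[top, bottom) x [left, right)``, in partition
    coordinates, clipped to the partition bounds.  ``tissue_count`` and
    ``background_count`` always sum to the scored area (clipped area by
    default; nominal ``box_size**2`` when out-of-bounds pixels are counted as
    background).
    """

    center: Coord
    top: int
    left: int
    bottom: int
    right: int
    tissue_count: int
    background_count: int

    @property
    def area(self) -> int:
        return (self.bottom - self.top) * (self.right - self.left)

    @property
    def density(self) -> float:
        return self.tissue_count / (self.tissue_count + self.background_count)

    @property
    def extent(self) -> Tuple[int, int, int, int]:
        return self.top, self.left, self.bottom, self.right


@dataclass(frozen=True)
class FocusPointRegion:
    """An accepted box with its priority tier, in partition and slide frames."""

    box: CandidateBox
    tier: str
    partition_index: int
    slide_top: int
    slide_left: int
    slide_bottom: int
    slide_right: int

    @property
    def density(self) -> float:
        return self.box.density

    @property
    def slide_extent(self) -> Tuple[int, int, int, int]:
        return self.slide_top, self.slide_left, self.slide_bottom, self.slide_right


@dataclass(frozen=True)
class Decision:
    """Outcome of the density test for one candidate box."""

    action: str  # "accept" | "reject" | "discard"
    tier: Optional[str] = None


@dataclass
class RppdResult:
    """Everything a single-partition run produced."""

    regions: List[FocusPointRegion]
    iterations: int
    n_accepted: int
    n_discarded: int
    n_rejected: int
    failures_at_exit: int
    termination_reason: str  # "pixel_exhaustion" | "failure_budget"
    initial_tissue: int
    final_tissue: int
    removed_total: int


def build_tissue_index(mask: np.ndarray) -> TissueIndex:
    """Store all tissue-labeled coordinates of ``mask`` in an index (Omega)."""
    return TissueIndex(mask)


def sample_seed(index: TissueIndex, rng: np.random.Generator) -> Coord:
    """Draw the next random tissue pixel ``F_i`` uniformly from the index."""
    return index.sample(rng)


def box_extent(
    center: Coord, box_size: int, shape: Tuple[int, int]
) -> Tuple[int, int, int, int]:
    """Half-open extent of a ``box_size`` square centered on ``center``,
    clipped to ``shape``.

    For even sizes the center sits at offset ``box_size // 2`` from the top /
    left of the nominal box (a 150 box spans 74 pixels above and 75 below the
    center row).
    """
    r, c = center
    half_lo = (box_size - 1) // 2
    half_hi = box_size // 2
    top = max(0, r - half_lo)
    left = max(0, c - half_lo)
    bottom = min(shape[0], r + half_hi + 1)
    right = min(shape[1], c + half_hi + 1)
    return top, left, bottom, right


def make_candidate_box(
    center: Coord, config: RppdConfig, mask: np.ndarray
) -> CandidateBox:
    """Score the candidate box centered on ``center`` against ``mask``.

    Tissue/background counts are taken over the extent clipped to the mask
    bounds; with ``config.clip_boxes=False`` the out-of-bounds part of the
    nominal box is counted as background instead.
    """
    mask = np.asarray(mask)
    r, c = center
    if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
        raise ValueError(f"center {center} lies outside mask of shape {mask.shape}")
    top, left, bottom, right = box_extent(center, config.box_size, mask.shape)
    tissue = int(np.count_nonzero(mask[top:bottom, left:right]))
    area = (bottom - top) * (right - left)
    background = area - tissue
    if not config.clip_boxes:
        background += config.box_area - area
    return CandidateBox(
        center=(int(r), int(c)),
        top=top,
        left=left,
        bottom=bottom,
        right=right,
        tissue_count=tissue,
        background_count=background,
    )


def classify_candidate(density: float, config: RppdConfig) -> Decision:
    """Accept (with a tier), reject, or discard a candidate by its density.

    ``density >= T_r`` accepts; the tier is the highest cutoff not exceeding
    the density (cutoffs closed at the lower end).  ``density <
    discard_threshold`` discards (debris removal).  Anything between is a
    plain reject.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must lie in [0, 1], got {density}")
    if density >= config.accept_threshold:
        cuts = config.tier_cutoffs
        idx = int(np.searchsorted(cuts, density, side="right")) - 1
        tier = config.tier_name(idx) if idx >= 0 else UNTIERED_LABEL
        return Decision("accept", tier)
    if density < config.discard_threshold:
        return Decision("discard")
    return Decision("reject")


def remove_box_pixels(index: TissueIndex, box: CandidateBox) -> int:
    """Consume every index member inside the box extent; returns the count."""
    return index.remove_box(box.top, box.bottom, box.left, box.right)


def run_rppd(
    mask: np.ndarray,
    config: Optional[RppdConfig] = None,
    rng: Optional[np.random.Generator] = None,
    partition_index: int = 1,
    origin: Coord = (0, 0),
) -> RppdResult:
    """Run the full density search on one partition mask.

    ``origin`` is the partition's top-left corner in slide coordinates; the
    returned regions carry both partition-local and slide extents.  The run is
    deterministic given ``mask``, ``config`` and the generator state.
    """
    config = config or RppdConfig()
    rng = rng if rng is not None else np.random.default_rng()
    index = build_tissue_index(mask)

    regions: List[FocusPointRegion] = []
    iterations = n_accepted = n_discarded = n_rejected = 0
    failures = 0
    removed_total = 0
    reason = "pixel_exhaustion"
    orow, ocol = origin

    while True:
        if index.n_alive < config.t_min:
            reason = "pixel_exhaustion"
            break
        if failures >= config.max_failures:
            reason = "failure_budget"
            break
        center = sample_seed(index, rng)
        box = make_candidate_box(center, config, index.alive)
        decision = classify_candidate(box.density, config)
        iterations += 1
        if decision.action == "accept":
            removed_total += remove_box_pixels(index, box)
            failures = 0
            n_accepted += 1
            regions.append(
                FocusPointRegion(
                    box=box,
                    tier=decision.tier,
                    partition_index=partition_index,
                    slide_top=orow + box.top,
                    slide_left=ocol + box.left,
                    slide_bottom=orow + box.bottom,
                    slide_right=ocol + box.right,
                )
            )
        elif decision.action == "discard":
            removed_total += remove_box_pixels(index, box)
            failures += 1
            n_discarded += 1
        else:
            failures += 1
            n_rejected += 1

    return RppdResult(
        regions=regions,
        iterations=iterations,
        n_accepted=n_accepted,
        n_discarded=n_discarded,
        n_rejected=n_rejected,
        failures_at_exit=failures,
        termination_reason=reason,
        initial_tissue=index.initial_count,
        final_tissue=index.n_alive,
        removed_total=removed_total,
    )


def map_regions_to_slide(
    regions_by_partition: Mapping[int, Sequence[FocusPointRegion]],
    partitions: Sequence[Partition],
) -> List[FocusPointRegion]:
    """Offset partition-local regions by their partition origin and merge.

    Partitions are keyed by their 1-based row-major index; an unknown key is
    an error.
    """
    origins: Dict[int, Coord] = {p.index: (p.origin_row, p.origin_col) for p in partitions}
    merged: List[FocusPointRegion] = []
    for pidx in sorted(regions_by_partition):
        if pidx not in origins:
            raise ValueError(f"unknown partition index {pidx}; have {sorted(origins)}")
        orow, ocol = origins[pidx]
        for region in regions_by_partition[pidx]:
            box = region.box
            merged.append(
                replace(
                    region,
                    slide_top=orow + box.top,
                    slide_left=ocol + box.left,
                    slide_bottom=orow + box.bottom,
                    slide_right=ocol + box.right,
                )
            )
    return merged
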