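"""Configuration for the random-patch density search.

A single :class:`RppdConfig` carries every tunable of the algorithm: the
candidate box geometry, the acceptance threshold ``T_r``, the low-density
discard rule, the remaining-tissue floor ``T_min`` and the consecutive-failure
budget, plus the preprocessing knobs (partition grid, CLAHE tiles/clip).

Two operating points are used in practice:

* focus-point mode (default): 150 px boxes, ``T_r`` = 0.15, four priority
  tiers (black/green/blue/red) at cutoffs 0.15/0.30/0.50/0.75;
* tissue-bounding mode (:meth:`RppdConfig.for_tissue_bounding`): 40 px boxes,
  ``T_r`` = 0.10, a single untiered acceptance class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Tuple

import yaml

#: Tier names for the canonical four ascending cutoffs, lowest priority first.
TIER_NAMES_4 = ("black", "green", "blue", "red")

#: Label used when the config defines no priority tiers (tissue-bounding mode).
UNTIERED_LABEL = "accepted"


@dataclass(frozen=True)
class RppdConfig:
    """All tunable thresholds and sizes of the density search.

    Parameters
    ----------
    box_size : int
        Side length of the candidate box in pixels.
    tier_cutoffs : tuple of float
        Ascending density fractions delimiting priority tiers.  Four cutoffs
        produce the canonical black/green/blue/red scale; an empty tuple means
        untiered acceptance.
    accept_threshold : float
        ``T_r`` — minimum density for a candidate to be accepted.
    discard_threshold : float
        Densities strictly below this are treated as insignificant debris:
        the box pixels are consumed (removed from the tissue index) without
        producing a region.
    t_min_fraction : float
        The search stops once the remaining tissue count drops below
        ``t_min_fraction * box_size**2`` (even a perfectly placed box could
        not reach the lowest tier).
    max_failures : int
        Budget of consecutive non-acceptances tolerated before the search
        gives up on a partition.
    clip_boxes : bool
        If True (default), boxes near the partition border are clipped and the
        density denominator is the clipped area.  If False, out-of-bounds
        pixels count as background.
    partition_rows, partition_cols : int or None
        Partition grid.  ``None`` selects 2x3 for landscape inputs and 3x2
        otherwise (six partitions either way).
    clahe_tiles : (int, int)
        CLAHE tile grid per partition.
    clahe_clip : float
        CLAHE clip limit (fraction-of-histogram convention).
    """

    box_size: int = 150
    tier_cutoffs: Tuple[float, ...] = (0.15, 0.30, 0.50, 0.75)
    accept_threshold: float = 0.15
    discard_threshold: float = 0.10
    t_min_fraction: float = 0.15
    max_failures: int = 100
    clip_boxes: bool = True
    partition_rows: Optional[int] = None
    partition_cols: Optional[int] = None
    clahe_tiles: Tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01

    def __post_init__(self) -> None:
        if self.box_size < 1:
            raise ValueError(f"box_size must be >= 1, got {self.box_size}")
        if self.max_failures < 1:
            raise ValueError(f"max_failures must be >= 1, got {self.max_failures}")
        if not 0.0 < self.discard_threshold <= self.accept_threshold:
            raise ValueError(
                "need 0 < discard_threshold <= accept_threshold, got "
                f"{self.discard_threshold} / {self.accept_threshold}"
            )
        if not 0.0 < self.accept_threshold <= 1.0:
            raise ValueError(f"accept_threshold must be in (0, 1], got {self.accept_threshold}")
        if not 0.0 < self.t_min_fraction <= 1.0:
            raise ValueError(f"t_min_fraction must be in (0, 1], got {self.t_min_fraction}")
        cuts = tuple(float(c) for c in self.tier_cutoffs)
        object.__setattr__(self, "tier_cutoffs", cuts)
        if any(not 0.0 < c <= 1.0 for c in cuts):
            raise ValueError(f"tier cutoffs must lie in (0, 1], got {cuts}")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"tier cutoffs must be strictly ascending, got {cuts}")
        if (self.partition_rows is None) != (self.partition_cols is None):
            raise ValueError("partition_rows and partition_cols must be set together")

    # -- derived quantities -------------------------------------------------

    @property
    def box_area(self) -> int:
        return self.box_size * self.box_size

    @property
    def t_min(self) -> float:
        """Remaining-tissue floor in pixels (``t_min_fraction * box_size**2``)."""
        return self.t_min_fraction * self.box_area

    def tier_name(self, index: int) -> str:
        if len(self.tier_cutoffs) == 4:
            return TIER_NAMES_4[index]
        return f"tier{index + 1}"

    def partition_grid(self, shape: Tuple[int, ...]) -> Tuple[int, int]:
        """Resolve the partition grid for an image of the given shape.

        Defaults to six partitions: 2 rows x 3 cols for landscape images,
        3 x 2 for portrait/square ones.
        """
        if self.partition_rows is not None and self.partition_cols is not None:
            return self.partition_rows, self.partition_cols
        height, width = shape[0], shape[1]
        return (2, 3) if width > height else (3, 2)

    # -- construction helpers ----------------------------------------------

    @classmethod
    def for_tissue_bounding(cls, **overrides) -> "RppdConfig":
        """The tissue-localization operating point: 40 px boxes, ``T_r`` = 10%,
        single untiered acceptance class, no partitioning."""
        params = dict(
            box_size=40,
            accept_threshold=0.10,
            discard_threshold=0.10,
            tier_cutoffs=(),
            partition_rows=1,
            partition_cols=1,
        )
        params.update(overrides)
        return cls(**params)

    def replace(self, **changes) -> "RppdConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RppdConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {
            k: tuple(v) if k in ("tier_cutoffs", "clahe_tiles") and v is not None else v
            for k, v in data.items()
        }
        return cls(**coerced)

    @classmethod
    def from_yaml(cls, path) -> "RppdConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
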