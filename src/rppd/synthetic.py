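"""Synthetic whole-slide fixtures with exact ground truth.

The generator emulates the statistical structure the detection pipeline
consumes, not histological texture: dark-stained tissue pixels on a bright
background, organised as

* planted rectangular (or elliptical) regions with a controllable internal
  tissue density — the "hot spots" the search should find;
* sparse Bernoulli scatter over the background — the debris that slide
  preparation spreads across real slides and that the discard rule ignores;
* a smooth multiplicative illumination field — the uneven camera lighting
  that motivates per-partition thresholding.

Ground truth records the exact tissue mask, the planted geometry and the
expected priority tier of each region, so recovery and false positives can be
judged automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import RppdConfig
from .errors import PlacementError

#: Default canvas: one-ninth the linear area of a 4140x3096 slide thumbnail,
#: small enough for fast batch experiments.
DEFAULT_SHAPE = (1032, 1380)

#: Mean RGB of a rendered stained-tissue pixel (DAB-like brown) and of the
#: near-white background.
STAIN_RGB = (110.0, 72.0, 45.0)
BACKGROUND_LEVEL = 245.0


@dataclass(frozen=True)
class PlantedRegion:
    """Geometry and density of one planted high-density region."""

    top: int
    left: int
    height: int
    width: int
    density: float
    shape: str = "rect"  # "rect" | "ellipse"

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width

    @property
    def extent(self) -> Tuple[int, int, int, int]:
        return self.top, self.left, self.bottom, self.right

    def expected_tier(self, config: Optional[RppdConfig] = None) -> Optional[str]:
        """Tier a box fully interior to this region would receive."""
        config = config or RppdConfig()
        cuts = config.tier_cutoffs
        idx = int(np.searchsorted(cuts, self.density, side="right")) - 1
        if self.density < config.accept_threshold or idx < 0:
            return None
        return config.tier_name(idx)

    def support(self) -> np.ndarray:
        """Boolean (height, width) footprint of the region shape."""
        if self.shape == "rect":
            return np.ones((self.height, self.width), dtype=bool)
        if self.shape == "ellipse":
            rr = (np.arange(self.height) - (self.height - 1) / 2.0) / (self.height / 2.0)
            cc = (np.arange(self.width) - (self.width - 1) / 2.0) / (self.width / 2.0)
            return rr[:, None] ** 2 + cc[None, :] ** 2 <= 1.0
        raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass
class SyntheticGroundTruth:
    """Exact truth for one generated slide or mask fixture."""

    tissue_mask: np.ndarray
    planted_regions: List[PlantedRegion]
    scatter_fraction: float
    illumination_field: Optional[np.ndarray] = None

    @property
    def shape(self) -> Tuple[int, int]:
        return self.tissue_mask.shape

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "scatter_fraction": self.scatter_fraction,
            "planted_regions": [
                {
                    "top": r.top,
                    "left": r.left,
                    "height": r.height,
                    "width": r.width,
                    "density": r.density,
                    "shape": r.shape,
                    "expected_tier": r.expected_tier(),
                }
                for r in self.planted_regions
            ],
        }


def _fill_regions(
    mask: np.ndarray, regions: Sequence[PlantedRegion], rng: np.random.Generator
) -> None:
    for region in regions:
        if not 0.0 < region.density <= 1.0:
            raise ValueError(f"region density must lie in (0, 1], got {region.density}")
        if region.top < 0 or region.left < 0 or region.bottom > mask.shape[0] or region.right > mask.shape[1]:
            raise ValueError(f"region {region.extent} exceeds canvas {mask.shape}")
        support = region.support()
        if region.density >= 1.0:
            block = support
        else:
            block = support & (rng.random((region.height, region.width)) < region.density)
        mask[region.top : region.bottom, region.left : region.right] |= block


def _sprinkle_scatter(
    mask: np.ndarray,
    regions: Sequence[PlantedRegion],
    scatter_fraction: float,
    rng: np.random.Generator,
) -> None:
    if scatter_fraction <= 0:
        return
    keep_out = np.zeros(mask.shape, dtype=bool)
    for region in regions:
        keep_out[region.top : region.bottom, region.left : region.right] = True
    scatter = rng.random(mask.shape) < scatter_fraction
    mask |= scatter & ~keep_out


def generate_binary_fixture(
    shape: Tuple[int, int],
    regions: Sequence[PlantedRegion] = (),
    scatter_fraction: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, SyntheticGroundTruth]:
    """Build a binary mask directly (no rendering, no thresholding).

    Planted regions keep their exact Bernoulli densities; scatter is only
    drawn outside the planted extents.
    """
    rng = rng if rng is not None else np.random.default_rng()
    mask = np.zeros(shape, dtype=bool)
    regions = list(regions)
    _fill_regions(mask, regions, rng)
    _sprinkle_scatter(mask, regions, scatter_fraction, rng)
    truth = SyntheticGroundTruth(mask.copy(), regions, float(scatter_fraction))
    return mask, truth


def _place_regions(
    shape: Tuple[int, int],
    n_regions: int,
    sizes: Sequence[Tuple[int, int]],
    densities: Sequence[float],
    region_shape: str,
    margin: int,
    rng: np.random.Generator,
    max_attempts: int,
) -> List[PlantedRegion]:
    """Rejection-sample disjoint placements separated by ``margin`` pixels."""
    placed: List[PlantedRegion] = []
    for i in range(n_regions):
        h, w = sizes[i]
        lo_r, hi_r = margin, shape[0] - margin - h
        lo_c, hi_c = margin, shape[1] - margin - w
        if hi_r < lo_r or hi_c < lo_c:
            raise PlacementError(f"region of size {h}x{w} does not fit canvas {shape}")
        for _ in range(max_attempts):
            top = int(rng.integers(lo_r, hi_r + 1))
            left = int(rng.integers(lo_c, hi_c + 1))
            ok = not any(
                top - margin < p.bottom
                and p.top - margin < top + h
                and left - margin < p.right
                and p.left - margin < left + w
                for p in placed
            )
            if ok:
                placed.append(PlantedRegion(top, left, h, w, float(densities[i]), region_shape))
                break
        else:
            raise PlacementError(
                f"could not place region {i + 1}/{n_regions} after {max_attempts} attempts"
            )
    return placed


def _illumination_field(
    shape: Tuple[int, int], strength: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field in [1 - strength, 1].

    A coarse random grid is smoothed and resampled to full resolution, giving
    low-frequency shading like a camera's uneven illumination.
    """
    coarse = rng.random((4, 5))
    coarse = ndimage.gaussian_filter(coarse, sigma=1.0, mode="nearest")
    zoom = (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1])
    fine = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    fine = fine[: shape[0], : shape[1]]
    lo, hi = fine.min(), fine.max()
    unit = (fine - lo) / (hi - lo) if hi > lo else np.zeros_like(fine)
    return 1.0 - strength * unit


def render_slide(
    truth_mask: np.ndarray,
    illumination: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render a tissue mask as an RGB thumbnail: dark stain on bright ground."""
    rng = rng if rng is not None else np.random.default_rng()
    h, w = truth_mask.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = BACKGROUND_LEVEL + rng.normal(0.0, 3.0, size=(h, w))[..., None]
    stain = np.asarray(STAIN_RGB) + rng.normal(0.0, 12.0, size=(h, w, 3))
    img[truth_mask] = stain[truth_mask]
    if illumination is not None:
        img *= illumination[..., None]
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_slide(
    shape: Tuple[int, int] = DEFAULT_SHAPE,
    n_regions: int = 5,
    density_range: Tuple[float, float] = (0.8, 0.95),
    densities: Optional[Sequence[float]] = None,
    region_size: Tuple[int, int] = (200, 280),
    region_shape: str = "rect",
    scatter_fraction: float = 0.01,
    illumination_strength: float = 0.15,
    margin: int = 40,
    max_attempts: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, SyntheticGroundTruth]:
    """Generate an RGB whole-slide thumbnail with known ground truth.

    Parameters mirror the study conditions: ``n_regions`` disjoint planted
    regions with per-region internal density drawn from ``density_range`` (or
    given explicitly via ``densities``), side lengths drawn from
    ``region_size``, Bernoulli background scatter, and a smooth multiplicative
    illumination field of the given ``strength``.

    Returns the rendered uint8 RGB image and the ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if densities is not None:
        if len(densities) != n_regions:
            raise ValueError(f"need {n_regions} densities, got {len(densities)}")
        dens = [float(d) for d in densities]
    else:
        dens = [float(rng.uniform(*density_range)) for _ in range(n_regions)]
    sizes = [
        (int(rng.integers(region_size[0], region_size[1] + 1)),
         int(rng.integers(region_size[0], region_size[1] + 1)))
        for _ in range(n_regions)
    ]
    placed = _place_regions(
        shape, n_regions, sizes, dens, region_shape, margin, rng, max_attempts
    )
    mask = np.zeros(shape, dtype=bool)
    _fill_regions(mask, placed, rng)
    _sprinkle_scatter(mask, placed, scatter_fraction, rng)
    field = (
        _illumination_field(shape, illumination_strength, rng)
        if illumination_strength > 0
        else None
    )
    image = render_slide(mask, field, rng)
    truth = SyntheticGroundTruth(mask.copy(), placed, float(scatter_fraction), field)
    return image, truth
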