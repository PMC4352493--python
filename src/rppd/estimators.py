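"""scikit-learn style estimators wrapping the detection pipelines.

Each estimator accepts either an RGB thumbnail ``(H, W, 3)`` or a boolean
tissue mask ``(H, W)`` as ``X`` in :meth:`fit`; RGB inputs are segmented with
the grayscale -> CLAHE -> Otsu chain first.  Fitted attributes follow the
sklearn trailing-underscore convention, and all estimators support
``get_params`` / ``set_params`` / ``clone`` so they compose with sklearn
model selection.

* :class:`RPPDDetector` — partitioned adaptive focus-point search.
* :class:`TissueBounder` — small-box search plus maximal enclosing box.
* :class:`KMeansFocusFinder` / :class:`CMeansFocusFinder` — the fixed-k
  clustering baselines with centroid-centered boxes.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import baselines as _baselines
from .config import RppdConfig
from .core import FocusPointRegion, map_regions_to_slide, run_rppd
from .preprocess import partition_image, preprocess_slide, segment_partition
from .tissue_bounds import judge_bounding, run_tissue_bounding


def _validate_input(X: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Return (array, is_rgb); reject anything else."""
    X = np.asarray(X)
    if X.ndim == 3 and X.shape[2] == 3:
        return X, True
    if X.ndim == 2:
        return X.astype(bool), False
    raise ValueError(
        f"X must be an (H, W, 3) RGB image or an (H, W) binary mask, got shape {X.shape}"
    )


class _ConfiguredEstimator(BaseEstimator):
    """Shared plumbing: build an RppdConfig from the estimator params."""

    def _segment(self, rgb: np.ndarray) -> np.ndarray:
        return segment_partition(
            rgb, tile_grid=self.clahe_tiles, clip_limit=self.clahe_clip
        )


class RPPDDetector(_ConfiguredEstimator):
    """Adaptive focus-point region detector.

    Partitions the slide (six partitions by default), segments each partition
    and runs the random-patch density search per partition with a
    deterministic per-partition RNG stream derived from ``random_state``.

    Attributes after ``fit``: ``regions_`` (slide-frame
    :class:`~rppd.core.FocusPointRegion` list), ``results_`` (per-partition
    run summaries), ``partitions_``, ``masks_``, ``tissue_mask_`` (stitched),
    ``n_regions_``, ``config_``.
    """

    def __init__(
        self,
        box_size: int = 150,
        tier_cutoffs: Tuple[float, ...] = (0.15, 0.30, 0.50, 0.75),
        accept_threshold: float = 0.15,
        discard_threshold: float = 0.10,
        t_min_fraction: float = 0.15,
        max_failures: int = 100,
        clip_boxes: bool = True,
        partition_rows: Optional[int] = None,
        partition_cols: Optional[int] = None,
        clahe_tiles: Tuple[int, int] = (8, 8),
        clahe_clip: float = 0.01,
        random_state: Optional[int] = None,
    ):
        self.box_size = box_size
        self.tier_cutoffs = tier_cutoffs
        self.accept_threshold = accept_threshold
        self.discard_threshold = discard_threshold
        self.t_min_fraction = t_min_fraction
        self.max_failures = max_failures
        self.clip_boxes = clip_boxes
        self.partition_rows = partition_rows
        self.partition_cols = partition_cols
        self.clahe_tiles = clahe_tiles
        self.clahe_clip = clahe_clip
        self.random_state = random_state

    def _make_config(self) -> RppdConfig:
        return RppdConfig(
            box_size=self.box_size,
            tier_cutoffs=tuple(self.tier_cutoffs),
            accept_threshold=self.accept_threshold,
            discard_threshold=self.discard_threshold,
            t_min_fraction=self.t_min_fraction,
            max_failures=self.max_failures,
            clip_boxes=self.clip_boxes,
            partition_rows=self.partition_rows,
            partition_cols=self.partition_cols,
            clahe_tiles=tuple(self.clahe_tiles),
            clahe_clip=self.clahe_clip,
        )

    def fit(self, X, y=None):
        X, is_rgb = _validate_input(X)
        config = self._make_config()
        if is_rgb:
            parts, masks = preprocess_slide(X, config)
        else:
            rows, cols = config.partition_grid(X.shape)
            parts = partition_image(X, rows, cols)
            masks = [p.pixels.astype(bool) for p in parts]

        seeds = np.random.SeedSequence(self.random_state).spawn(len(parts))
        results = {}
        regions_by_partition = {}
        for part, mask, seed in zip(parts, masks, seeds):
            rng = np.random.default_rng(seed)
            result = run_rppd(mask, config, rng, partition_index=part.index)
            results[part.index] = result
            regions_by_partition[part.index] = result.regions

        self.config_ = config
        self.partitions_ = parts
        self.masks_ = masks
        tissue = np.zeros(X.shape[:2], dtype=bool)
        for part, mask in zip(parts, masks):
            tissue[
                part.origin_row : part.origin_row + mask.shape[0],
                part.origin_col : part.origin_col + mask.shape[1],
            ] = mask
        self.tissue_mask_ = tissue
        self.results_ = results
        self.regions_ = map_regions_to_slide(regions_by_partition, parts)
        self.n_regions_ = len(self.regions_)
        return self

    def fit_detect(self, X) -> List[FocusPointRegion]:
        """Convenience: fit and return the detected regions."""
        return self.fit(X).regions_


class TissueBounder(_ConfiguredEstimator):
    """Tissue localization: small-box search plus maximal enclosing box.

    Runs un-partitioned with 40 px boxes and ``T_r`` = 10% by default.
    Attributes after ``fit``: ``bounding_``, ``enclosing_box_``,
    ``small_boxes_``, ``tissue_mask_``, ``config_``.
    """

    def __init__(
        self,
        box_size: int = 40,
        accept_threshold: float = 0.10,
        discard_threshold: float = 0.10,
        t_min_fraction: float = 0.15,
        max_failures: int = 100,
        clahe_tiles: Tuple[int, int] = (8, 8),
        clahe_clip: float = 0.01,
        random_state: Optional[int] = None,
    ):
        self.box_size = box_size
        self.accept_threshold = accept_threshold
        self.discard_threshold = discard_threshold
        self.t_min_fraction = t_min_fraction
        self.max_failures = max_failures
        self.clahe_tiles = clahe_tiles
        self.clahe_clip = clahe_clip
        self.random_state = random_state

    def _make_config(self) -> RppdConfig:
        return RppdConfig.for_tissue_bounding(
            box_size=self.box_size,
            accept_threshold=self.accept_threshold,
            discard_threshold=self.discard_threshold,
            t_min_fraction=self.t_min_fraction,
            max_failures=self.max_failures,
            clahe_tiles=tuple(self.clahe_tiles),
            clahe_clip=self.clahe_clip,
        )

    def fit(self, X, y=None):
        X, is_rgb = _validate_input(X)
        config = self._make_config()
        mask = self._segment(X) if is_rgb else X
        rng = np.random.default_rng(np.random.SeedSequence(self.random_state))
        bounding = run_tissue_bounding(mask, config, rng)
        self.config_ = config
        self.tissue_mask_ = mask
        self.bounding_ = bounding
        self.enclosing_box_ = bounding.enclosing_box
        self.small_boxes_ = bounding.small_boxes
        return self

    def judge(self, truth_mask, miss_tolerance: float = 0.05) -> str:
        """"correct" / "localization_error" for the fitted bounding result."""
        return judge_bounding(self.bounding_, truth_mask, miss_tolerance)


class _ClusterBoxFinder(_ConfiguredEstimator):
    """Shared logic of the fixed-k clustering baselines."""

    def _cluster(self, pts, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def fit(self, X, y=None):
        X, is_rgb = _validate_input(X)
        mask = self._segment(X) if is_rgb else X
        pts = np.argwhere(mask)
        rng = np.random.default_rng(np.random.SeedSequence(self.random_state))
        if self.max_points is not None and len(pts) > self.max_points:
            keep = rng.choice(len(pts), size=self.max_points, replace=False)
            pts = pts[np.sort(keep)]
        result = self._cluster(pts, rng)
        self.tissue_mask_ = mask
        self.result_ = result
        self.centers_ = result.centers
        self.labels_ = result.labels
        self.objective_ = result.objective
        self.boxes_ = _baselines.boxes_from_centers(result.centers, self.box_size, mask)
        return self


class KMeansFocusFinder(_ClusterBoxFinder):
    """k-means over tissue-pixel coordinates with centroid-centered boxes.

    ``max_points`` optionally subsamples the tissue pixels before clustering
    (uniformly, reproducibly) to bound the cost on large slides.
    """

    def __init__(
        self,
        n_clusters: int = 120,
        box_size: int = 150,
        max_iter: int = 100,
        tol: float = 1e-4,
        max_points: Optional[int] = None,
        clahe_tiles: Tuple[int, int] = (8, 8),
        clahe_clip: float = 0.01,
        random_state: Optional[int] = None,
    ):
        self.n_clusters = n_clusters
        self.box_size = box_size
        self.max_iter = max_iter
        self.tol = tol
        self.max_points = max_points
        self.clahe_tiles = clahe_tiles
        self.clahe_clip = clahe_clip
        self.random_state = random_state

    def _cluster(self, pts, rng):
        return _baselines.kmeans_cluster(
            pts, self.n_clusters, rng, max_iter=self.max_iter, tol=self.tol
        )


class CMeansFocusFinder(_ClusterBoxFinder):
    """Fuzzy c-means over tissue-pixel coordinates with center boxes."""

    def __init__(
        self,
        n_clusters: int = 120,
        m: float = 2.0,
        box_size: int = 150,
        max_iter: int = 150,
        tol: float = 1e-5,
        max_points: Optional[int] = None,
        clahe_tiles: Tuple[int, int] = (8, 8),
        clahe_clip: float = 0.01,
        random_state: Optional[int] = None,
    ):
        self.n_clusters = n_clusters
        self.m = m
        self.box_size = box_size
        self.max_iter = max_iter
        self.tol = tol
        self.max_points = max_points
        self.clahe_tiles = clahe_tiles
        self.clahe_clip = clahe_clip
        self.random_state = random_state

    def _cluster(self, pts, rng):
        return _baselines.fcm_cluster(
            pts, self.n_clusters, m=self.m, rng=rng, max_iter=self.max_iter, tol=self.tol
        )
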