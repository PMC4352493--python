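"""Comparison clustering baselines: k-means and fuzzy c-means.

Both methods cluster the (row, col) coordinates of tissue pixels — no
intensity features — so that clusters form where tissue pixels are dense,
and each final cluster center is turned into one fixed-size box for
evaluation parity with the density search.  Unlike the adaptive search, both
need the number of clusters chosen in advance.

k-means minimises the summed squared distance of points to their assigned
center (Lloyd iterations); fuzzy c-means minimises the membership-weighted
objective ``J_m = sum_ij u_ij^m ||x_i - c_j||^2`` with fuzzifier ``m > 1``
and row-normalised memberships.  The Lloyd loop is written out here (rather
than delegated) so that the per-iteration objective trace is available; the
scikit-learn implementation serves as an independent cross-check in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .config import RppdConfig
from .core import CandidateBox, make_candidate_box


@dataclass
class ClusteringResult:
    """Centers, assignments and the objective trace of one clustering run."""

    centers: np.ndarray  # (k, 2) float
    labels: np.ndarray  # (n,) hard assignment (argmax membership for fuzzy)
    memberships: Optional[np.ndarray]  # (n, c) for fuzzy c-means, else None
    objective: float
    objective_history: List[float]
    iterations: int
    converged: bool


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of coordinates, got {pts.shape}")
    return pts


def _init_centers(pts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct data points as initial centers (distinct coordinates when
    the data allows it)."""
    unique = np.unique(pts, axis=0)
    pool = unique if len(unique) >= k else pts
    idx = rng.choice(len(pool), size=k, replace=False)
    return pool[idx].astype(float).copy()


def kmeans_cluster(
    points,
    k: int,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> ClusteringResult:
    """Lloyd's k-means on pixel coordinates.

    Initial centers are k random distinct points; iterations stop when the
    largest center shift falls below ``tol`` or after ``max_iter`` rounds.
    The recorded objective (after each assignment step) is non-increasing.
    An emptied cluster is re-seeded on the point farthest from its center.
    """
    pts = _as_points(points)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(pts) < k:
        raise ValueError(f"need at least k={k} points, got {len(pts)}")
    rng = rng if rng is not None else np.random.default_rng()
    centers = _init_centers(pts, k, rng)

    history: List[float] = []
    labels = np.zeros(len(pts), dtype=int)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        history.append(float(d2[np.arange(len(pts)), labels].sum()))
        new_centers = centers.copy()
        for j in range(k):
            members = labels == j
            if members.any():
                new_centers[j] = pts[members].mean(axis=0)
            else:
                new_centers[j] = pts[d2.min(axis=1).argmax()]
        shift = float(np.abs(new_centers - centers).max())
        centers = new_centers
        if shift < tol:
            converged = True
            break
    # final assignment against the converged centers
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    objective = float(d2[np.arange(len(pts)), labels].sum())
    history.append(objective)
    return ClusteringResult(
        centers=centers,
        labels=labels,
        memberships=None,
        objective=objective,
        objective_history=history,
        iterations=iteration,
        converged=converged,
    )


def fcm_cluster(
    points,
    c: int,
    m: float = 2.0,
    rng: Optional[np.random.Generator] = None,
    max_iter: int = 150,
    tol: float = 1e-5,
) -> ClusteringResult:
    """Fuzzy c-means on pixel coordinates.

    Alternates membership and center updates minimising ``J_m``; memberships
    are row-normalised (each point's degrees sum to 1) and a point coincident
    with a center receives full membership in it.  Stops when the largest
    membership change falls below ``tol`` or after ``max_iter`` rounds.
    """
    pts = _as_points(points)
    if c < 1:
        raise ValueError(f"c must be >= 1, got {c}")
    if len(pts) < c:
        raise ValueError(f"need at least c={c} points, got {len(pts)}")
    if not m > 1.0:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    rng = rng if rng is not None else np.random.default_rng()
    centers = _init_centers(pts, c, rng)

    def memberships_for(cent: np.ndarray) -> np.ndarray:
        d2 = ((pts[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0.0
        with np.errstate(divide="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        u = np.empty_like(d2)
        finite_rows = ~zero.any(axis=1)
        u[finite_rows] = inv[finite_rows] / inv[finite_rows].sum(axis=1, keepdims=True)
        # coincident point: full membership in (the first) zero-distance center
        bad = ~finite_rows
        if bad.any():
            u[bad] = 0.0
            first = zero[bad].argmax(axis=1)
            u[np.flatnonzero(bad), first] = 1.0
        return u, d2

    u, d2 = memberships_for(centers)
    history: List[float] = [float(((u**m) * d2).sum())]
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        um = u**m
        centers = (um.T @ pts) / um.sum(axis=0)[:, None]
        u_new, d2 = memberships_for(centers)
        history.append(float(((u_new**m) * d2).sum()))
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < tol:
            converged = True
            break
    return ClusteringResult(
        centers=centers,
        labels=u.argmax(axis=1),
        memberships=u,
        objective=history[-1],
        objective_history=history,
        iterations=iteration,
        converged=converged,
    )


def boxes_from_centers(
    centers: np.ndarray,
    box_size: int,
    mask: np.ndarray,
) -> List[CandidateBox]:
    """One density-scored box per cluster center, clipped to the mask.

    Continuous centers are rounded to the nearest pixel and clamped into the
    mask bounds so every cluster yields a box.
    """
    mask = np.asarray(mask)
    config = RppdConfig(box_size=box_size)
    boxes: List[CandidateBox] = []
    for center in np.asarray(centers, dtype=float):
        if not np.all(np.isfinite(center)):
            raise ValueError(f"non-finite cluster center {center}")
        r = int(np.clip(round(center[0]), 0, mask.shape[0] - 1))
        c = int(np.clip(round(center[1]), 0, mask.shape[1] - 1))
        boxes.append(make_candidate_box((r, c), config, mask))
    return boxes
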