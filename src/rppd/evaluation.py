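"""Evaluation metrics: false-positive rate and localization accuracy.

The false-positive rate of a slide is the area of the incorrectly placed
boxes relative to the slide area::

    FPR = box_area * n_incorrect / image_area * 100   (percent)

and the average over a set of slides is the AFPR.  Localization accuracy for
the tissue-bounding task counts slides whose enclosing box missed a
significant share of the tissue::

    accuracy = (1 - n_errors / n_images) * 100        (percent)

Whether a box is "incorrect" is decided automatically against synthetic
ground truth: a box is incorrect iff the fraction of its area lying on true
tissue falls below ``min_overlap``.  Two conventions are useful and both are
reported by the batch helpers: the majority rule (``min_overlap = 0.5``) and
the off-tissue rule (``min_overlap <= T_r``, matching the idea that a false
positive is a box essentially outside the tissue borders; under this rule a
box legitimately accepted at density >= T_r can never be a false positive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import CandidateBox, FocusPointRegion

Extent = Tuple[int, int, int, int]


def false_positive_rate(box_area: int, n_incorrect: int, image_area: int) -> float:
    """Percent of the image area covered by incorrectly placed boxes."""
    if image_area <= 0:
        raise ValueError(f"image_area must be positive, got {image_area}")
    if box_area < 0 or box_area > image_area:
        raise ValueError(f"box_area {box_area} outside [0, image_area={image_area}]")
    if n_incorrect < 0:
        raise ValueError(f"n_incorrect must be >= 0, got {n_incorrect}")
    return box_area * n_incorrect / image_area * 100.0


def localization_accuracy(n_errors: int, n_images: int) -> float:
    """Percent of images whose bounding box was judged correct."""
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    if not 0 <= n_errors <= n_images:
        raise ValueError(f"n_errors must lie in [0, {n_images}], got {n_errors}")
    return (1.0 - n_errors / n_images) * 100.0


def _extent_of(region: Union[FocusPointRegion, CandidateBox, Extent]) -> Extent:
    if isinstance(region, FocusPointRegion):
        return region.slide_extent
    if isinstance(region, CandidateBox):
        return region.extent
    t, l, b, r = region
    return int(t), int(l), int(b), int(r)


def judge_boxes(
    regions: Sequence[Union[FocusPointRegion, CandidateBox, Extent]],
    truth_mask: np.ndarray,
    min_overlap: float = 0.5,
) -> np.ndarray:
    """Boolean "correct" flag per box against the true tissue mask.

    A box is correct iff the fraction of its area overlapping true tissue is
    at least ``min_overlap`` (boundary closed).  Extents are slide-frame,
    half-open, and must lie within the truth mask.
    """
    truth_mask = np.asarray(truth_mask).astype(bool)
    if truth_mask.ndim != 2:
        raise ValueError(f"expected a 2-D truth mask, got shape {truth_mask.shape}")
    correct = np.zeros(len(regions), dtype=bool)
    for i, region in enumerate(regions):
        t, l, b, r = _extent_of(region)
        if t < 0 or l < 0 or b > truth_mask.shape[0] or r > truth_mask.shape[1] or b <= t or r <= l:
            raise ValueError(
                f"box extent {(t, l, b, r)} invalid for truth of shape {truth_mask.shape}"
            )
        area = (b - t) * (r - l)
        overlap = int(truth_mask[t:b, l:r].sum()) / area
        correct[i] = overlap >= min_overlap
    return correct


@dataclass
class EvaluationReport:
    """Per-image box judgements and their set-level aggregates."""

    per_image: pd.DataFrame  # image_id, n_boxes, n_incorrect, fpr_percent, accuracy_percent
    afpr_percent: float
    mean_accuracy_percent: float
    localization_accuracy_percent: Optional[float] = None
    set_assignments: Optional[pd.Series] = None

    def to_csv(self, path) -> None:
        self.per_image.to_csv(path, index=False)

    def summary(self) -> dict:
        out = {
            "n_images": int(len(self.per_image)),
            "afpr_percent": self.afpr_percent,
            "mean_accuracy_percent": self.mean_accuracy_percent,
        }
        if self.localization_accuracy_percent is not None:
            out["localization_accuracy_percent"] = self.localization_accuracy_percent
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


def evaluate_focus_batch(
    batches: Sequence[Tuple[str, Sequence[FocusPointRegion], np.ndarray]],
    box_size: int,
    min_overlap: float = 0.5,
) -> EvaluationReport:
    """Judge focus-point regions for a batch of (image_id, regions, truth).

    Per image, the FPR uses the nominal box area and the truth-mask area;
    ``accuracy_percent`` is reported as ``100 - FPR`` (the per-image
    complement used alongside the AFPR).  AFPR is the unweighted mean.
    """
    rows = []
    for image_id, regions, truth in batches:
        truth = np.asarray(truth)
        correct = judge_boxes(list(regions), truth, min_overlap=min_overlap)
        n_incorrect = int((~correct).sum())
        fpr = false_positive_rate(box_size * box_size, n_incorrect, truth.size)
        rows.append(
            {
                "image_id": image_id,
                "n_boxes": len(correct),
                "n_incorrect": n_incorrect,
                "fpr_percent": fpr,
                "accuracy_percent": 100.0 - fpr,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["image_id", "n_boxes", "n_incorrect", "fpr_percent", "accuracy_percent"]
    )
    afpr = float(frame["fpr_percent"].mean()) if len(frame) else 0.0
    return EvaluationReport(
        per_image=frame,
        afpr_percent=afpr,
        mean_accuracy_percent=100.0 - afpr,
    )


def evaluate_bounding_batch(judgements: Sequence[str]) -> float:
    """Localization accuracy (percent) from per-image bounding judgements."""
    n_errors = sum(1 for j in judgements if j != "correct")
    return localization_accuracy(n_errors, len(judgements))
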