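"""Stage scoring: Jaccard overlap, alignment accuracy, classification metrics.

Segmentation is scored by the Jaccard index (intersection over union of
pixel sets) between predicted and reference crowns.  The reference-to-
predicted matching is greedy: reference crowns, taken in descending size
order, each claim the not-yet-claimed predicted crown with the largest
intersection; unmatched references score 0 and enter the mean.

Classification is scored by rank-1 accuracy (fraction of trees whose
top-ranked species is correct), cross-entropy (mean negative natural log
of the posterior probability assigned to the true species, with a 1e-12
floor to keep it finite) and per-species precision/recall/F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .classification import Prediction
from .segmentation import CrownLabelGrid

__all__ = [
    "SegmentationScore",
    "ClassificationScore",
    "jaccard",
    "score_segmentation",
    "score_classification",
]

POSTERIOR_FLOOR = 1e-12


@dataclass
class SegmentationScore:
    """Per-reference-crown Jaccard indices and their mean.

    ``mean_jaccard`` averages over all reference crowns, counting each
    unmatched reference as 0.
    """

    per_crown_jaccard: dict[int, float]
    mean_jaccard: float
    unmatched_reference: int
    unmatched_predicted: int

    def __post_init__(self) -> None:
        for k, j in self.per_crown_jaccard.items():
            if not 0.0 <= j <= 1.0:
                raise ValueError(f"Jaccard for reference {k} outside [0, 1]: {j}")


@dataclass
class ClassificationScore:
    """Rank-1 accuracy, cross-entropy (nats) and per-species P/R/F1."""

    rank1: float
    cross_entropy: float
    per_class: dict[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.rank1 <= 1.0:
            raise ValueError(f"rank1 outside [0, 1]: {self.rank1}")
        if self.cross_entropy < 0:
            raise ValueError(f"cross_entropy must be >= 0: {self.cross_entropy}")


def jaccard(a: set, b: set) -> float:
    """Jaccard index |A n B| / |A u B|; two empty sets score 0."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def _label_pixel_sets(grid: CrownLabelGrid) -> dict[int, set[tuple[int, int]]]:
    sets: dict[int, set[tuple[int, int]]] = {}
    labels = grid.labels
    for k in range(1, grid.n_crowns + 1):
        rows, cols = np.nonzero(labels == k)
        if rows.size:
            sets[k] = set(zip(rows.tolist(), cols.tolist()))
    return sets


def score_segmentation(
    predicted: CrownLabelGrid, reference: CrownLabelGrid
) -> SegmentationScore:
    """Greedy size-ordered matching of reference to predicted crowns.

    Reference crowns in descending pixel-count order each claim the
    unclaimed predicted crown maximizing the intersection (ties toward the
    smaller predicted label); references with no intersecting unclaimed
    prediction stay unmatched and score 0.
    """
    if predicted.labels.shape != reference.labels.shape:
        raise ValueError(
            f"grid geometry mismatch: predicted {predicted.labels.shape} vs "
            f"reference {reference.labels.shape}"
        )
    pred_sets = _label_pixel_sets(predicted)
    ref_sets = _label_pixel_sets(reference)
    claimed: set[int] = set()
    per_crown: dict[int, float] = {}
    for ref_k in sorted(ref_sets, key=lambda k: (-len(ref_sets[k]), k)):
        ref_px = ref_sets[ref_k]
        best_k, best_inter = None, 0
        for pred_k in sorted(pred_sets):
            if pred_k in claimed:
                continue
            inter = len(ref_px & pred_sets[pred_k])
            if inter > best_inter:
                best_k, best_inter = pred_k, inter
        if best_k is None:
            per_crown[ref_k] = 0.0
        else:
            claimed.add(best_k)
            per_crown[ref_k] = jaccard(ref_px, pred_sets[best_k])
    matched = sum(1 for j in per_crown.values() if j > 0.0)
    mean_j = float(np.mean(list(per_crown.values()))) if per_crown else 0.0
    return SegmentationScore(
        per_crown_jaccard=per_crown,
        mean_jaccard=mean_j,
        unmatched_reference=len(ref_sets) - len(claimed),
        unmatched_predicted=len(pred_sets) - len(claimed),
    )


def score_classification(
    predictions: Sequence[Prediction], truth: dict[str, str]
) -> ClassificationScore:
    """Score predictions against true species labels keyed by crown_id.

    Conventions: precision of a never-predicted species is 0 (not
    undefined); F1 is 0 whenever either component is 0; cross-entropy is
    in nats with posteriors floored at 1e-12.
    """
    if not predictions:
        raise ValueError("no predictions supplied")
    missing = [p.crown_id for p in predictions if p.crown_id not in truth]
    if missing:
        raise ValueError(f"missing truth labels for crowns {missing[:5]}")
    y_true = [truth[p.crown_id] for p in predictions]
    y_pred = [p.label for p in predictions]
    rank1 = sum(1 for t, p in zip(y_true, y_pred) if t == p) / len(predictions)
    ce = -float(
        np.mean(
            [
                math.log(max(p.posterior.get(t, 0.0), POSTERIOR_FLOOR))
                for p, t in zip(predictions, y_true)
            ]
        )
    )
    classes = sorted(set(y_true) | set(y_pred))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    per_class = {
        k: (float(p), float(r), float(f))
        for k, p, r, f in zip(classes, prec, rec, f1)
    }
    return ClassificationScore(
        rank1=rank1, cross_entropy=max(ce, 0.0) + 0.0, per_class=per_class
    )
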