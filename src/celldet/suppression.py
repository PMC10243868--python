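"""Detection thresholding and single-/multi-class non-maximum suppression.

Single-class NMS (SCNMS) greedily suppresses overlapping detections *within*
each predicted class, so one cell can survive twice under two different class
labels.  Multi-class NMS (MCNMS) runs one greedy pass over all classes jointly
so that no two kept boxes overlap at Jaccard >= eta regardless of class —
eliminating contradictory classifications of the same cell.  A brute-force
oracle over tiny instances is provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import Box, boxes_to_array, pairwise_jaccard

__all__ = [
    "Detection",
    "SuppressionResult",
    "SuppressionMode",
    "NonMaxSuppressor",
    "threshold_detections",
    "scnms",
    "mcnms",
    "brute_force_suppression",
]


@dataclass(frozen=True)
class Detection:
    """A detected box with its per-class probability vector.

    ``argmax_class`` and ``score`` are derived from ``probs``: the class with
    the largest probability and that probability.  The vector entries must
    each lie in [0, 1]; it need not be normalized (detector heads commonly
    emit independent per-class confidences).
    """

    box: Box
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probs must be a non-empty 1-D vector")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"class probabilities must lie in [0, 1], got {self.probs}")
        object.__setattr__(self, "probs", tuple(float(x) for x in p))

    @property
    def argmax_class(self) -> int:
        return int(np.argmax(self.probs))

    @property
    def score(self) -> float:
        return float(max(self.probs))


class SuppressionMode(str, Enum):
    SINGLE_CLASS = "single_class"
    MULTI_CLASS = "multi_class"


@dataclass(frozen=True)
class SuppressionResult:
    """Outcome of a suppression pass.

    ``kept`` holds surviving detections in selection order (descending score);
    ``suppressed`` pairs each pruned detection with the input index of the
    kept detection that suppressed it.  Together they exhaust the input.
    """

    kept: tuple[Detection, ...]
    suppressed: tuple[tuple[Detection, int], ...]
    kept_indices: tuple[int, ...] = field(default=())

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.suppressed)


def threshold_detections(
    detections: Sequence[Detection], varrho: float = 0.5
) -> list[Detection]:
    """Keep detections whose top-class probability is >= ``varrho``.

    ``varrho`` is the classification confidence threshold (boundary
    inclusive); it must lie in [0, 1].
    """
    if not 0 <= varrho <= 1:
        raise ValueError(f"varrho must be in [0, 1], got {varrho}")
    return [d for d in detections if d.score >= varrho]


def _greedy(
    detections: Sequence[Detection], eta: float, same_class_only: bool
) -> SuppressionResult:
    if not 0 <= eta <= 1:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    n = len(detections)
    if n == 0:
        return SuppressionResult((), (), ())
    scores = np.array([d.score for d in detections])
    classes = np.array([d.argmax_class for d in detections])
    # stable sort -> equal scores keep input order (smaller index wins)
    order = np.argsort(-scores, kind="stable")
    jac = pairwise_jaccard(
        boxes_to_array([d.box for d in detections]),
        boxes_to_array([d.box for d in detections]),
    )
    kept_idx: list[int] = []
    suppressor = np.full(n, -1, dtype=int)
    for i in order:
        blocked = False
        for k in kept_idx:
            if same_class_only and classes[k] != classes[i]:
                continue
            if jac[i, k] >= eta:
                suppressor[i] = k
                blocked = True
                break
        if not blocked:
            kept_idx.append(int(i))
    suppressed = tuple(
        (detections[i], int(suppressor[i])) for i in order if suppressor[i] >= 0
    )
    return SuppressionResult(
        kept=tuple(detections[i] for i in kept_idx),
        suppressed=suppressed,
        kept_indices=tuple(kept_idx),
    )


def scnms(detections: Sequence[Detection], eta: float = 0.3) -> SuppressionResult:
    """Single-class NMS: greedy suppression within each predicted class.

    Within each class independently, detections are visited by descending
    top-class probability and pruned iff they overlap an already-kept
    detection *of the same class* at Jaccard >= ``eta``; the result is the
    union over classes.  Input detections are assumed already thresholded.
    """
    return _greedy(detections, eta, same_class_only=True)


def mcnms(detections: Sequence[Detection], eta: float = 0.3) -> SuppressionResult:
    """Multi-class NMS: one greedy pass across all classes jointly.

    Detections are visited by descending top-class probability regardless of
    class and pruned iff they overlap *any* already-kept detection at
    Jaccard >= ``eta``.  Consequently no two kept boxes overlap at >= ``eta``,
    so no cell can carry two contradictory class labels.
    """
    return _greedy(detections, eta, same_class_only=False)


def brute_force_suppression(
    detections: Sequence[Detection],
    eta: float,
    mode: SuppressionMode | str = SuppressionMode.MULTI_CLASS,
) -> SuppressionResult:
    """Independent small-instance oracle for SCNMS/MCNMS.

    Repeatedly extracts the maximum-score remaining detection (ties -> the
    smallest input index) and deletes its conflicts, computing every overlap
    with shapely polygon geometry rather than the package's own box algebra.
    Refuses instances larger than 12 detections; intended for verification
    only.
    """
    from shapely.geometry import box as shapely_box

    mode = SuppressionMode(mode)
    if len(detections) > 12:
        raise ValueError("brute-force oracle limited to <= 12 detections")
    if not 0 <= eta <= 1:
        raise ValueError(f"eta must be in [0, 1], got {eta}")

    polys = [shapely_box(*d.box.as_corners()) for d in detections]

    def overlap(i: int, j: int) -> float:
        inter = polys[i].intersection(polys[j]).area
        union = polys[i].union(polys[j]).area
        return inter / union

    remaining = list(range(len(detections)))
    kept: list[int] = []
    suppressed: list[tuple[Detection, int]] = []
    while remaining:
        best = min(remaining, key=lambda i: (-detections[i].score, i))
        kept.append(best)
        remaining.remove(best)
        for i in list(remaining):
            if mode is SuppressionMode.SINGLE_CLASS and (
                detections[i].argmax_class != detections[best].argmax_class
            ):
                continue
            if overlap(i, best) >= eta:
                suppressed.append((detections[i], best))
                remaining.remove(i)
    return SuppressionResult(
        kept=tuple(detections[i] for i in kept),
        suppressed=tuple(suppressed),
        kept_indices=tuple(kept),
    )


class NonMaxSuppressor(BaseEstimator):
    """Thresholding plus SCNMS/MCNMS as a scikit-learn-style transformer.

    Parameters
    ----------
    eta
        Jaccard overlap threshold at which a detection is suppressed
        (boundary inclusive).  Default 0.3.
    varrho
        Classification confidence threshold applied before suppression.
        Default 0.5.
    mode
        ``"single_class"`` (per-class SCNMS) or ``"multi_class"`` (joint
        MCNMS, the inference default that forbids contradictory labels).

    Attributes
    ----------
    mode_ : SuppressionMode
        Validated suppression mode after :meth:`fit`.
    """

    def __init__(
        self,
        eta: float = 0.3,
        varrho: float = 0.5,
        mode: SuppressionMode | str = SuppressionMode.MULTI_CLASS,
    ):
        self.eta = eta
        self.varrho = varrho
        self.mode = mode

    def fit(self, X: Sequence[Detection] | None = None, y=None) -> "NonMaxSuppressor":
        if not 0 <= self.eta <= 1:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")
        if not 0 <= self.varrho <= 1:
            raise ValueError(f"varrho must be in [0, 1], got {self.varrho}")
        self.mode_ = SuppressionMode(self.mode)
        return self

    def transform(self, X: Sequence[Detection]) -> SuppressionResult:
        if not hasattr(self, "mode_"):
            self.fit()
        survivors = threshold_detections(X, self.varrho)
        if self.mode_ is SuppressionMode.SINGLE_CLASS:
            return scnms(survivors, self.eta)
        return mcnms(survivors, self.eta)

    def fit_transform(self, X: Sequence[Detection], y=None) -> SuppressionResult:
        return self.fit(X).transform(X)
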