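"""Cascade sample selection for partially annotated training data.

A cascade of ``Z`` classifier stages partitions candidate proposals into
positives and negatives by increasing overlap thresholds

    phi_z = phi_1 + (z - 1) * rho,      z = 1 .. Z,

a candidate being positive at stage ``z`` iff its best Jaccard overlap with a
reference annotation satisfies ``overlap >= phi_z``.  Under partial
annotation, unlabeled true objects masquerade as background, so the plain
partition poisons the negative pool.  The dual-layer filter re-examines the
final-stage negatives: those with ``overlap >= phi_ignore`` stay as *refined
negatives* (genuinely hard background near an annotated object), while
near-zero-overlap negatives — where unlabeled objects hide — are moved to an
*ignored* class that contributes nothing to training.

Soft-sampling weights complement this: instead of discarding background, every
non-ignored candidate receives an attention weight in (0, 1] — 1 for
positives, lower for low-overlap background — emitted for consumption by an
external trainer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .geometry import Box, boxes_to_array, pairwise_jaccard

__all__ = [
    "StagePlan",
    "Candidate",
    "SampleLabel",
    "SampleAssignment",
    "CascadeSampler",
    "stage_thresholds",
    "partition_stage",
    "refine_negatives",
    "soft_weights",
    "linear_soft_weight",
    "match_candidates",
]

WeightFn = Callable[[float, float], float]


@dataclass(frozen=True)
class StagePlan:
    """Cascade stage thresholds.

    Parameters
    ----------
    phi1
        First-stage positive/negative overlap threshold, in (0, 1).
        Default 0.5.
    rho
        Per-stage threshold increment (>= 0).  Default 0.1.
    n_stages
        Number of cascade stages ``Z`` (>= 1).  Default 3.
    phi_ignore
        Second-layer threshold separating refined negatives from ignored
        instances, with ``0 <= phi_ignore < phi1``.  Default 0.1.
    """

    phi1: float = 0.5
    rho: float = 0.1
    n_stages: int = 3
    phi_ignore: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.phi1 < 1:
            raise ValueError(f"phi1 must be in (0, 1), got {self.phi1}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.n_stages < 1:
            raise ValueError(f"n_stages must be >= 1, got {self.n_stages}")
        if not 0 <= self.phi_ignore < self.phi1:
            raise ValueError(
                f"phi_ignore must satisfy 0 <= phi_ignore < phi1, got {self.phi_ignore}"
            )
        last = self.phi1 + (self.n_stages - 1) * self.rho
        if last >= 1:
            raise ValueError(
                f"derived threshold phi_{self.n_stages} = {last:g} must be < 1"
            )

    @property
    def thresholds(self) -> tuple[float, ...]:
        return tuple(self.phi1 + z * self.rho for z in range(self.n_stages))


@dataclass(frozen=True)
class Candidate:
    """A proposal box with its objectness score and reference overlap.

    ``overlap`` is the candidate's maximum Jaccard index over all reference
    annotations (0 when no annotation exists); ``matched_annotation`` records
    which annotation achieved it.
    """

    box: Box
    score: float
    overlap: float
    matched_annotation: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= 1:
            raise ValueError(f"overlap must be in [0, 1], got {self.overlap}")


class SampleLabel(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    REFINED_NEGATIVE = "refined_negative"
    IGNORED = "ignored"


@dataclass(frozen=True)
class SampleAssignment:
    """Stage-wise training role and attention weight of one candidate."""

    candidate: Candidate
    stage: int
    label: SampleLabel
    weight: float


def stage_thresholds(plan: StagePlan) -> list[float]:
    """Overlap thresholds ``[phi_1, phi_1 + rho, ..., phi_1 + (Z-1) rho]``.

    Strictly increasing whenever ``rho > 0``; construction of ``plan`` already
    guarantees every derived threshold is < 1.
    """
    return list(plan.thresholds)


def partition_stage(
    candidates: Sequence[Candidate], plan: StagePlan, stage: int
) -> tuple[list[Candidate], list[Candidate]]:
    """Split candidates into (positives, negatives) at cascade stage ``stage``.

    A candidate is positive iff ``overlap >= phi_stage`` (boundary inclusive).
    The two lists are disjoint and together exhaust the input.
    """
    if not 1 <= stage <= plan.n_stages:
        raise ValueError(f"stage must be in [1, {plan.n_stages}], got {stage}")
    phi = plan.thresholds[stage - 1]
    positives = [c for c in candidates if c.overlap >= phi]
    negatives = [c for c in candidates if c.overlap < phi]
    return positives, negatives


def refine_negatives(
    negatives: Sequence[Candidate], plan: StagePlan
) -> tuple[list[Candidate], list[Candidate]]:
    """Second filtering layer: split negatives into (refined, ignored).

    Negatives with ``overlap >= phi_ignore`` are kept as refined negatives;
    the rest — where unlabeled objects are likely hiding — are ignored.
    Intended for the final-stage negatives.
    """
    refined = [c for c in negatives if c.overlap >= plan.phi_ignore]
    ignored = [c for c in negatives if c.overlap < plan.phi_ignore]
    return refined, ignored


def linear_soft_weight(
    overlap: float, score: float, *, phi1: float = 0.5, w_min: float = 0.1
) -> float:
    """Default soft-sampling weight, linear in overlap.

    ``w = w_min + (1 - w_min) * overlap / phi1`` clipped to ``[w_min, 1]``:
    pure background gets the floor ``w_min`` and the weight rises to 1 as the
    overlap approaches the positive threshold.  The score is accepted for
    interface compatibility but unused by this default.
    """
    w = w_min + (1.0 - w_min) * overlap / phi1
    return float(min(1.0, max(w_min, w)))


def soft_weights(
    candidates: Sequence[Candidate],
    plan: StagePlan,
    weight_fn: WeightFn | None = None,
) -> list[float]:
    """Attention weights for all candidates.

    Positives (``overlap >= phi1``) receive weight 1; every other candidate
    receives ``weight_fn(overlap, score)``, which must lie in (0, 1].
    """
    if weight_fn is None:
        weight_fn = lambda o, s: linear_soft_weight(o, s, phi1=plan.phi1)
    out = []
    for c in candidates:
        if c.overlap >= plan.phi1:
            out.append(1.0)
            continue
        w = float(weight_fn(c.overlap, c.score))
        if not 0 < w <= 1:
            raise ValueError(
                f"weight_fn returned {w} for overlap={c.overlap}, "
                f"score={c.score}; soft weights must lie in (0, 1]"
            )
        out.append(w)
    return out


def match_candidates(
    proposal_boxes: Sequence[Box],
    scores: Sequence[float],
    annotation_boxes: Sequence[Box],
) -> list[Candidate]:
    """Attach to each proposal its best overlap against the annotations.

    The overlap is the maximum Jaccard over all annotations regardless of
    class; ties are broken toward the lowest annotation index.  With no
    annotations every overlap is 0.
    """
    if len(proposal_boxes) == 0:
        return []
    if len(annotation_boxes) == 0:
        return [
            Candidate(box=b, score=float(s), overlap=0.0, matched_annotation=None)
            for b, s in zip(proposal_boxes, scores)
        ]
    jac = pairwise_jaccard(boxes_to_array(proposal_boxes), boxes_to_array(annotation_boxes))
    best = np.argmax(jac, axis=1)  # argmax returns the lowest index on ties
    out = []
    for i, (b, s) in enumerate(zip(proposal_boxes, scores)):
        ov = float(jac[i, best[i]])
        out.append(
            Candidate(
                box=b,
                score=float(s),
                overlap=ov,
                matched_annotation=int(best[i]) if ov > 0 else None,
            )
        )
    return out


class CascadeSampler(BaseEstimator):
    """Cascade sample selection with dual-layer negative filtering.

    A stateless transformer in the scikit-learn idiom: ``fit`` validates the
    configuration and freezes the stage thresholds, ``transform`` maps a
    candidate sequence to per-stage :class:`SampleAssignment` lists.

    Parameters
    ----------
    phi1, rho, n_stages, phi_ignore
        See :class:`StagePlan`.
    refine_all_stages
        Apply the second filtering layer at every stage instead of only the
        final one (ablation switch; the default matches the intended design).
    weight_fn
        Optional ``(overlap, score) -> weight`` override for the
        soft-sampling weight; defaults to :func:`linear_soft_weight`.

    Attributes
    ----------
    plan_ : StagePlan
        Validated stage plan.
    thresholds_ : tuple of float
        Derived per-stage overlap thresholds.
    """

    def __init__(
        self,
        phi1: float = 0.5,
        rho: float = 0.1,
        n_stages: int = 3,
        phi_ignore: float = 0.1,
        refine_all_stages: bool = False,
        weight_fn: WeightFn | None = None,
    ):
        self.phi1 = phi1
        self.rho = rho
        self.n_stages = n_stages
        self.phi_ignore = phi_ignore
        self.refine_all_stages = refine_all_stages
        self.weight_fn = weight_fn

    def fit(self, X: Sequence[Candidate] | None = None, y=None) -> "CascadeSampler":
        self.plan_ = StagePlan(self.phi1, self.rho, self.n_stages, self.phi_ignore)
        self.thresholds_ = self.plan_.thresholds
        return self

    def transform(
        self, X: Sequence[Candidate]
    ) -> dict[int, list[SampleAssignment]]:
        """Assign labels and weights to candidates at every cascade stage.

        Returns a mapping ``stage (1-based) -> [SampleAssignment, ...]`` with
        one assignment per candidate per stage, preserving input order.
        """
        if not hasattr(self, "plan_"):
            self.fit()
        plan = self.plan_
        weights = soft_weights(X, plan, self.weight_fn)
        out: dict[int, list[SampleAssignment]] = {}
        for stage in range(1, plan.n_stages + 1):
            phi = plan.thresholds[stage - 1]
            refine_here = self.refine_all_stages or stage == plan.n_stages
            assignments = []
            for c, w in zip(X, weights):
                if c.overlap >= phi:
                    label = SampleLabel.POSITIVE
                    weight = 1.0
                elif refine_here and c.overlap < plan.phi_ignore:
                    label = SampleLabel.IGNORED
                    weight = 0.0
                elif refine_here:
                    label = SampleLabel.REFINED_NEGATIVE
                    weight = w
                else:
                    label = SampleLabel.NEGATIVE
                    weight = w
                assignments.append(SampleAssignment(c, stage, label, weight))
            out[stage] = assignments
        return out

    def fit_transform(self, X: Sequence[Candidate], y=None):
        return self.fit(X).transform(X)
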