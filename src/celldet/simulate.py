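"""Synthetic multi-class cell fields with partial annotation.

The generator emulates the geometry and statistics of a partially annotated
microscopy field: ``n_cells`` elliptical cells of ``n_classes`` types are
placed on a textured background with bounded mutual overlap, a controllable
fraction ``unlabeled_fraction`` of them is withheld from the annotation set
(unlabeled true objects masquerading as background — the weak-supervision
failure mode), and around every true object jittered candidate proposals are
emitted with objectness scores positively correlated with their overlap,
together with pure-background proposals and classifier-style detections whose
probability vectors are peaked on the true class.

It exercises box geometry and sampling/suppression statistics; it makes no
attempt at photorealistic cytomorphology.  All randomness flows from the
single ``seed`` through one named generator, so identical specs reproduce
bit-identical fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import draw as skdraw
from skimage import transform as sktransform

from .geometry import Box, LevelMap, jaccard, pairwise_jaccard, boxes_to_array
from .reporting import Annotation
from .sampling import Candidate, match_candidates
from .suppression import Detection

__all__ = [
    "FieldSpec",
    "Proposal",
    "SimulatedField",
    "TwoLevelFixture",
    "simulate_field",
    "simulate_two_level",
]


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one simulated field.

    Defaults give a 512 x 512 field of 40 cells of 5 types, fully annotated,
    with moderately noisy proposals (3 per object plus 20 background boxes)
    and well-calibrated detections (≈95% probability mass on the true class).
    """

    field_size: int = 512
    n_classes: int = 5
    n_cells: int = 40
    cell_radius_range: tuple[float, float] = (8.0, 16.0)
    unlabeled_fraction: float = 0.0
    class_mixture: Optional[tuple[float, ...]] = None
    seed: int = 0
    max_true_jaccard: float = 0.3
    proposals_per_object: int = 3
    n_background_proposals: int = 20
    proposal_jitter: float = 0.35
    score_noise: float = 0.08
    detection_jitter: float = 0.08
    confusion: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.unlabeled_fraction <= 1:
            raise ValueError("unlabeled_fraction must lie in [0, 1]")
        if self.n_classes < 1 or self.n_cells < 0:
            raise ValueError("n_classes must be >= 1 and n_cells >= 0")
        if self.class_mixture is not None:
            mix = np.asarray(self.class_mixture, dtype=float)
            if mix.size != self.n_classes or not np.isclose(mix.sum(), 1.0):
                raise ValueError("class_mixture must have n_classes entries summing to 1")
        if not 0 < self.max_true_jaccard <= 1:
            raise ValueError("max_true_jaccard must lie in (0, 1]")


@dataclass(frozen=True)
class Proposal:
    """A candidate box, its score, and its provenance in the simulation."""

    box: Box
    score: float
    source_index: Optional[int]  # index into true objects, None for background
    overlap_true: float  # Jaccard against the source true box (0 for background)


@dataclass(frozen=True)
class SimulatedField:
    image: np.ndarray
    true_boxes: tuple[Box, ...]
    true_classes: tuple[int, ...]
    annotation_indices: tuple[int, ...]
    annotations: tuple[Annotation, ...]
    proposals: tuple[Proposal, ...]
    detections: tuple[Detection, ...]
    spec: FieldSpec

    @property
    def unlabeled_indices(self) -> tuple[int, ...]:
        labeled = set(self.annotation_indices)
        return tuple(i for i in range(len(self.true_boxes)) if i not in labeled)

    def candidates(self) -> list[Candidate]:
        """Proposals as :class:`Candidate`, overlaps taken vs annotations."""
        return match_candidates(
            [p.box for p in self.proposals],
            [p.score for p in self.proposals],
            [a.box for a in self.annotations],
        )


def _place_cells(
    rng: np.random.Generator, spec: FieldSpec, width: int, height: int
) -> list[Box]:
    lo, hi = spec.cell_radius_range
    boxes: list[Box] = []
    attempts = 0
    max_attempts = 300 * max(spec.n_cells, 1)
    while len(boxes) < spec.n_cells:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells with pairwise Jaccard < "
                f"{spec.max_true_jaccard} in a {width}x{height} field"
            )
        attempts += 1
        rx, ry = rng.uniform(lo, hi, size=2)
        cx = rng.uniform(rx + 1, width - rx - 1)
        cy = rng.uniform(ry + 1, height - ry - 1)
        cand = Box(cx - rx, cy - ry, cx + rx, cy + ry)
        if all(jaccard(cand, b) < spec.max_true_jaccard for b in boxes):
            boxes.append(cand)
    return boxes


def _render(
    rng: np.random.Generator,
    boxes: Sequence[Box],
    classes: Sequence[int],
    spec: FieldSpec,
    width: int,
    height: int,
) -> np.ndarray:
    base = np.array([0.87, 0.84, 0.90])
    img = np.empty((height, width, 3))
    img[:] = base
    texture = ndimage.gaussian_filter(rng.normal(0, 0.06, (height, width)), sigma=3)
    img += texture[..., None]
    for b, c in zip(boxes, classes):
        hue = (c + 0.5) / spec.n_classes
        rgb = skcolor.hsv2rgb(np.array([[[hue, 0.55, 0.55]]]))[0, 0]
        cy, cx = (b.y_min + b.y_max) / 2, (b.x_min + b.x_max) / 2
        rr, cc = skdraw.ellipse(
            cy, cx, b.height / 2, b.width / 2, shape=(height, width)
        )
        img[rr, cc] = rgb
    return np.clip(img, 0, 1)


def _jitter_box(
    rng: np.random.Generator, b: Box, sd_frac: float, width: int, height: int
) -> Box:
    rx, ry = b.width / 2, b.height / 2
    dx = rng.normal(0, sd_frac * rx)
    dy = rng.normal(0, sd_frac * ry)
    sx = float(np.clip(rng.normal(1.0, sd_frac / 3), 0.6, 1.6))
    sy = float(np.clip(rng.normal(1.0, sd_frac / 3), 0.6, 1.6))
    cx = (b.x_min + b.x_max) / 2 + dx
    cy = (b.y_min + b.y_max) / 2 + dy
    x0 = float(np.clip(cx - rx * sx, 0, width - 2))
    y0 = float(np.clip(cy - ry * sy, 0, height - 2))
    x1 = float(np.clip(cx + rx * sx, x0 + 1, width))
    y1 = float(np.clip(cy + ry * sy, y0 + 1, height))
    return Box(x0, y0, x1, y1)


def simulate_field(
    spec: FieldSpec, width: int | None = None, height: int | None = None
) -> SimulatedField:
    """Generate one simulated field.

    ``width``/``height`` override the square ``spec.field_size`` (used by the
    two-level fixture for rectangular crops).  Deterministic given
    ``spec.seed``.
    """
    width = int(width or spec.field_size)
    height = int(height or spec.field_size)
    rng = np.random.default_rng(spec.seed)

    boxes = _place_cells(rng, spec, width, height)
    mixture = (
        np.asarray(spec.class_mixture, dtype=float)
        if spec.class_mixture is not None
        else np.full(spec.n_classes, 1.0 / spec.n_classes)
    )
    classes = rng.choice(spec.n_classes, size=len(boxes), p=mixture)
    image = _render(rng, boxes, classes, spec, width, height)

    n_labeled = round((1 - spec.unlabeled_fraction) * spec.n_cells)
    labeled = np.sort(rng.choice(len(boxes), size=n_labeled, replace=False)) if boxes else np.array([], dtype=int)
    annotations = tuple(
        Annotation(box=boxes[i], class_label=int(classes[i])) for i in labeled
    )

    proposals: list[Proposal] = []
    for i, b in enumerate(boxes):
        for _ in range(spec.proposals_per_object):
            pb = _jitter_box(rng, b, spec.proposal_jitter, width, height)
            ov = jaccard(pb, b)
            score = float(
                np.clip(0.15 + 0.75 * ov + rng.normal(0, spec.score_noise), 0.01, 0.99)
            )
            proposals.append(Proposal(pb, score, i, ov))
    lo, hi = spec.cell_radius_range
    for _ in range(spec.n_background_proposals):
        rx, ry = rng.uniform(lo, hi, size=2)
        cx = rng.uniform(rx + 1, width - rx - 1)
        cy = rng.uniform(ry + 1, height - ry - 1)
        pb = Box(cx - rx, cy - ry, cx + rx, cy + ry)
        score = float(np.clip(rng.normal(0.12, 0.06), 0.01, 0.99))
        proposals.append(Proposal(pb, score, None, 0.0))

    detections: list[Detection] = []
    conc_true = 30.0 * (1 - spec.confusion)
    conc_other = (
        30.0 * spec.confusion / max(spec.n_classes - 1, 1)
        if spec.n_classes > 1
        else 0.0
    )
    for i, b in enumerate(boxes):
        db = _jitter_box(rng, b, spec.detection_jitter, width, height)
        alpha = np.full(spec.n_classes, max(conc_other, 1e-3))
        alpha[classes[i]] = conc_true
        probs = rng.dirichlet(alpha)
        detections.append(Detection(box=db, probs=tuple(probs)))
    # a handful of spurious low-confidence background detections
    for _ in range(int(rng.poisson(1.0)) if boxes else 0):
        rx, ry = rng.uniform(lo, hi, size=2)
        cx = rng.uniform(rx + 1, width - rx - 1)
        cy = rng.uniform(ry + 1, height - ry - 1)
        probs = rng.dirichlet(np.full(spec.n_classes, 2.0))
        detections.append(
            Detection(box=Box(cx - rx, cy - ry, cx + rx, cy + ry), probs=tuple(probs))
        )

    return SimulatedField(
        image=image,
        true_boxes=tuple(boxes),
        true_classes=tuple(int(c) for c in classes),
        annotation_indices=tuple(int(i) for i in labeled),
        annotations=annotations,
        proposals=tuple(proposals),
        detections=tuple(detections),
        spec=spec,
    )


@dataclass(frozen=True)
class TwoLevelFixture:
    """Paired low-/high-magnification fixture for cascade plumbing tests."""

    low_image: np.ndarray
    rois: tuple[Box, ...]
    level_map: LevelMap
    crops: tuple[SimulatedField, ...]

    def map_to_low(self, roi_index: int, box: Box) -> Box:
        """Map a crop-local high-mag box into low-magnification coordinates."""
        roi = self.rois[roi_index]
        sx, sy = self.level_map.scale_x, self.level_map.scale_y
        return Box(
            roi.x_min + box.x_min / sx,
            roi.y_min + box.y_min / sy,
            roi.x_min + box.x_max / sx,
            roi.y_min + box.y_max / sy,
        )


def simulate_two_level(
    spec: FieldSpec,
    roi_layout: Sequence[Box],
    scale: float = 4.0,
    low_size: tuple[int, int] = (256, 256),
) -> TwoLevelFixture:
    """Simulate a low-magnification overview with high-magnification ROIs.

    Each ROI (in low-mag coordinates, inside ``low_size``) receives a
    high-magnification crop of ``scale`` times its linear size, populated by
    :func:`simulate_field` with ``spec.n_cells`` split across ROIs in
    proportion to area.  Overlapping ROIs are permitted with a warning.
    """
    low_w, low_h = low_size
    if not roi_layout:
        raise ValueError("need at least one ROI")
    for roi in roi_layout:
        if roi.x_max > low_w or roi.y_max > low_h:
            raise ValueError(f"ROI {roi} exceeds the low-magnification frame")
    jac = pairwise_jaccard(boxes_to_array(roi_layout), boxes_to_array(roi_layout))
    np.fill_diagonal(jac, 0)
    if np.any(jac > 0):
        warnings.warn("overlapping ROIs in layout", RuntimeWarning, stacklevel=2)

    level_map = LevelMap(scale_x=scale, scale_y=scale)
    areas = np.array([r.area for r in roi_layout])
    shares = areas / areas.sum()
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(len(roi_layout)) % (
        2**31
    )
    crops = []
    for roi, share, child_seed in zip(roi_layout, shares, child_seeds):
        n = max(int(round(spec.n_cells * share)), 1)
        sub = replace(spec, n_cells=n, seed=int(child_seed))
        crops.append(
            simulate_field(
                sub, width=int(round(roi.width * scale)), height=int(round(roi.height * scale))
            )
        )

    rng = np.random.default_rng(spec.seed)
    low = np.empty((low_h, low_w, 3))
    low[:] = np.array([0.92, 0.90, 0.94])
    low += ndimage.gaussian_filter(rng.normal(0, 0.04, (low_h, low_w)), sigma=2)[..., None]
    for roi, crop in zip(roi_layout, crops):
        h = int(roi.y_max) - int(roi.y_min)
        w = int(roi.x_max) - int(roi.x_min)
        thumb = sktransform.resize(crop.image, (h, w), anti_aliasing=True)
        low[int(roi.y_min) : int(roi.y_min) + h, int(roi.x_min) : int(roi.x_min) + w] = thumb
    return TwoLevelFixture(
        low_image=np.clip(low, 0, 1),
        rois=tuple(roi_layout),
        level_map=level_map,
        crops=tuple(crops),
    )
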