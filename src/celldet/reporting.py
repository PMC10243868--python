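"""Detection evaluation, confusion matrices, differential counts and
inter-observer agreement.

Evaluation follows the common detection convention: detections are matched
one-to-one to reference annotations greedily by descending score at a Jaccard
threshold (default 0.5), either class-agnostically ("detection" metrics) or
requiring the predicted class to equal the reference class ("classification"
metrics).  Per-class recall, precision, F1 and accuracy are derived from the
match counts; row-normalized confusion matrices summarize classification
errors among matched pairs.

Clinical reporting covers the bone-marrow nucleated differential cell count
(NDC) — per-type percentages over all counted cells, flagged adequate only
when at least 500 cells were counted — and Cohen's kappa for intra- and
inter-observer agreement with the conventional interpretation bands
(poor <= 0.20 < fair <= 0.40 < moderate <= 0.60 < good <= 0.80 < excellent).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Box, boxes_to_array, pairwise_jaccard
from .suppression import Detection

__all__ = [
    "Annotation",
    "MatchResult",
    "NDCReport",
    "match_detections",
    "metrics",
    "confusion_matrix",
    "cohen_kappa",
    "kappa_band",
    "ndc_report",
    "pr_auc",
]

KAPPA_BANDS = ((0.20, "poor"), (0.40, "fair"), (0.60, "moderate"), (0.80, "good"))


@dataclass(frozen=True)
class Annotation:
    """Reference-standard box with a single class label."""

    box: Box
    class_label: int
    annotator: Optional[str] = None

    def __post_init__(self) -> None:
        if self.class_label < 0:
            raise ValueError(f"class_label must be >= 0, got {self.class_label}")


@dataclass(frozen=True)
class MatchResult:
    """Per-class match counts plus the matched (detection, annotation) pairs.

    For every class, TP + FN equals the number of reference annotations of
    that class.
    """

    true_positives: dict[int, int]
    false_positives: dict[int, int]
    false_negatives: dict[int, int]
    pairs: tuple[tuple[Detection, Annotation], ...]
    class_aware: bool

    @property
    def classes(self) -> list[int]:
        keys = set(self.true_positives) | set(self.false_positives) | set(self.false_negatives)
        return sorted(keys)


def match_detections(
    detections: Sequence[Detection],
    annotations: Sequence[Annotation],
    iou_threshold: float = 0.5,
    class_aware: bool = False,
) -> MatchResult:
    """Greedy one-to-one matching of detections to annotations.

    Detections are visited by descending score; each claims the unmatched
    annotation of maximal Jaccard >= ``iou_threshold`` (restricted to
    annotations of its predicted class when ``class_aware``).  Unclaimed
    detections are false positives (under their predicted class); unclaimed
    annotations are false negatives.  In class-agnostic mode a matched pair is
    a true positive of the *annotation's* class, so the per-class counts
    measure pure localization.
    """
    if not 0 < iou_threshold <= 1:
        raise ValueError(f"iou_threshold must be in (0, 1], got {iou_threshold}")
    classes = set(a.class_label for a in annotations) | set(
        d.argmax_class for d in detections
    )
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    pairs: list[tuple[Detection, Annotation]] = []
    if annotations and detections:
        jac = pairwise_jaccard(
            boxes_to_array([d.box for d in detections]),
            boxes_to_array([a.box for a in annotations]),
        )
    else:
        jac = np.zeros((len(detections), len(annotations)))
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))
    taken = np.zeros(len(annotations), dtype=bool)
    matched_det = np.zeros(len(detections), dtype=bool)
    for i in order:
        det = detections[i]
        best_j, best_ov = -1, -1.0
        for j, ann in enumerate(annotations):
            if taken[j]:
                continue
            if class_aware and ann.class_label != det.argmax_class:
                continue
            if jac[i, j] >= iou_threshold and jac[i, j] > best_ov:
                best_j, best_ov = j, jac[i, j]
        if best_j >= 0:
            taken[best_j] = True
            matched_det[i] = True
            pairs.append((det, annotations[best_j]))
            tp[annotations[best_j].class_label] += 1
    for i, det in enumerate(detections):
        if not matched_det[i]:
            fp[det.argmax_class] += 1
    for j, ann in enumerate(annotations):
        if not taken[j]:
            fn[ann.class_label] += 1
    return MatchResult(tp, fp, fn, tuple(pairs), class_aware)


def metrics(match: MatchResult) -> pd.DataFrame:
    """Per-class recall, precision, F1 and accuracy, plus a macro average.

    Zero-denominator metrics are NaN ("undefined") and excluded from the
    average row.  Accuracy uses (TP + TN) / |universe| where the universe is
    all evaluated objects: every annotation plus every unmatched detection,
    so TN for class ``c`` counts objects that are neither predicted nor
    referenced as ``c``.
    """
    rows = {}
    universe = sum(match.true_positives.values()) + sum(
        match.false_negatives.values()
    ) + sum(match.false_positives.values())
    for c in match.classes:
        tp, fp, fn = (
            match.true_positives.get(c, 0),
            match.false_positives.get(c, 0),
            match.false_negatives.get(c, 0),
        )
        recall = tp / (tp + fn) if tp + fn else math.nan
        precision = tp / (tp + fp) if tp + fp else math.nan
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision and recall and not (math.isnan(precision) or math.isnan(recall))
            else (0.0 if (tp + fn and tp + fp) else math.nan)
        )
        tn = universe - tp - fp - fn
        accuracy = (tp + tn) / universe if universe else math.nan
        rows[c] = {"recall": recall, "precision": precision, "f1": f1, "accuracy": accuracy}
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.loc["average"] = df.mean(skipna=True)
    return df


def confusion_matrix(
    pairs: Sequence[tuple[Detection, Annotation]], normalize: str = "row"
) -> pd.DataFrame:
    """Reference-class x predicted-class matrix from matched pairs.

    With ``normalize="row"`` each row sums to 100 (percentages of that
    reference class); ``normalize="none"`` returns raw counts.
    """
    if normalize not in ("row", "none"):
        raise ValueError(f"unknown normalize mode {normalize!r}")
    if not pairs:
        return pd.DataFrame()
    refs = [ann.class_label for _, ann in pairs]
    preds = [det.argmax_class for det, _ in pairs]
    labels = sorted(set(refs) | set(preds))
    mat = pd.crosstab(
        pd.Series(refs, name="reference"), pd.Series(preds, name="predicted")
    ).reindex(index=labels, columns=labels, fill_value=0)
    if normalize == "row":
        sums = mat.sum(axis=1)
        mat = mat.div(sums.replace(0, np.nan), axis=0) * 100
    return mat


def cohen_kappa(
    labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]
) -> tuple[float, str]:
    """Cohen's kappa between two raters, with its interpretation band.

    ``kappa = (p_o - p_e) / (1 - p_e)`` where ``p_o`` is the observed
    agreement and ``p_e`` the chance agreement from the marginal products.
    When both raters are constant and identical (``p_e = 1``) agreement is
    perfect but chance-uncorrectable; kappa is defined as 1 with a warning.
    """
    if len(labels_a) != len(labels_b) or len(labels_a) == 0:
        raise ValueError("label sequences must be non-empty and equal-length")
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    n = len(a)
    p_o = float((a.values == b.values).mean())
    cats = sorted(set(a) | set(b), key=repr)
    p_e = sum(
        (a == c).sum() / n * (b == c).sum() / n for c in cats
    )
    if p_e >= 1.0 - 1e-15:
        warnings.warn(
            "both raters are constant and identical (p_e = 1); kappa defined as 1",
            RuntimeWarning,
            stacklevel=2,
        )
        kappa = 1.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), kappa_band(kappa)


def kappa_band(kappa: float) -> str:
    """Conventional agreement band for a kappa value.

    Cut points 0.20 / 0.40 / 0.60 / 0.80, upper bounds inclusive:
    poor, fair, moderate, good, excellent.
    """
    for upper, name in KAPPA_BANDS:
        if kappa <= upper + 1e-12:
            return name
    return "excellent"


@dataclass(frozen=True)
class NDCReport:
    """Nucleated differential cell count report.

    ``percentages`` are over the counted total and sum to 100 whenever the
    total is positive; ``adequate`` is True only when at least
    ``min_cells`` cells were counted (the >=500-cell adequacy rule).
    """

    counts: dict[int, int]
    percentages: dict[int, float]
    total: int
    adequate: bool
    min_cells: int = 500


def ndc_report(
    detections: Sequence[Detection] | Mapping[int, int],
    class_names: Mapping[int, str] | None = None,
    exclude: Sequence[int] = (),
    min_cells: int = 500,
) -> NDCReport:
    """Differential count over classified detections (or raw counts).

    ``exclude`` lists non-countable categories (e.g. megakaryocytes) removed
    before percentages are formed.  The report is flagged inadequate when
    fewer than ``min_cells`` cells remain.
    """
    if isinstance(detections, Mapping):
        counts = {int(c): int(n) for c, n in detections.items()}
    else:
        counts = {}
        for d in detections:
            counts[d.argmax_class] = counts.get(d.argmax_class, 0) + 1
    counts = {c: n for c, n in sorted(counts.items()) if c not in set(exclude)}
    total = sum(counts.values())
    percentages = {c: 100.0 * n / total for c, n in counts.items()} if total else {}
    return NDCReport(
        counts=counts,
        percentages=percentages,
        total=total,
        adequate=total >= min_cells,
        min_cells=min_cells,
    )


def pr_auc(
    detections: Sequence[Detection],
    annotations: Sequence[Annotation],
    iou_threshold: float = 0.5,
    class_aware: bool = True,
) -> float:
    """Area under the interpolated precision-recall curve.

    Detections are matched once at ``iou_threshold`` (greedy by score); the
    PR curve is traced by sweeping the score cut across all detections, the
    precision envelope is interpolated (precision at each recall is the
    maximum at any higher score), and the area is the sum over recall
    increments.  Returns NaN when there are no annotations.
    """
    if not annotations:
        return math.nan
    if not detections:
        return 0.0
    match = match_detections(detections, annotations, iou_threshold, class_aware)
    matched_dets = {id(det) for det, _ in match.pairs}
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))
    tp_cum = np.cumsum([1 if id(detections[i]) in matched_dets else 0 for i in order])
    fp_cum = np.cumsum([0 if id(detections[i]) in matched_dets else 1 for i in order])
    recall = tp_cum / len(annotations)
    precision = tp_cum / (tp_cum + fp_cum)
    # interpolated precision envelope
    precision = np.maximum.accumulate(precision[::-1])[::-1]
    recall = np.concatenate([[0.0], recall])
    return float(np.sum(np.diff(recall) * precision))
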