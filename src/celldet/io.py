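"""COCO-style JSON serialization of annotations, candidates and detections.

Boxes are stored in COCO ``bbox`` convention ``[x_min, y_min, width,
height]`` and converted to corner form internally.  Detections additionally
carry a ``probs`` per-class probability vector; sample assignments are
annotations augmented with ``overlap``, ``stage``, ``label`` and ``weight``
fields.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Sequence

from .geometry import Box
from .reporting import Annotation
from .sampling import Candidate, SampleAssignment
from .suppression import Detection, SuppressionResult

__all__ = [
    "load_annotations",
    "save_annotations",
    "load_detections",
    "save_detections",
    "load_candidates",
    "save_assignments",
    "load_config",
]


def _load(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _dump(obj: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def load_annotations(path: str | Path) -> list[Annotation]:
    doc = _load(path)
    out = []
    for rec in doc.get("annotations", []):
        out.append(
            Annotation(
                box=Box.from_xywh(rec["bbox"]),
                class_label=int(rec["category_id"]),
                annotator=rec.get("annotator"),
            )
        )
    return out


def save_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    doc = {
        "annotations": [
            {
                "id": i,
                "bbox": a.box.to_xywh(),
                "category_id": a.class_label,
                **({"annotator": a.annotator} if a.annotator else {}),
            }
            for i, a in enumerate(annotations)
        ],
        "categories": [
            {"id": c} for c in sorted({a.class_label for a in annotations})
        ],
    }
    _dump(doc, path)


def load_detections(path: str | Path) -> list[Detection]:
    doc = _load(path)
    return [
        Detection(box=Box.from_xywh(rec["bbox"]), probs=tuple(rec["probs"]))
        for rec in doc.get("annotations", [])
    ]


def save_detections(detections: Sequence[Detection], path: str | Path) -> None:
    doc = {
        "annotations": [
            {
                "id": i,
                "bbox": d.box.to_xywh(),
                "category_id": d.argmax_class,
                "score": d.score,
                "probs": list(d.probs),
            }
            for i, d in enumerate(detections)
        ]
    }
    _dump(doc, path)


def save_suppression_result(result: SuppressionResult, path: str | Path) -> None:
    doc = {
        "kept": [
            {
                "bbox": d.box.to_xywh(),
                "category_id": d.argmax_class,
                "score": d.score,
                "probs": list(d.probs),
            }
            for d in result.kept
        ],
        "suppressed": [
            {
                "bbox": d.box.to_xywh(),
                "category_id": d.argmax_class,
                "score": d.score,
                "suppressed_by": supp,
            }
            for d, supp in result.suppressed
        ],
    }
    _dump(doc, path)


def load_candidates(path: str | Path) -> list[Candidate]:
    doc = _load(path)
    out = []
    for rec in doc.get("annotations", []):
        out.append(
            Candidate(
                box=Box.from_xywh(rec["bbox"]),
                score=float(rec.get("score", 0.0)),
                overlap=float(rec.get("overlap", 0.0)),
                matched_annotation=rec.get("matched_annotation"),
            )
        )
    return out


def save_assignments(
    assignments: Sequence[SampleAssignment], path: str | Path
) -> None:
    doc = {
        "annotations": [
            {
                "id": i,
                "bbox": a.candidate.box.to_xywh(),
                "score": a.candidate.score,
                "overlap": a.candidate.overlap,
                "stage": a.stage,
                "label": a.label.value,
                "weight": a.weight,
            }
            for i, a in enumerate(assignments)
        ]
    }
    _dump(doc, path)


def load_config(path: str | Path) -> dict:
    """Plain-JSON threshold/config file loader."""
    return _load(path)
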