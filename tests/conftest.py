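import numpy as np
import pytest

from celldet import Box, Detection


def pixel_jaccard(a: Box, b: Box) -> float:
    """Independent integer-rasterization Jaccard oracle.

    Enumerates member pixels of each box under the half-open convention
    (pixel (x, y) belongs to a box iff x_min <= x < x_max etc.) and counts
    set intersection over union.  Valid only for integer-coordinate boxes.
    """
    pa = {
        (x, y)
        for x in range(int(a.x_min), int(a.x_max))
        for y in range(int(a.y_min), int(a.y_max))
    }
    pb = {
        (x, y)
        for x in range(int(b.x_min), int(b.x_max))
        for y in range(int(b.y_min), int(b.y_max))
    }
    return len(pa & pb) / len(pa | pb)


def random_box(rng: np.random.Generator, frame: float = 100.0, max_side: float = 30.0) -> Box:
    w = rng.uniform(2, max_side)
    h = rng.uniform(2, max_side)
    x = rng.uniform(0, frame - w)
    y = rng.uniform(0, frame - h)
    return Box(x, y, x + w, y + h)


def random_detections(
    rng: np.random.Generator, n: int, n_classes: int = 5, frame: float = 60.0
) -> list[Detection]:
    """Clustered random detections with plenty of mutual overlap."""
    dets = []
    for _ in range(n):
        box = random_box(rng, frame=frame, max_side=25.0)
        probs = rng.dirichlet(np.full(n_classes, 0.8))
        dets.append(Detection(box=box, probs=tuple(probs)))
    return dets


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
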