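"""Adaptive, data-oriented learning-rate schedules.

The adaptive schedule derives its step length from the size of the training
data rather than from fixed iteration milestones.  With ``I`` training images
of ``w x h`` pixels tiled into ``q x q`` patches, the data holds

    N = I * ceil(w / q) * ceil(h / q)

patches (data augmentation excluded).  The learning-rate multiplier at
iteration ``L`` is

    r(L) = max(0, 1 - floor(L / step) * alpha),

a staircase that starts at 1 and drops by ``alpha`` (default 10%) each time
``step`` iterations complete.  The step length is ``step = N / alpha`` by
default, so the decay horizon grows with the data; the alternative reading
``step = alpha * N`` is available via ``interpretation="proportional"``.
A fixed milestone schedule (the conventional 160k/240k baseline) is included
for comparison.
"""

from __future__ import annotations

import math
from typing import Iterator

__all__ = ["AdaptiveSchedule", "FixedStepSchedule"]


class AdaptiveSchedule:
    """Learning-rate multiplier schedule scaled to the training-data size.

    Parameters
    ----------
    n_images
        Number of training images ``I`` (> 0).
    image_width, image_height
        Image size ``w x h`` in pixels (> 0).
    patch_side
        Unit patch side ``q`` in pixels (> 0).  Non-divisible sizes use
        ceiling division, matching the tiling convention.
    alpha
        Step fraction in (0, 1]; each completed step lowers the multiplier
        by ``alpha``.  Default 0.1.
    interpretation
        ``"inverse"`` (default): ``step = N / alpha``; ``"proportional"``:
        ``step = alpha * N``.
    """

    def __init__(
        self,
        n_images: int,
        image_width: int,
        image_height: int,
        patch_side: int,
        alpha: float = 0.1,
        interpretation: str = "inverse",
    ):
        if min(n_images, image_width, image_height, patch_side) <= 0:
            raise ValueError("n_images, image size and patch_side must be positive")
        if not 0 < alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {alpha}")
        if interpretation not in ("inverse", "proportional"):
            raise ValueError(f"unknown interpretation {interpretation!r}")
        self.n_images = n_images
        self.image_width = image_width
        self.image_height = image_height
        self.patch_side = patch_side
        self.alpha = alpha
        self.interpretation = interpretation

    @property
    def n_patches(self) -> int:
        """Total unit patches N in the training data (augmentation excluded)."""
        return (
            self.n_images
            * math.ceil(self.image_width / self.patch_side)
            * math.ceil(self.image_height / self.patch_side)
        )

    @property
    def step_size(self) -> float:
        """Iterations per learning-rate step."""
        if self.interpretation == "inverse":
            return self.n_patches / self.alpha
        return self.alpha * self.n_patches

    def multiplier(self, iteration: float) -> float:
        """Multiplier ``r`` at the given iteration; clamped below at 0."""
        if iteration < 0:
            raise ValueError(f"iteration must be >= 0, got {iteration}")
        return max(0.0, 1.0 - math.floor(iteration / self.step_size) * self.alpha)

    def table(self, max_iteration: int, stride: int = 1) -> Iterator[tuple[int, float]]:
        """Yield ``(iteration, multiplier)`` rows up to ``max_iteration``."""
        for it in range(0, max_iteration + 1, stride):
            yield it, self.multiplier(it)


class FixedStepSchedule:
    """Conventional milestone schedule: cut the rate by 10% at fixed points.

    The baseline counterpart to :class:`AdaptiveSchedule`: the multiplier is
    ``(1 - cut) ** k`` after passing ``k`` milestones (default 160k and 240k
    iterations, 10% cuts), independent of the training-data size.
    """

    def __init__(self, milestones: tuple[int, ...] = (160_000, 240_000), cut: float = 0.1):
        if not 0 < cut < 1:
            raise ValueError(f"cut must be in (0, 1), got {cut}")
        self.milestones = tuple(sorted(milestones))
        self.cut = cut

    def multiplier(self, iteration: float) -> float:
        if iteration < 0:
            raise ValueError(f"iteration must be >= 0, got {iteration}")
        passed = sum(iteration >= m for m in self.milestones)
        return (1.0 - self.cut) ** passed

    def table(self, max_iteration: int, stride: int = 1) -> Iterator[tuple[int, float]]:
        for it in range(0, max_iteration + 1, stride):
            yield it, self.multiplier(it)
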