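"""Jaccard-gated patch selection, augmentation, and histogram-specification
color normalization.

Patch selection gates augmentation on the *positive fraction* of a patch: the
fraction of its area covered by the union of reference annotation boxes.  Only
patches with positive fraction > 0 (i.e. containing some annotated cell) are
augmented.  The augmentation set comprises small-angle rotations (5°..25° in
5° steps), right-angle rotations (90°, 180°, 270°), horizontal/vertical
mirror flips, and photometric jitter: multiplicative contrast and saturation
in ±20% and additive brightness in ±12.5% on a [0, 1] intensity scale.

Normalization is histogram specification: each channel of an input image is
mapped through its own empirical CDF and then through the inverse of a
reference CDF (quantile matching), aligning the image's color distribution
with the reference distribution.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from skimage import color as skcolor
from skimage import transform as sktransform
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import Box, TileGrid

__all__ = [
    "PatchSelection",
    "AugmentationSpec",
    "ReferenceHistogram",
    "HistogramSpecifier",
    "positive_fraction",
    "select_for_augmentation",
    "augment",
    "fit_reference_histogram",
    "histogram_specify",
    "default_reference_histogram",
]

N_LEVELS = 256


@dataclass(frozen=True)
class PatchSelection:
    """A tile with its positive fraction and the resulting selection flag."""

    patch: Box
    positive_fraction: float
    selected: bool


@dataclass(frozen=True)
class AugmentationSpec:
    """Configuration of the augmentation operation set.

    ``rotation_angles`` defaults to the five 5°-step rotations plus the three
    right-angle rotations.  ``contrast_range`` and ``saturation_range`` are
    the half-widths of multiplicative jitter factors drawn from
    ``[1 - r, 1 + r]``; ``brightness_range`` is the half-width of an additive
    offset on a [0, 1] scale.  ``n_jitter`` photometric copies are emitted
    per patch.  All randomness flows from ``seed``.
    """

    rotation_angles: tuple[float, ...] = (5, 10, 15, 20, 25, 90, 180, 270)
    flips: tuple[str, ...] = ("horizontal", "vertical")
    contrast_range: float = 0.2
    saturation_range: float = 0.2
    brightness_range: float = 0.125
    n_jitter: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contrast_range <= 0.2:
            raise ValueError("contrast_range must lie in [0, 0.2]")
        if not 0 <= self.saturation_range <= 0.2:
            raise ValueError("saturation_range must lie in [0, 0.2]")
        if not 0 <= self.brightness_range <= 0.125:
            raise ValueError("brightness_range must lie in [0, 0.125]")
        for f in self.flips:
            if f not in ("horizontal", "vertical"):
                raise ValueError(f"unknown flip axis {f!r}")

    @property
    def n_copies(self) -> int:
        """Number of augmented copies emitted per patch."""
        n = len(self.rotation_angles) + len(self.flips)
        if self.contrast_range or self.saturation_range or self.brightness_range:
            n += self.n_jitter
        return max(n, 1)


@dataclass(frozen=True)
class ReferenceHistogram:
    """Per-channel cumulative intensity distribution on a [0, 1] level grid.

    ``levels`` has shape (L,), ``cdfs`` shape (C, L); each CDF is
    non-decreasing and ends at 1.
    """

    levels: np.ndarray
    cdfs: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        cdfs = np.atleast_2d(np.asarray(self.cdfs, dtype=float))
        if np.any(np.diff(cdfs, axis=1) < -1e-12):
            raise ValueError("reference CDFs must be non-decreasing")
        if not np.allclose(cdfs[:, -1], 1.0):
            raise ValueError("reference CDFs must end at 1")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "cdfs", cdfs)

    @property
    def n_channels(self) -> int:
        return self.cdfs.shape[0]

    def median(self, channel: int) -> float:
        """Level at which the channel CDF crosses 0.5."""
        return float(np.interp(0.5, self.cdfs[channel], self.levels))

    # plain-text (TSV) serialization --------------------------------------
    def to_text(self) -> str:
        header = "level\t" + "\t".join(f"cdf_{c}" for c in range(self.n_channels))
        lines = [header]
        for i, lv in enumerate(self.levels):
            vals = "\t".join(f"{self.cdfs[c, i]:.10g}" for c in range(self.n_channels))
            lines.append(f"{lv:.10g}\t{vals}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ReferenceHistogram":
        arr = np.loadtxt(io.StringIO(text), skiprows=1)
        return cls(levels=arr[:, 0], cdfs=arr[:, 1:].T)


def positive_fraction(patch: Box, annotations: Sequence[Box]) -> float:
    """Fraction of the patch area covered by the union of annotation boxes.

    Overlapping annotations are not double-counted: the numerator is the area
    of ``(union of annotation boxes) ∩ patch``.
    """
    if not annotations:
        return 0.0
    patch_poly = shapely_box(*patch.as_corners())
    union = unary_union([shapely_box(*a.as_corners()) for a in annotations])
    return float(patch_poly.intersection(union).area / patch_poly.area)


def select_for_augmentation(
    grid: TileGrid, annotations: Sequence[Box]
) -> list[PatchSelection]:
    """Flag every tile whose positive fraction is > 0 for augmentation."""
    out = []
    for tile in grid.tiles:
        pf = positive_fraction(tile, annotations)
        out.append(PatchSelection(patch=tile, positive_fraction=pf, selected=pf > 0))
    return out


def _as_float_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return img


def _rotate(img: np.ndarray, angle: float) -> np.ndarray:
    # right angles are exact (no interpolation, no exposed corners)
    if angle % 90 == 0:
        return np.ascontiguousarray(np.rot90(img, k=int(angle // 90) % 4))
    # fill exposed corners with the per-channel median background color
    if img.ndim == 2:
        return sktransform.rotate(img, angle, cval=float(np.median(img)))
    chans = [
        sktransform.rotate(img[..., c], angle, cval=float(np.median(img[..., c])))
        for c in range(img.shape[-1])
    ]
    return np.stack(chans, axis=-1)


def _jitter(img: np.ndarray, spec: AugmentationSpec, rng: np.random.Generator) -> np.ndarray:
    out = img.copy()
    cf = rng.uniform(1 - spec.contrast_range, 1 + spec.contrast_range)
    sf = rng.uniform(1 - spec.saturation_range, 1 + spec.saturation_range)
    bo = rng.uniform(-spec.brightness_range, spec.brightness_range)
    # contrast: scale deviation from the mean intensity
    out = out.mean() + cf * (out - out.mean())
    out = np.clip(out, 0, 1)
    if out.ndim == 3 and out.shape[-1] == 3 and spec.saturation_range:
        hsv = skcolor.rgb2hsv(out)
        hsv[..., 1] = np.clip(hsv[..., 1] * sf, 0, 1)
        out = skcolor.hsv2rgb(hsv)
    return np.clip(out + bo, 0, 1)


def augment(patch_image: np.ndarray, spec: AugmentationSpec) -> list[np.ndarray]:
    """Emit the configured augmentation copies of one patch.

    Rotations, flips and photometric jitters are emitted independently (not
    composed).  Deterministic given ``spec.seed``; all outputs are clipped to
    [0, 1].  An identity spec (no angles, no flips, zero ranges) yields a
    single unchanged copy.
    """
    img = _as_float_image(patch_image)
    rng = np.random.default_rng(spec.seed)
    copies: list[np.ndarray] = []
    for angle in spec.rotation_angles:
        copies.append(np.clip(_rotate(img, angle), 0, 1))
    for f in spec.flips:
        copies.append(np.flip(img, axis=1 if f == "horizontal" else 0).copy())
    if spec.contrast_range or spec.saturation_range or spec.brightness_range:
        for _ in range(spec.n_jitter):
            copies.append(_jitter(img, spec, rng))
    if not copies:
        copies.append(img.copy())
    return copies


def transform_box(
    box: Box,
    width: float,
    height: float,
    *,
    angle: float = 0.0,
    flip: str | None = None,
) -> Box | None:
    """Map an annotation box through the same rotation/flip as its patch.

    Rotation is counter-clockwise about the patch center (matching the image
    rotation); the transformed box is the axis-aligned bounding box of the
    rotated corners, clipped to the patch.  Returns ``None`` when the clipped
    box is empty.
    """
    xs = np.array([box.x_min, box.x_max, box.x_min, box.x_max])
    ys = np.array([box.y_min, box.y_min, box.y_max, box.y_max])
    if flip == "horizontal":
        xs = width - xs
    elif flip == "vertical":
        ys = height - ys
    elif flip is not None:
        raise ValueError(f"unknown flip axis {flip!r}")
    if angle % 360 != 0:
        th = np.deg2rad(angle)
        cx, cy = width / 2, height / 2
        xr = cx + (xs - cx) * np.cos(th) + (ys - cy) * np.sin(th)
        yr = cy - (xs - cx) * np.sin(th) + (ys - cy) * np.cos(th)
        xs, ys = xr, yr
    x0, x1 = np.clip([xs.min(), xs.max()], 0, width)
    y0, y1 = np.clip([ys.min(), ys.max()], 0, height)
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        return None
    return Box(float(x0), float(y0), float(x1), float(y1))


def _channels(img: np.ndarray) -> np.ndarray:
    """View an image as (C, n_pixels)."""
    if img.ndim == 2:
        return img.reshape(1, -1)
    return np.moveaxis(img, -1, 0).reshape(img.shape[-1], -1)


def fit_reference_histogram(images: Iterable[np.ndarray]) -> ReferenceHistogram:
    """Pool per-channel pixel histograms over images into a reference CDF.

    All images must share the channel count; intensities are binned on a
    uniform 256-level grid over [0, 1].
    """
    images = [_as_float_image(im) for im in images]
    if not images:
        raise ValueError("need at least one image to fit a reference histogram")
    n_chan = _channels(images[0]).shape[0]
    edges = np.linspace(0, 1, N_LEVELS + 1)
    counts = np.zeros((n_chan, N_LEVELS))
    for im in images:
        ch = _channels(im)
        if ch.shape[0] != n_chan:
            raise ValueError("images must share the channel count")
        for c in range(n_chan):
            counts[c] += np.histogram(ch[c], bins=edges)[0]
    cdfs = np.cumsum(counts, axis=1) / counts.sum(axis=1, keepdims=True)
    # level assigned to each bin is its upper edge: CDF(x) = P(I <= x)
    return ReferenceHistogram(levels=edges[1:], cdfs=cdfs)


def histogram_specify(image: np.ndarray, ref: ReferenceHistogram) -> np.ndarray:
    """Match the image's per-channel distribution to the reference CDF.

    Each pixel is sent through the channel's empirical CDF (mid-rank
    estimate) and then through the inverse reference CDF.  A constant channel
    carries no distributional information and is mapped to the reference
    median.
    """
    img = _as_float_image(image)
    ch = _channels(img)
    if ch.shape[0] != ref.n_channels:
        raise ValueError(
            f"image has {ch.shape[0]} channels but reference has {ref.n_channels}"
        )
    out = np.empty_like(ch)
    n = ch.shape[1]
    for c in range(ch.shape[0]):
        vals = ch[c]
        if np.ptp(vals) == 0:
            out[c] = ref.median(c)
            continue
        order = np.argsort(vals, kind="stable")
        ranks = np.empty(n)
        ranks[order] = np.arange(n)
        # mid-rank CDF estimate, then average ties so equal inputs map equally
        u = (ranks + 0.5) / n
        uniq, inv = np.unique(vals, return_inverse=True)
        u = np.bincount(inv, weights=u) / np.bincount(inv)
        u = u[inv]
        out[c] = np.interp(u, ref.cdfs[c], ref.levels)
    if img.ndim == 2:
        return out.reshape(img.shape)
    return np.moveaxis(out.reshape(img.shape[-1], *img.shape[:-1]), 0, -1)


def default_reference_histogram(n_channels: int = 3) -> ReferenceHistogram:
    """Synthetic natural-image-like reference distribution.

    A stand-in reference with smooth unimodal per-channel intensity
    distributions whose means and spreads mimic broad natural-image
    statistics (red slightly brighter than green than blue).  Deterministic
    closed form; users with a corpus should fit their own reference with
    :func:`fit_reference_histogram`.
    """
    params = [(4.0, 3.2), (4.0, 3.6), (3.6, 4.0), (4.0, 4.0)]
    levels = np.linspace(0, 1, N_LEVELS)
    cdfs = np.stack(
        [stats.beta(a, b).cdf(levels) for a, b in params[:n_channels]]
    )
    cdfs /= cdfs[:, -1:]
    return ReferenceHistogram(levels=levels, cdfs=cdfs)


class HistogramSpecifier(BaseEstimator, TransformerMixin):
    """Histogram-specification normalizer in the scikit-learn idiom.

    ``fit`` pools the reference CDF from a sequence of images (or adopts a
    ready-made :class:`ReferenceHistogram` passed as ``reference``);
    ``transform`` quantile-matches each input image to it.

    Parameters
    ----------
    reference
        Optional pre-fitted :class:`ReferenceHistogram`.  When given, ``fit``
        ignores its input images.  When omitted and ``fit`` receives no
        images, the packaged synthetic natural-image-like reference is used.

    Attributes
    ----------
    reference_ : ReferenceHistogram
        The reference distribution used by :meth:`transform`.
    """

    def __init__(self, reference: ReferenceHistogram | None = None):
        self.reference = reference

    def fit(self, X: Sequence[np.ndarray] | None = None, y=None) -> "HistogramSpecifier":
        if self.reference is not None:
            self.reference_ = self.reference
        elif X:
            self.reference_ = fit_reference_histogram(X)
        else:
            self.reference_ = default_reference_histogram()
        return self

    def transform(self, X: Sequence[np.ndarray] | np.ndarray) -> list[np.ndarray]:
        if not hasattr(self, "reference_"):
            raise RuntimeError("HistogramSpecifier must be fitted before transform")
        if isinstance(X, np.ndarray) and X.ndim <= 3:
            X = [X]
        return [histogram_specify(im, self.reference_) for im in X]
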