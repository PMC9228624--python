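"""Probability-density binarization and mask application.

The outline of the extracted structures is obtained by thresholding the
scale-band image at a value chi chosen from the intensity probability
distribution: keep the brightest ``top_fraction`` of the structure pixels
(pixels with positive intensity). A second, fixed threshold (chi = 1)
binarizes the deconvolved outline, and the final product multiplies the
expanded image by that logic matrix — extraction, never re-scaling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import EmptyStructureError, ParameterError
from .stack import ImageStack

__all__ = [
    "BinaryMask",
    "threshold_from_top_fraction",
    "binarize",
    "apply_mask",
    "TopFractionBinarizer",
    "FixedThresholdBinarizer",
]


@dataclass
class BinaryMask:
    """A logic matrix together with the threshold that produced it."""

    data: np.ndarray
    threshold_used: float
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.isin(self.data, (0, 1)).all():
            raise ParameterError("mask entries must be 0 or 1")
        self.data = self.data.astype(np.uint8)

    @property
    def support_size(self) -> int:
        return int(self.data.sum())


def threshold_from_top_fraction(image: np.ndarray, top_fraction: float,
                                population: str = "positive") -> float:
    """Threshold chi retaining the brightest ``top_fraction`` of pixels.

    chi is the k-th largest intensity with k = ceil(top_fraction * N) over
    the reference population — by default the N pixels of positive
    intensity (the structure pixels after the scale-band split), i.e. the
    (1 - top_fraction) quantile of the structure-intensity distribution;
    ``population="all"`` ranks against every pixel instead. At least k
    pixels satisfy intensity >= chi (more under ties).
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ParameterError("top_fraction must be in (0, 1]")
    if population not in ("positive", "all"):
        raise ParameterError("population must be 'positive' or 'all'")
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ParameterError("image is empty")
    if np.all(image <= 0):
        raise EmptyStructureError(
            "cannot choose a threshold: image has no positive intensity")
    pool = image[image > 0] if population == "positive" else image.ravel()
    k = math.ceil(top_fraction * pool.size)
    return float(np.partition(pool, pool.size - k)[pool.size - k])


def binarize(image: np.ndarray, chi: float, source_tag: str = "") -> BinaryMask:
    """Logic matrix: 1 where intensity >= chi, else 0 (inclusive at chi)."""
    image = np.asarray(image, dtype=float)
    if not np.isfinite(chi):
        raise ParameterError("threshold chi must be finite")
    mask = (image >= chi).astype(np.uint8)
    if mask.sum() == 0:
        warnings.warn(
            f"binarization at chi={chi} produced an empty mask (image max "
            f"{image.max():.4g}); structure may be over-shrunken", stacklevel=2)
    return BinaryMask(mask, threshold_used=float(chi), source_tag=source_tag)


def apply_mask(expanded, mask) -> np.ndarray | ImageStack:
    """Elementwise product of an image (or stack) with binary mask(s).

    Surviving intensities are exactly those of the input: the operation
    extracts, it never rescales. ``mask`` may be a BinaryMask / 2D array for
    a single slice, or a sequence of per-slice masks for a stack.
    """
    if isinstance(expanded, ImageStack):
        masks = mask if isinstance(mask, (list, tuple)) else [mask] * expanded.n_slices
        if len(masks) != expanded.n_slices:
            raise ParameterError("need one mask per slice")
        out = np.empty_like(expanded.data)
        for z in range(expanded.n_slices):
            out[z] = apply_mask(expanded.data[z], masks[z])
        return expanded.with_data(out)
    image = np.asarray(expanded, dtype=float)
    mdata = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    if mdata.shape != image.shape:
        raise ParameterError(
            f"mask shape {mdata.shape} does not match image shape {image.shape}")
    return image * mdata


class TopFractionBinarizer(TransformerMixin, BaseEstimator):
    """Binarize each slice at its own top-fraction intensity threshold.

    After ``transform``, ``thresholds_`` holds the resolved chi per slice.
    """

    def __init__(self, top_fraction: float = 0.15, population: str = "positive"):
        self.top_fraction = top_fraction
        self.population = population

    def fit(self, X, y=None):
        if not (0.0 < self.top_fraction <= 1.0):
            raise ParameterError("top_fraction must be in (0, 1]")
        if self.population not in ("positive", "all"):
            raise ParameterError("population must be 'positive' or 'all'")
        self.fitted_ = True
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 2
        stack = X[None, ...] if squeeze else X
        out = np.empty(stack.shape, dtype=np.uint8)
        self.thresholds_ = []
        for z in range(stack.shape[0]):
            chi = threshold_from_top_fraction(stack[z], self.top_fraction,
                                              self.population)
            out[z] = binarize(stack[z], chi, source_tag="post-DWT").data
            self.thresholds_.append(chi)
        return out[0] if squeeze else out


class FixedThresholdBinarizer(TransformerMixin, BaseEstimator):
    """Binarize at a fixed threshold (default 1, the post-deconvolution cut)."""

    def __init__(self, threshold: float = 1.0):
        self.threshold = threshold

    def fit(self, X, y=None):
        if not np.isfinite(self.threshold):
            raise ParameterError("threshold must be finite")
        self.fitted_ = True
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        return (X >= self.threshold).astype(np.uint8)
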