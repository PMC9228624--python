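"""2D discrete wavelet decomposition and scale-band reconstruction.

A structure of characteristic size between ``2**n_low`` and ``2**n_high``
pixels lives in the detail sub-bands of decomposition orders n_low..n_high
of a dyadic multiresolution analysis. Reconstructing from those orders only
(approximation and all other detail orders zeroed) extracts the structures
of the desired scale, discarding both high-frequency noise (orders below
n_low) and slowly varying illumination (the approximation and any orders
above n_high).

The transform itself is the standard separable Mallat scheme (PyWavelets,
symmetric boundary extension); the default analysis uses the Coiflet-3
wavelet to order 6 and keeps orders 4-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ParameterError

__all__ = [
    "WaveletDecomposition",
    "BandSelection",
    "decompose",
    "reconstruct",
    "reconstruct_band",
    "characteristic_band_for_width",
    "WaveletBandExtractor",
]


@dataclass(frozen=True)
class BandSelection:
    """Inclusive range [n_low, n_high] of decomposition orders to keep."""

    n_low: int = 4
    n_high: int = 6

    def __post_init__(self) -> None:
        if not (1 <= self.n_low <= self.n_high):
            raise ParameterError("require 1 <= n_low <= n_high")


@dataclass
class WaveletDecomposition:
    """Multi-level 2D DWT coefficients plus the analysis filter pair.

    ``details[n]`` (n = 1 finest ... max_level coarsest) holds the three
    orientation sub-bands (horizontal, vertical, diagonal) of order n;
    ``approximation`` is the order-``max_level`` low-pass residue.
    """

    wavelet_name: str
    max_level: int
    approximation: np.ndarray
    details: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]
    original_shape: tuple[int, int]
    mode: str = "symmetric"

    @property
    def lowpass_filter(self) -> np.ndarray:
        """Analysis low-pass filter g[k]."""
        return np.asarray(pywt.Wavelet(self.wavelet_name).dec_lo)

    @property
    def highpass_filter(self) -> np.ndarray:
        """Analysis high-pass filter h[k]."""
        return np.asarray(pywt.Wavelet(self.wavelet_name).dec_hi)

    def _to_coeff_list(self, *, keep_approx: bool,
                       keep_levels: set[int]) -> list:
        approx = (self.approximation if keep_approx
                  else np.zeros_like(self.approximation))
        coeffs: list = [approx]
        for n in range(self.max_level, 0, -1):
            trio = self.details[n]
            if n in keep_levels:
                coeffs.append(tuple(trio))
            else:
                coeffs.append(tuple(np.zeros_like(c) for c in trio))
        return coeffs


def decompose(image: np.ndarray, wavelet_name: str = "coif3",
              max_level: int = 6) -> WaveletDecomposition:
    """Multi-level separable 2D DWT of a single image.

    Warns (but proceeds) when ``max_level`` exceeds the level advisable for
    the image size and filter length; symmetric extension keeps the
    transform perfectly invertible regardless.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ParameterError("decompose expects a nonempty 2D image")
    if max_level < 1:
        raise ParameterError("max_level must be >= 1")
    try:
        wav = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        families = ", ".join(pywt.families(short=True))
        raise ParameterError(
            f"unknown wavelet {wavelet_name!r}; supported families: "
            f"{families}") from exc
    advisable = pywt.dwt_max_level(min(image.shape), wav.dec_len)
    if max_level > advisable:
        warnings.warn(
            f"decomposition level {max_level} exceeds the advisable maximum "
            f"{advisable} for shape {image.shape} and wavelet "
            f"{wavelet_name}; boundary effects grow at the coarsest orders",
            stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # pywt repeats the level warning
        coeffs = pywt.wavedec2(image, wav, mode="symmetric", level=max_level)
    details = {}
    for i, trio in enumerate(coeffs[1:], start=1):
        n = max_level - i + 1  # coeffs[1] is the coarsest order
        details[n] = tuple(np.asarray(c) for c in trio)
    return WaveletDecomposition(
        wavelet_name=wavelet_name,
        max_level=max_level,
        approximation=np.asarray(coeffs[0]),
        details=details,
        original_shape=image.shape,
    )


def _inverse(dec: WaveletDecomposition, coeffs: list) -> np.ndarray:
    out = pywt.waverec2(coeffs, pywt.Wavelet(dec.wavelet_name), mode=dec.mode)
    h, w = dec.original_shape
    return out[:h, :w]


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Full inverse transform (perfect reconstruction of the input)."""
    coeffs = dec._to_coeff_list(keep_approx=True,
                                keep_levels=set(range(1, dec.max_level + 1)))
    return _inverse(dec, coeffs)


def reconstruct_band(dec: WaveletDecomposition, band: BandSelection,
                     clip_negative: bool = False) -> np.ndarray:
    """Reconstruct only the detail orders in ``band`` (approximation zeroed).

    The result is the scale-band image M_d; the complementary image
    (input minus the result) carries the undesired structures. Detail-only
    reconstructions oscillate around zero; ``clip_negative`` clamps at 0 for
    downstream intensity thresholding.
    """
    if band.n_high > dec.max_level:
        raise ParameterError(
            f"band {band.n_low}..{band.n_high} exceeds decomposition level "
            f"{dec.max_level}")
    keep = set(range(band.n_low, band.n_high + 1))
    out = _inverse(dec, dec._to_coeff_list(keep_approx=False, keep_levels=keep))
    if clip_negative:
        out = np.clip(out, 0.0, None)
    return out


def characteristic_band_for_width(width_px_min: float, width_px_max: float,
                                  max_level: int = 6) -> BandSelection:
    """Decomposition orders covering structures of the given pixel widths.

    n_low = floor(log2(min width)), n_high = ceil(log2(max width)), clamped
    to [1, max_level]; e.g. widths 16-64 px map to orders 4-6.
    """
    if width_px_min <= 0 or width_px_max < width_px_min:
        raise ParameterError("require 0 < width_px_min <= width_px_max")
    n_low = int(np.clip(np.floor(np.log2(width_px_min)), 1, max_level))
    n_high = int(np.clip(np.ceil(np.log2(width_px_max)), 1, max_level))
    return BandSelection(n_low=n_low, n_high=max(n_high, n_low))


class WaveletBandExtractor(TransformerMixin, BaseEstimator):
    """Slice-wise scale-band extraction transformer.

    transform(X) decomposes each slice of a 2D image or (z, y, x) stack and
    returns the reconstruction restricted to detail orders
    [n_low, n_high], negatives clipped at 0 by default.
    """

    def __init__(self, wavelet: str = "coif3", max_level: int = 6,
                 n_low: int = 4, n_high: int = 6, clip_negative: bool = True):
        self.wavelet = wavelet
        self.max_level = max_level
        self.n_low = n_low
        self.n_high = n_high
        self.clip_negative = clip_negative

    def fit(self, X, y=None):
        band = BandSelection(self.n_low, self.n_high)
        if band.n_high > self.max_level:
            raise ParameterError("n_high must not exceed max_level")
        self.band_ = band
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 2
        stack = X[None, ...] if squeeze else X
        out = np.empty_like(stack)
        for z in range(stack.shape[0]):
            dec = decompose(stack[z], self.wavelet, self.max_level)
            out[z] = reconstruct_band(dec, self.band_, self.clip_negative)
        return out[0] if squeeze else out
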