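"""Image-quality and resolution metrics: PSNR, SSIM, line-profile FWHM."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from ._constants import MAX_INTENSITY
from .errors import ParameterError, UndefinedFWHMError

__all__ = ["psnr", "ssim", "ProfileMeasurement", "line_profile", "fwhm"]


def _check_pair(reference, test):
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise ParameterError(
            f"shape mismatch: {reference.shape} vs {test.shape}")
    return reference, test


def psnr(reference: np.ndarray, test: np.ndarray,
         max_value: float = MAX_INTENSITY) -> float:
    """Peak signal-to-noise ratio 10*log10(max^2 / MSE), in dB.

    Identical images have zero MSE; the infinite PSNR is reported as the
    ``inf`` sentinel.
    """
    if max_value <= 0:
        raise ParameterError("max_value must be positive")
    reference, test = _check_pair(reference, test)
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_value ** 2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray,
         max_value: float = MAX_INTENSITY) -> float:
    """Mean structural similarity with the standard Wang et al. settings.

    11x11 Gaussian window (sigma 1.5), stabilizers C1 = (0.01 max)^2 and
    C2 = (0.03 max)^2, population (not sample) covariance.
    """
    reference, test = _check_pair(reference, test)
    if min(reference.shape) < 11:
        raise ParameterError("images must be at least 11 px per side for SSIM")
    return float(structural_similarity(
        reference, test, data_range=max_value, gaussian_weights=True,
        sigma=1.5, win_size=11, use_sample_covariance=False,
        K1=0.01, K2=0.03))


@dataclass
class ProfileMeasurement:
    """An intensity line profile with physical positions in nm."""

    positions_nm: np.ndarray
    intensities: np.ndarray
    peak_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions_nm.ndim != 1 or self.positions_nm.shape != self.intensities.shape:
            raise ParameterError("positions and intensities must be matching 1D arrays")
        if self.positions_nm.size < 3:
            raise ParameterError("profile needs at least 3 samples")
        if np.any(np.diff(self.positions_nm) <= 0):
            raise ParameterError("positions must be strictly increasing")
        self.peak_index = int(np.argmax(self.intensities))


def line_profile(image: np.ndarray, row: int, x0: int, x1: int,
                 pitch_nm: float) -> ProfileMeasurement:
    """Horizontal intensity profile image[row, x0:x1] with nm positions."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ParameterError("line_profile expects a 2D image")
    if not (0 <= row < image.shape[0]) or not (0 <= x0 < x1 <= image.shape[1]):
        raise ParameterError("profile window out of bounds")
    cols = np.arange(x0, x1)
    return ProfileMeasurement(cols * pitch_nm, image[row, x0:x1])


def _half_crossing(positions, values, half, peak, direction) -> float:
    """Position where the profile crosses ``half``, walking from the peak."""
    idx = range(peak - 1, -1, -1) if direction < 0 else range(peak + 1, len(values))
    prev = peak
    for i in idx:
        if values[i] < half:
            # linear interpolation between samples i (below) and prev (above)
            x0, x1 = positions[i], positions[prev]
            y0, y1 = values[i], values[prev]
            return x0 + (half - y0) / (y1 - y0) * (x1 - x0)
        prev = i
    raise UndefinedFWHMError(
        "profile does not cross half-maximum on "
        + ("the left" if direction < 0 else "the right"))


def fwhm(profile: ProfileMeasurement, baseline: float = 0.0,
         peak_index: int | None = None) -> float:
    """Full width at half maximum of a line profile, in nm.

    Half-maximum is ``baseline + (peak - baseline) / 2`` (the default
    baseline 0 suits background-subtracted images; pass e.g. the window
    minimum for profiles riding on a noise pedestal). Crossings on each side
    of the peak are located by linear interpolation between the adjacent
    samples; a profile that never crosses on one side has no FWHM and
    raises :class:`UndefinedFWHMError`.

    ``peak_index`` overrides the default global-maximum peak — useful when
    the structure position is known and noise spikes elsewhere in the
    window would otherwise be mistaken for the peak.
    """
    values = profile.intensities
    peak = profile.peak_index if peak_index is None else int(peak_index)
    if not (0 <= peak < values.size):
        raise ParameterError("peak_index out of range")
    peak_val = values[peak]
    if peak_val <= baseline:
        raise UndefinedFWHMError("peak does not rise above the baseline")
    half = baseline + (peak_val - baseline) / 2.0
    left = _half_crossing(profile.positions_nm, values, half, peak, -1)
    right = _half_crossing(profile.positions_nm, values, half, peak, +1)
    return float(right - left)
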