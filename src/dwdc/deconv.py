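"""Accelerated, damped Richardson-Lucy deconvolution of the structure outline.

The binarized outline M_edL is deconvolved against the system PSF (an
isotropic Gaussian of radius delta_r = xi * r_perp) to shrink it toward the
filament skeleton. Three refinements over plain Richardson-Lucy:

* damping — ratio deviations smaller than ``damping`` times the observed
  dynamic range are treated as exactly 1, so near-converged pixels stop
  updating and background noise is not amplified;
* acceleration — the scalar extrapolation factor
  f = <M_mid - M_k, M_k - M_{k-1}> / ||M_k - M_{k-1}||^2 (clamped to [0, 1))
  extrapolates each multiplicative step along the current update direction
  (vector extrapolation in the Biggs-Andrews sense);
* per-iteration clipping of negatives (extrapolation can undershoot zero).

Initialization is the observed mask itself, so exact zeros stay zero and the
estimate can only tighten the outline — the desired behavior for skeleton
extraction. A divergence guard aborts when the total intensity grows beyond
ten times the input (the over-processing failure mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._constants import RL_EPS
from .errors import EmptyStructureError, OverProcessingError, ParameterError
from .masking import BinaryMask
from .optics import OpticalModel, make_psf_2d

__all__ = [
    "LRConfig",
    "lr_step",
    "acceleration_factor",
    "richardson_lucy",
    "lr_deconvolve",
    "RichardsonLucyDeconvolver",
]

#: kernels wider than this use FFT convolution on a reflect-padded image
_FFT_KERNEL_SIZE = 15


@dataclass(frozen=True)
class LRConfig:
    """Deconvolution settings (defaults are the optimized values)."""

    k_max: int = 10
    damping: float = 0.01
    xi: float = 2.5
    truncation_sigmas: float = 3.0
    clamp_acceleration: bool = True
    accelerate: bool = True
    flat_init: bool = False

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ParameterError("k_max must be >= 1")
        if self.damping < 0:
            raise ParameterError("damping must be nonnegative")
        if self.xi <= 0:
            raise ParameterError("xi must be positive")


def _convolve(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2D convolution with reflective boundary handling.

    Direct convolution for compact kernels; for wide kernels the image is
    reflect-padded by the kernel half-width and convolved in the frequency
    domain, which is equivalent up to floating-point error.
    """
    if max(kernel.shape) <= _FFT_KERNEL_SIZE:
        return ndimage.convolve(image, kernel, mode="reflect")
    py, px = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((py, py), (px, px)), mode="reflect")
    out = signal.fftconvolve(padded, kernel, mode="same")
    return out[py:py + image.shape[0], px:px + image.shape[1]]


def _check_psf(psf: np.ndarray) -> np.ndarray:
    psf = np.asarray(psf, dtype=float)
    if abs(psf.sum() - 1.0) > 1e-8:
        raise ParameterError("PSF must be normalized to unit sum")
    if np.any(psf < 0):
        raise ParameterError("PSF must be nonnegative")
    return psf


def lr_step(estimate: np.ndarray, observed: np.ndarray, psf: np.ndarray,
            damping: float = 0.0) -> np.ndarray:
    """One multiplicative Richardson-Lucy update M_mid.

    M_mid = M_k * { [observed / (M_k conv P)] corr P }, with the ratio
    denominator floored at a small epsilon (masks contain exact zeros) and,
    for damping > 0, ratio deviations below ``damping`` times the observed
    dynamic range reset to exactly 1.
    """
    psf = _check_psf(psf)
    estimate = np.asarray(estimate, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any(estimate < 0) or np.any(observed < 0):
        raise ParameterError("estimate and observed must be nonnegative")
    blurred = _convolve(estimate, psf)
    ratio = observed / np.maximum(blurred, RL_EPS)
    if damping > 0:
        span = float(observed.max() - observed.min())
        tol = damping * (span if span > 0 else 1.0)
        ratio = np.where(np.abs(ratio - 1.0) < tol, 1.0, ratio)
    correction = _convolve(ratio, psf[::-1, ::-1])
    return estimate * correction


def acceleration_factor(m_mid: np.ndarray, m_k: np.ndarray,
                        m_km1: np.ndarray, clamp: bool = True) -> float:
    """Extrapolation weight f from successive update differences.

    f = <M_mid - M_k, M_k - M_{k-1}> / <M_k - M_{k-1}, M_k - M_{k-1}>
    (elementwise products summed); 0 when the denominator vanishes; clamped
    to [0, 1) when ``clamp`` is on.
    """
    u = np.asarray(m_mid, dtype=float) - np.asarray(m_k, dtype=float)
    v = np.asarray(m_k, dtype=float) - np.asarray(m_km1, dtype=float)
    den = float((v * v).sum())
    if den == 0.0:
        return 0.0
    f = float((u * v).sum()) / den
    if clamp:
        f = min(max(f, 0.0), 1.0 - 1e-9)
    return f


def richardson_lucy(observed: np.ndarray, psf: np.ndarray, k_max: int = 10,
                    damping: float = 0.01, accelerate: bool = True,
                    clamp_acceleration: bool = True,
                    init: np.ndarray | None = None,
                    log: list | None = None) -> np.ndarray:
    """Run k_max accelerated damped RL iterations.

    Each iteration computes the multiplicative update M_mid, the
    extrapolation factor f (0 on the first iteration or when acceleration is
    off), then M_{k+1} = M_mid + f * (M_mid - M_k), clipped at 0. With
    damping 0 and acceleration off this is plain textbook Richardson-Lucy.
    """
    observed = np.asarray(observed, dtype=float)
    m_k = observed.copy() if init is None else np.asarray(init, dtype=float).copy()
    total_in = float(observed.sum())
    if total_in == 0.0:
        raise EmptyStructureError("deconvolution input is empty")
    m_prev: np.ndarray | None = None
    for k in range(k_max):
        m_mid = lr_step(m_k, observed, psf, damping)
        if accelerate and m_prev is not None:
            f = acceleration_factor(m_mid, m_k, m_prev, clamp_acceleration)
        else:
            f = 0.0
        m_next = m_mid + f * (m_mid - m_k)
        np.clip(m_next, 0.0, None, out=m_next)
        total = float(m_next.sum())
        if log is not None:
            log.append({"iteration": k + 1, "f": f, "total_intensity": total,
                        "area_ge_1": int((m_next >= 1.0).sum())})
        if total > 10.0 * total_in:
            raise OverProcessingError(
                f"total intensity grew to {total:.3g} (> 10x input "
                f"{total_in:.3g}) at iteration {k + 1}: over-processing")
        m_prev, m_k = m_k, m_next
    return m_k


def lr_deconvolve(mask: BinaryMask | np.ndarray, model: OpticalModel,
                  cfg: LRConfig | None = None, pitch_nm: float = 63.0,
                  log: list | None = None) -> np.ndarray:
    """Deconvolve a binary outline with the PSF of radius xi * r_perp.

    Returns the final real-valued matrix; its suprathreshold set
    {output >= 1} is the shrunken skeleton, tighter than the input mask.
    """
    if cfg is None:
        cfg = LRConfig()
    data = mask.data if isinstance(mask, BinaryMask) else np.asarray(mask)
    data = data.astype(float)
    if data.sum() == 0:
        raise EmptyStructureError("cannot deconvolve an empty mask")
    psf_model = OpticalModel(
        numerical_aperture=model.numerical_aperture,
        excitation_wavelength_nm=model.excitation_wavelength_nm,
        refractive_index=model.refractive_index,
        xi=cfg.xi,
    )
    psf = make_psf_2d(psf_model, pitch_nm, cfg.truncation_sigmas)
    init = np.full_like(data, data.mean()) if cfg.flat_init else None
    return richardson_lucy(data, psf, k_max=cfg.k_max, damping=cfg.damping,
                           accelerate=cfg.accelerate,
                           clamp_acceleration=cfg.clamp_acceleration,
                           init=init, log=log)


class RichardsonLucyDeconvolver(TransformerMixin, BaseEstimator):
    """Slice-wise deconvolution transformer over binary outline arrays.

    Parameters mirror :class:`LRConfig` plus the optical model and working
    pitch; ``psf_`` and per-slice ``iteration_logs_`` are set on fit/transform.
    """

    def __init__(self, xi: float = 2.5, k_max: int = 10, damping: float = 0.01,
                 truncation_sigmas: float = 3.0, accelerate: bool = True,
                 clamp_acceleration: bool = True, flat_init: bool = False,
                 numerical_aperture: float = 1.4,
                 excitation_wavelength_nm: float = 640.0,
                 refractive_index: float = 1.515, pitch_nm: float = 63.0):
        self.xi = xi
        self.k_max = k_max
        self.damping = damping
        self.truncation_sigmas = truncation_sigmas
        self.accelerate = accelerate
        self.clamp_acceleration = clamp_acceleration
        self.flat_init = flat_init
        self.numerical_aperture = numerical_aperture
        self.excitation_wavelength_nm = excitation_wavelength_nm
        self.refractive_index = refractive_index
        self.pitch_nm = pitch_nm

    def _config(self) -> LRConfig:
        return LRConfig(k_max=self.k_max, damping=self.damping, xi=self.xi,
                        truncation_sigmas=self.truncation_sigmas,
                        clamp_acceleration=self.clamp_acceleration,
                        accelerate=self.accelerate, flat_init=self.flat_init)

    def fit(self, X, y=None):
        cfg = self._config()
        model = OpticalModel(
            numerical_aperture=self.numerical_aperture,
            excitation_wavelength_nm=self.excitation_wavelength_nm,
            refractive_index=self.refractive_index, xi=cfg.xi)
        self.model_ = model
        self.psf_ = make_psf_2d(model, self.pitch_nm, self.truncation_sigmas)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 2
        stack = X[None, ...] if squeeze else X
        out = np.empty_like(stack)
        self.iteration_logs_ = []
        cfg = self._config()
        for z in range(stack.shape[0]):
            log: list = []
            out[z] = lr_deconvolve(stack[z], self.model_, cfg,
                                   pitch_nm=self.pitch_nm, log=log)
            self.iteration_logs_.append(log)
        return out[0] if squeeze else out
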