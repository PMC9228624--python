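"""Synthetic filament phantoms and their confocal-style degradation.

Ground-truth images are sparse bundles of smooth curved filaments of fixed
width on an exactly-zero background, mimicking a cytoskeletal (microtubule)
network at fine pixel pitch. Degradation follows the standard image-formation
model: Gaussian blur of a given physical radius followed by additive Gaussian
read noise, clipped to the working 8-bit-equivalent range [0, 255].

Each filament path is a random cubic Bezier curve whose endpoints lie on the
field border (so filaments span the field) and whose interior control points
are displaced perpendicular to the chord by an amount set by
``curvature_scale``. Strokes of width > 1 px are drawn by binary dilation of
the 1 px path with a disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._constants import MAX_INTENSITY
from .errors import ParameterError
from .stack import ImageStack

__all__ = ["PhantomSpec", "DegradationSpec", "generate_ground_truth", "degrade"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic filament field.

    Defaults give a 1024 px field at 63 nm pitch with six 1-px-wide
    filaments of intensity 200 — a sparse bundle geometry whose nonzero
    fraction stays well below 25%.
    """

    image_size_px: int = 1024
    pixel_pitch_nm: float = 63.0
    n_filaments: int = 6
    filament_width_nm: float = 63.0
    filament_intensity: float = 200.0
    curvature_scale: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px <= 0:
            raise ParameterError("image_size_px must be positive")
        if self.pixel_pitch_nm <= 0:
            raise ParameterError("pixel_pitch_nm must be positive")
        if self.n_filaments < 0:
            raise ParameterError("n_filaments must be nonnegative")
        if self.filament_width_nm <= 0:
            raise ParameterError("filament_width_nm must be positive")
        if self.filament_intensity <= 0:
            raise ParameterError("filament_intensity must be positive")
        if self.curvature_scale < 0:
            raise ParameterError("curvature_scale must be nonnegative")

    @property
    def stroke_width_px(self) -> int:
        """Rasterized stroke width: round(width / pitch), at least 1 px."""
        return max(int(round(self.filament_width_nm / self.pixel_pitch_nm)), 1)


@dataclass(frozen=True)
class DegradationSpec:
    """Blur + additive Gaussian noise corruption of a ground-truth image."""

    blur_radius_nm: float = 270.0
    noise_mean: float = 0.0
    noise_std: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blur_radius_nm < 0:
            raise ParameterError("blur_radius_nm must be nonnegative")
        if self.noise_std < 0:
            raise ParameterError("noise_std must be nonnegative")


def _edge_point(rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform random point on the border of a size x size field."""
    edge = rng.integers(4)
    t = rng.uniform(0, size - 1)
    if edge == 0:
        return np.array([0.0, t])
    if edge == 1:
        return np.array([size - 1.0, t])
    if edge == 2:
        return np.array([t, 0.0])
    return np.array([t, size - 1.0])


def _bezier_path(rng: np.random.Generator, size: int,
                 curvature_scale: float) -> np.ndarray:
    """Dense (row, col) samples of one random cubic Bezier filament path."""
    p0 = _edge_point(rng, size)
    p3 = _edge_point(rng, size)
    while np.linalg.norm(p3 - p0) < 0.25 * size:  # avoid degenerate stubs
        p3 = _edge_point(rng, size)
    chord = p3 - p0
    normal = np.array([-chord[1], chord[0]])
    normal /= max(np.linalg.norm(normal), 1e-12)
    ctrl = []
    for frac in (1.0 / 3.0, 2.0 / 3.0):
        offset = rng.uniform(-1.0, 1.0) * curvature_scale * size
        ctrl.append(p0 + frac * chord + offset * normal)
    p1, p2 = ctrl
    # ~2 samples per pixel of arc length keeps the rasterized path connected
    n_samples = max(int(4 * np.linalg.norm(chord)), 16)
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    path = ((1 - t) ** 3 * p0 + 3 * (1 - t) ** 2 * t * p1
            + 3 * (1 - t) * t ** 2 * p2 + t ** 3 * p3)
    return path


def generate_ground_truth(spec: PhantomSpec) -> ImageStack:
    """Generate a single-slice ground-truth filament image.

    Deterministic for a fixed seed. Filaments may overlap (bundles); the
    composite keeps the constant stroke intensity, and background pixels are
    exactly zero.
    """
    stroke = spec.stroke_width_px
    if spec.image_size_px < max(4, 2 * stroke):
        raise ParameterError(
            f"image_size_px={spec.image_size_px} is too small to contain a "
            f"filament of stroke width {stroke} px")
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    canvas = np.zeros((size, size), dtype=bool)
    for _ in range(spec.n_filaments):
        # a strongly bowed path may leave the field; out-of-field samples are
        # dropped, and a path that barely crosses the field is redrawn
        for _attempt in range(32):
            path = _bezier_path(rng, size, spec.curvature_scale)
            rr = np.round(path[:, 0]).astype(int)
            cc = np.round(path[:, 1]).astype(int)
            inside = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            if inside.sum() >= 2 * size:  # >= ~size/2 rasterized pixels
                break
        mask = np.zeros_like(canvas)
        mask[rr[inside], cc[inside]] = True
        if stroke > 1:
            r = (stroke - 1) / 2.0
            yy, xx = np.mgrid[-int(np.ceil(r)):int(np.ceil(r)) + 1,
                              -int(np.ceil(r)):int(np.ceil(r)) + 1]
            selem = yy ** 2 + xx ** 2 <= r ** 2 + 1e-9
            mask = ndimage.binary_dilation(mask, structure=selem)
        canvas |= mask
    image = canvas.astype(float) * spec.filament_intensity
    return ImageStack(image[None, ...], pitch_xy_nm=spec.pixel_pitch_nm)


def degrade(truth: ImageStack, spec: DegradationSpec) -> ImageStack:
    """Apply slice-wise Gaussian blur and additive Gaussian noise.

    The blur kernel is normalized (reflective boundaries), so blur conserves
    total intensity up to boundary effects; the result is clipped to
    [0, 255]. With zero blur, zero mean and zero STD the operation is the
    identity. Deterministic for a fixed seed.
    """
    sigma_px = spec.blur_radius_nm / truth.pitch_xy_nm
    rng = np.random.default_rng(spec.seed)
    out = np.empty_like(truth.data)
    for z in range(truth.n_slices):
        sl = truth.data[z]
        if sigma_px > 0:
            sl = ndimage.gaussian_filter(sl, sigma=sigma_px, mode="reflect")
        if spec.noise_std > 0:
            sl = sl + rng.normal(spec.noise_mean, spec.noise_std, sl.shape)
        elif spec.noise_mean != 0:
            sl = sl + spec.noise_mean
        out[z] = sl
    if spec.blur_radius_nm == 0 and spec.noise_mean == 0 and spec.noise_std == 0:
        return truth.with_data(truth.data.copy())
    return truth.with_data(np.clip(out, 0.0, MAX_INTENSITY))
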