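"""Image stack container and multi-page TIFF I/O.

An :class:`ImageStack` is a (z, y, x) array of nonnegative intensities with
physical pitch metadata in nanometres. Single 2D images are stored as
one-slice stacks. TIFF files are read with :mod:`tifffile`; pitches given
explicitly always win over TIFF resolution tags.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile

from .errors import ParameterError

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """A z-stack of fluorescence images with physical pitch metadata.

    Parameters
    ----------
    data : ndarray, shape (z, y, x)
        Nonnegative, finite intensities.
    pitch_xy_nm : float
        Lateral sample spacing in nanometres.
    pitch_z_nm : float
        Axial spacing between slices in nanometres.
    """

    data: np.ndarray
    pitch_xy_nm: float = 250.0
    pitch_z_nm: float = 1000.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None, ...]
        if self.data.ndim != 3 or self.data.size == 0:
            raise ParameterError("stack data must be a nonempty 2D or 3D array")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("stack intensities must be finite")
        if np.any(self.data < 0):
            raise ParameterError("stack intensities must be nonnegative")
        if self.pitch_xy_nm <= 0 or self.pitch_z_nm <= 0:
            raise ParameterError("pitches must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def slice(self, z: int) -> np.ndarray:
        return self.data[z]

    def with_data(self, data: np.ndarray, *, pitch_xy_nm: float | None = None,
                  pitch_z_nm: float | None = None) -> "ImageStack":
        """Return a copy holding ``data``, optionally with updated pitches."""
        return replace(
            self,
            data=data,
            pitch_xy_nm=self.pitch_xy_nm if pitch_xy_nm is None else pitch_xy_nm,
            pitch_z_nm=self.pitch_z_nm if pitch_z_nm is None else pitch_z_nm,
        )


def _pitch_from_tags(tif: tifffile.TiffFile) -> float | None:
    """Lateral pitch in nm from TIFF resolution tags, if present and sane."""
    try:
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if xres is None:
            return None
        num, den = xres.value
        if num == 0:
            return None
        per_unit = num / den  # samples per unit
        unit_nm = {2: 2.54e7, 3: 1e7}.get(getattr(unit, "value", 2) if unit else 2)
        if unit_nm is None:
            return None
        return unit_nm / per_unit
    except Exception:
        return None


def read_stack(path, pitch_xy_nm: float | None = None,
               pitch_z_nm: float | None = None) -> ImageStack:
    """Read a (multi-page) TIFF into an :class:`ImageStack`.

    Explicit pitches override TIFF resolution tags; absent both, the
    defaults (250 nm lateral, 1000 nm axial) apply.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray().astype(float)
        tag_pitch = _pitch_from_tags(tif)
    if pitch_xy_nm is None:
        pitch_xy_nm = tag_pitch if tag_pitch is not None else 250.0
    if pitch_z_nm is None:
        pitch_z_nm = 1000.0
    if data.ndim == 2:
        data = data[None, ...]
    return ImageStack(np.clip(data, 0.0, None), pitch_xy_nm, pitch_z_nm)


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a 32-bit float multi-page TIFF with resolution tags.

    A single-slice stack is written as an ordinary single-page 2D TIFF.
    """
    px_per_cm = 1e7 / stack.pitch_xy_nm
    data = stack.data.astype(np.float32)
    if data.shape[0] == 1:
        data = data[0]
    tifffile.imwrite(
        path,
        data,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
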