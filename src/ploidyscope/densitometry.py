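"""Feulgen densitometry: grayscale nucleus patches -> integrated optical density.

A Feulgen-stained nucleus absorbs light in proportion to its DNA content, so
the transmitted intensity I at a pixel relates to the incident (background)
intensity I0 through the optical density OD = log10(I0 / I).  Summing OD over
the nucleus mask gives the integrated optical density (IOD), the raw
measurement the ploidy pipeline normalizes to c-units.

Optical density uses base-10 logarithms, the densitometric convention.
Saturated pixels (brighter than the background, e.g. glare) are clamped to
OD 0 and counted, rather than failing the whole specimen.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import MeasurementError, SaturationWarning

__all__ = [
    "ImagePatch",
    "od_transform",
    "integrate_iod",
    "load_patch",
    "save_patch",
]


@dataclass
class ImagePatch:
    """A transmitted-light grayscale patch around one nucleus.

    Parameters
    ----------
    pixels
        2-D array of transmitted intensities, all strictly positive.
    background_intensity
        The clear-background (incident) intensity I0, strictly positive.
        Pixels brighter than I0 are treated as saturated, not invalid.
    """

    pixels: np.ndarray
    background_intensity: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise MeasurementError("image patch must be a 2-D intensity grid")
        if self.background_intensity <= 0:
            raise MeasurementError("background intensity must be positive")
        if np.any(self.pixels <= 0):
            raise MeasurementError("all pixel intensities must be positive")

    @property
    def n_saturated(self) -> int:
        """Number of pixels brighter than the background reference."""
        return int(np.sum(self.pixels > self.background_intensity))


def od_transform(patch: ImagePatch) -> np.ndarray:
    """Per-pixel optical density, OD = log10(I0 / I).

    Pixels equal to the background map to OD 0 exactly; pixels brighter than
    the background are clamped to OD 0 and a :class:`SaturationWarning` is
    issued (glare, not a measurement failure).
    """
    n_sat = patch.n_saturated
    if n_sat:
        warnings.warn(
            f"{n_sat} pixel(s) brighter than background clamped to OD 0",
            SaturationWarning,
            stacklevel=2,
        )
    od = np.log10(patch.background_intensity / patch.pixels)
    return np.maximum(od, 0.0)


def integrate_iod(patch: ImagePatch, mask: np.ndarray) -> float:
    """Integrated optical density: sum of OD over the nucleus mask.

    The mask must be a boolean grid congruent with the patch and nonempty.
    IOD is nonnegative and additive over disjoint masks.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != patch.pixels.shape:
        raise MeasurementError(
            f"mask shape {mask.shape} does not match patch {patch.pixels.shape}"
        )
    if not mask.any():
        raise MeasurementError("nucleus mask is empty")
    od = od_transform(patch)
    return float(od[mask].sum())


def load_patch(path, background_intensity: float) -> ImagePatch:
    """Read a grayscale PNG/TIFF into an :class:`ImagePatch`."""
    import imageio.v3 as iio

    pixels = np.asarray(iio.imread(path), dtype=float)
    if pixels.ndim == 3:  # collapse identical channels
        pixels = pixels.mean(axis=-1)
    return ImagePatch(pixels=pixels, background_intensity=background_intensity)


def save_patch(path, patch: ImagePatch) -> None:
    """Write the patch as a 16-bit grayscale image (PNG or TIFF by suffix)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(patch.pixels, 0, 65535).astype(np.uint16))
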