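"""Membrane-localization quantification from fluorescence images.

The input is a single-channel intensity image plus a binary background
annotation (true = background, e.g. from interactive segmentation) and a
micron-per-pixel calibration. The whole-cell area is the inverse of the
background annotation. The membrane compartment is approximated by a
band just inside the cell edge: the background is morphologically
dilated inward by a physical distance (2 um by default) using a
Euclidean disk whose pixel radius is the calibrated distance rounded to
the nearest pixel, and the dilated region is intersected with the cell
area. At the reference calibration of 0.1083 um/pixel a 2 um dilation
gives a disk radius of round(18.47) = 18 px.

Two localization conventions are reported: the integrated-intensity
fraction, sum(I over band) / sum(I over cell), bounded in [0, 1]; and
the mean-intensity ratio, mean(I over band) / mean(I over cell), which
is unbounded. The fraction is the headline output because it is bounded
like a percentage-of-protein readout; the mean ratio matches a
mean-intensity measurement convention. Both are invariant under global
intensity rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.morphology import dilation, disk

__all__ = [
    "LabeledImage",
    "LocalizationResult",
    "cell_mask_from_background",
    "membrane_band",
    "localization_ratio",
    "read_image",
    "read_mask",
    "write_image",
]

#: calibration of the reference acquisition setup, um per pixel
DEFAULT_UM_PER_PIXEL = 0.1083

#: physical dilation distance approximating the membrane compartment, um
DEFAULT_DILATION_UM = 2.0


@dataclass
class LabeledImage:
    """Intensity raster + background annotation + pixel calibration."""

    intensity: np.ndarray
    background_mask: np.ndarray
    um_per_pixel: float = DEFAULT_UM_PER_PIXEL

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D raster")
        if self.intensity.shape != self.background_mask.shape:
            raise ValueError(
                f"shape mismatch: intensity {self.intensity.shape} vs "
                f"background mask {self.background_mask.shape}"
            )
        if (self.intensity < 0).any():
            raise ValueError("intensity must be non-negative")
        if not self.um_per_pixel > 0:
            raise ValueError("um_per_pixel must be positive")


@dataclass
class LocalizationResult:
    cell_mask: np.ndarray
    membrane_mask: np.ndarray
    membrane_fraction: float
    mean_intensity_ratio: float


def cell_mask_from_background(background_mask: np.ndarray) -> np.ndarray:
    """Whole-cell area: logical complement of the background annotation."""
    background_mask = np.asarray(background_mask, dtype=bool)
    cell = ~background_mask
    if not cell.any():
        warnings.warn("all-background image: empty cell mask", stacklevel=2)
    return cell


def dilation_radius_px(um_per_pixel: float, dilation_um: float) -> int:
    """Disk radius in pixels for a physical dilation distance."""
    if not dilation_um > 0:
        raise ValueError("dilation_um must be positive")
    if not um_per_pixel > 0:
        raise ValueError("um_per_pixel must be positive")
    radius = int(round(dilation_um / um_per_pixel))
    if radius < 1:
        raise ValueError(
            f"dilation of {dilation_um} um rounds to 0 px at "
            f"{um_per_pixel} um/pixel: calibration too coarse"
        )
    return radius


def membrane_band(
    background_mask: np.ndarray,
    um_per_pixel: float = DEFAULT_UM_PER_PIXEL,
    dilation_um: float = DEFAULT_DILATION_UM,
) -> np.ndarray:
    """Membrane band: background dilated inward, clipped to the cell area.

    A cell pixel belongs to the band iff its Euclidean distance to the
    nearest background pixel is at most the disk radius.
    """
    background_mask = np.asarray(background_mask, dtype=bool)
    radius = dilation_radius_px(um_per_pixel, dilation_um)
    dilated = dilation(background_mask, footprint=disk(radius))
    return dilated & cell_mask_from_background(background_mask)


def localization_ratio(
    image: LabeledImage,
    dilation_um: float = DEFAULT_DILATION_UM,
) -> LocalizationResult:
    """Quantify membrane localization of the imaged signal.

    Raises on an empty cell mask or a cell with zero total intensity
    (both leave the ratio undefined).
    """
    cell = cell_mask_from_background(image.background_mask)
    if not cell.any():
        raise ValueError("empty cell mask: nothing to quantify")
    band = membrane_band(image.background_mask, image.um_per_pixel, dilation_um)
    total_cell = float(image.intensity[cell].sum())
    if total_cell <= 0:
        raise ValueError("zero total cell intensity: ratio undefined")
    total_band = float(image.intensity[band].sum())
    mean_cell = total_cell / cell.sum()
    mean_band = total_band / band.sum() if band.any() else 0.0
    return LocalizationResult(
        cell_mask=cell,
        membrane_mask=band,
        membrane_fraction=total_band / total_cell,
        mean_intensity_ratio=mean_band / mean_cell,
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF as a float array."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image")
    return arr.astype(float)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask TIFF (nonzero = true)."""
    return tifffile.imread(str(path)) != 0


def write_image(path: str | Path, array: np.ndarray) -> None:
    """Write an array as 16-bit grayscale TIFF (values clipped to uint16)."""
    arr = np.clip(np.asarray(array), 0, np.iinfo(np.uint16).max)
    tifffile.imwrite(str(path), arr.astype(np.uint16))
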