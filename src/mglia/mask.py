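"""Binary cell masks: container, validation, preprocessing, and file I/O.

A :class:`CellMask` is a 2D boolean raster of a single microglial cell plus
a spatial calibration in μm per pixel.  Per-cell feature operations require
exactly one 8-connected foreground component.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import filters, measure, morphology

from .features import DEFAULT_CALIBRATION_UM_PER_PX


class EmptyMaskError(ValueError):
    """Raised when a mask has no foreground after cleaning."""


class MultiComponentError(ValueError):
    """Raised when a per-cell operation receives a multi-component mask."""


@dataclass(frozen=True)
class CellMask:
    """Binary 2D raster of one cell with μm/px calibration."""

    pixels: np.ndarray
    calibration: float = DEFAULT_CALIBRATION_UM_PER_PX

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {arr.shape}")
        object.__setattr__(self, "pixels", arr.astype(bool))
        if not self.calibration > 0:
            raise ValueError(f"calibration must be positive, got {self.calibration}")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def n_components(self) -> int:
        if not self.pixels.any():
            return 0
        return int(measure.label(self.pixels, connectivity=2).max())

    def require_single_component(self) -> None:
        n = self.n_components()
        if n == 0:
            raise EmptyMaskError("mask has no foreground pixels")
        if n != 1:
            raise MultiComponentError(
                f"per-cell operation requires a single 8-connected component, found {n}"
            )


def preprocess_mask(
    raster: np.ndarray,
    threshold_method: str = "otsu",
    min_object_px: int = 0,
    single_cell: bool = False,
    calibration: float = DEFAULT_CALIBRATION_UM_PER_PX,
) -> CellMask:
    """Binarize a grayscale raster into a :class:`CellMask`.

    Already-binary input (boolean, or exactly two values {0, max}) is passed
    through unchanged, so the operation is idempotent on its own output.

    Parameters
    ----------
    threshold_method:
        ``"otsu"`` (between-class variance) or ``"mean"``.
    min_object_px:
        Remove connected components smaller than this pixel count.
    single_cell:
        Keep only the largest 8-connected component.
    """
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image, got shape {arr.shape}")
    if arr.dtype == bool:
        fg = arr.copy()
    else:
        values = np.unique(arr)
        if values.size <= 2 and values.min() == 0:
            fg = arr > 0
        else:
            if threshold_method == "otsu":
                thr = filters.threshold_otsu(arr)
            elif threshold_method == "mean":
                thr = arr.mean()
            else:
                raise ValueError(f"unknown threshold_method {threshold_method!r}")
            fg = arr > thr
    if min_object_px > 1:
        # max_size removes components of size ≤ its value
        fg = morphology.remove_small_objects(fg, max_size=min_object_px - 1, connectivity=2)
    if fg.any() and single_cell:
        labels = measure.label(fg, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        fg = labels == counts.argmax()
    if not fg.any():
        raise EmptyMaskError("no foreground pixels remain after thresholding/cleaning")
    return CellMask(fg, calibration)


def load_mask(path: str | Path, calibration: float = DEFAULT_CALIBRATION_UM_PER_PX) -> CellMask:
    """Read an 8-bit single-channel TIFF or PNG mask (0 background, >0 foreground)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:  # collapse trivial channel axes
        arr = arr[..., 0]
    return CellMask(arr > 0, calibration)


def save_mask(mask: CellMask, path: str | Path) -> None:
    """Write a mask as 8-bit single-channel TIFF or PNG (0/255)."""
    path = Path(path)
    img = np.where(mask.pixels, 255, 0).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, img)
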