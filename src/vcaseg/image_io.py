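"""Raster I/O, grayscale conversion, and region-of-interest cropping.

The pipeline works on 2-D intensity images normalized to [0, 1] floats,
0-based (row, col) coordinates, origin at the top-left. En-face OCTA
angiograms are exported as PNG/TIFF/JPEG; color exports are collapsed to
luma before any analysis because every downstream stage is intensity-based.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import BoundsError, IOFailure, ShapeError, UnsupportedFormatError

#: Rec. 601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class RectROI:
    """Axis-aligned rectangular region of interest (inclusive top-left corner)."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise BoundsError(f"ROI must be at least 1x1, got {self.height}x{self.width}")
        if self.top < 0 or self.left < 0:
            raise BoundsError(f"ROI origin must be non-negative, got ({self.top}, {self.left})")

    def check_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape[:2]
        if self.top + self.height > rows or self.left + self.width > cols:
            raise BoundsError(
                f"ROI (top={self.top}, left={self.left}, height={self.height}, "
                f"width={self.width}) exceeds image of shape {rows}x{cols}"
            )


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster, returning the stored array.

    Grayscale files come back 2-D, color files as (rows, cols, channels);
    callers pass color rasters through :func:`to_grayscale`.
    """
    p = Path(path)
    if p.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise UnsupportedFormatError(f"unsupported image format {p.suffix!r} for {p}")
    if not p.exists():
        raise IOFailure(f"image file not found: {p}")
    try:
        arr = iio.imread(p)
    except Exception as exc:  # noqa: BLE001 - backend-specific failures
        raise IOFailure(f"cannot read image {p}: {exc}") from exc
    return np.asarray(arr)


def write_gray(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write a [0, 1] float or uint8 2-D image as an 8-bit grayscale PNG."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.rint(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    try:
        iio.imwrite(Path(path), arr)
    except Exception as exc:  # noqa: BLE001
        raise IOFailure(f"cannot write image {path}: {exc}") from exc


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 grayscale PNG."""
    write_gray(path, np.where(np.asarray(mask, dtype=bool), np.uint8(255), np.uint8(0)))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a 0/255 PNG back into a boolean mask."""
    return np.asarray(read_image(path)) > 0


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) raster to one channel with Rec. 601 luma weights.

    Single-channel input is returned unchanged. Integer input stays integer
    (rounded), float input stays float, so the output range is a subset of
    the input range either way.
    """
    a = np.asarray(arr)
    if a.ndim == 2:
        return a
    if a.ndim == 3 and a.shape[2] in (3, 4):
        rgb = a[..., :3].astype(np.float64)
        gray = rgb @ np.asarray(LUMA_WEIGHTS)
        if np.issubdtype(a.dtype, np.integer):
            return np.rint(gray).astype(a.dtype)
        return gray
    raise ShapeError(f"expected 1, 3, or 4 channels, got array of shape {a.shape}")


def normalize(img: np.ndarray) -> np.ndarray:
    """Scale an intensity image to [0, 1] float64.

    Integer images divide by their dtype maximum (255 for 8-bit, 65535 for
    16-bit); float images must already lie in [0, 1].
    """
    a = np.asarray(img)
    if a.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got shape {a.shape}")
    if np.issubdtype(a.dtype, np.integer):
        return a.astype(np.float64) / float(np.iinfo(a.dtype).max)
    a = a.astype(np.float64)
    if not np.all(np.isfinite(a)):
        raise ShapeError("image contains non-finite intensities")
    if a.size and (a.min() < 0.0 or a.max() > 1.0):
        raise ShapeError("float image intensities must lie in [0, 1]")
    return a


def crop_roi(img: np.ndarray, roi: RectROI) -> np.ndarray:
    """Copy the ROI out of ``img``; the source is left untouched."""
    a = np.asarray(img)
    roi.check_within(a.shape)
    return a[roi.top : roi.top + roi.height, roi.left : roi.left + roi.width].copy()


def load_gray(path: str | os.PathLike, roi: RectROI | None = None) -> np.ndarray:
    """Read, gray-convert, normalize to [0, 1], and optionally crop."""
    img = normalize(to_grayscale(read_image(path)))
    if roi is not None:
        img = crop_roi(img, roi)
    return img
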