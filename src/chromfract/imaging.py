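"""Raster input and the pseudo-3D landscape representation.

A segmented nucleus is represented as a :class:`NucleusSurface`: an 8-bit
grayscale image interpreted as a height field (z = gray level) restricted to
a binary segmentation mask.  Color images are converted to luminance first;
segmentation itself is an input, never computed here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "NucleusSurface",
    "to_grayscale",
    "validate_mask",
    "load_nucleus",
    "save_gray",
]

#: 8-connectivity structuring element for component labelling.
_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class NucleusSurface:
    """Pseudo-3D landscape of one segmented nucleus.

    Parameters
    ----------
    gray : (H, W) uint8 array
        Gray levels in [0, 255]; z coordinate of the landscape.
    mask : (H, W) bool array
        True inside the nucleus.  Must be a single 8-connected component.
    pixel_size_um : float
        Edge length of one pixel in micrometres.  Required for areas in
        µm²; the fractal estimates are pixel-unit computations and do not
        use it.
    """

    gray: np.ndarray
    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        gray = np.asarray(self.gray)
        mask = np.asarray(self.mask, dtype=bool)
        if gray.ndim != 2:
            raise ValueError("gray image must be 2-D")
        if gray.shape != mask.shape:
            raise ValueError(
                f"image {gray.shape} and mask {mask.shape} dimensions differ"
            )
        if gray.dtype != np.uint8:
            g = np.asarray(gray)
            if np.any(g < 0) or np.any(g > 255):
                raise ValueError("gray levels must lie in [0, 255]")
            gray = g.astype(np.uint8)
        validate_mask(mask)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "gray", gray)
        object.__setattr__(self, "mask", mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check that *mask* is non-empty and a single 8-connected component.

    Multi-component masks are rejected rather than silently reduced to the
    largest component, so segmentation errors surface early.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("mask is empty: no nucleus pixels")
    _, n = ndimage.label(mask, structure=_EIGHT)
    if n != 1:
        raise ValueError(f"mask has {n} 8-connected components; expected exactly 1")
    return mask


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB image to 8-bit luminance.

    Uses ITU-R BT.601 weights, Y = 0.299 R + 0.587 G + 0.114 B, rounded
    half away from zero and clamped to [0, 255] — the standard luminance
    definition for 8-bit imagery.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    if np.any(img < 0) or np.any(img > 255):
        raise ValueError("channel values must lie in [0, 255]")
    rgb = img.astype(np.float64)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    # round half away from zero (np.round rounds half to even)
    y = np.floor(y + 0.5)
    return np.clip(y, 0, 255).astype(np.uint8)


def _read_raster(path: str | os.PathLike) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode in ("RGB",):
                return np.asarray(im)
            if im.mode in ("RGBA", "P"):
                return np.asarray(im.convert("RGB"))
            if im.mode in ("L", "1"):
                return np.asarray(im.convert("L"))
            if im.mode in ("I", "I;16", "F"):
                arr = np.asarray(im.convert("I"))
                if arr.max() > 255 or arr.min() < 0:
                    raise ValueError(
                        f"{path}: only 8-bit gray or 24-bit RGB rasters supported"
                    )
                return arr.astype(np.uint8)
            raise ValueError(f"{path}: unsupported raster mode {im.mode!r}")
    except FileNotFoundError:
        raise IOError(f"cannot read raster file: {path}") from None
    except (OSError, Image.UnidentifiedImageError) as exc:
        raise IOError(f"cannot read raster file: {path} ({exc})") from None


def load_nucleus(
    image_path: str | os.PathLike,
    mask_path: str | os.PathLike,
    pixel_size_um: float,
) -> NucleusSurface:
    """Load a nucleus image and its segmentation mask from raster files.

    PNG, TIFF and BMP are supported, 8-bit gray or 24-bit RGB.  Color
    images pass through :func:`to_grayscale`; grayscale images are used
    as-is.  Any strictly positive mask pixel counts as inside (tolerating
    both 0/1 and 0/255 mask dialects).
    """
    img = _read_raster(image_path)
    gray = to_grayscale(img) if img.ndim == 3 else img
    mraw = _read_raster(mask_path)
    if mraw.ndim == 3:
        mraw = to_grayscale(mraw)
    if gray.shape != mraw.shape:
        raise ValueError(
            f"image {gray.shape} ({image_path}) and mask {mraw.shape} "
            f"({mask_path}) dimensions differ"
        )
    return NucleusSurface(gray=gray, mask=mraw > 0, pixel_size_um=pixel_size_um)


def save_gray(arr: np.ndarray, path: str | os.PathLike) -> None:
    """Write an (H, W) uint8 array (image or 0/255 mask) as a raster file."""
    arr = np.asarray(arr)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
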