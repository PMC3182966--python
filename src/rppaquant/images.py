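"""Scanner image I/O.

Arrays are scanned to single-channel grayscale TIFFs; 16-bit unsigned is
the native depth (intensity ceiling 65535) and 8-bit inputs are accepted
and recorded as such, never rescaled.  Values are preserved bit-exactly on
a write/read round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

from .errors import UnsupportedImageError

MAX_INTENSITY = 65535


@dataclass
class ArrayImage:
    """One scanned (or simulated) array image.

    Attributes
    ----------
    pixels
        2-D unsigned integer intensity matrix, row-major, 0-based, y down.
    bit_depth
        8 or 16.
    pixel_size
        Physical pixel size in µm/pixel (from the layout or scanner).
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size: float = 10.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise UnsupportedImageError(
                f"expected a 2-D single-channel image, got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise UnsupportedImageError(
                f"expected an integer pixel type, got {self.pixels.dtype}"
            )
        lim = (1 << self.bit_depth) - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > lim):
            raise UnsupportedImageError(
                f"pixel values outside [0, {lim}] for bit depth {self.bit_depth}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def saturated(self) -> np.ndarray:
        """Boolean mask of pixels at the intensity ceiling."""
        return self.pixels == (1 << self.bit_depth) - 1


def read_image(path, pixel_size: float = 10.0) -> ArrayImage:
    """Read a single-channel TIFF of at most 16 bits.

    Raises :class:`UnsupportedImageError` for RGB / multi-page / float /
    deeper-than-16-bit files; 8-bit files are accepted with
    ``bit_depth=8`` and their values left untouched.
    """
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise UnsupportedImageError(
                f"{path}: multi-page TIFF ({len(tif.pages)} pages) not supported"
            )
        arr = tif.pages[0].asarray()
    if arr.ndim != 2:
        raise UnsupportedImageError(
            f"{path}: RGB/multi-channel image of shape {arr.shape} not supported"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise UnsupportedImageError(
            f"{path}: non-integer pixel type {arr.dtype} not supported"
        )
    if arr.size and (arr.min() < 0 or arr.max() > MAX_INTENSITY):
        raise UnsupportedImageError(
            f"{path}: intensities exceed the 16-bit ceiling {MAX_INTENSITY}"
        )
    if arr.dtype.itemsize == 1:
        bit_depth = 8
    else:
        bit_depth = 16
        arr = arr.astype(np.uint16)
    return ArrayImage(pixels=arr, bit_depth=bit_depth, pixel_size=pixel_size)


def write_image(image: ArrayImage, path):
    """Write an :class:`ArrayImage` as an uncompressed grayscale TIFF."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    tifffile.imwrite(path, image.pixels.astype(dtype))
    return path
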