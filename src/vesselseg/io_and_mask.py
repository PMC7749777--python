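"""Raster I/O, channel extraction and automatic field-of-view masking.

Fundus cameras image a roughly circular field of view (FOV) surrounded by an
uninformative black frame.  Some public datasets ship FOV masks, many do
not, so an automatic mask is built from the red channel (strongest
disc/background separation): threshold, keep the largest connected
component, fill holes, and erode the rim to suppress bright-edge false
positives.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
from scipy import ndimage as ndi
from skimage.morphology import disk, erosion

from ._validation import DegenerateRegionError, as_binary, as_rgb
from .misodata import isodata_threshold

__all__ = ["read_image", "extract_channel", "make_fov_mask", "write_binary"]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG/PPM/TIFF raster as an (H, W, 3) float image on [0, 1].

    Grayscale files are replicated across the three planes; an alpha plane,
    if present, is dropped.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path!r}")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = np.clip(arr.astype(np.float64), 0.0, 1.0)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValueError(f"unsupported raster layout {arr.shape} in {path!r}")
    return as_rgb(arr, name=str(path))


def extract_channel(img: np.ndarray, channel: str) -> np.ndarray:
    """Return the named color plane of an RGB image, unchanged."""
    img = as_rgb(img)
    try:
        idx = _CHANNELS[channel]
    except KeyError:
        raise ValueError(
            f"unknown channel {channel!r}; expected one of {sorted(_CHANNELS)}"
        ) from None
    return img[:, :, idx].copy()


def make_fov_mask(img: np.ndarray, erosion_radius: int = 3) -> np.ndarray:
    """Automatic field-of-view mask from the red plane.

    The red plane is thresholded with the global ISODATA routine; the
    largest connected bright component is kept, interior holes are filled,
    and the boundary is eroded by a disc of ``erosion_radius`` pixels.
    """
    img = as_rgb(img)
    red = img[:, :, 0]
    try:
        t = isodata_threshold(red)
        raw = red > t
    except DegenerateRegionError:
        # constant red plane: either fully lit (whole frame is FOV) or dark
        raw = np.full(red.shape, bool(red.flat[0] > 0))
    if not raw.any():
        raise ValueError("no field of view detected")
    labels, n = ndi.label(raw, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndi.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    raw = ndi.binary_fill_holes(raw)
    if erosion_radius > 0:
        raw = erosion(raw, disk(erosion_radius))
    if not raw.any():
        raise ValueError("no field of view detected")
    return raw


def write_binary(img: np.ndarray, path) -> None:
    """Write a binary image as an 8-bit 0/255 PNG (lossless round trip)."""
    img = as_binary(img)
    try:
        iio.imwrite(path, (img.astype(np.uint8) * 255))
    except Exception as exc:
        raise IOError(f"cannot write binary image to {path!r}: {exc}") from exc


def read_binary(path) -> np.ndarray:
    """Read a 0/255 (or 0/1) mask file back to a boolean image."""
    arr = read_image(path)
    return arr[:, :, 0] > 0.5
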