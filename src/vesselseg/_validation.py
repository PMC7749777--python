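"""Shared array conventions and validation helpers.

Image conventions used throughout the package:

* grayscale images are 2-D ``float64`` arrays with intensities in ``[0, 1]``
  (row-major, 0-based, origin top-left);
* RGB images are ``(H, W, 3)`` float arrays with the same intensity scale;
* binary images are 2-D boolean arrays with vessel/foreground ``True``.
"""

from __future__ import annotations

import numpy as np


class DegenerateRegionError(ValueError):
    """Raised when a region has too little intensity variation to threshold."""


def as_gray(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate and return a 2-D float grayscale image."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have positive dimensions")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def as_binary(img: np.ndarray, name: str = "mask") -> np.ndarray:
    """Validate and return a 2-D boolean image."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    if arr.dtype != bool:
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be boolean or 0/1 valued")
        arr = arr.astype(bool)
    return arr


def as_rgb(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Validate and return an (H, W, 3) float RGB image on [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"{name} must have positive dimensions")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError(f"{name} intensities must lie in [0, 1]")
    return arr


def check_same_shape(a: np.ndarray, b: np.ndarray, what: str = "images") -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what} have mismatched shapes {a.shape} vs {b.shape}")
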