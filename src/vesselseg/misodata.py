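"""Modified ISODATA (MISODATA) thresholding.

Classic ISODATA (Ridler–Calvard) iterates the threshold to the midpoint of
the means of the two classes it induces.  The modified scheme computed here
reconciles one *global* ISODATA threshold over the whole region of interest
with *local* ISODATA thresholds computed per square tile: a tile keeps its
local threshold only when it lies within a tolerance band around the global
one, otherwise it falls back to the global value.  This guards vessel-free
tiles, where a purely local threshold would hallucinate foreground out of
background noise, while still letting tiles with genuinely different
background statistics adapt.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from ._validation import DegenerateRegionError, as_binary, as_gray, check_same_shape

__all__ = [
    "MisodataConfig",
    "ThresholdMap",
    "isodata_threshold",
    "misodata_map",
    "binarize",
]


@dataclass
class MisodataConfig:
    """Parameters of the local/global threshold reconciliation.

    tile
        Side length in pixels of the square local segments.
    tolerance
        Maximum allowed ``|T_local - T_global|`` as a fraction of the
        observed ROI intensity range before a tile falls back to the
        global threshold.
    max_iter, eps
        Iteration cap and convergence tolerance of the ISODATA fixed-point
        iteration.
    min_coverage
        Minimum fraction of a tile that must lie inside the ROI for a local
        threshold to be attempted; sparser tiles inherit the global value.
    interpolate
        Bilinearly interpolate tile thresholds between tile centers when
        binarizing (avoids blocking seams); ``False`` restores hard
        per-tile thresholds.
    """

    tile: int = 64
    tolerance: float = 0.25
    max_iter: int = 100
    eps: float = 1.0 / 512.0
    min_coverage: float = 0.25
    interpolate: bool = True

    def __post_init__(self) -> None:
        if self.tile < 8:
            raise ValueError("tile must be >= 8 px")
        if not 0.0 < self.tolerance <= 1.0:
            raise ValueError("tolerance must lie in (0, 1]")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class ThresholdMap:
    """Per-tile thresholds chosen by the local/global reconciliation."""

    global_t: float
    thresholds: np.ndarray  # (n_tile_rows, n_tile_cols) float
    provenance: np.ndarray  # same grid, "local" or "global"
    tile: int
    shape: tuple[int, int]
    interpolate: bool = True
    tile_rows: np.ndarray = field(default=None, repr=False)  # tile-center rows
    tile_cols: np.ndarray = field(default=None, repr=False)  # tile-center cols

    def to_json(self) -> str:
        return json.dumps(
            {
                "global_t": self.global_t,
                "tile": self.tile,
                "shape": list(self.shape),
                "thresholds": self.thresholds.tolist(),
                "provenance": self.provenance.tolist(),
            },
            indent=2,
        )


def isodata_threshold(
    img: np.ndarray,
    roi: np.ndarray | None = None,
    *,
    max_iter: int = 100,
    eps: float = 1.0 / 512.0,
) -> float:
    """Iterative intensity threshold of ``img`` restricted to ``roi``.

    Starting from the ROI mean, iterates ``T <- (mean{x <= T} + mean{x > T})/2``
    until the update is below ``eps`` or ``max_iter`` is reached.

    Raises
    ------
    DegenerateRegionError
        If the ROI holds fewer than two distinct intensities.
    """
    img = as_gray(img)
    if roi is None:
        vals = img.ravel()
    else:
        roi = as_binary(roi, "roi")
        check_same_shape(img, roi)
        vals = img[roi]
    if vals.size == 0:
        raise ValueError("roi is empty")
    if vals.max() - vals.min() == 0:
        raise DegenerateRegionError("degenerate region: no threshold")

    t = float(vals.mean())
    for _ in range(max_iter):
        below = vals <= t
        lo = vals[below]
        hi = vals[~below]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (float(lo.mean()) + float(hi.mean()))
        # converged only once the update is small AND the induced class
        # partition is stable — |dT| alone can stall short of the fixed
        # point when the class means drift slowly
        done = (abs(t_new - t) < eps
                and int(np.count_nonzero(vals <= t_new)) == int(lo.size))
        t = t_new
        if done:
            break
    return t


def misodata_map(
    img: np.ndarray, roi: np.ndarray, cfg: MisodataConfig | None = None
) -> ThresholdMap:
    """Compute the reconciled local/global threshold grid for ``img``.

    Tiles with insufficient ROI coverage or degenerate intensity content
    inherit the global threshold; a local threshold is kept only when it
    falls within ``tolerance * (ROI intensity range)`` of the global one.
    """
    cfg = cfg or MisodataConfig()
    img = as_gray(img)
    roi = as_binary(roi, "roi")
    check_same_shape(img, roi)
    if not roi.any():
        raise ValueError("roi is empty")

    t_global = isodata_threshold(img, roi, max_iter=cfg.max_iter, eps=cfg.eps)
    vals = img[roi]
    vrange = float(vals.max() - vals.min())

    h, w = img.shape
    n_r = max(1, -(-h // cfg.tile))
    n_c = max(1, -(-w // cfg.tile))
    thresholds = np.full((n_r, n_c), t_global, dtype=np.float64)
    provenance = np.full((n_r, n_c), "global", dtype=object)
    tile_rows = np.empty(n_r)
    tile_cols = np.empty(n_c)

    for i in range(n_r):
        r0, r1 = i * cfg.tile, min((i + 1) * cfg.tile, h)
        tile_rows[i] = 0.5 * (r0 + r1 - 1)
        for j in range(n_c):
            c0, c1 = j * cfg.tile, min((j + 1) * cfg.tile, w)
            tile_cols[j] = 0.5 * (c0 + c1 - 1)
            sub_roi = roi[r0:r1, c0:c1]
            if sub_roi.mean() < cfg.min_coverage:
                continue
            try:
                t_local = isodata_threshold(
                    img[r0:r1, c0:c1], sub_roi, max_iter=cfg.max_iter, eps=cfg.eps
                )
            except DegenerateRegionError:
                continue
            if abs(t_local - t_global) <= cfg.tolerance * vrange:
                thresholds[i, j] = t_local
                provenance[i, j] = "local"

    return ThresholdMap(
        global_t=t_global,
        thresholds=thresholds,
        provenance=provenance,
        tile=cfg.tile,
        shape=(h, w),
        interpolate=cfg.interpolate,
        tile_rows=tile_rows,
        tile_cols=tile_cols,
    )


def threshold_surface(tmap: ThresholdMap) -> np.ndarray:
    """Expand a ThresholdMap to a full-frame per-pixel threshold image."""
    h, w = tmap.shape
    n_r, n_c = tmap.thresholds.shape
    if not tmap.interpolate or (n_r == 1 and n_c == 1):
        # hard per-tile thresholds
        ri = np.minimum(np.arange(h) // tmap.tile, n_r - 1)
        ci = np.minimum(np.arange(w) // tmap.tile, n_c - 1)
        return tmap.thresholds[np.ix_(ri, ci)]
    rows = tmap.tile_rows
    cols = tmap.tile_cols
    # clamp to the tile-center hull => constant extrapolation at the border
    rr = np.clip(np.arange(h, dtype=np.float64), rows[0], rows[-1])
    cc = np.clip(np.arange(w, dtype=np.float64), cols[0], cols[-1])
    if n_r == 1:
        surf_rows = tmap.thresholds  # no row interpolation possible
        interp = RegularGridInterpolator((cols,), tmap.thresholds[0], method="linear")
        return np.broadcast_to(interp(cc)[None, :], (h, w)).copy()
    if n_c == 1:
        interp = RegularGridInterpolator((rows,), tmap.thresholds[:, 0], method="linear")
        return np.broadcast_to(interp(rr)[:, None], (h, w)).copy()
    interp = RegularGridInterpolator((rows, cols), tmap.thresholds, method="linear")
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    return interp(np.stack([grid_r.ravel(), grid_c.ravel()], axis=1)).reshape(h, w)


def binarize(img: np.ndarray, tmap: ThresholdMap, roi: np.ndarray) -> np.ndarray:
    """Foreground = inside ROI and strictly above the per-pixel threshold."""
    img = as_gray(img)
    roi = as_binary(roi, "roi")
    check_same_shape(img, roi)
    if (img.shape[0], img.shape[1]) != tuple(tmap.shape):
        raise ValueError("threshold map does not cover this frame")
    surf = threshold_surface(tmap)
    return roi & (img > surf)
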