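"""Fusion and postprocessing: combine the MISODATA (Block-I) and B-COSFIRE
(Block-II) binary maps into the final vessel segmentation.

The chain, after both branches have produced their binary maps, is
prune -> AND -> shape filter -> gate with the enhanced image -> threshold
-> OR -> restrict to the field of view.  The AND keeps only pixels both
branches agree on (suppressing each branch's idiosyncratic false
positives); gating the enhanced image with that consensus and
re-thresholding re-anchors vessels at their correct position before the
final OR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label, regionprops

from ._validation import as_binary, as_gray, check_same_shape
from .bcosfire import BcosfireConfig, enhance, segment_enhanced
from .io_and_mask import extract_channel, make_fov_mask
from .misodata import DegenerateRegionError, MisodataConfig, binarize, isodata_threshold, misodata_map
from .preprocess import (
    PreprocessConfig,
    background,
    clahe,
    difference_image,
    remove_light_reflex,
    smooth,
)

__all__ = [
    "PostprocessConfig",
    "prune_small",
    "shape_filter",
    "and_fuse",
    "or_fuse",
    "gate_enhanced",
    "segment",
    "PipelineError",
]


@dataclass
class PostprocessConfig:
    """Component-level rejection rules.

    A component is removed by ``shape_filter`` only when it is both
    non-elongated (eccentricity below ``min_eccentricity``) and small
    (area below ``round_area_bound``); elongated components always
    survive.  ``prune_small`` removes every component below ``min_area``.
    """

    min_area: int = 25
    min_eccentricity: float = 0.7
    round_area_bound: int = 300
    connectivity: int = 8  # 4 or 8

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if not 0.0 <= self.min_eccentricity < 1.0:
            raise ValueError("min_eccentricity must lie in [0, 1)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


class PipelineError(RuntimeError):
    """Failure in a named stage of the end-to-end pipeline."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _label(img: np.ndarray, cfg: PostprocessConfig) -> np.ndarray:
    conn = 2 if cfg.connectivity == 8 else 1
    return label(img, connectivity=conn)


def prune_small(img: np.ndarray, cfg: PostprocessConfig | None = None) -> np.ndarray:
    """Remove connected components with fewer than ``min_area`` pixels."""
    cfg = cfg or PostprocessConfig()
    img = as_binary(img)
    if not img.any():
        return img.copy()
    labels = _label(img, cfg)
    counts = np.bincount(labels.ravel())
    keep = counts >= cfg.min_area
    keep[0] = False
    return keep[labels]


def shape_filter(img: np.ndarray, cfg: PostprocessConfig | None = None) -> np.ndarray:
    """Reject small round components; keep everything elongated.

    Eccentricity is that of the ellipse with the same second moments as
    the component, so a disc scores ~0 and a line segment scores ~1.
    """
    cfg = cfg or PostprocessConfig()
    img = as_binary(img)
    if not img.any():
        return img.copy()
    labels = _label(img, cfg)
    out = img.copy()
    for region in regionprops(labels):
        if region.eccentricity < cfg.min_eccentricity and region.area < cfg.round_area_bound:
            out[labels == region.label] = False
    return out


def and_fuse(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise conjunction of two binary maps."""
    a = as_binary(a, "a")
    b = as_binary(b, "b")
    check_same_shape(a, b)
    return a & b


def or_fuse(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pixelwise disjunction of two binary maps."""
    a = as_binary(a, "a")
    b = as_binary(b, "b")
    check_same_shape(a, b)
    return a | b


def gate_enhanced(p1: np.ndarray, enhanced: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Gate the enhanced image with a binary map and re-threshold.

    ``gated = p1 * I_E_C`` pixelwise; the result is thresholded with the
    global ISODATA routine inside the ROI to give I_s2.
    """
    p1 = as_binary(p1, "p1")
    enhanced = as_gray(enhanced, "enhanced")
    roi = as_binary(roi, "roi")
    check_same_shape(p1, enhanced)
    check_same_shape(p1, roi)
    gated = p1 * enhanced
    try:
        t = isodata_threshold(gated, roi)
    except DegenerateRegionError:
        warnings.warn("degenerate gated image: returning empty segmentation")
        return np.zeros(p1.shape, dtype=bool)
    return roi & (gated > t)


def segment(
    img: np.ndarray,
    pre_cfg: PreprocessConfig | None = None,
    mis_cfg: MisodataConfig | None = None,
    bc_cfg: BcosfireConfig | None = None,
    post_cfg: PostprocessConfig | None = None,
    fov: np.ndarray | None = None,
    return_intermediates: bool = False,
):
    """Run the full hybrid segmentation pipeline on an RGB fundus image.

    Parameters
    ----------
    img
        (H, W, 3) float RGB image on [0, 1].
    fov
        Optional externally supplied field-of-view mask; when ``None`` the
        automatic red-channel mask is built.
    return_intermediates
        Also return a dict of the named intermediate images
        (Id, Is1, IEC, IsC, IAnd, Ip1, Is2).

    Returns
    -------
    Binary vessel map restricted to the FOV, or ``(map, intermediates)``.
    """
    pre_cfg = pre_cfg or PreprocessConfig()
    mis_cfg = mis_cfg or MisodataConfig()
    bc_cfg = bc_cfg or BcosfireConfig()
    post_cfg = post_cfg or PostprocessConfig()

    def run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

    green = run("green channel", extract_channel, img, "green")
    if fov is None:
        fov = run("fov mask", make_fov_mask, img)
    else:
        fov = as_binary(fov, "fov")

    # Block I: denoise, equalize, subtract background, threshold
    opened = run("light reflex removal", remove_light_reflex, green, pre_cfg)
    smoothed = run("smoothing", smooth, opened, pre_cfg)
    i_clahe = run("clahe", clahe, smoothed, pre_cfg)
    i_avg = run("background", background, i_clahe, pre_cfg)
    i_d = run("difference image", difference_image, i_avg, i_clahe)
    tmap = run("misodata map", misodata_map, i_d, fov, mis_cfg)
    i_s1 = run("misodata binarize", binarize, i_d, tmap, fov)
    i_s1 = run("prune Is1", prune_small, i_s1, post_cfg)

    # Block II: B-COSFIRE enhancement on the masked preprocessed image.
    # Outside the FOV the frame is black; filling it with the interior
    # median removes the strong artificial edge at the FOV rim.
    masked = i_clahe.copy()
    masked[~fov] = np.median(i_clahe[fov]) if fov.any() else 0.0
    i_ec = run("bcosfire enhance", enhance, masked, bc_cfg)
    i_sc = run("bcosfire segment", segment_enhanced, i_ec, fov)

    # fusion
    i_and = run("AND fusion", and_fuse, i_s1, i_sc)
    i_p1 = run("postprocess", lambda m: shape_filter(prune_small(m, post_cfg), post_cfg), i_and)
    i_s2 = run("gate enhanced", gate_enhanced, i_p1, i_ec, fov)
    final = run("OR fusion", or_fuse, i_p1, i_s2) & fov

    if return_intermediates:
        inter = {
            "Id": i_d,
            "Is1": i_s1,
            "IEC": i_ec,
            "IsC": i_sc,
            "IAnd": i_and,
            "Ip1": i_p1,
            "Is2": i_s2,
            "fov": fov,
        }
        return final, inter
    return final
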