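"""B-COSFIRE line filters: bar (symmetric) and bar-ending (asymmetric)
detectors built from blurred, shifted Difference-of-Gaussians responses.

A B-COSFIRE filter is a set of tuples ``S = {(sigma_i, rho_i, phi_i)}``:
each tuple takes the half-wave-rectified response of a center-off DoG
filter of scale ``sigma_i``, blurs it with a Gaussian-weighted maximum
whose spread grows with the radial distance (``sigma' = sigma0 + alpha *
rho_i``), and shifts it by ``rho_i`` opposite to the polar angle ``phi_i``
so that all tuple responses meet at the filter center.  The filter output
is the weighted geometric mean of the aligned responses — an AND-like
combination that is nonzero only where *every* constituent response is
nonzero.  Symmetric filters (tuples on both sides of the center) respond
along line interiors; asymmetric filters (tuples on one side) respond at
line endings.  Rotation invariance comes from taking the maximum over a
bank of rotated copies.

The DoG is center-off (inner Gaussian of SD ``0.5 sigma`` subtracted with
larger amplitude), so dark lines on a bright background — retinal vessels
in the green plane — yield positive responses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from ._validation import as_binary, as_gray, check_same_shape
from .misodata import DegenerateRegionError, isodata_threshold

__all__ = [
    "DoGParams",
    "CosfireTuple",
    "CosfireFilter",
    "FilterParams",
    "BcosfireConfig",
    "dog_kernel",
    "dog_response",
    "blur_sigma",
    "blur_shift",
    "cosfire_response",
    "configure_line_filter",
    "rotation_invariant",
    "enhance",
    "segment_enhanced",
]

INNER_SIGMA_RATIO = 0.5  # SD of the internal Gaussian relative to sigma


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians scale and support.

    ``sigma`` is the outer SD in pixels; the inner SD is fixed at
    ``0.5 sigma``.  The kernel is evaluated on a square grid of half-width
    ``ceil(support_factor * sigma)``.
    """

    sigma: float
    support_factor: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def radius(self) -> int:
        return int(np.ceil(self.support_factor * self.sigma))


@dataclass(frozen=True)
class CosfireTuple:
    """One support point: DoG scale, radial distance, polar angle."""

    sigma: float
    rho: float
    phi: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        object.__setattr__(self, "phi", float(self.phi) % (2.0 * np.pi))


@dataclass(frozen=True)
class CosfireFilter:
    """A configured B-COSFIRE filter: tuple set plus blur constants.

    Tuple weights follow a Gaussian falloff in rho,
    ``w_i = exp(-rho_i^2 / (2 sigma_hat^2))`` with
    ``sigma_hat = max(rho_i) / 3`` (all weights 1 when every rho is 0).
    """

    tuples: tuple[CosfireTuple, ...]
    sigma0: float
    alpha: float
    kind: str  # "symmetric" | "asymmetric"

    def __post_init__(self) -> None:
        if len(self.tuples) < 1:
            raise ValueError("a filter needs at least one tuple")
        if self.kind not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown filter kind {self.kind!r}")

    @property
    def weights(self) -> np.ndarray:
        rhos = np.array([t.rho for t in self.tuples])
        rho_max = rhos.max()
        if rho_max == 0:
            return np.ones_like(rhos)
        sigma_hat = rho_max / 3.0
        return np.exp(-(rhos**2) / (2.0 * sigma_hat**2))

    def rotated(self, psi: float) -> "CosfireFilter":
        """Copy of the filter with every tuple angle offset by ``psi``."""
        return CosfireFilter(
            tuples=tuple(
                CosfireTuple(t.sigma, t.rho, t.phi + psi) for t in self.tuples
            ),
            sigma0=self.sigma0,
            alpha=self.alpha,
            kind=self.kind,
        )


@dataclass
class FilterParams:
    """Structural parameters of one filter: DoG scale, radii, blur constants."""

    sigma: float
    rhos: tuple[float, ...]
    sigma0: float
    alpha: float


@dataclass
class BcosfireConfig:
    """Bank configuration for the symmetric + asymmetric filter pair.

    Defaults are the published retinal configuration of the B-COSFIRE
    detector; ``t`` is the response-threshold fraction of the maximum
    (applied inside each oriented response).
    """

    symmetric: FilterParams = field(
        default_factory=lambda: FilterParams(2.4, (0, 2, 4, 6, 8), 3.0, 0.7)
    )
    asymmetric: FilterParams = field(
        default_factory=lambda: FilterParams(
            1.8, tuple(range(0, 23, 2)), 2.0, 0.1
        )
    )
    n_orientations: int = 12
    t: float = 0.4
    combine: str = "sum"  # how enhance() merges the two responses: sum | max

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError("t must lie in [0, 1]")
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be >= 1")


def dog_kernel(p: DoGParams) -> np.ndarray:
    """Evaluate the center-off DoG kernel on its (2r+1)^2 support grid.

    ``DoG(x, y) = G_sigma(x, y) - G_{0.5 sigma}(x, y)`` with unit-integral
    Gaussians, so the center value is negative and the kernel sum tends to
    zero as the support grows.
    """
    r = p.radius
    x, y = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    rr2 = x**2 + y**2
    s_out = p.sigma
    s_in = INNER_SIGMA_RATIO * p.sigma
    outer = np.exp(-rr2 / (2 * s_out**2)) / (2 * np.pi * s_out**2)
    inner = np.exp(-rr2 / (2 * s_in**2)) / (2 * np.pi * s_in**2)
    return outer - inner


def dog_response(img: np.ndarray, p: DoGParams) -> np.ndarray:
    """Half-wave-rectified DoG convolution, reflective borders."""
    img = as_gray(img)
    out = ndi.convolve(img, dog_kernel(p), mode="mirror")
    return np.maximum(out, 0.0)


def blur_sigma(filt: CosfireFilter, rho: float) -> float:
    """Blur spread for a tuple at radial distance rho: sigma0 + alpha * rho."""
    if rho < 0:
        raise ValueError("rho must be >= 0")
    return filt.sigma0 + filt.alpha * rho


def _weighted_max_blur(resp: np.ndarray, sigma_p: float) -> np.ndarray:
    """Gaussian-weighted maximum over a +-3 sigma' window.

    ``B(x) = max_{|x'| <= 3 sigma'} resp(x - x') * G_{sigma'}(x')`` — a
    grayscale dilation by the Gaussian in the log domain.
    """
    r = int(np.ceil(3.0 * sigma_p))
    x, y = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1))
    g = np.exp(-(x**2 + y**2) / (2 * sigma_p**2)) / (2 * np.pi * sigma_p**2)
    with np.errstate(divide="ignore"):
        log_resp = np.log(resp)
        structure = np.log(g)
        out = ndi.grey_dilation(log_resp, structure=structure, mode="nearest")
    return np.exp(out)


def _tuple_shift(tup: CosfireTuple) -> tuple[float, float]:
    """(row, col) displacement moving a tuple's response to the center."""
    dx = -tup.rho * np.cos(tup.phi)
    dy = -tup.rho * np.sin(tup.phi)
    return (dy, dx)


def blur_shift(
    resp: np.ndarray, tup: CosfireTuple, filt: CosfireFilter
) -> np.ndarray:
    """Blur a rectified DoG response and shift it onto the filter center."""
    resp = as_gray(resp, "response")
    sp = blur_sigma(filt, tup.rho)
    out = _weighted_max_blur(resp, sp)
    if tup.rho > 0:
        out = ndi.shift(out, shift=_tuple_shift(tup), order=1, mode="nearest")
    return out


def _raw_response(
    img_or_resp_cache: dict,
    img: np.ndarray,
    filt: CosfireFilter,
) -> np.ndarray:
    """Unthresholded weighted geometric mean of the tuple responses.

    ``img_or_resp_cache`` memoizes the angle-independent pieces — the
    rectified DoG response per sigma and the blurred response per
    (sigma, rho) — so a rotation bank pays only for the shifts.
    """
    weights = filt.weights
    wsum = weights.sum()
    log_acc = np.zeros_like(img, dtype=np.float64)
    zero = np.zeros(img.shape, dtype=bool)
    for tup, w in zip(filt.tuples, weights):
        key_dog = ("dog", tup.sigma)
        if key_dog not in img_or_resp_cache:
            img_or_resp_cache[key_dog] = dog_response(img, DoGParams(tup.sigma))
        key_blur = ("blur", tup.sigma, tup.rho)
        if key_blur not in img_or_resp_cache:
            img_or_resp_cache[key_blur] = _weighted_max_blur(
                img_or_resp_cache[key_dog], blur_sigma(filt, tup.rho)
            )
        s = img_or_resp_cache[key_blur]
        if tup.rho > 0:
            s = ndi.shift(s, shift=_tuple_shift(tup), order=1, mode="nearest")
            s = np.maximum(s, 0.0)  # bilinear interpolation cannot go below 0
        zero |= s <= 0
        with np.errstate(divide="ignore"):
            log_acc += np.where(s > 0, w * np.log(np.maximum(s, 1e-300)), 0.0)
    out = np.exp(log_acc / wsum)
    out[zero] = 0.0
    return out


def _threshold_fraction(resp: np.ndarray, t: float) -> np.ndarray:
    """Zero every value below ``t * max(resp)``."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    if t == 0.0:
        return resp
    cut = t * resp.max()
    return np.where(resp >= cut, resp, 0.0)


def cosfire_response(
    img: np.ndarray, filt: CosfireFilter, t: float = 0.0
) -> np.ndarray:
    """Single-orientation B-COSFIRE response, thresholded at ``t * max``.

    The weighted geometric mean annihilates at any pixel where a
    constituent tuple response is zero, so the filter fires only when the
    full line support is present.
    """
    img = as_gray(img)
    out = _raw_response({}, img, filt)
    return _threshold_fraction(out, t)


def configure_line_filter(kind: str, cfg: BcosfireConfig | None = None) -> CosfireFilter:
    """Analytic tuple placement for a vertical straight-line prototype.

    Symmetric filters place tuples at angles pi/2 and 3 pi/2 for every
    positive rho (both directions along the line) plus the center tuple;
    asymmetric filters use only pi/2 (one direction), responding at line
    endings.
    """
    cfg = cfg or BcosfireConfig()
    if kind == "symmetric":
        params = cfg.symmetric
    elif kind == "asymmetric":
        params = cfg.asymmetric
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    if len(params.rhos) == 0:
        raise ValueError("rho set must be nonempty")
    tuples: list[CosfireTuple] = []
    for rho in sorted(params.rhos):
        if rho == 0:
            tuples.append(CosfireTuple(params.sigma, 0.0, 0.0))
        elif kind == "symmetric":
            tuples.append(CosfireTuple(params.sigma, rho, np.pi / 2))
            tuples.append(CosfireTuple(params.sigma, rho, 3 * np.pi / 2))
        else:
            tuples.append(CosfireTuple(params.sigma, rho, np.pi / 2))
    if not tuples:
        raise ValueError("rho set produced no tuples")
    return CosfireFilter(
        tuples=tuple(tuples), sigma0=params.sigma0, alpha=params.alpha, kind=kind
    )


def rotation_invariant(
    img: np.ndarray, filt: CosfireFilter, cfg: BcosfireConfig | None = None
) -> np.ndarray:
    """Pointwise maximum over a bank of rotated filter copies.

    Symmetric filters are pi-periodic, so the bank spans [0, pi) in steps
    of pi/n; asymmetric filters span [0, 2 pi) in steps of 2 pi/n.
    """
    cfg = cfg or BcosfireConfig()
    img = as_gray(img)
    period = np.pi if filt.kind == "symmetric" else 2.0 * np.pi
    step = period / cfg.n_orientations
    cache: dict = {}
    out = None
    for k in range(cfg.n_orientations):
        resp = _threshold_fraction(
            _raw_response(cache, img, filt.rotated(k * step)), cfg.t
        )
        out = resp if out is None else np.maximum(out, resp)
    return out


def enhance(img: np.ndarray, cfg: BcosfireConfig | None = None) -> np.ndarray:
    """Vessel-enhanced image I_E_C: symmetric + asymmetric rotation banks.

    The symmetric bank traces vessel interiors; the asymmetric bank keeps
    responses alive at vessel endings where the symmetric support is
    incomplete.  The combined map is rescaled to [0, 1].
    """
    cfg = cfg or BcosfireConfig()
    img = as_gray(img)
    sym = rotation_invariant(img, configure_line_filter("symmetric", cfg), cfg)
    asym = rotation_invariant(img, configure_line_filter("asymmetric", cfg), cfg)
    if cfg.combine == "sum":
        out = sym + asym
    elif cfg.combine == "max":
        out = np.maximum(sym, asym)
    else:
        raise ValueError(f"unknown combine mode {cfg.combine!r}")
    peak = out.max()
    return out / peak if peak > 0 else out


def segment_enhanced(enhanced: np.ndarray, roi: np.ndarray) -> np.ndarray:
    """Binarize I_E_C inside the ROI with the global ISODATA threshold."""
    enhanced = as_gray(enhanced, "enhanced")
    roi = as_binary(roi, "roi")
    check_same_shape(enhanced, roi)
    try:
        t = isodata_threshold(enhanced, roi)
    except DegenerateRegionError:
        warnings.warn("degenerate enhanced image: returning empty segmentation")
        return np.zeros(enhanced.shape, dtype=bool)
    return roi & (enhanced > t)
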