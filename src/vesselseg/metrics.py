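"""Evaluation metrics for binary vessel segmentations.

Pixel-classification scores (Sn, Sp, Acc, AUC, MCC) are computed from the
confusion counts restricted to a region of interest; the structure-aware
C, A, L scores (and their product CAL) compare the segmented vessel
*network* to the gold standard on the full frame, penalizing
fragmentation, poor areal overlap and length mismatch respectively.

Notation: with ``N = TP + TN + FP + FN``, ``S = (TP + FN)/N`` and
``P = (TP + FP)/N``,

* ``Sn = TP/(TP + FN)``, ``Sp = TN/(TN + FP)``, ``Acc = (TP + TN)/N``,
* ``AUC = (Sn + Sp)/2`` (the two-point trapezoid, not a ROC integral),
* ``MCC = (TP/N - S P) / sqrt(P S (1 - S)(1 - P))``,
* ``C = 1 - min(1, |#C(G) - #C(S)| / #(G))`` over 8-connected components,
* ``A = #((d_e(S) n G) u (S n d_e(G))) / #(S u G)`` with disc dilation d_e,
* ``L = #((f(S) n d_b(G)) u (d_b(S) n f(G))) / #(f(S) u f(G))`` with
  skeletonization f, and ``CAL = C * A * L``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, skeletonize

from ._validation import as_binary, check_same_shape

__all__ = [
    "ConfusionCounts",
    "CalConfig",
    "MetricsReport",
    "confusion",
    "basic_scores",
    "mcc",
    "connectivity",
    "area_overlap",
    "length_similarity",
    "cal",
    "evaluate",
    "dice",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN pixel counts within a region of interest."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def s(self) -> float:
        """Gold foreground prevalence (TP + FN)/N."""
        return (self.tp + self.fn) / self.n

    @property
    def p(self) -> float:
        """Predicted foreground prevalence (TP + FP)/N."""
        return (self.tp + self.fp) / self.n


@dataclass
class CalConfig:
    """Dilation tolerances (pixels) of the A and L scores."""

    epsilon: float = 2.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if self.epsilon < 0 or self.beta < 0:
            raise ValueError("tolerances must be >= 0")


@dataclass
class MetricsReport:
    """All scores for one prediction/gold pair (NaN where undefined)."""

    sn: float
    sp: float
    acc: float
    auc: float
    mcc: float
    c: float
    a: float
    l: float
    cal: float

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(pred: np.ndarray, gold: np.ndarray, roi: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN over the ROI-true pixels only."""
    pred = as_binary(pred, "pred")
    gold = as_binary(gold, "gold")
    roi = as_binary(roi, "roi")
    check_same_shape(pred, gold)
    check_same_shape(pred, roi)
    if not roi.any():
        raise ValueError("roi is empty")
    p = pred[roi]
    g = gold[roi]
    tp = int(np.count_nonzero(p & g))
    tn = int(np.count_nonzero(~p & ~g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def basic_scores(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(Sn, Sp, Acc, AUC); Sn or Sp is NaN (with a warning) when undefined."""
    if c.tp + c.fn > 0:
        sn = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("no gold-positive pixels: Sn undefined")
        sn = math.nan
    if c.tn + c.fp > 0:
        sp = c.tn / (c.tn + c.fp)
    else:
        warnings.warn("no gold-negative pixels: Sp undefined")
        sp = math.nan
    acc = (c.tp + c.tn) / c.n
    auc = (sn + sp) / 2.0
    return sn, sp, acc, auc


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in its prevalence form."""
    s, p = c.s, c.p
    denom = p * s * (1.0 - s) * (1.0 - p)
    if denom <= 0:
        warnings.warn("degenerate class prevalence: MCC undefined")
        return math.nan
    return (c.tp / c.n - s * p) / math.sqrt(denom)


def connectivity(pred: np.ndarray, gold: np.ndarray) -> float:
    """C score: penalize mismatch in 8-connected component counts."""
    pred = as_binary(pred, "pred")
    gold = as_binary(gold, "gold")
    check_same_shape(pred, gold)
    n_gold_px = int(np.count_nonzero(gold))
    if n_gold_px == 0:
        raise ValueError("gold segmentation is empty")
    _, n_g = ndi.label(gold, structure=_EIGHT)
    _, n_p = ndi.label(pred, structure=_EIGHT)
    return 1.0 - min(1.0, abs(n_g - n_p) / n_gold_px)


def area_overlap(pred: np.ndarray, gold: np.ndarray, cfg: CalConfig | None = None) -> float:
    """A score: dilation-tolerant Jaccard overlap of the two vessel areas."""
    cfg = cfg or CalConfig()
    pred = as_binary(pred, "pred")
    gold = as_binary(gold, "gold")
    check_same_shape(pred, gold)
    union = pred | gold
    if not union.any():
        raise ValueError("both segmentations are empty")
    se = disk(int(round(cfg.epsilon)))
    pred_d = dilation(pred, se)
    gold_d = dilation(gold, se)
    num = (pred_d & gold) | (pred & gold_d)
    return float(np.count_nonzero(num) / np.count_nonzero(union))


def length_similarity(pred: np.ndarray, gold: np.ndarray, cfg: CalConfig | None = None) -> float:
    """L score: dilation-tolerant overlap of the two skeleton networks."""
    cfg = cfg or CalConfig()
    pred = as_binary(pred, "pred")
    gold = as_binary(gold, "gold")
    check_same_shape(pred, gold)
    if not pred.any() or not gold.any():
        raise ValueError("pred and gold must both be nonempty")
    sk_pred = skeletonize(pred)
    sk_gold = skeletonize(gold)
    sk_union = sk_pred | sk_gold
    if not sk_union.any():
        raise ValueError("empty skeleton union")
    se = disk(int(round(cfg.beta)))
    pred_d = dilation(pred, se)
    gold_d = dilation(gold, se)
    num = (sk_pred & gold_d) | (pred_d & sk_gold)
    return float(np.count_nonzero(num) / np.count_nonzero(sk_union))


def cal(c: float, a: float, l: float) -> float:
    """CAL = C * A * L."""
    return c * a * l


def dice(pred: np.ndarray, gold: np.ndarray) -> float:
    """Dice coefficient 2|P n G| / (|P| + |G|); 1.0 when both are empty."""
    pred = as_binary(pred, "pred")
    gold = as_binary(gold, "gold")
    check_same_shape(pred, gold)
    denom = int(np.count_nonzero(pred)) + int(np.count_nonzero(gold))
    if denom == 0:
        return 1.0
    return 2.0 * np.count_nonzero(pred & gold) / denom


def evaluate(
    pred: np.ndarray,
    gold: np.ndarray,
    roi: np.ndarray | None = None,
    cfg: CalConfig | None = None,
) -> MetricsReport:
    """Assemble all scores for one prediction/gold pair.

    Confusion-based scores use the ROI (full frame when ``None``); the
    structural C/A/L scores always use the full binary frames.
    """
    cfg = cfg or CalConfig()
    pred = as_binary(pred, "pred")
    gold = as_binary(gold, "gold")
    if roi is None:
        roi = np.ones(pred.shape, dtype=bool)
    counts = confusion(pred, gold, roi)
    sn, sp, acc, auc = basic_scores(counts)
    m = mcc(counts)
    c = connectivity(pred, gold)
    if pred.any():
        a = area_overlap(pred, gold, cfg)
        l = length_similarity(pred, gold, cfg)
    else:
        a = 0.0
        l = 0.0
    return MetricsReport(sn=sn, sp=sp, acc=acc, auc=auc, mcc=m, c=c, a=a, l=l,
                         cal=cal(c, a, l))
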