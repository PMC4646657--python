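"""Pixelwise segmentation evaluation.

Confusion counts against a reference mask, the Se/Sp/Acc summary metrics
with the (Se+Sp)/2 Auc surrogate (a definitional average, not a ROC
threshold sweep), Dice overlap, TP/FP/FN/TN difference maps for
visualization, and the paired t-test used to compare per-image metric
tables between methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "performance_metrics",
    "auc_from_se_sp",
    "dice",
    "paired_t_test",
    "difference_map",
    "DIFFERENCE_LABELS",
    "round_metric",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    se: float
    sp: float
    acc: float
    auc: float

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {
            "se": round_metric(self.se, ndigits),
            "sp": round_metric(self.sp, ndigits),
            "acc": round_metric(self.acc, ndigits),
            "auc": round_metric(self.auc, ndigits),
        }


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must contain only 0/1 values, found {vals[:5]}")
    return arr.astype(bool)


def confusion_counts(
    pred: np.ndarray, truth: np.ndarray, roi: Optional[np.ndarray] = None
) -> ConfusionCounts:
    """Pixel confusion counts of ``pred`` against ``truth`` within ``roi``
    (all pixels when no region of interest is given)."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if roi is not None:
        r = _as_binary(roi, "roi")
        if r.shape != p.shape:
            raise ValueError(f"roi shape {r.shape} does not match masks {p.shape}")
        p, t = p[r], t[r]
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        tn=int(np.count_nonzero(~p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
    )


def performance_metrics(c: ConfusionCounts) -> MetricsReport:
    """Se = tp/(tp+fn), Sp = tn/(tn+fp), Acc = (tp+tn)/total,
    Auc = (Se+Sp)/2."""
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no positive pixels in truth")
    if c.tn + c.fp == 0:
        raise ValueError("specificity undefined: no negative pixels in truth")
    se = c.tp / (c.tp + c.fn)
    sp = c.tn / (c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    return MetricsReport(se=se, sp=sp, acc=acc, auc=auc_from_se_sp(se, sp))


def auc_from_se_sp(se: float, sp: float) -> float:
    """The (Se + Sp) / 2 summary used as 'Auc' in the evaluation."""
    return (se + sp) / 2.0


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|P&T| / (|P| + |T|); 1.0 when both masks are empty."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(p & t)) / denom


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on d = a - b, two-sided p with n-1 dof.

    Raises on zero-variance differences (the statistic is undefined).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be two equal-length 1-D sequences")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate paired t-test: differences have zero variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * _sps.t.sf(abs(t), n - 1)
    return float(t), float(p)


#: label codes of :func:`difference_map` (2 * pred + truth)
DIFFERENCE_LABELS = {0: "TN", 1: "FN", 2: "FP", 3: "TP"}


def difference_map(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-pixel agreement labels for visualization (uint8 codes, see
    :data:`DIFFERENCE_LABELS`)."""
    p = _as_binary(pred, "pred")
    t = _as_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return (2 * p.astype(np.uint8) + t.astype(np.uint8)).astype(np.uint8)


def round_metric(x: float, ndigits: int = 3) -> float:
    """Round half up at ``ndigits`` decimals (report/table convention).

    Quantizes through three guard digits first so that values sitting on a
    decimal half (e.g. (0.758 + 0.965) / 2 = 0.8615, stored in binary just
    below it) round the way the printed tables do.
    """
    guard = Decimal(repr(float(x))).quantize(
        Decimal(1).scaleb(-(ndigits + 3)), rounding=ROUND_HALF_UP
    )
    return float(guard.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))
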