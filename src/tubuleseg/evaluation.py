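"""Pixel-level segmentation metrics and the TP/FN/FP overlay renderer.

Metrics follow the standard definitions over pixel sets A (predicted tubule
pixels) and B (ground-truth tubule pixels):

    DSC         = 2 |A∩B| / (|A| + |B|)  =  2 TP / (2 TP + FP + FN)
    recall      = 100 * TP / (TP + FN)
    specificity = 100 * TN / (FP + TN)
    FPR         = 100 - specificity

DSC of two empty masks is defined as 1.0 (correctly predicting "no tubule"
is not penalised).  Recall/specificity/FPR are reported in percent; DSC as a
fraction with a percent accessor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "binarize", "score", "aggregate", "overlay"]


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    dsc: float  # fraction in [0, 1]
    recall: float  # percent
    specificity: float  # percent
    fpr: float  # percent

    @property
    def dsc_percent(self) -> float:
        return 100.0 * self.dsc

    @property
    def total_pixels(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "MetricsReport":
        denom = 2 * tp + fp + fn
        dsc = 1.0 if denom == 0 else 2.0 * tp / denom
        recall = 100.0 * tp / (tp + fn) if tp + fn > 0 else 100.0
        specificity = 100.0 * tn / (fp + tn) if fp + tn > 0 else 100.0
        return cls(
            tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
            dsc=dsc, recall=recall, specificity=specificity, fpr=100.0 - specificity,
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "dsc": self.dsc, "dsc_percent": self.dsc_percent,
            "recall": self.recall, "specificity": self.specificity, "fpr": self.fpr,
        }


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a [0,1] probability map; pixels >= threshold become 1."""
    arr = np.asarray(prob_map)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("probability map values must lie in [0, 1]")
    return (arr >= threshold).astype(np.uint8)


def _check_binary_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def score(pred: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Confusion counts and derived metrics for one mask pair."""
    p, t = _check_binary_pair(pred, truth)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return MetricsReport.from_counts(tp, fp, tn, fn)


def aggregate(reports: list[MetricsReport], mode: str = "macro") -> MetricsReport:
    """Combine per-image reports.

    ``macro``: unweighted mean of each metric across images (counts summed
    for reference).  ``micro``: metrics recomputed from the summed counts.
    """
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    tp = sum(r.tp for r in reports)
    fp = sum(r.fp for r in reports)
    tn = sum(r.tn for r in reports)
    fn = sum(r.fn for r in reports)
    if mode == "micro":
        return MetricsReport.from_counts(tp, fp, tn, fn)
    if mode == "macro":
        n = len(reports)
        spec_mean = sum(r.specificity for r in reports) / n
        return MetricsReport(
            tp=tp, fp=fp, tn=tn, fn=fn,
            dsc=sum(r.dsc for r in reports) / n,
            recall=sum(r.recall for r in reports) / n,
            specificity=spec_mean,
            fpr=100.0 - spec_mean,
        )
    raise ValueError(f"unknown aggregation mode: {mode!r}")


OVERLAY_COLORS = {
    "tp": (0, 200, 0),  # green: correctly segmented
    "fn": (0, 80, 255),  # blue: missed regions that must be segmented
    "fp": (255, 0, 0),  # red: incorrectly segmented
}


def overlay(
    pred: np.ndarray,
    truth: np.ndarray,
    image: np.ndarray,
    alpha: float = 0.5,
) -> np.ndarray:
    """Alpha-blend TP (green), FN (blue) and FP (red) tints over the image."""
    p, t = _check_binary_pair(pred, truth)
    if image.shape[:2] != p.shape:
        raise ValueError(f"image shape {image.shape[:2]} does not match masks {p.shape}")
    out = image.astype(np.float64).copy()
    for region, color in (
        (p & t, OVERLAY_COLORS["tp"]),
        (~p & t, OVERLAY_COLORS["fn"]),
        (p & ~t, OVERLAY_COLORS["fp"]),
    ):
        out[region] = (1.0 - alpha) * out[region] + alpha * np.asarray(color, dtype=np.float64)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
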