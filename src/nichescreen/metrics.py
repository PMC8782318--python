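"""Model accuracy and map-similarity statistics.

Accuracy: presence-vs-background AUC (rank-based Mann-Whitney), percent
correctly classified (PCC) and the True Skill Statistic (TSS) at a
threshold.  The default threshold maximizes TSS, a standard reproducible
choice for presence/background evaluation; the threshold used is always
recorded in the output.

Similarity between two suitability maps: Schoener's D (total-variation
affinity), Warren's I (Hellinger affinity) on cell values normalized to sum
to one over the shared valid mask, and Pearson's r on the raw values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


def _average_ranks(v: np.ndarray) -> np.ndarray:
    """Midranks (1-based, ties averaged); lean equivalent of rankdata."""
    order = np.argsort(v, kind="stable")
    s = v[order]
    new_grp = np.empty(s.size, dtype=bool)
    new_grp[0] = True
    np.not_equal(s[1:], s[:-1], out=new_grp[1:])
    starts = np.flatnonzero(new_grp)
    counts = np.diff(np.append(starts, s.size))
    avg = starts + (counts + 1) / 2.0  # average 1-based rank per tie group
    ranks = np.empty(s.size)
    ranks[order] = np.repeat(avg, counts)
    return ranks


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(presence score > background score), ties as 1/2."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = _average_ranks(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


@dataclass
class EvalMetrics:
    """Thresholded confusion-matrix metrics plus AUC."""

    auc: float
    pcc: float
    tss: float
    threshold_used: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN

    @property
    def sensitivity(self) -> float:
        tp, _, _, fn = self.confusion
        return tp / (tp + fn) if tp + fn else float("nan")

    @property
    def specificity(self) -> float:
        _, fp, tn, _ = self.confusion
        return tn / (tn + fp) if tn + fp else float("nan")


def _confusion_at(p: np.ndarray, b: np.ndarray, thr: float) -> tuple[int, int, int, int]:
    tp = int((p >= thr).sum())
    fn = p.size - tp
    fp = int((b >= thr).sum())
    tn = b.size - fp
    return tp, fp, tn, fn


def max_tss_threshold(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Threshold (among observed score values) maximizing TSS; ties -> lowest."""
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    candidates = np.unique(np.concatenate([p, b]))
    best_thr, best_tss = candidates[0], -np.inf
    for thr in candidates:
        tp, fp, tn, fn = _confusion_at(p, b, thr)
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_thr = tss, thr
    return float(best_thr)


def confusion_metrics(
    presence_scores: np.ndarray,
    background_scores: np.ndarray,
    threshold: float | None = None,
) -> EvalMetrics:
    """AUC, PCC and TSS at a threshold (default: the max-TSS threshold).

    A score ≥ threshold predicts presence.  PCC is reported as a
    proportion in [0, 1].
    """
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if threshold is None:
        threshold = max_tss_threshold(p, b)
    tp, fp, tn, fn = _confusion_at(p, b, threshold)
    total = tp + fp + tn + fn
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return EvalMetrics(
        auc=auc(p, b),
        pcc=(tp + tn) / total,
        tss=sens + spec - 1.0,
        threshold_used=float(threshold),
        confusion=(tp, fp, tn, fn),
    )


@dataclass
class SimilarityStats:
    """Niche-overlap statistics between two suitability maps."""

    d: float
    i: float
    r_maps: float  # NaN when either map is constant over the shared mask


def niche_overlap(map1, map2) -> SimilarityStats:
    """Schoener's D, Warren's I and Pearson's r between two suitability maps.

    Accepts two ``rasters_io.Layer`` objects (grid-compatible) or two
    masked/plain arrays of equal shape.  D and I are computed on cell
    values normalized to sum to 1 over the shared valid mask; r on the raw
    values.  Constant maps make r undefined: NaN is returned with a warning.
    """
    a, b, ok = _common_values(map1, map2)
    if ok.sum() == 0:
        raise ValueError("no shared valid cells between the two maps")
    a, b = a[ok], b[ok]
    sa, sb = a.sum(), b.sum()
    if sa <= 0 or sb <= 0:
        raise ValueError("maps must have positive total suitability")
    p, q = a / sa, b / sb
    d = 1.0 - 0.5 * np.abs(p - q).sum()
    i = 1.0 - 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("niche_overlap: constant map; Pearson r undefined")
        r = float("nan")
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return SimilarityStats(d=float(d), i=float(i), r_maps=r)


def _common_values(map1, map2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    from .rasters_io import Layer  # local import to avoid a cycle

    if isinstance(map1, Layer) and isinstance(map2, Layer):
        if not map1.grid.compatible(map2.grid):
            raise ValueError("maps are not grid-compatible")
        a = map1.values.filled(np.nan).ravel()
        b = map2.values.filled(np.nan).ravel()
    else:
        a = np.ma.filled(np.ma.masked_invalid(np.asarray(map1, dtype=float)), np.nan).ravel()
        b = np.ma.filled(np.ma.masked_invalid(np.asarray(map2, dtype=float)), np.nan).ravel()
        if a.shape != b.shape:
            raise ValueError("maps must have the same shape")
    ok = ~np.isnan(a) & ~np.isnan(b)
    return a, b, ok
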