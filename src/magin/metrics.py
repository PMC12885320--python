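"""CAFA-style evaluation: protein-centric Fmax, IC-weighted Smin,
micro-averaged AUPR, class-centric AUC, the annotation-frequency Naive
baseline, and frequency/depth error strata.

All metrics operate on an m x L score matrix against an ancestor-closed
binary truth matrix over the same protein and term orders.  Thresholded
metrics sweep the inclusive grid {0.00, 0.01, ..., 1.00}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_auc_score

THRESHOLDS = np.round(np.linspace(0.0, 1.0, 101), 2)

FREQ_BUCKETS = (("high", 100, np.inf), ("medium", 10, 99), ("low", 0, 9))
DEPTH_BUCKETS = (("shallow", 0, 3), ("medium", 4, 6), ("deep", 7, 20))


def _check(scores, truth):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise ValueError("score and truth shapes differ")
    return scores, (truth > 0).astype(int)


def fmax(scores: np.ndarray, truth: np.ndarray,
         thresholds: np.ndarray = THRESHOLDS) -> tuple[float, float]:
    """Protein-centric maximum F-measure over the threshold grid.

    At each threshold, precision is averaged only over proteins with at
    least one predicted term (the CAFA convention) while recall is
    averaged over every protein that has at least one true term; ties on
    F return the smallest threshold.
    """
    scores, truth = _check(scores, truth)
    m = scores.shape[0]
    if m < 1:
        raise ValueError("need at least one protein")
    n_true = truth.sum(axis=1)
    annotated = n_true > 0
    if not annotated.any():
        raise ValueError("truth matrix has no annotated protein")
    best, best_t = 0.0, float(thresholds[0])
    for t in thresholds:
        pred = scores >= t
        tp = (pred & (truth == 1)).sum(axis=1)
        n_pred = pred.sum(axis=1)
        covered = n_pred > 0
        prec = tp[covered] / n_pred[covered] if covered.any() else np.array([])
        p = prec.mean() if prec.size else 0.0
        r = (tp[annotated] / n_true[annotated]).mean()
        f = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        if f > best + 1e-12:
            best, best_t = float(f), float(t)
    return best, best_t


def smin(scores: np.ndarray, truth: np.ndarray, ic: dict[str, float],
         terms: list[str], thresholds: np.ndarray = THRESHOLDS) -> float:
    """Minimum semantic distance sqrt(ru^2 + mi^2) over the grid.

    ru (remaining uncertainty) averages the summed information content of
    missed true terms per protein; mi (misinformation) that of predicted
    false terms.  The sweep runs over the positive thresholds (0, 1] —
    the t = 0 point predicts every term for every protein and carries no
    information about the ranking.
    """
    scores, truth = _check(scores, truth)
    missing = [t for t in terms if t not in ic]
    if missing:
        raise KeyError(f"IC table missing terms: {missing}")
    w = np.array([ic[t] for t in terms], dtype=float)
    m = scores.shape[0]
    best = np.inf
    for t in thresholds[thresholds > 0]:
        pred = scores >= t
        ru = float((((truth == 1) & ~pred) @ w).sum() / m)
        mi = float(((pred & (truth == 0)) @ w).sum() / m)
        best = min(best, float(np.sqrt(ru ** 2 + mi ** 2)))
    return best


def aupr_micro(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the pair-pooled precision-recall curve (trapezoidal)."""
    scores, truth = _check(scores, truth)
    y = truth.ravel()
    if y.sum() == 0:
        raise ValueError("no positive protein-term pairs")
    prec, rec, _ = precision_recall_curve(y, scores.ravel())
    return float(_trapezoid_auc(rec, prec))


def aupr_macro(scores: np.ndarray, truth: np.ndarray) -> float:
    """Unweighted mean of per-term PR areas over terms with a positive."""
    scores, truth = _check(scores, truth)
    areas = []
    for j in range(truth.shape[1]):
        if truth[:, j].sum() == 0:
            continue
        prec, rec, _ = precision_recall_curve(truth[:, j], scores[:, j])
        areas.append(_trapezoid_auc(rec, prec))
    if not areas:
        raise ValueError("no term with a positive")
    return float(np.mean(areas))


def term_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[float | None, int]:
    """Mean per-term ROC AUC over terms with both classes present.

    The rank-based AUC scores ties as 0.5, so a constant-score predictor
    lands on exactly 0.5 for every mixed term.  Returns (mean, n_terms);
    mean is None when no term qualifies.
    """
    scores, truth = _check(scores, truth)
    aucs = []
    for j in range(truth.shape[1]):
        col = truth[:, j]
        if 0 < col.sum() < len(col):
            aucs.append(roc_auc_score(col, scores[:, j]))
    if not aucs:
        return None, 0
    return float(np.mean(aucs)), len(aucs)


def naive_baseline(train_ann, terms: list[str],
                   proteins: list[str]) -> np.ndarray:
    """Annotation-frequency predictor: identical score vector per protein.

    score(p, t) = fraction of training proteins annotated with t; terms
    unseen in training score 0.
    """
    if not train_ann.propagated:
        raise ValueError("training annotations must be propagated")
    n = len(train_ann.by_protein)
    if n == 0:
        raise ValueError("empty training set")
    freq = np.array([
        sum(1 for ts in train_ann.by_protein.values() if t in ts) / n
        for t in terms])
    return np.tile(freq, (len(proteins), 1))


def per_term_f1(scores: np.ndarray, truth: np.ndarray,
                thresholds: np.ndarray = THRESHOLDS) -> np.ndarray:
    """Best-over-thresholds F1 for every term column independently."""
    scores, truth = _check(scores, truth)
    L = scores.shape[1]
    out = np.zeros(L)
    for t in thresholds:
        pred = scores >= t
        tp = (pred & (truth == 1)).sum(axis=0)
        fp = (pred & (truth == 0)).sum(axis=0)
        fn = ((~pred) & (truth == 1)).sum(axis=0)
        denom = 2 * tp + fp + fn
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
        out = np.maximum(out, f1)
    return out


def error_strata(scores: np.ndarray, truth: np.ndarray, terms: list[str],
                 train_ann, depths: dict[str, int]) -> dict:
    """Mean per-term best F1 bucketed by training frequency and depth.

    Frequency buckets: high >= 100 training occurrences, medium 10-99,
    low < 10.  Depth buckets: shallow 0-3, medium 4-6, deep 7-20.  Empty
    buckets are reported as absent.
    """
    f1 = per_term_f1(scores, truth)
    counts = {t: sum(1 for ts in train_ann.by_protein.values() if t in ts)
              for t in terms}
    out: dict = {"frequency": {}, "depth": {}}
    for name, lo, hi in FREQ_BUCKETS:
        vals = [f1[j] for j, t in enumerate(terms) if lo <= counts[t] <= hi]
        if vals:
            out["frequency"][name] = {"mean_f1": float(np.mean(vals)),
                                      "n_terms": len(vals)}
    for name, lo, hi in DEPTH_BUCKETS:
        vals = [f1[j] for j, t in enumerate(terms)
                if t in depths and lo <= depths[t] <= hi]
        if vals:
            out["depth"][name] = {"mean_f1": float(np.mean(vals)),
                                  "n_terms": len(vals)}
    return out


@dataclass
class EvalReport:
    """Bundle of the four headline metrics plus per-term strata."""

    fmax: float
    fmax_threshold: float
    smin: float
    aupr: float
    auc: float | None
    auc_n_terms: int
    strata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        auc = "n/a" if self.auc is None else f"{self.auc:.3f}"
        return (f"Fmax {self.fmax:.3f} (t={self.fmax_threshold:.2f})  "
                f"Smin {self.smin:.3f}  AUPR {self.aupr:.3f}  "
                f"AUC {auc} ({self.auc_n_terms} terms)")


def evaluate_scores(scores: np.ndarray, truth: np.ndarray, terms: list[str],
                    ic: dict[str, float], train_ann=None,
                    depths: dict[str, int] | None = None) -> EvalReport:
    """Full metric suite on one score/truth pair."""
    f, thr = fmax(scores, truth)
    s = smin(scores, truth, ic, terms)
    pr = aupr_micro(scores, truth)
    a, n = term_auc(scores, truth)
    strata = {}
    if train_ann is not None and depths is not None:
        strata = error_strata(scores, truth, terms, train_ann, depths)
    return EvalReport(f, thr, s, pr, a, n, strata)
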