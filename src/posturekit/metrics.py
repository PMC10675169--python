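"""Evaluation statistics for per-second multilabel tracks.

Accuracy, the multilabel confusion table with truth-conditional rates, the
intersection-over-union TP / (TP + FP + FN), per-label AUROC and Cohen's
kappa with its interpretation bands.  Seconds unlabelled in either track are
dropped pairwise before any counting.

"Mean" figures are macro averages over the eight labels; pooled (micro)
figures are reported alongside.  The headline kappa for two multilabel
tracks is the unweighted mean of the per-label kappa values, with per-label
values always available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .annotation import AlignmentError, AnnotationTrack
from .labels import LABELS, N_LABELS


def _paired_labels(pred: AnnotationTrack, truth: AnnotationTrack) -> tuple[np.ndarray, np.ndarray]:
    if len(pred) != len(truth):
        raise AlignmentError(f"track lengths differ: {len(pred)} vs {len(truth)}")
    keep = ~(pred.unlabelled | truth.unlabelled)
    return pred.labels[keep].astype(np.int64), truth.labels[keep].astype(np.int64)


def _counts(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Per-label [TP, FP, TN, FN] counts; shape (8, 4)."""
    tp = ((pred == 1) & (truth == 1)).sum(axis=0)
    fp = ((pred == 1) & (truth == 0)).sum(axis=0)
    tn = ((pred == 0) & (truth == 0)).sum(axis=0)
    fn = ((pred == 0) & (truth == 1)).sum(axis=0)
    return np.stack([tp, fp, tn, fn], axis=1)


@dataclass
class AccuracyResult:
    micro: float                 # pooled (TP+TN)/(all) over all labels
    macro: float                 # mean of per-label accuracies
    per_label: dict[str, float]

    def __float__(self) -> float:
        return self.micro


def accuracy(pred: AnnotationTrack, truth: AnnotationTrack) -> AccuracyResult:
    """Fraction of correct label decisions, pooled and per label."""
    p, t = _paired_labels(pred, truth)
    c = _counts(p, t)
    tp, fp, tn, fn = c[:, 0], c[:, 1], c[:, 2], c[:, 3]
    per = (tp + tn) / np.maximum(tp + fp + tn + fn, 1)
    micro = float((tp + tn).sum() / max((tp + fp + tn + fn).sum(), 1))
    return AccuracyResult(micro=micro, macro=float(per.mean()),
                          per_label=dict(zip(LABELS, per.astype(float))))


@dataclass
class IoUResult:
    mean: float                  # macro mean over labels where defined
    per_label: dict[str, float]  # NaN where TP+FP+FN = 0

    def __float__(self) -> float:
        return self.mean


def iou_score(pred: AnnotationTrack, truth: AnnotationTrack) -> IoUResult:
    """Intersection over union, TP / (TP + FP + FN), per label and macro."""
    p, t = _paired_labels(pred, truth)
    c = _counts(p, t)
    denom = c[:, 0] + c[:, 1] + c[:, 3]
    per = np.where(denom > 0, c[:, 0] / np.maximum(denom, 1), np.nan)
    undefined = [LABELS[j] for j in range(N_LABELS) if denom[j] == 0]
    if undefined:
        warnings.warn(f"IoU undefined (no positives in prediction or truth) for: {undefined}")
    defined = per[~np.isnan(per)]
    mean = float(defined.mean()) if defined.size else float("nan")
    return IoUResult(mean=mean, per_label=dict(zip(LABELS, per.astype(float))))


@dataclass
class ConfusionTable:
    """Per-label counts and truth-conditional rates.

    TP and FN rates are normalized within truth-positives; TN and FP rates
    within truth-negatives, matching the usual rate presentation (an FN rate
    of 0.42 means 42% of truly positive seconds were missed).
    """

    counts: dict[str, dict[str, int]]
    rates: dict[str, dict[str, float]]
    n_compared: int


def confusion(pred: AnnotationTrack, truth: AnnotationTrack) -> ConfusionTable:
    p, t = _paired_labels(pred, truth)
    c = _counts(p, t)
    counts, rates = {}, {}
    for j, name in enumerate(LABELS):
        tp, fp, tn, fn = (int(v) for v in c[j])
        pos, neg = tp + fn, tn + fp
        counts[name] = {"TP": tp, "FP": fp, "TN": tn, "FN": fn}
        rates[name] = {
            "TP": tp / pos if pos else float("nan"),
            "FN": fn / pos if pos else float("nan"),
            "TN": tn / neg if neg else float("nan"),
            "FP": fp / neg if neg else float("nan"),
        }
    return ConfusionTable(counts=counts, rates=rates, n_compared=p.shape[0])


def auroc(scores: np.ndarray, truth: AnnotationTrack) -> dict[str, float]:
    """Per-label area under the ROC curve.

    Equals the probability that a random positive second outscores a random
    negative one, ties counted one half.  Labels with a single class among
    the compared seconds are reported as NaN with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.shape != (len(truth), N_LABELS):
        raise AlignmentError(
            f"scores must be ({len(truth)}, {N_LABELS}); got {scores.shape}"
        )
    keep = ~truth.unlabelled
    s, t = scores[keep], truth.labels[keep]
    out: dict[str, float] = {}
    missing = []
    for j, name in enumerate(LABELS):
        col = t[:, j]
        if col.min() == col.max():
            out[name] = float("nan")
            missing.append(name)
        else:
            out[name] = float(roc_auc_score(col, s[:, j]))
    if missing:
        warnings.warn(f"AUROC undefined (single-class truth) for: {missing}")
    return out


@dataclass
class KappaResult:
    overall: float               # unweighted mean of defined per-label kappas
    per_label: dict[str, float]  # NaN where chance agreement is 1

    def __float__(self) -> float:
        return self.overall


def _kappa_binary(a: np.ndarray, b: np.ndarray) -> float:
    n = a.shape[0]
    n11 = int(((a == 1) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    pa1, pb1 = a.sum() / n, b.sum() / n
    p_o = (n11 + n00) / n
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    if p_e >= 1.0 - 1e-15:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def cohens_kappa(track_a: AnnotationTrack, track_b: AnnotationTrack) -> KappaResult:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e), per label.

    p_e comes from the two tracks' marginal label frequencies.  Labels on
    which both tracks are constant have no chance-corrected agreement and are
    reported NaN; the overall value is the mean over defined labels.
    """
    a, b = _paired_labels(track_a, track_b)
    if a.shape[0] == 0:
        raise AlignmentError("no pairwise-labelled seconds to compare")
    per = {name: _kappa_binary(a[:, j], b[:, j]) for j, name in enumerate(LABELS)}
    vals = np.array([v for v in per.values() if not np.isnan(v)])
    if vals.size == 0:
        warnings.warn("kappa undefined for every label (constant tracks)")
        overall = float("nan")
    else:
        overall = float(vals.mean())
    return KappaResult(overall=overall, per_label=per)


#: Agreement bands for interpreting kappa.  The band between weak and strong
#: carries no name in the source scale (an apparent typesetting omission);
#: "moderate" is used here, consistent with neighbouring scales.
_KAPPA_BANDS = (
    (0.20, "none"),
    (0.39, "minimal"),
    (0.59, "weak"),
    (0.79, "moderate"),
    (0.90, "strong"),
)


def interpret_kappa(value: float) -> str:
    """Map a kappa value to its agreement band; negative values mean 'none'."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1]; got {value}")
    for upper, name in _KAPPA_BANDS:
        if value <= upper + 1e-12:
            return name
    return "almost perfect"
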