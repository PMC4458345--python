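"""Segmentation evaluation: centroid matching and detection metrics.

Detected nuclei are compared to ground-truth centroids by greedy one-to-one
matching inside a spherical neighborhood whose radius corresponds to the
average nucleus diameter.  From the matched count TP, the spurious and missed
counts follow as FP = n_seg − TP and FN = n_gt − TP, and four standard
detection metrics are derived:

    Recall    = TP / (TP + FN)
    Precision = TP / (TP + FP)
    Accuracy  = TP / (TP + FN + FP)
    F-measure = 2·Precision·Recall / (Precision + Recall)
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ValidationError


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    n_gt: int
    n_seg: int
    pairs: list[tuple[int, int]]  # (gt index, seg index), one-to-one


@dataclass
class Metrics:
    recall: float
    precision: float
    accuracy: float
    f_measure: float


def match_centroids(gt, seg, radius: float) -> MatchResult:
    """Greedy one-to-one centroid matching within a spherical neighborhood.

    Ground-truth centroids are visited in input order; each claims the closest
    still-unmatched segmentation centroid within Euclidean distance
    ``radius`` (distance ties go to the lowest seg index).  Claimed centroids
    are consumed, so matching is one-to-one.
    """
    if radius <= 0:
        raise ValidationError(f"radius must be positive, got {radius}")
    gt = np.asarray(gt, float).reshape(-1, 3)
    seg = np.asarray(seg, float).reshape(-1, 3)
    taken = np.zeros(len(seg), bool)
    pairs = []
    for gi, g in enumerate(gt):
        if len(seg) == 0:
            break
        d = np.linalg.norm(seg - g, axis=1)
        d[taken] = np.inf
        candidates = np.flatnonzero(d <= radius)
        if len(candidates) == 0:
            continue
        best = candidates[np.argmin(d[candidates])]  # argmin returns first on ties
        taken[best] = True
        pairs.append((gi, int(best)))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(seg) - tp, fn=len(gt) - tp, n_gt=len(gt), n_seg=len(seg), pairs=pairs
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(m: MatchResult) -> Metrics:
    """The four detection metrics; every 0/0 is defined as 0."""
    if m.n_gt == 0 and m.n_seg == 0:
        raise ValidationError("metrics undefined: no ground-truth and no segmented objects")
    recall = _ratio(m.tp, m.tp + m.fn)
    precision = _ratio(m.tp, m.tp + m.fp)
    accuracy = _ratio(m.tp, m.tp + m.fn + m.fp)
    f_measure = _ratio(2 * precision * recall, precision + recall)
    return Metrics(recall=recall, precision=precision, accuracy=accuracy, f_measure=f_measure)


def metrics_from_counts(n_gt: int, n_seg: int, tp: int) -> Metrics:
    """Metrics straight from a (# ground truth, # segmented, # matched) triple."""
    if tp > min(n_gt, n_seg):
        raise ValidationError(f"tp={tp} exceeds min(n_gt={n_gt}, n_seg={n_seg})")
    return compute_metrics(
        MatchResult(tp=tp, fp=n_seg - tp, fn=n_gt - tp, n_gt=n_gt, n_seg=n_seg, pairs=[])
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Half-up decimal rounding as used in reported tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def volume_summary(volumes) -> tuple[float, float, int]:
    """Mean and sample standard deviation (n−1; 0 when n = 1) of volumes.

    Accepts an iterable of numbers or of records with a ``volume_um3`` field.
    """
    vals = np.array(
        [getattr(v, "volume_um3", v) for v in volumes], dtype=float
    )
    if vals.size == 0:
        raise ValidationError("volume_summary needs at least one volume")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return mean, sd, int(vals.size)
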