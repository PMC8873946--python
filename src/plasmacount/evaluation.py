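"""Concordance evaluation: assignment matching, confusion matrix, macro-F1,
plasma-cell percentage, report-range midpoints and ICC.

Detections are paired with ground-truth points by minimum-cost linear sum
assignment on Euclidean distances, gated at a 15 px (3.75 um) threshold.
Matching is class-agnostic; class identities then populate the 3-class
(negative, positive, background) confusion matrix.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import UndefinedPercentageError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MATCH_THRESHOLD = 15.0
DEFAULT_PIXEL_SIZE = 0.25

# confusion-matrix axis order
CLASS_ORDER = ("neg", "pos", "bg")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]  # (truth idx, detection idx, distance)
    unmatched_truth: list[int]
    unmatched_detections: list[int]
    threshold: float = DEFAULT_MATCH_THRESHOLD


def _as_xy(points) -> np.ndarray:
    if len(points) == 0:
        return np.empty((0, 2), dtype=np.float64)
    return np.array([(p.x, p.y) for p in points], dtype=np.float64)


def match(truth, detections, threshold: float = DEFAULT_MATCH_THRESHOLD) -> MatchResult:
    """Class-agnostic optimal matching under a distance gate.

    Distances above ``threshold`` are replaced by a constant B larger than any
    feasible total cost (B = threshold*(n+m)+1), so the solver always prefers
    maximizing the number of genuine matches before minimizing distance;
    B-cost assignments are then discarded as unmatched.
    """
    t_xy = _as_xy(truth)
    d_xy = _as_xy(detections)
    n, m = len(t_xy), len(d_xy)
    if n == 0 or m == 0:
        return MatchResult([], list(range(n)), list(range(m)), threshold)
    dist = np.sqrt(
        ((t_xy[:, None, :] - d_xy[None, :, :]) ** 2).sum(axis=2)
    )
    big = threshold * (n + m) + 1.0
    cost = np.where(dist > threshold, big, dist)
    rows, cols = linear_sum_assignment(cost)
    pairs = []
    matched_t, matched_d = set(), set()
    for r, c in zip(rows, cols):
        if dist[r, c] <= threshold:
            pairs.append((int(r), int(c), float(dist[r, c])))
            matched_t.add(int(r))
            matched_d.add(int(c))
    unmatched_truth = [i for i in range(n) if i not in matched_t]
    unmatched_detections = [j for j in range(m) if j not in matched_d]
    return MatchResult(pairs, unmatched_truth, unmatched_detections, threshold)


@dataclass
class ConfusionMatrix3:
    """3x3 counts; rows = truth class, cols = predicted class, order
    (negative, positive, background).  The (bg, bg) cell is structurally 0."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=np.int64))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValidationError("confusion matrix must be 3x3")
        if self.counts[2, 2] != 0:
            raise ValidationError("(background, background) cell must be 0")

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts + other.counts)

    def total(self) -> int:
        return int(self.counts.sum())


_IDX = {"neg": 0, "pos": 1, "bg": 2}


def confusion(result: MatchResult, truth_classes, detection_classes) -> ConfusionMatrix3:
    """Bookkeeping: matched pair -> (truth class, detected class); unmatched
    truth -> (truth class, background); unmatched detection -> (background,
    detected class)."""
    cm = np.zeros((3, 3), dtype=np.int64)
    for t_i, d_i, _ in result.pairs:
        cm[_IDX[truth_classes[t_i]], _IDX[detection_classes[d_i]]] += 1
    for t_i in result.unmatched_truth:
        cm[_IDX[truth_classes[t_i]], _IDX["bg"]] += 1
    for d_i in result.unmatched_detections:
        cm[_IDX["bg"], _IDX[detection_classes[d_i]]] += 1
    return ConfusionMatrix3(cm)


def macro_f1(cm: ConfusionMatrix3) -> float:
    """Unweighted mean of the negative- and positive-class F1 scores.

    Background is excluded from the average.  A class with no truth and no
    predictions contributes F1 = 1 by convention (logged) so perfect empty
    patches score 1.0.
    """
    c = cm.counts
    f1s = []
    for k in (0, 1):
        tp = c[k, k]
        fn = c[k, :].sum() - tp
        fp = c[:, k].sum() - tp
        if tp == 0 and fp == 0 and fn == 0:
            logger.info("macro_f1: class %s absent from truth and predictions; F1=1", CLASS_ORDER[k])
            f1s.append(1.0)
        else:
            f1s.append(2.0 * tp / (2.0 * tp + fp + fn))
    return float(np.mean(f1s))


def plasma_percentage(n_pos: int, n_neg: int) -> float:
    """100 * n_pos / (n_pos + n_neg)."""
    if n_pos < 0 or n_neg < 0:
        raise ValidationError("counts must be >= 0")
    total = n_pos + n_neg
    if total == 0:
        raise UndefinedPercentageError("no cells counted; percentage undefined")
    return 100.0 * n_pos / total


_QUALITATIVE = {"normal", "not increased", "less than 5%"}
_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[-–—]\s*(\d+(?:\.\d+)?)\s*%?\s*$")
_SINGLE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*%?\s*$")


def report_midpoint(report: str) -> float:
    """Numeric value recorded for a clinical-report percentage token.

    Ranges like "5-10%" map to their midpoint (7.5); the qualitative tokens
    "normal", "not increased" and "less than 5%" map to 2.5, the middle of
    the 0-5% interval; a single value maps to itself.
    """
    token = report.strip().lower().rstrip(".")
    if token in _QUALITATIVE:
        return 2.5
    m = _RANGE_RE.match(token)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    m = _SINGLE_RE.match(token)
    if m:
        return float(m.group(1))
    raise ValidationError(f"unparseable report token: {report!r}")


def icc_absolute(ratings: np.ndarray) -> float:
    """Single-measure two-way random-effects absolute-agreement ICC (ICC(A,1)).

    ``ratings`` is an (n subjects) x (k raters) table.  From the two-way
    ANOVA mean squares MSR (subjects), MSC (raters) and MSE (residual):

        ICC = (MSR - MSE) / (MSR + (k-1)*MSE + (k/n)*(MSC - MSE))
    """
    y = np.asarray(ratings, dtype=np.float64)
    if y.ndim != 2:
        raise ValidationError("ratings must be a 2-D table")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(y)):
        raise ValidationError("ratings must be finite")
    grand = y.mean()
    subj_means = y.mean(axis=1)
    rater_means = y.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        logger.warning("icc_absolute: zero total variance; defining ICC = 1.0")
        return 1.0
    return float((msr - mse) / denom)


def pixels_to_microns(d: float, pixel_size: float = DEFAULT_PIXEL_SIZE) -> float:
    """Convert a pixel distance to microns at the given scan resolution."""
    if d < 0:
        raise ValidationError("distance must be >= 0")
    return d * pixel_size


def evaluate_detections(truth, detections, threshold: float = DEFAULT_MATCH_THRESHOLD):
    """Convenience: match + confusion + macro-F1 for labelled point lists."""
    res = match(truth, detections, threshold)
    cm = confusion(res, [p.label for p in truth], [d.label for d in detections])
    return res, cm, macro_f1(cm)
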