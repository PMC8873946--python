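"""Turn class heatmaps into point detections.

The two cell-class pseudoprobability maps are smoothed (3x3 median filter then
Gaussian blur) and peak-called with a minimum-distance constraint of 10 px.
Peaks from the two class maps are merged with cross-class suppression so one
cell cannot be counted as both classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_DISTANCE = 10.0
DEFAULT_THRESHOLD = 0.5
DEFAULT_GAUSSIAN_SIGMA = 1.0


@dataclass(frozen=True)
class ClassHeatmaps:
    """Per-pixel pseudoprobabilities for (background, negative, positive)."""

    p_bg: np.ndarray
    p_neg: np.ndarray
    p_pos: np.ndarray
    pixel_size: float = 0.25

    def __post_init__(self):
        if not (self.p_bg.shape == self.p_neg.shape == self.p_pos.shape):
            raise ValidationError("heatmaps must share one shape")
        total = self.p_bg + self.p_neg + self.p_pos
        if not np.allclose(total, 1.0, atol=1e-4):
            raise ValidationError("heatmaps must sum to 1 per pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_bg.shape


@dataclass(frozen=True)
class Detection:
    x: int
    y: int
    label: str  # 'neg' | 'pos'
    score: float


def smooth(heatmap: np.ndarray, sigma: float = DEFAULT_GAUSSIAN_SIGMA) -> np.ndarray:
    """3x3 median filter followed by a Gaussian blur (reflect boundaries)."""
    if not np.all(np.isfinite(heatmap)):
        raise ValidationError("heatmap contains non-finite values")
    out = ndimage.median_filter(heatmap, size=3, mode="reflect")
    if sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=sigma, mode="reflect")
    return out


def detect_peaks(
    heatmap: np.ndarray,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[tuple[int, int, float]]:
    """Local maxima >= threshold with greedy score-descending suppression.

    Candidate peaks are pixels that are maximal in their 3x3 neighbourhood.
    Candidates are visited in decreasing score (ties broken by row-major
    position) and accepted if strictly farther than ``min_distance`` from
    every already accepted peak.  Returns (x, y, score) triples.
    """
    footprint_max = ndimage.maximum_filter(heatmap, size=3, mode="reflect")
    cand = (heatmap >= footprint_max) & (heatmap >= threshold)
    ys, xs = np.nonzero(cand)
    if len(ys) == 0:
        return []
    scores = heatmap[ys, xs]
    order = np.lexsort((xs, ys, -scores))
    accepted: list[tuple[int, int, float]] = []
    acc_xy = np.empty((0, 2), dtype=np.float64)
    md2 = float(min_distance) ** 2
    for i in order:
        x, y = int(xs[i]), int(ys[i])
        if acc_xy.size:
            d2 = (acc_xy[:, 0] - x) ** 2 + (acc_xy[:, 1] - y) ** 2
            if np.any(d2 <= md2):
                continue
        accepted.append((x, y, float(scores[i])))
        acc_xy = np.vstack([acc_xy, [x, y]])
    return accepted


def call_detections(
    heatmaps: ClassHeatmaps,
    min_distance: float = DEFAULT_MIN_DISTANCE,
    threshold: float = DEFAULT_THRESHOLD,
    sigma: float = DEFAULT_GAUSSIAN_SIGMA,
    presmoothed: bool = False,
) -> list[Detection]:
    """Peak-call each class map independently, then merge across classes.

    If a negative and a positive peak lie within ``min_distance`` of each
    other the higher score wins (exact tie -> positive, logged).  Output is
    sorted by (y, x).
    """
    maps = {"neg": heatmaps.p_neg, "pos": heatmaps.p_pos}
    per_class: list[tuple[float, int, int, int, str]] = []
    for label, m in maps.items():
        sm = m if presmoothed else smooth(m, sigma=sigma)
        for x, y, score in detect_peaks(sm, min_distance=min_distance, threshold=threshold):
            # sort key: score desc, positive first on ties, then row-major
            per_class.append((score, 0 if label == "pos" else 1, y, x, label))
    per_class.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    accepted: list[Detection] = []
    md2 = float(min_distance) ** 2
    for score, prio, y, x, label in per_class:
        clash = False
        for a in accepted:
            if a.label != label and (a.x - x) ** 2 + (a.y - y) ** 2 <= md2:
                if a.score == score:
                    logger.info(
                        "cross-class tie at (%d,%d) vs (%d,%d); positive kept", x, y, a.x, a.y
                    )
                clash = True
                break
        if not clash:
            accepted.append(Detection(x=x, y=y, label=label, score=score))
    accepted.sort(key=lambda d: (d.y, d.x))
    return accepted


def write_detections(path, detections: list[Detection]) -> None:
    """TSV like the annotations point file plus a score column."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("x\ty\tclass\tscore\n")
        for d in detections:
            fh.write(f"{d.x}\t{d.y}\t{d.label}\t{d.score:.6f}\n")
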