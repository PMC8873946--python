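"""Single-image snapshot analysis: counts, percentage and a labelled overlay."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..detection import Detection, call_detections
from ..errors import UndefinedPercentageError, ValidationError
from ..evaluation import plasma_percentage
from ..network.model import Network, Normalizer, predict_heatmaps

MAX_SNAPSHOT_SIDE = 8192

POSITIVE_COLOR = (255, 140, 0)  # orange markers for plasma cells
NEGATIVE_COLOR = (30, 90, 255)  # blue markers for other nucleated cells


@dataclass
class SnapshotResult:
    n_pos: int
    n_neg: int
    percentage: float | None  # None when no cells were detected
    detections: list[Detection]
    overlay: np.ndarray  # (H, W, 3) uint8, same dims as input
    pixel_size: float
    model_id: str

    @property
    def percentage_defined(self) -> bool:
        return self.percentage is not None


def _draw_marker(img: np.ndarray, x: int, y: int, color, radius: int = 4) -> None:
    h, w, _ = img.shape
    yy, xx = np.mgrid[max(0, y - radius) : min(h, y + radius + 1),
                      max(0, x - radius) : min(w, x + radius + 1)]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    ring = (d2 <= radius**2) & (d2 >= (radius - 2) ** 2)
    img[yy[ring], xx[ring]] = color


def _draw_scale_bar(img: np.ndarray, pixel_size: float, microns: float = 25.0) -> None:
    h, w, _ = img.shape
    length = int(round(microns / pixel_size))
    length = min(length, w - 10)
    if length < 2:
        return
    y = h - 8
    img[y : y + 3, 5 : 5 + length] = (0, 0, 0)


def analyze_snapshot(
    image: np.ndarray,
    network: Network,
    normalizer: Normalizer,
    pixel_size: float = 0.25,
    model_id: str = "unknown",
    det_kwargs: dict | None = None,
) -> SnapshotResult:
    """Run the detection pipeline once on an RGB snapshot.

    The image is reflect-padded on the right/bottom to the network's
    divisibility constraint; detections landing in that synthetic margin are
    discarded.  Deterministic for a fixed checkpoint.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("snapshot must be an (H, W, 3) RGB image")
    h, w, _ = image.shape
    if max(h, w) > MAX_SNAPSHOT_SIDE:
        raise ValidationError(
            f"snapshot side exceeds the configured bound of {MAX_SNAPSHOT_SIDE} px"
        )
    d = network.config.divisor
    pad_y = (-h) % d
    pad_x = (-w) % d
    padded = (
        np.pad(image, ((0, pad_y), (0, pad_x), (0, 0)), mode="reflect")
        if (pad_x or pad_y)
        else image
    )
    hm = predict_heatmaps(network, padded, normalizer, pixel_size=pixel_size)
    dets = [
        det
        for det in call_detections(hm, **(det_kwargs or {}))
        if det.x < w and det.y < h
    ]
    n_pos = sum(1 for det in dets if det.label == "pos")
    n_neg = len(dets) - n_pos
    try:
        pct = plasma_percentage(n_pos, n_neg)
    except UndefinedPercentageError:
        pct = None
    overlay = image.copy()
    for det in dets:
        _draw_marker(overlay, det.x, det.y,
                     POSITIVE_COLOR if det.label == "pos" else NEGATIVE_COLOR)
    _draw_scale_bar(overlay, pixel_size)
    return SnapshotResult(
        n_pos=n_pos,
        n_neg=n_neg,
        percentage=pct,
        detections=dets,
        overlay=overlay,
        pixel_size=pixel_size,
        model_id=model_id,
    )
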