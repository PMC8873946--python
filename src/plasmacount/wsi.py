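"""Shift-and-stitch whole-slide inference.

A sliding window (default 2048 px) of disjoint core rectangles covers the
slide; each core is read with 32 px of context padding per side (2112 px
network input at the defaults), mirror-reflected where the window exceeds the
slide.  Detections falling in the pad ring are discarded, so cores own their
detections and stitching is exact and order-free whenever the network's
receptive-field radius does not exceed the pad.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detection import Detection, call_detections
from .errors import GeometryError, UndefinedPercentageError, ValidationError
from .evaluation import plasma_percentage
from .network.model import Network, Normalizer, predict_heatmaps

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2048
DEFAULT_PAD = 32


class ArraySlide:
    """Slide reader over an in-memory (H, W, 3) uint8 array.

    ``read_region`` mirror-reflects any part of the request outside bounds.
    """

    def __init__(self, image: np.ndarray):
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValidationError("slide array must be (H, W, 3)")
        self.image = image

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]

    def read_region(self, x: int, y: int, w: int, h: int) -> np.ndarray:
        H, W = self.height, self.width
        top = max(0, -y)
        left = max(0, -x)
        bottom = max(0, y + h - H)
        right = max(0, x + w - W)
        img = self.image
        if top or left or bottom or right:
            img = np.pad(img, ((top, bottom), (left, right), (0, 0)), mode="reflect")
        return img[y + top : y + top + h, x + left : x + left + w]


class TiffSlide(ArraySlide):
    """Slide reader for (tiled, possibly pyramidal) TIFF files; uses level 0."""

    def __init__(self, path: str | Path):
        import tifffile

        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        super().__init__(np.asarray(arr, dtype=np.uint8))


def open_slide(path: str | Path) -> ArraySlide:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
        return TiffSlide(path)
    from PIL import Image

    return ArraySlide(np.asarray(Image.open(path).convert("RGB")))


@dataclass(frozen=True)
class Tile:
    x: int
    y: int
    w: int
    h: int


@dataclass
class TilingPlan:
    tiles: list[Tile]
    slide_width: int
    slide_height: int
    window: int = DEFAULT_WINDOW
    pad: int = DEFAULT_PAD

    @property
    def padded_tile_size(self) -> int:
        return self.window + 2 * self.pad


def plan_tiles(
    slide_width: int,
    slide_height: int,
    window: int = DEFAULT_WINDOW,
    pad: int = DEFAULT_PAD,
    mask: np.ndarray | None = None,
    mask_downsample: int = 1,
) -> TilingPlan:
    """Row-major grid of disjoint window-sized cores; the last row/column is
    truncated at the slide edge.  With a mask, tiles whose core contains no
    masked pixel are omitted."""
    if slide_width < 1 or slide_height < 1:
        raise ValidationError("slide dimensions must be positive")
    if window < 1 or pad < 0:
        raise ValidationError("window must be >= 1 and pad >= 0")
    if mask is not None:
        mh, mw = mask.shape
        exp_h = -(-slide_height // mask_downsample)
        exp_w = -(-slide_width // mask_downsample)
        if abs(mh - exp_h) > 1 or abs(mw - exp_w) > 1:
            raise GeometryError(
                f"mask of shape {mh}x{mw} does not match slide "
                f"{slide_height}x{slide_width} at downsample {mask_downsample}"
            )
    tiles = []
    for y in range(0, slide_height, window):
        for x in range(0, slide_width, window):
            w = min(window, slide_width - x)
            h = min(window, slide_height - y)
            if mask is not None:
                my0 = y // mask_downsample
                mx0 = x // mask_downsample
                my1 = -(-(y + h) // mask_downsample)
                mx1 = -(-(x + w) // mask_downsample)
                if not np.any(mask[my0:my1, mx0:mx1]):
                    continue
            tiles.append(Tile(x, y, w, h))
    return TilingPlan(tiles, slide_width, slide_height, window, pad)


def infer_tile(
    slide: ArraySlide,
    tile: Tile,
    network: Network,
    normalizer: Normalizer,
    pad: int = DEFAULT_PAD,
    det_kwargs: dict | None = None,
) -> list[Detection]:
    """Run the detection pipeline on one padded tile.

    The padded read window is mirror-reflected where it exceeds slide bounds
    and extended (right/bottom, also reflected) to the network's divisibility
    constraint; detections outside the core are discarded and survivors are
    reported in core-local coordinates.
    """
    d = network.config.divisor
    w_pad = tile.w + 2 * pad
    h_pad = tile.h + 2 * pad
    extra_x = (-w_pad) % d
    extra_y = (-h_pad) % d
    img = slide.read_region(tile.x - pad, tile.y - pad, w_pad + extra_x, h_pad + extra_y)
    hm = predict_heatmaps(network, img, normalizer)
    dets = call_detections(hm, **(det_kwargs or {}))
    out = []
    for det in dets:
        cx, cy = det.x - pad, det.y - pad
        if 0 <= cx < tile.w and 0 <= cy < tile.h:
            out.append(Detection(x=cx, y=cy, label=det.label, score=det.score))
    return out


def stitch(
    plan: TilingPlan,
    per_tile: list[list[Detection]],
    mask: np.ndarray | None = None,
    mask_downsample: int = 1,
) -> tuple[list[Detection], dict]:
    """Offset core-local detections into the slide frame and summarize.

    Cores are disjoint and pad detections were discarded, so no deduplication
    is needed.  Output is sorted by (y, x); the summary carries counts and
    the plasma-cell percentage (None when no cells were found).
    """
    if len(per_tile) != len(plan.tiles):
        raise ValidationError("one detection list per tile required")
    merged: list[Detection] = []
    for tile, dets in zip(plan.tiles, per_tile):
        for det in dets:
            gx, gy = det.x + tile.x, det.y + tile.y
            if mask is not None and not mask[gy // mask_downsample, gx // mask_downsample]:
                continue
            merged.append(Detection(x=gx, y=gy, label=det.label, score=det.score))
    merged.sort(key=lambda det: (det.y, det.x))
    n_pos = sum(1 for det in merged if det.label == "pos")
    n_neg = len(merged) - n_pos
    try:
        pct = plasma_percentage(n_pos, n_neg)
    except UndefinedPercentageError:
        pct = None
    summary = {
        "n_pos": n_pos,
        "n_neg": n_neg,
        "n_total": len(merged),
        "plasma_percentage": pct,
        "tiles_processed": len(plan.tiles),
    }
    return merged, summary


def run_slide(
    slide: ArraySlide,
    network: Network,
    normalizer: Normalizer,
    window: int = DEFAULT_WINDOW,
    pad: int = DEFAULT_PAD,
    mask: np.ndarray | None = None,
    mask_downsample: int = 1,
    det_kwargs: dict | None = None,
) -> tuple[list[Detection], dict]:
    """Plan, infer every tile sequentially, and stitch."""
    rf = network.config.receptive_field_radius
    if pad < rf:
        logger.warning(
            "pad %d px is smaller than the network receptive-field radius %d px; "
            "stitching will not be exact near tile borders",
            pad,
            rf,
        )
    plan = plan_tiles(slide.width, slide.height, window, pad, mask, mask_downsample)
    per_tile = [
        infer_tile(slide, t, network, normalizer, pad, det_kwargs) for t in plan.tiles
    ]
    return stitch(plan, per_tile, mask, mask_downsample)


def write_summary(path: str | Path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
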