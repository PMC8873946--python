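"""Point-annotation data model: label rasters, padded tile export, point files.

Cells are annotated by a single point at the cell center.  A point annotation
set is rendered into an 8-bit label raster where 0 = background, 1 = negative
cell and 2 = positive cell; training targets are produced by grayscale
dilation of that raster.  Coordinates are 0-based pixel indices with the
origin at the top-left corner, x growing rightward and y downward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    BoundsError,
    DuplicateAnnotationError,
    PointFileParseError,
    ValidationError,
)

logger = logging.getLogger(__name__)

LABEL_BACKGROUND = 0
LABEL_NEGATIVE = 1
LABEL_POSITIVE = 2

CLASS_NAMES = {"neg": LABEL_NEGATIVE, "pos": LABEL_POSITIVE}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

POINT_FILE_HEADER = ("x", "y", "class")


@dataclass(frozen=True)
class PointAnnotation:
    """A cell centroid with its class label ('neg' or 'pos')."""

    x: int
    y: int
    label: str

    def __post_init__(self):
        if self.label not in CLASS_NAMES:
            raise ValidationError(
                f"label must be one of {sorted(CLASS_NAMES)}, got {self.label!r}"
            )
        if self.x < 0 or self.y < 0:
            raise ValidationError(f"coordinates must be non-negative: ({self.x}, {self.y})")

    @property
    def code(self) -> int:
        return CLASS_NAMES[self.label]


@dataclass(frozen=True)
class TileSpec:
    """Rectangular export window: a core region plus context padding per side."""

    x: int
    y: int
    core_size: int = 512
    pad: int = 32

    def __post_init__(self):
        if self.core_size <= 0:
            raise ValidationError("core_size must be positive")
        if self.pad < 0:
            raise ValidationError("pad must be non-negative")

    @property
    def export_size(self) -> int:
        return self.core_size + 2 * self.pad


def encode_labels(points: Sequence[PointAnnotation], shape: tuple[int, int]) -> np.ndarray:
    """Render point annotations into an 8-bit label raster of shape (H, W)."""
    h, w = shape
    raster = np.zeros((h, w), dtype=np.uint8)
    for p in points:
        if not (0 <= p.x < w and 0 <= p.y < h):
            raise BoundsError(f"point ({p.x}, {p.y}) outside raster of shape {h}x{w}")
        if raster[p.y, p.x] != 0:
            raise DuplicateAnnotationError(f"two annotations share pixel ({p.x}, {p.y})")
        raster[p.y, p.x] = p.code
    return raster


def decode_labels(raster: np.ndarray) -> list[PointAnnotation]:
    """Inverse of :func:`encode_labels` for point (undilated) rasters.

    Scans nonzero pixels in row-major order.
    """
    ys, xs = np.nonzero(raster)
    return [
        PointAnnotation(int(x), int(y), CLASS_CODES[int(raster[y, x])])
        for y, x in zip(ys, xs)
    ]


def disc_structuring_element(radius: int) -> np.ndarray:
    """Boolean disc: pixels within Euclidean distance ``radius`` of the center."""
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def dilate_labels(raster: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale (max) dilation with a disc element.

    Each annotated point becomes a disc of its class value.  Where discs of
    value 1 and 2 overlap, 2 prevails (max semantics); collisions are logged.
    """
    if radius == 0:
        return raster.copy()
    selem = disc_structuring_element(radius)
    out = ndimage.grey_dilation(raster, footprint=selem, mode="constant", cval=0)
    neg_disc = ndimage.grey_dilation(
        (raster == LABEL_NEGATIVE).astype(np.uint8), footprint=selem, mode="constant", cval=0
    )
    collisions = int(np.sum((out == LABEL_POSITIVE) & (neg_disc > 0)))
    if collisions:
        logger.info("dilate_labels: %d pixels where a value-2 disc overrode value 1", collisions)
    return out.astype(np.uint8)


def _reflect_pad_2d(a: np.ndarray, top: int, bottom: int, left: int, right: int) -> np.ndarray:
    pads = [(top, bottom), (left, right)] + [(0, 0)] * (a.ndim - 2)
    return np.pad(a, pads, mode="reflect")


def export_tile(
    image: np.ndarray, labels: np.ndarray, tile: TileSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Export a padded tile from parent image/label rasters.

    Returns ``(padded_image, padded_labels, core_mask)``, each of side
    ``core_size + 2*pad``.  Annotations whose centers fall only in the pad
    ring are removed from the exported labels; the pad region may extend past
    the parent frame, in which case it is mirror-reflected.
    """
    h, w = labels.shape
    cs, pad = tile.core_size, tile.pad
    if not (0 <= tile.x and 0 <= tile.y and tile.x + cs <= w and tile.y + cs <= h):
        raise BoundsError(
            f"core region ({tile.x},{tile.y})+{cs} outside parent of shape {h}x{w}"
        )
    x0, y0 = tile.x - pad, tile.y - pad
    x1, y1 = tile.x + cs + pad, tile.y + cs + pad
    top = max(0, -y0)
    left = max(0, -x0)
    bottom = max(0, y1 - h)
    right = max(0, x1 - w)
    img_p = _reflect_pad_2d(image, top, bottom, left, right)
    lbl_p = _reflect_pad_2d(labels, top, bottom, left, right)
    sy = slice(y0 + top, y1 + top)
    sx = slice(x0 + left, x1 + left)
    out_img = img_p[sy, sx].copy()
    out_lbl = lbl_p[sy, sx].copy()
    # reflection may duplicate annotations into the pad ring; the pad ring
    # carries image context only, so all labels outside the core are cleared
    core = np.zeros(out_lbl.shape[:2], dtype=bool)
    core[pad : pad + cs, pad : pad + cs] = True
    out_lbl[~core] = 0
    return out_img, out_lbl, core


def write_points(path: str | Path, points: Iterable[PointAnnotation]) -> None:
    """Write a TSV point file (header ``x\\ty\\tclass``), importable into
    digital-pathology viewers as point annotations."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(POINT_FILE_HEADER) + "\n")
        for p in points:
            fh.write(f"{p.x}\t{p.y}\t{p.label}\n")


def read_points(path: str | Path) -> list[PointAnnotation]:
    """Read a TSV point file written by :func:`write_points`."""
    path = Path(path)
    points: list[PointAnnotation] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise PointFileParseError("empty file (missing header)", line=1)
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header[:3] != POINT_FILE_HEADER:
        raise PointFileParseError(
            f"bad header {lines[0]!r}, expected {POINT_FILE_HEADER}", line=1
        )
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise PointFileParseError(f"expected 3 tab-separated fields, got {len(parts)}", line=i)
        try:
            x = int(parts[0])
            y = int(parts[1])
        except ValueError as exc:
            raise PointFileParseError(f"non-integer coordinate in {line!r}", line=i) from exc
        label = parts[2].strip()
        if label not in CLASS_NAMES:
            raise PointFileParseError(
                f"class token {label!r} not in {sorted(CLASS_NAMES)}", line=i
            )
        try:
            points.append(PointAnnotation(x, y, label))
        except ValidationError as exc:
            raise PointFileParseError(str(exc), line=i) from exc
    return points
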