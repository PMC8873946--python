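"""Synthetic IHC-like image generator with known ground truth.

Emulates brightfield patches of CD138-stained marrow: positive (plasma) cells
are drawn as a nucleus disc surrounded by a brown membrane ring, negative
nucleated cells as a blue nucleus disc only, on a pale background.  Optional
artifact blobs mimic nonspecific brown staining and carry no ground-truth
point.  Everything is deterministic under the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotations import PointAnnotation, write_points
from .errors import PlacementError, ValidationError

MEMBRANE_THICKNESS = 3  # px; ring width separating the two classes by color topology
MAX_PLACEMENT_ATTEMPTS = 10_000


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic patch."""

    width: int = 128
    height: int = 128
    n_positive: int = 5
    n_negative: int = 15
    cell_radius_range: tuple[int, int] = (3, 5)
    min_separation: float = 14.0
    membrane_color: tuple[int, int, int] = (125, 80, 38)  # DAB-like brown
    nucleus_color: tuple[int, int, int] = (64, 60, 150)  # hematoxylin-like blue
    background_color: tuple[int, int, int] = (232, 226, 220)
    n_artifact_blobs: int = 0
    noise_sd: float = 3.0
    pixel_size: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValidationError("cell counts must be >= 0")
        if self.min_separation <= 0:
            raise ValidationError("min_separation must be > 0")
        rmin, rmax = self.cell_radius_range
        if not (0 < rmin <= rmax):
            raise ValidationError("cell_radius_range must satisfy 0 < min <= max")
        for c in (self.membrane_color, self.nucleus_color, self.background_color):
            if any(not (0 <= v <= 255) for v in c):
                raise ValidationError(f"color {c} outside [0, 255]")
        if min(self.width, self.height) <= 2 * rmax:
            raise ValidationError("image sides must exceed twice the max cell radius")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.n_positive + self.n_negative


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    truth: list[PointAnnotation]
    tissue_mask: np.ndarray  # (H, W) bool
    spec: SceneSpec

    @property
    def truth_percentage(self) -> float:
        n_pos = sum(1 for p in self.truth if p.label == "pos")
        total = len(self.truth)
        if total == 0:
            raise ValidationError("scene has no cells; percentage undefined")
        return 100.0 * n_pos / total


def _check_feasible(spec: SceneSpec) -> None:
    # crude area check before rejection sampling: each center excludes a disc
    # of radius min_separation/2 for the others
    rmax = spec.cell_radius_range[1]
    margin = rmax + MEMBRANE_THICKNESS + 1
    free_w = spec.width - 2 * margin
    free_h = spec.height - 2 * margin
    if free_w <= 0 or free_h <= 0:
        if spec.n_cells > 0:
            raise PlacementError("image too small for cell margin")
        return
    per_cell = np.pi * (spec.min_separation / 2.0) ** 2
    if spec.n_cells * per_cell > 0.85 * free_w * free_h:
        raise PlacementError(
            f"infeasible placement: {spec.n_cells} cells with min_separation "
            f"{spec.min_separation} exceed ~85% of placeable area"
        )


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    rmax = spec.cell_radius_range[1]
    margin = rmax + MEMBRANE_THICKNESS + 1
    centers: list[tuple[int, int]] = []
    for _ in range(spec.n_cells):
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            x = int(rng.integers(margin, spec.width - margin))
            y = int(rng.integers(margin, spec.height - margin))
            if all(
                (x - cx) ** 2 + (y - cy) ** 2 >= spec.min_separation**2
                for cx, cy in centers
            ):
                centers.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centers) + 1}/{spec.n_cells} after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts (min_separation={spec.min_separation})"
            )
    return np.array(centers, dtype=int).reshape(-1, 2)


def _paint_disc(img: np.ndarray, cx: int, cy: int, r_in: float, r_out: float, color) -> None:
    h, w, _ = img.shape
    x0, x1 = max(0, int(cx - r_out - 1)), min(w, int(cx + r_out + 2))
    y0, y1 = max(0, int(cy - r_out - 1)), min(h, int(cy + r_out + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    sel = (d2 >= r_in**2) & (d2 <= r_out**2)
    img[y0:y1, x0:x1][sel] = color


def generate_patch(spec: SceneSpec) -> SyntheticScene:
    """Render one patch with exact ground-truth centroids.

    Positive cells: nucleus disc + membrane ring in ``membrane_color``.
    Negative cells: nucleus disc only.  Artifact blobs are irregular clusters
    of membrane-colored discs with no truth point, kept clear of every cell.
    Additive clipped Gaussian noise is applied last.
    """
    _check_feasible(spec)
    rng = np.random.default_rng(spec.seed)
    img = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    img[...] = np.array(spec.background_color, dtype=np.uint8)

    centers = _place_centers(spec, rng)
    radii = rng.integers(
        spec.cell_radius_range[0], spec.cell_radius_range[1] + 1, size=spec.n_cells
    )
    labels = ["pos"] * spec.n_positive + ["neg"] * spec.n_negative

    # artifact blobs: drawn first so cells stay crisp on top
    rmax = spec.cell_radius_range[1]
    keepout = rmax + MEMBRANE_THICKNESS + spec.min_separation
    for _ in range(spec.n_artifact_blobs):
        blob_r = float(rng.uniform(3, 7))
        placed = False
        for attempt in range(MAX_PLACEMENT_ATTEMPTS):
            bx = int(rng.integers(0, spec.width))
            by = int(rng.integers(0, spec.height))
            if centers.size == 0 or np.all(
                (centers[:, 0] - bx) ** 2 + (centers[:, 1] - by) ** 2
                > (keepout + blob_r) ** 2
            ):
                placed = True
                break
        if not placed:
            raise PlacementError("could not place artifact blob clear of all cells")
        # irregular cluster of overlapping discs
        n_lumps = int(rng.integers(2, 5))
        for _ in range(n_lumps):
            dx, dy = rng.normal(scale=blob_r / 2, size=2)
            _paint_disc(img, bx + dx, by + dy, 0, blob_r * rng.uniform(0.6, 1.0),
                        spec.membrane_color)

    truth: list[PointAnnotation] = []
    for (cx, cy), r, label in zip(centers, radii, labels):
        if label == "pos":
            _paint_disc(img, cx, cy, r, r + MEMBRANE_THICKNESS, spec.membrane_color)
        _paint_disc(img, cx, cy, 0, r, spec.nucleus_color)
        truth.append(PointAnnotation(int(cx), int(cy), label))

    if spec.noise_sd > 0:
        noise = rng.normal(scale=spec.noise_sd, size=img.shape)
        img = np.clip(img.astype(np.float64) + noise, 0, 255).astype(np.uint8)

    mask = np.ones((spec.height, spec.width), dtype=bool)
    return SyntheticScene(image=img, truth=truth, tissue_mask=mask, spec=spec)


def generate_slide(
    spec: SceneSpec, grid: tuple[int, int], margin: int = 0
) -> SyntheticScene:
    """Mosaic of independently seeded patches forming a small synthetic slide.

    ``grid`` is (rows, cols).  Each patch uses ``spec`` with its own derived
    seed; truth points are reported in slide coordinates.  The tissue mask
    marks patch areas, leaving any ``margin`` border unmasked background.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise ValidationError("grid must be at least 1x1")
    if margin < 0:
        raise ValidationError("margin must be >= 0")
    sh = rows * spec.height + 2 * margin
    sw = cols * spec.width + 2 * margin
    img = np.empty((sh, sw, 3), dtype=np.uint8)
    img[...] = np.array(spec.background_color, dtype=np.uint8)
    mask = np.zeros((sh, sw), dtype=bool)
    truth: list[PointAnnotation] = []
    for r in range(rows):
        for c in range(cols):
            # patch (0, 0) reuses spec.seed so a 1x1 slide equals generate_patch
            sub = replace(spec, seed=spec.seed + r * cols + c)
            patch = generate_patch(sub)
            y0 = margin + r * spec.height
            x0 = margin + c * spec.width
            img[y0 : y0 + spec.height, x0 : x0 + spec.width] = patch.image
            mask[y0 : y0 + spec.height, x0 : x0 + spec.width] = True
            truth.extend(
                PointAnnotation(p.x + x0, p.y + y0, p.label) for p in patch.truth
            )
    return SyntheticScene(image=img, truth=truth, tissue_mask=mask, spec=spec)


def write_scene(scene: SyntheticScene, out_dir: str | Path, stem: str = "patch") -> dict:
    """Write image PNG + truth TSV + mask PNG; returns the paths."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_path = out / f"{stem}_img.png"
    tsv_path = out / f"{stem}_truth.tsv"
    mask_path = out / f"{stem}_mask.png"
    Image.fromarray(scene.image).save(img_path)
    write_points(tsv_path, scene.truth)
    Image.fromarray((scene.tissue_mask * 255).astype(np.uint8)).save(mask_path)
    return {"image": img_path, "truth": tsv_path, "mask": mask_path}


def write_slide_tiff(
    scene: SyntheticScene, path: str | Path, tile: int = 256, levels: int = 2
) -> Path:
    """Write the scene image as a tiled multi-resolution TIFF."""
    import tifffile

    path = Path(path)
    img = scene.image
    subs = []
    level = img
    for _ in range(max(0, levels - 1)):
        level = level[::2, ::2]
        subs.append(level)
    with tifffile.TiffWriter(path) as tw:
        tw.write(
            img,
            tile=(tile, tile),
            photometric="rgb",
            subifds=len(subs),
            metadata=None,
        )
        for s in subs:
            tw.write(
                s,
                tile=(tile, tile),
                photometric="rgb",
                subfiletype=1,
                metadata=None,
            )
    return path
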