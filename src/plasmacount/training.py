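"""Training loop: augmentation, class-weighted categorical cross-entropy,
SGD epochs, validation macro-F1 model selection and grid search.

Validation macro-F1 is computed per epoch by running the full inference
pipeline (softmax heatmaps -> smoothing -> peak calling -> assignment
matching -> confusion matrix) on the held-out tiles; the checkpoint returned
is the epoch with the best validation macro-F1.
"""

from __future__ import annotations

import copy
import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .annotations import PointAnnotation, dilate_labels, encode_labels
from .detection import call_detections
from .errors import TrainingError, ValidationError
from .evaluation import confusion, macro_f1, match
from .network.layers import SGD
from .network.model import (
    Network,
    NetworkConfig,
    Normalizer,
    build_network,
    predict_heatmaps,
    softmax_channels,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hyperparams:
    learning_rate: float = 0.05
    class_weights: tuple[float, float, float] = (0.2, 1.0, 1.0)  # (bg, neg, pos)
    max_epochs: int = 200
    batch_size: int = 4
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be > 0")
        if any(w <= 0 for w in self.class_weights):
            raise ValidationError("class weights must be > 0")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass(frozen=True)
class AugmentationPolicy:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    rotate: bool = True
    right_angles_only: bool = False
    brightness_range: tuple[float, float] = (0.8, 1.25)

    def __post_init__(self):
        if not (0 <= self.p_hflip <= 1 and 0 <= self.p_vflip <= 1):
            raise ValidationError("flip probabilities must lie in [0, 1]")
        lo, hi = self.brightness_range
        if not (0 < lo <= hi):
            raise ValidationError("brightness range must be positive")

    def sample(self, rng: np.random.Generator) -> "AugmentDraw":
        if self.rotate:
            if self.right_angles_only:
                angle = 90.0 * int(rng.integers(0, 4))
            else:
                angle = float(rng.uniform(0.0, 360.0))
        else:
            angle = 0.0
        return AugmentDraw(
            hflip=bool(rng.random() < self.p_hflip),
            vflip=bool(rng.random() < self.p_vflip),
            angle=angle,
            brightness=float(rng.uniform(*self.brightness_range)),
        )


@dataclass(frozen=True)
class AugmentDraw:
    hflip: bool = False
    vflip: bool = False
    angle: float = 0.0  # degrees counterclockwise
    brightness: float = 1.0


def augment(
    image: np.ndarray, labels: np.ndarray, draw: AugmentDraw
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one augmentation draw identically to image and label raster.

    Geometry goes to both (labels nearest-neighbour, rotation voids refilled
    by reflection); brightness to the image only.
    """
    if image.shape[:2] != labels.shape:
        raise ValidationError("image and labels must share spatial shape")
    img, lbl = image, labels
    if draw.hflip:
        img = img[:, ::-1]
        lbl = lbl[:, ::-1]
    if draw.vflip:
        img = img[::-1]
        lbl = lbl[::-1]
    angle = draw.angle % 360.0
    if angle:
        if angle % 90.0 == 0.0:
            k = int(angle // 90)
            img = np.rot90(img, k)
            lbl = np.rot90(lbl, k)
        else:
            img = ndimage.rotate(
                img, angle, reshape=False, order=1, mode="reflect"
            )
            lbl = ndimage.rotate(
                lbl, angle, reshape=False, order=0, mode="reflect"
            )
    if draw.brightness != 1.0:
        img = np.clip(img.astype(np.float32) * draw.brightness, 0, 255).astype(np.uint8)
    return np.ascontiguousarray(img), np.ascontiguousarray(lbl)


@dataclass
class Sample:
    """One training tile: image, dilated label raster, ground-truth points."""

    image: np.ndarray  # (H, W, 3) uint8
    labels: np.ndarray  # (H, W) uint8, already dilated
    points: list[PointAnnotation]


def make_sample(image, points, dilation_radius: int = 5) -> Sample:
    raster = encode_labels(points, image.shape[:2])
    return Sample(image=image, labels=dilate_labels(raster, dilation_radius), points=points)


def split_dataset(n: int, fraction: float = 0.8, seed: int = 0) -> tuple[list[int], list[int]]:
    """Seeded tile-level train/validation split (default 80/20)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = max(1, int(round(fraction * n)))
    if n_train >= n:
        n_train = n - 1 if n > 1 else n
    return sorted(order[:n_train].tolist()), sorted(order[n_train:].tolist())


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, class_weights
) -> tuple[float, np.ndarray]:
    """Pixelwise weighted categorical cross-entropy (weighted mean) and its
    gradient w.r.t. the logits."""
    probs = softmax_channels(logits.astype(np.float64))
    n, c, h, w = logits.shape
    wmap = np.asarray(class_weights, dtype=np.float64)[labels]  # (N, H, W)
    wsum = wmap.sum()
    idx_n, idx_y, idx_x = np.meshgrid(
        np.arange(n), np.arange(h), np.arange(w), indexing="ij"
    )
    p_true = probs[idx_n, labels, idx_y, idx_x]
    loss = float((wmap * -np.log(np.clip(p_true, 1e-12, None))).sum() / wsum)
    onehot = np.zeros_like(probs)
    onehot[idx_n, labels, idx_y, idx_x] = 1.0
    dlogits = (probs - onehot) * wmap[:, None] / wsum
    return loss, dlogits.astype(np.float32)


@dataclass
class TrainResult:
    network: Network
    normalizer: Normalizer
    history: pd.DataFrame
    best_epoch: int
    best_val_f1: float
    hp: Hyperparams


def _validation_f1(network, normalizer, samples, det_kwargs) -> float:
    cm_total = None
    for s in samples:
        hm = predict_heatmaps(network, s.image, normalizer)
        dets = call_detections(hm, **det_kwargs)
        res = match(s.points, dets)
        cm = confusion(res, [p.label for p in s.points], [d.label for d in dets])
        cm_total = cm if cm_total is None else cm_total + cm
    return macro_f1(cm_total)


def train(
    dataset: list[Sample],
    split: tuple[list[int], list[int]],
    hp: Hyperparams,
    config: NetworkConfig,
    policy: AugmentationPolicy | None = None,
    det_kwargs: dict | None = None,
    stop_at_f1: float | None = None,
) -> TrainResult:
    """SGD on the class-weighted categorical cross-entropy, selecting the
    epoch with the best validation macro-F1.  Fully reproducible under
    (hp.seed, hp); ``stop_at_f1`` optionally ends the run once the validation
    score reaches a target (used by the overfit smoke run)."""
    train_idx, val_idx = split
    if not train_idx or not val_idx:
        raise ValidationError("both train and validation splits must be nonempty")
    det_kwargs = det_kwargs or {}
    train_samples = [dataset[i] for i in train_idx]
    val_samples = [dataset[i] for i in val_idx]

    normalizer = Normalizer.fit([s.image for s in train_samples])
    network = build_network(config)
    opt = SGD(network.params(), lr=hp.learning_rate, momentum=hp.momentum)
    rng = np.random.default_rng(hp.seed)

    history_rows = []
    best = (-1.0, -1, None)  # (f1, epoch, state)
    for epoch in range(1, hp.max_epochs + 1):
        order = rng.permutation(len(train_samples))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), hp.batch_size):
            batch_idx = order[start : start + hp.batch_size]
            imgs, lbls = [], []
            for i in batch_idx:
                s = train_samples[i]
                if policy is not None:
                    img, lbl = augment(s.image, s.labels, policy.sample(rng))
                else:
                    img, lbl = s.image, s.labels
                imgs.append(normalizer.apply(img))
                lbls.append(lbl.astype(np.int64))
            x = np.stack(imgs)
            y = np.stack(lbls)
            logits = network.forward(x, train=True)
            loss, dlogits = weighted_cross_entropy(logits, y, hp.class_weights)
            if not np.isfinite(loss):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch} (lr={hp.learning_rate}, "
                    f"weights={hp.class_weights})"
                )
            opt.zero_grad()
            network.backprop(dlogits)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        epoch_loss /= n_batches
        try:
            val_f1 = _validation_f1(network, normalizer, val_samples, det_kwargs)
        except ValidationError as exc:
            raise TrainingError(
                f"non-finite network outputs during validation at epoch {epoch} "
                f"(lr={hp.learning_rate}): {exc}"
            ) from exc
        history_rows.append({"epoch": epoch, "loss": epoch_loss, "val_macro_f1": val_f1})
        if val_f1 > best[0]:
            best = (val_f1, epoch, copy.deepcopy(network.state_dict()))
        if stop_at_f1 is not None and val_f1 >= stop_at_f1:
            break

    network.load_state_dict(best[2])
    return TrainResult(
        network=network,
        normalizer=normalizer,
        history=pd.DataFrame(history_rows),
        best_epoch=best[1],
        best_val_f1=best[0],
        hp=hp,
    )


@dataclass
class GridSearchResult:
    best_hp: Hyperparams
    best_result: TrainResult
    table: pd.DataFrame


def grid_search(
    dataset: list[Sample],
    split: tuple[list[int], list[int]],
    learning_rates: list[float],
    class_weight_grid: list[tuple[float, float, float]],
    base_hp: Hyperparams = Hyperparams(),
    config: NetworkConfig = NetworkConfig(),
    policy: AugmentationPolicy | None = None,
) -> GridSearchResult:
    """Exhaustive grid over learning rate x class weights; selects the cell
    with maximal validation macro-F1 (first in grid order on ties).  Cells
    whose runs diverge are marked failed and never selected."""
    if not learning_rates or not class_weight_grid:
        raise ValidationError("grid must be nonempty")
    rows = []
    best: tuple[float, Hyperparams, TrainResult] | None = None
    for lr, weights in itertools.product(learning_rates, class_weight_grid):
        hp = replace(base_hp, learning_rate=lr, class_weights=tuple(weights))
        try:
            result = train(dataset, split, hp, config, policy=policy)
            score = result.best_val_f1
            status = "ok"
        except TrainingError as exc:
            logger.warning("grid cell (lr=%s, w=%s) failed: %s", lr, weights, exc)
            result, score, status = None, np.nan, "failed"
        rows.append(
            {
                "learning_rate": lr,
                "class_weights": tuple(weights),
                "val_macro_f1": score,
                "status": status,
            }
        )
        if status == "ok" and (best is None or score > best[0]):
            best = (score, hp, result)
    if best is None:
        raise TrainingError("every grid cell failed")
    return GridSearchResult(best_hp=best[1], best_result=best[2], table=pd.DataFrame(rows))
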