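"""Fully-convolutional encoder-decoder with a 3-class categorical head.

A stack of conv-(bn)-relu encoder stages separated by 2x2 max pooling, and a
mirrored decoder using factor-2 bilinear upsampling, skip concatenation and
convolutions, emitting per-pixel logits over (background, negative, positive)
at input resolution.  Inputs of any size divisible by 2^(n_stages-1) are
accepted.  The paper-scale VGG-style encoder exists only as a config preset;
`pretrained_encoder` is a configuration hook and is never required.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..detection import ClassHeatmaps
from ..errors import ShapeError, ValidationError
from .layers import BatchNorm2d, BilinearUp2, Conv2d, MaxPool2, Param, ReLU


@dataclass(frozen=True)
class NetworkConfig:
    encoder_channels: tuple[int, ...] = (12, 24)
    use_batchnorm: bool = True
    n_classes: int = 3
    pretrained_encoder: str | None = None  # hook; no weights are shipped
    seed: int = 0

    def __post_init__(self):
        if len(self.encoder_channels) < 1:
            raise ValidationError("need at least one encoder stage")
        if any(c < 1 for c in self.encoder_channels):
            raise ValidationError("channel counts must be positive")
        if self.n_classes != 3:
            raise ValidationError("the head is fixed at 3 classes")

    @property
    def n_stages(self) -> int:
        return len(self.encoder_channels)

    @property
    def divisor(self) -> int:
        return 2 ** (self.n_stages - 1)

    @property
    def receptive_field_radius(self) -> int:
        """Analytic Chebyshev (per-axis) radius of the receptive field."""
        j = 1.0  # input pixels per feature-map step
        r = 0.0
        for s in range(self.n_stages):
            r += 2.0 * j  # two 3x3 convs
            if s < self.n_stages - 1:
                r += 0.5 * j  # 2x2 max pool
                j *= 2.0
        for s in range(self.n_stages - 2, -1, -1):
            r += 1.0 * j  # bilinear up reads one neighbour at the coarse scale
            j /= 2.0
            r += 2.0 * j  # two 3x3 decoder convs
        return int(math.ceil(r))


class _ConvBlock:
    def __init__(self, c_in, c_out, use_bn, rng):
        self.layers = []
        for i, (a, b) in enumerate(((c_in, c_out), (c_out, c_out))):
            self.layers.append(Conv2d(a, b, 3, rng))
            if use_bn:
                self.layers.append(BatchNorm2d(b))
            self.layers.append(ReLU())

    def forward(self, x, train):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, g):
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        return g

    def params(self, prefix):
        out = []
        for i, lyr in enumerate(self.layers):
            for name, p in lyr.params():
                out.append((f"{prefix}.{i}.{name}", p))
        return out


class Network:
    """U-Net-like fully-convolutional segmentation network."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.encoder_channels
        use_bn = config.use_batchnorm
        self.enc = [
            _ConvBlock(3 if s == 0 else ch[s - 1], ch[s], use_bn, rng)
            for s in range(config.n_stages)
        ]
        self.pools = [MaxPool2() for _ in range(config.n_stages - 1)]
        self.ups = [BilinearUp2() for _ in range(config.n_stages - 1)]
        self.dec = [
            _ConvBlock(ch[s] + ch[s + 1], ch[s], use_bn, rng)
            for s in range(config.n_stages - 1)
        ]
        self.head = Conv2d(ch[0], config.n_classes, 1, rng)

    # -- parameter plumbing -------------------------------------------------

    def params(self) -> list[tuple[str, Param]]:
        out = []
        for s, blk in enumerate(self.enc):
            out.extend(blk.params(f"enc{s}"))
        for s, blk in enumerate(self.dec):
            out.extend(blk.params(f"dec{s}"))
        for name, p in self.head.params():
            out.append((f"head.{name}", p))
        return out

    def _bn_layers(self):
        for blk in self.enc + self.dec:
            for lyr in blk.layers:
                if isinstance(lyr, BatchNorm2d):
                    yield lyr

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.value for name, p in self.params()}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn{i}.running_mean"] = bn.running_mean
            state[f"bn{i}.running_var"] = bn.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.params():
            p.value = np.asarray(state[name], dtype=np.float32)
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean = np.asarray(state[f"bn{i}.running_mean"], dtype=np.float32)
            bn.running_var = np.asarray(state[f"bn{i}.running_var"], dtype=np.float32)

    # -- forward / backward -------------------------------------------------

    def check_input_size(self, h: int, w: int):
        d = self.config.divisor
        if h % d or w % d:
            raise ShapeError(
                f"input {h}x{w} not divisible by 2^(n_stages-1) = {d}"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 3, H, W) float32 normalized -> logits (N, 3, H, W)."""
        self.check_input_size(x.shape[2], x.shape[3])
        skips = []
        h = x
        for s in range(self.config.n_stages):
            h = self.enc[s].forward(h, train)
            if s < self.config.n_stages - 1:
                skips.append(h)
                h = self.pools[s].forward(h, train)
        for s in range(self.config.n_stages - 2, -1, -1):
            h = self.ups[s].forward(h, train)
            h = np.concatenate([skips[s], h], axis=1)
            h = self.dec[s].forward(h, train)
        return self.head.forward(h, train)

    def backprop(self, dlogits: np.ndarray) -> None:
        """Full backward pass matching :meth:`forward`."""
        g = self.head.backward(dlogits)
        n_stages = self.config.n_stages
        d_skip = {}
        # decoder ran for s = n_stages-2 .. 0, so reverse: s = 0 .. n_stages-2
        for s in range(0, n_stages - 1):
            g = self.dec[s].backward(g)
            c_skip = self.config.encoder_channels[s]
            d_skip[s] = g[:, :c_skip]
            g = self.ups[s].backward(g[:, c_skip:])
        # encoder ran s = 0..n_stages-1; reverse
        for s in range(n_stages - 1, -1, -1):
            if s < n_stages - 1:
                g = self.pools[s].backward(g)
                g = g + d_skip[s]
            g = self.enc[s].backward(g)


def build_network(config: NetworkConfig) -> Network:
    if config.pretrained_encoder is not None:
        raise ValidationError(
            "pretrained encoder weights are a configuration hook only; "
            "no weight files are shipped with this package"
        )
    return Network(config)


@dataclass
class Normalizer:
    """Per-channel (x - mean) / sd using training-set statistics."""

    mean: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.float32))
    std: np.ndarray = field(default_factory=lambda: np.ones(3, dtype=np.float32))

    @classmethod
    def fit(cls, images: list[np.ndarray]) -> "Normalizer":
        stacked = np.concatenate([im.reshape(-1, 3).astype(np.float64) for im in images])
        mean = stacked.mean(axis=0)
        std = stacked.std(axis=0)
        std[std == 0] = 1.0
        return cls(mean.astype(np.float32), std.astype(np.float32))

    def apply(self, image: np.ndarray) -> np.ndarray:
        """uint8 (H, W, 3) -> normalized float32 (3, H, W)."""
        x = (image.astype(np.float32) - self.mean) / self.std
        return np.ascontiguousarray(x.transpose(2, 0, 1))


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_heatmaps(
    network: Network, image: np.ndarray, normalizer: Normalizer,
    pixel_size: float = 0.25,
) -> ClassHeatmaps:
    """Run the network in eval mode and convert logits to pseudoprobabilities."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("expected an (H, W, 3) RGB image")
    x = normalizer.apply(image)[None]
    if not np.all(np.isfinite(x)):
        raise ValidationError("normalized input contains non-finite values")
    logits = network.forward(x, train=False)
    probs = softmax_channels(logits.astype(np.float64))[0]
    return ClassHeatmaps(
        p_bg=probs[0], p_neg=probs[1], p_pos=probs[2], pixel_size=pixel_size
    )


def probe_receptive_field(network: Network, size: int | None = None) -> int:
    """Empirical Chebyshev receptive-field radius.

    Perturbs the center pixel of a random input (eval mode) and measures the
    per-axis bounding radius of changed logits.
    """
    if size is None:
        d = network.config.divisor
        size = int(np.ceil((4 * network.config.receptive_field_radius + 8) / d)) * d
    rng = np.random.default_rng(123)
    x = rng.normal(size=(1, 3, size, size)).astype(np.float32)
    y0 = network.forward(x, train=False)
    c = size // 2
    x2 = x.copy()
    x2[0, :, c, c] += 10.0
    y1 = network.forward(x2, train=False)
    diff = np.abs(y1 - y0).max(axis=(0, 1)) > 1e-6
    ys, xs = np.nonzero(diff)
    if len(ys) == 0:
        return 0
    return int(max(np.abs(ys - c).max(), np.abs(xs - c).max()))


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(
    path: str | Path,
    network: Network,
    normalizer: Normalizer,
    metadata: dict | None = None,
) -> None:
    """Bundle weights + config + normalizer stats + training metadata."""
    path = Path(path)
    meta = {
        "config": {
            "encoder_channels": list(network.config.encoder_channels),
            "use_batchnorm": network.config.use_batchnorm,
            "n_classes": network.config.n_classes,
            "seed": network.config.seed,
        },
        "normalizer": {
            "mean": normalizer.mean.tolist(),
            "std": normalizer.std.tolist(),
        },
        "metadata": metadata or {},
    }
    arrays = {f"param:{k}": v for k, v in network.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[Network, Normalizer, dict]:
    path = Path(path)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {
            k.removeprefix("param:"): data[k] for k in data.files if k.startswith("param:")
        }
    cfg = NetworkConfig(
        encoder_channels=tuple(meta["config"]["encoder_channels"]),
        use_batchnorm=meta["config"]["use_batchnorm"],
        n_classes=meta["config"]["n_classes"],
        seed=meta["config"]["seed"],
    )
    net = Network(cfg)
    net.load_state_dict(state)
    norm = Normalizer(
        np.asarray(meta["normalizer"]["mean"], dtype=np.float32),
        np.asarray(meta["normalizer"]["std"], dtype=np.float32),
    )
    return net, norm, meta["metadata"]
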