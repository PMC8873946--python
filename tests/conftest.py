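"""Shared fixtures: synthetic datasets and (session-scoped) trained models."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from plasmacount.network.model import NetworkConfig
from plasmacount.synthetic import SceneSpec, generate_patch
from plasmacount.training import (
    AugmentationPolicy,
    Hyperparams,
    make_sample,
    train,
)

BASE_SPEC = SceneSpec(width=128, height=128, noise_sd=4.0, n_artifact_blobs=1, seed=0)
SMALL_CONFIG = NetworkConfig(encoder_channels=(12, 24), seed=0)


def varied_scenes(n: int, seed: int = 42, seed0: int = 1000):
    """Synthetic patches with ~20 cells each and varying class counts."""
    rng = np.random.default_rng(seed)
    scenes = []
    for i in range(n):
        n_pos = int(rng.integers(2, 9))
        n_neg = int(rng.integers(12, 19))
        scenes.append(
            generate_patch(
                replace(BASE_SPEC, n_positive=n_pos, n_negative=n_neg, seed=seed0 + i)
            )
        )
    return scenes


@pytest.fixture(scope="session")
def trained_model():
    """Headline run: 20 train / 5 validation synthetic patches (~25 s CPU)."""
    scenes = varied_scenes(25)
    samples = [make_sample(s.image, s.truth, dilation_radius=5) for s in scenes]
    split = (list(range(20)), list(range(20, 25)))
    hp = Hyperparams(
        learning_rate=0.05, class_weights=(0.2, 1.0, 1.0),
        max_epochs=30, batch_size=5, seed=0,
    )
    result = train(
        samples, split, hp, SMALL_CONFIG,
        policy=AugmentationPolicy(), stop_at_f1=1.0,
    )
    return {"result": result, "samples": samples, "split": split, "scenes": scenes}


@pytest.fixture(scope="session")
def mini_checkpoint(tmp_path_factory):
    """Cheap overfit-one-patch checkpoint for interface-level contract tests."""
    from plasmacount.network.model import save_checkpoint

    scene = generate_patch(
        SceneSpec(width=128, height=128, n_positive=5, n_negative=15, seed=7)
    )
    sample = make_sample(scene.image, scene.truth, dilation_radius=5)
    hp = Hyperparams(learning_rate=0.05, class_weights=(0.2, 1.0, 1.0),
                     max_epochs=40, batch_size=1, seed=0)
    result = train([sample], ([0], [0]), hp, SMALL_CONFIG, stop_at_f1=1.0)
    path = tmp_path_factory.mktemp("ckpt") / "mini.npz"
    save_checkpoint(path, result.network, result.normalizer,
                    metadata={"model_id": "mini-overfit", "val_macro_f1": result.best_val_f1})
    return {"path": path, "scene": scene, "result": result}
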