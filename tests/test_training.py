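import hashlib
from dataclasses import replace

import numpy as np
import pytest

from plasmacount.annotations import PointAnnotation, encode_labels
from plasmacount.errors import TrainingError, ValidationError
from plasmacount.network.model import NetworkConfig
from plasmacount.synthetic import SceneSpec, generate_patch
from plasmacount.training import (
    AugmentationPolicy,
    AugmentDraw,
    Hyperparams,
    Sample,
    augment,
    grid_search,
    make_sample,
    split_dataset,
    train,
    weighted_cross_entropy,
)

TINY_CFG = NetworkConfig(encoder_channels=(6, 8), seed=0)


def tiny_samples(n=3, seed=0):
    scenes = [
        generate_patch(
            SceneSpec(width=64, height=64, n_positive=2, n_negative=4, seed=seed + i)
        )
        for i in range(n)
    ]
    return [make_sample(s.image, s.truth, dilation_radius=4) for s in scenes]


class TestHyperparams:
    def test_max_epochs_zero_rejected(self):
        with pytest.raises(ValidationError):
            Hyperparams(max_epochs=0)

    def test_bad_lr_and_weights(self):
        with pytest.raises(ValidationError):
            Hyperparams(learning_rate=0.0)
        with pytest.raises(ValidationError):
            Hyperparams(class_weights=(0.0, 1.0, 1.0))


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 255, (32, 32, 3), dtype=np.uint8)
        lbl = encode_labels(
            [PointAnnotation(5, 9, "neg"), PointAnnotation(20, 25, "pos")], (32, 32)
        )
        return img, lbl

    def test_identity_draw(self):
        img, lbl = self._pair()
        out_img, out_lbl = augment(img, lbl, AugmentDraw())
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_lbl, lbl)

    def test_hflip_moves_labels(self):
        img, lbl = self._pair()
        _, out_lbl = augment(img, lbl, AugmentDraw(hflip=True))
        assert out_lbl[9, 32 - 1 - 5] == 1
        assert out_lbl[25, 32 - 1 - 20] == 2

    def test_four_quarter_turns_identity(self):
        img, lbl = self._pair()
        out_img, out_lbl = img, lbl
        for _ in range(4):
            out_img, out_lbl = augment(out_img, out_lbl, AugmentDraw(angle=90.0))
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_lbl, lbl)

    def test_arbitrary_rotation_preserves_value_set(self):
        img, lbl = self._pair()
        _, out_lbl = augment(img, lbl, AugmentDraw(angle=33.5))
        assert set(np.unique(out_lbl)) <= {0, 1, 2}

    def test_brightness_image_only(self):
        img, lbl = self._pair()
        out_img, out_lbl = augment(img, lbl, AugmentDraw(brightness=1.2))
        assert np.array_equal(out_lbl, lbl)
        assert out_img.mean() > img.mean()

    def test_policy_sampling_ranges(self):
        pol = AugmentationPolicy(right_angles_only=True)
        rng = np.random.default_rng(0)
        draws = [pol.sample(rng) for _ in range(20)]
        assert all(d.angle % 90 == 0 for d in draws)
        assert all(0.8 <= d.brightness <= 1.25 for d in draws)

    def test_policy_validation(self):
        with pytest.raises(ValidationError):
            AugmentationPolicy(p_hflip=1.5)


class TestLoss:
    def test_weight_rescaling_leaves_gradient_unchanged(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(2, 3, 8, 8))
        labels = rng.integers(0, 3, size=(2, 8, 8))
        _, g1 = weighted_cross_entropy(logits, labels, (0.5, 1.0, 2.0))
        _, g2 = weighted_cross_entropy(logits, labels, (1.5, 3.0, 6.0))
        assert np.allclose(g1, g2)

    def test_perfect_prediction_low_loss(self):
        labels = np.zeros((1, 4, 4), dtype=np.int64)
        logits = np.zeros((1, 3, 4, 4))
        logits[0, 0] = 30.0
        loss, _ = weighted_cross_entropy(logits, labels, (1, 1, 1))
        assert loss < 1e-8


class TestTrain:
    def test_empty_split_rejected(self):
        samples = tiny_samples(2)
        hp = Hyperparams(max_epochs=1)
        with pytest.raises(ValidationError):
            train(samples, ([], [0]), hp, TINY_CFG)

    def test_overfit_one_patch(self):
        scene = generate_patch(SceneSpec(n_positive=5, n_negative=15, seed=7))
        sample = make_sample(scene.image, scene.truth, dilation_radius=5)
        hp = Hyperparams(learning_rate=0.05, class_weights=(0.2, 1, 1),
                         max_epochs=40, batch_size=1, seed=0)
        res = train([sample], ([0], [0]), hp,
                    NetworkConfig(encoder_channels=(12, 24), seed=0))
        assert res.best_val_f1 == 1.0
        # convergence: the loss drops by >= 10x over the full overfit run
        loss0 = res.history["loss"].iloc[0]
        assert loss0 / res.history["loss"].min() >= 10.0

    def test_determinism_same_seed(self):
        samples = tiny_samples(3)
        hp = Hyperparams(learning_rate=0.02, max_epochs=3, batch_size=2, seed=5)
        pol = AugmentationPolicy(right_angles_only=True)

        def digest(res):
            h = hashlib.sha256()
            for _, arr in sorted(res.network.state_dict().items()):
                h.update(np.ascontiguousarray(arr).tobytes())
            return h.hexdigest()

        r1 = train(samples, ([0, 1], [2]), hp, TINY_CFG, policy=pol)
        r2 = train(samples, ([0, 1], [2]), hp, TINY_CFG, policy=pol)
        assert r1.history.equals(r2.history)
        assert digest(r1) == digest(r2)

    def test_diverging_lr_raises(self):
        samples = tiny_samples(2)
        hp = Hyperparams(learning_rate=1e8, max_epochs=5, batch_size=1, seed=0)
        with pytest.raises(TrainingError):
            train(samples, ([0], [1]), hp, TINY_CFG)


class TestGridSearch:
    def test_single_point_grid(self):
        samples = tiny_samples(2)
        base = Hyperparams(max_epochs=1, batch_size=1, seed=0)
        res = grid_search(samples, ([0], [1]), [0.02], [(0.2, 1, 1)], base, TINY_CFG)
        assert res.best_hp.learning_rate == 0.02
        assert len(res.table) == 1

    def test_degenerate_cell_marked_failed(self):
        samples = tiny_samples(2)
        base = Hyperparams(max_epochs=3, batch_size=1, seed=0)
        res = grid_search(
            samples, ([0], [1]), [0.02, 1e8], [(0.2, 1, 1)], base, TINY_CFG
        )
        failed = res.table[res.table["status"] == "failed"]
        assert len(failed) == 1
        assert failed["learning_rate"].item() == 1e8
        assert res.best_hp.learning_rate == 0.02

    def test_argmax_selection(self):
        samples = tiny_samples(3)
        base = Hyperparams(max_epochs=2, batch_size=1, seed=0)
        res = grid_search(
            samples, ([0, 1], [2]), [0.01, 0.05], [(0.2, 1, 1), (1, 1, 1)], base, TINY_CFG
        )
        ok = res.table[res.table["status"] == "ok"]
        assert res.best_result.best_val_f1 == ok["val_macro_f1"].max()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            grid_search(tiny_samples(2), ([0], [1]), [], [(1, 1, 1)])


class TestSplit:
    def test_split_80_20(self):
        tr, va = split_dataset(10, 0.8, seed=1)
        assert len(tr) == 8 and len(va) == 2
        assert sorted(tr + va) == list(range(10))

    def test_split_seeded(self):
        assert split_dataset(20, seed=3) == split_dataset(20, seed=3)
        assert split_dataset(20, seed=3) != split_dataset(20, seed=4)
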