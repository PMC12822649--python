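"""Classifier recipe: architecture, augmentation, training, inference."""

import dataclasses

import numpy as np
import pytest

from conftest import TRAIN_SPEC
from foveloc.classifier import (AugmentSpec, ClassifierSpec, augment,
                                build_model, classify_stack,
                                describe_architecture, load_image_directory,
                                load_model, train)
from foveloc.errors import ConfigurationError, DataError, ParameterError
from foveloc.scene import SceneParams, generate_scene


EXPECTED_SEQUENCE = [
    ("conv", 32), ("relu", None), ("pool", None),
    ("conv", 64), ("relu", None), ("pool", None),
    ("conv", 128), ("relu", None), ("pool", None),
    ("conv", 256), ("relu", None), ("pool", None),
    ("flatten", None),
    ("dense", 512), ("relu", None),
    ("dense", 256), ("relu", None),
    ("dense", 1),
]


def closed_form_parameter_count(input_size):
    """Independent layer-by-layer hand count: conv out*(in*9+1); dense
    from the flattened (rows/16 x cols/16 x 256) feature map."""
    total, cin = 0, 3
    for f in (32, 64, 128, 256):
        total += f * (cin * 9 + 1)
        cin = f
    features = (input_size[0] // 16) * (input_size[1] // 16) * 256
    for units in (512, 256, 1):
        total += features * units + units
        features = units
    return total


class TestBuildModel:
    def test_layer_sequence_matches_recipe(self):
        model = build_model(ClassifierSpec(input_size=(64, 64)))
        assert describe_architecture(model) == EXPECTED_SEQUENCE

    @pytest.mark.parametrize("size", [(256, 256), (64, 64), (128, 64)])
    def test_parameter_count_matches_hand_count(self, size):
        model = build_model(ClassifierSpec(input_size=size))
        assert model.parameter_count() == closed_form_parameter_count(size)

    def test_output_is_a_probability(self):
        model = build_model(ClassifierSpec(input_size=(32, 32)))
        rng = np.random.default_rng(0)
        p = model.predict(rng.random((4, 32, 32, 3)).astype(np.float32))
        assert np.all((p >= 0) & (p <= 1))

    @pytest.mark.parametrize("size", [(8, 8), (24, 24), (30, 32)])
    def test_too_small_or_indivisible_input_rejected(self, size):
        with pytest.raises(ConfigurationError):
            build_model(ClassifierSpec(input_size=size))


class TestAugment:
    def test_identity_ranges_return_input_exactly(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16, 3)).astype(np.float32)
        out = augment(img, AugmentSpec.identity(), 0)
        np.testing.assert_array_equal(out, img)

    def test_fixed_seed_is_deterministic(self):
        rng = np.random.default_rng(1)
        img = rng.random((16, 16, 3)).astype(np.float32)
        a = augment(img, AugmentSpec(), 42)
        b = augment(img, AugmentSpec(), 42)
        np.testing.assert_array_equal(a, b)
        c = augment(img, AugmentSpec(), 43)
        assert not np.array_equal(a, c)

    def test_pure_brightness_shift_arithmetic(self):
        aug = AugmentSpec(brightness=(0.1, 0.1), contrast=(1.0, 1.0),
                          saturation=(1.0, 1.0), hue=(0.0, 0.0))
        img = np.full((8, 8, 3), 0.5, dtype=np.float32)
        np.testing.assert_allclose(augment(img, aug, 0), 0.6, atol=1e-6)
        bright = np.full((8, 8, 3), 0.95, dtype=np.float32)
        np.testing.assert_allclose(augment(bright, aug, 0), 1.0, atol=1e-6)

    def test_output_stays_in_unit_range(self):
        rng = np.random.default_rng(2)
        img = rng.random((16, 16, 3)).astype(np.float32)
        for seed in range(10):
            out = augment(img, AugmentSpec(), seed)
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestTrain:
    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train(np.empty((0, 16, 16)), np.empty(0), TRAIN_SPEC)

    def test_single_class_rejected(self):
        imgs = np.random.default_rng(0).random((6, 32, 32)).astype(np.float32)
        with pytest.raises(DataError):
            train(imgs, np.ones(6), TRAIN_SPEC)

    def test_report_invariants_hold(self, trained_classifier):
        _model, report = trained_classifier
        assert len(report.val_accuracy) == TRAIN_SPEC.epochs
        assert report.best_val_accuracy == max(report.val_accuracy)
        assert report.val_accuracy[report.best_epoch] == report.best_val_accuracy

    def test_separable_set_reaches_perfect_holdout(self, trained_classifier):
        _model, report = trained_classifier
        assert report.best_val_accuracy == 1.0
        assert report.test_accuracy == 1.0


class TestClassifyStack:
    def test_threshold_must_be_open_interval(self, trained_classifier,
                                             default_scene):
        model, _ = trained_classifier
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                classify_stack(default_scene.volume, model, bad)

    def test_flags_cover_the_fovea_bscan(self, trained_classifier,
                                         default_scene):
        model, _ = trained_classifier
        flags, probs = classify_stack(default_scene.volume, model, 0.5)
        assert len(flags) == len(default_scene.volume)
        assert flags[default_scene.truth.fovea_bscan_index]
        assert len(probs) == len(flags)

    def test_raising_threshold_is_monotone(self, trained_classifier,
                                           default_scene):
        model, _ = trained_classifier
        low, probs = classify_stack(default_scene.volume, model, 0.3)
        high, _ = classify_stack(default_scene.volume, model, 0.9)
        for lo, hi in zip(low, high):
            assert not (hi and not lo)


def test_checkpoint_roundtrip(tmp_path, labeled_set):
    images, labels = labeled_set
    spec = dataclasses.replace(TRAIN_SPEC, input_size=(32, 32), epochs=2)
    model, report = train(images[:8] + images[-8:],
                          np.concatenate([labels[:8], labels[-8:]]),
                          spec, checkpoint_path=tmp_path / "model.npz")
    assert report.checkpoint_path is not None
    loaded, loaded_spec = load_model(tmp_path / "model.npz")
    assert loaded_spec == spec
    x = np.stack([np.dstack([images[0]] * 3)])
    from foveloc.classifier import prepare_image
    xp = np.stack([prepare_image(images[0], spec.input_size)])
    np.testing.assert_array_equal(loaded.predict(xp), model.predict(xp))


def test_directory_dataset_layout(tmp_path, labeled_set):
    import imageio.v3 as iio

    images, labels = labeled_set
    (tmp_path / "fovea").mkdir()
    (tmp_path / "no fovea").mkdir()
    for i in range(4):
        iio.imwrite(tmp_path / "fovea" / f"p{i}.png",
                    np.rint(images[i] * 255).astype(np.uint8))
        iio.imwrite(tmp_path / "no fovea" / f"n{i}.png",
                    np.rint(images[-1 - i] * 255).astype(np.uint8))
    x, y = load_image_directory(tmp_path, (32, 32))
    assert x.shape == (8, 32, 32, 3)
    assert sorted(y.tolist()) == [0.0] * 4 + [1.0] * 4
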