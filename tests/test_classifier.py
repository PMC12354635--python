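"""Architecture assembly, augmentation, splitting, staged-training bookkeeping."""

import numpy as np
import pytest

from danioscope.classifier import (
    BackboneSpec,
    ConfigurationError,
    EmbryoClassifier,
    GeometricAugmentParams,
    PhaseConfig,
    augment_geometric,
    augment_red_boost,
    build_model,
    n_frozen_layers,
    run_phase,
    split_train_val,
    train_three_phase,
)
from danioscope.nn.layers import GlobalAveragePooling
from danioscope.phenotypes import PhenotypeClass
from danioscope.synthetic import LabeledImage, generate_dataset


class TestBuildModel:
    def test_output_is_normalised_probability_vector(self, small_dataset):
        model = build_model(BackboneSpec(), seed=1)
        probs = model.predict_proba(small_dataset[:3])
        assert probs.shape == (3, 5)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert np.all(probs >= 0)

    def test_inference_is_deterministic(self, small_dataset):
        model = build_model(BackboneSpec(), seed=1)
        a = model.predict_proba(small_dataset[:2])
        b = model.predict_proba(small_dataset[:2])
        np.testing.assert_array_equal(a, b)

    def test_global_average_pooling_matches_mean_over_positions(self, rng):
        x = rng.normal(size=(2, 3, 5, 4))
        pooled = GlobalAveragePooling().forward(x)
        expected = np.array(
            [[x[n, :, :, c].mean() for c in range(4)] for n in range(2)]
        )
        np.testing.assert_allclose(pooled, expected)

    def test_unavailable_backbones_raise_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_model(BackboneSpec(name="resnet50"))
        with pytest.raises(ConfigurationError):
            BackboneSpec(name="alexnet")

    def test_save_load_roundtrip_preserves_predictions(self, tmp_path, small_dataset):
        model = build_model(BackboneSpec(), seed=3)
        model.save(tmp_path / "model")
        loaded = EmbryoClassifier.load(tmp_path / "model")
        np.testing.assert_allclose(
            model.predict_proba(small_dataset[:3]), loaded.predict_proba(small_dataset[:3])
        )

    def test_resizes_non_native_inputs(self):
        model = build_model(BackboneSpec(), seed=0)
        big = generate_dataset({PhenotypeClass.NORMAL: 1}, image_size=224, seed=0)
        probs = model.predict_proba(big)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)


class TestRedBoost:
    def test_multiplies_red_and_clips(self):
        img = LabeledImage(
            pixels=np.array([[[100, 50, 50], [200, 10, 10]]], dtype=np.uint8),
            label=PhenotypeClass.NORMAL,
        )
        out = augment_red_boost(img, factor=1.5)
        np.testing.assert_array_equal(out.pixels[0, 0], [150, 50, 50])
        np.testing.assert_array_equal(out.pixels[0, 1], [255, 10, 10])
        assert out.label is PhenotypeClass.NORMAL

    def test_unit_factor_is_identity(self, small_dataset):
        img = small_dataset[0]
        np.testing.assert_array_equal(augment_red_boost(img, 1.0).pixels, img.pixels)

    def test_nonpositive_factor_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            augment_red_boost(small_dataset[0], 0.0)


class TestGeometricAugment:
    def test_zero_ranges_give_identity(self, small_dataset):
        params = GeometricAugmentParams(
            rotation_range=0, zoom_range=0, horizontal_flip=False, brightness_range=0
        )
        img = small_dataset[0]
        np.testing.assert_array_equal(augment_geometric(img, params, seed=3).pixels, img.pixels)

    def test_flip_only_is_an_involution(self, small_dataset):
        params = GeometricAugmentParams(
            rotation_range=0, zoom_range=0, horizontal_flip=True, brightness_range=0
        )
        img = small_dataset[1]
        once = augment_geometric(img, params, seed=5)
        twice = augment_geometric(once, params, seed=5)
        np.testing.assert_array_equal(twice.pixels, img.pixels)

    def test_fixed_seed_repeats_transform(self, small_dataset):
        params = GeometricAugmentParams()
        img = small_dataset[2]
        a = augment_geometric(img, params, seed=11)
        b = augment_geometric(img, params, seed=11)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.pixels.shape == img.pixels.shape

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigurationError):
            GeometricAugmentParams(rotation_range=-1)
        with pytest.raises(ConfigurationError):
            GeometricAugmentParams(zoom_range=1.5)


class TestSplit:
    def test_eighty_twenty_stratified_counts(self):
        data = generate_dataset({c: 20 for c in PhenotypeClass}, image_size=64, seed=2)
        train, val = split_train_val(data, seed=0)
        assert len(train) == 80 and len(val) == 20
        for cls in PhenotypeClass:
            assert sum(im.label == cls for im in train) == 16
            assert sum(im.label == cls for im in val) == 4

    def test_split_is_disjoint_and_exhaustive(self, small_dataset):
        train, val = split_train_val(small_dataset, seed=1)
        train_ids = {id(im) for im in train}
        val_ids = {id(im) for im in val}
        assert not train_ids & val_ids
        assert train_ids | val_ids == {id(im) for im in small_dataset}

    def test_same_seed_same_split(self, small_dataset):
        a = split_train_val(small_dataset, seed=7)
        b = split_train_val(small_dataset, seed=7)
        assert [id(i) for i in a[0]] == [id(i) for i in b[0]]

    def test_underpopulated_class_rejected(self):
        data = generate_dataset(
            {PhenotypeClass.NORMAL: 10, PhenotypeClass.DEAD: 3}, image_size=64, seed=0
        )
        with pytest.raises(ValueError):
            split_train_val(data, seed=0)


class TestPhaseConfig:
    def test_table_defaults_per_phase(self):
        p1, p2, p3 = (PhaseConfig.for_phase(i) for i in (1, 2, 3))
        assert (p1.frozen_fraction, p2.frozen_fraction, p3.frozen_fraction) == (1.0, 1 / 3, 0.0)
        assert (p1.initial_learning_rate, p2.initial_learning_rate) == (1e-4, 1e-5)
        assert p3.initial_learning_rate == 1e-5
        assert p1.batch_size == 16 and p1.max_epochs == 100
        assert p1.plateau_factor == 0.5 and p1.plateau_patience == 5
        assert p1.min_learning_rate == 1e-6
        assert (p1.data_source, p2.data_source, p3.data_source) == ("external", "external", "own")

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            PhaseConfig.for_phase(2, frozen_fraction=1.2)

    def test_layer_count_arithmetic(self):
        assert n_frozen_layers(9, 1 / 3) == 3
        assert n_frozen_layers(4, 1.0) == 4
        assert n_frozen_layers(4, 0.0) == 0
        assert n_frozen_layers(4, 1 / 3) == 1


@pytest.fixture(scope="module")
def train_corpus():
    return generate_dataset({c: 10 for c in PhenotypeClass}, image_size=64, seed=41)


class TestFreezeBookkeeping:
    @pytest.mark.parametrize("phase_id", [1, 2, 3])
    def test_changed_parameters_are_complement_of_frozen_set(self, phase_id, train_corpus):
        model = build_model(BackboneSpec(), seed=2)
        cfg = PhaseConfig.for_phase(phase_id, max_epochs=1)
        before = model.network.state_dict()
        run_phase(model, train_corpus, cfg, seed=3)
        after = model.network.state_dict()

        n_frozen = n_frozen_layers(len(model.backbone_layers), cfg.frozen_fraction)
        frozen_names = set()
        for layer in model.backbone_layers[:n_frozen]:
            frozen_names.update(layer.params())
        for name in before:
            if name in frozen_names:
                np.testing.assert_array_equal(before[name], after[name]), name
            else:
                assert not np.array_equal(before[name], after[name]), name


class TestThreePhase:
    def test_missing_class_in_corpus_rejected(self, train_corpus):
        partial = [im for im in train_corpus if im.label is not PhenotypeClass.EDEMA]
        with pytest.raises(ValueError):
            train_three_phase(BackboneSpec(), partial, train_corpus, seed=0)

    def test_full_protocol_runs_and_records_histories(self, train_corpus):
        model = train_three_phase(
            BackboneSpec(),
            train_corpus,
            train_corpus,
            seed=4,
            phase_overrides={"max_epochs": 2},
        )
        assert set(model.histories) == {"phase1", "phase2", "phase3"}
        for history in model.histories.values():
            assert 1 <= len(history) <= 2
            assert all(np.isfinite(row["val_loss"]) for row in history)
        probs = model.predict_proba(train_corpus[:4])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_identical_seeds_reproduce_final_weights(self, train_corpus):
        kwargs = dict(seed=9, phase_overrides={"max_epochs": 1})
        a = train_three_phase(BackboneSpec(), train_corpus, train_corpus, **kwargs)
        b = train_three_phase(BackboneSpec(), train_corpus, train_corpus, **kwargs)
        sa, sb = a.network.state_dict(), b.network.state_dict()
        for name in sa:
            np.testing.assert_array_equal(sa[name], sb[name])
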