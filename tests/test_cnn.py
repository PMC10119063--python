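"""Dataset assembly, architecture, training behaviour and prediction maps."""

import numpy as np
import pytest

from ramanpath.cnn import (
    CNNConfig,
    build_model,
    evaluate,
    extract_dense_features,
    load_model,
    predict_map,
    prepare_dataset,
    save_model,
    spectra_to_tensors,
    train,
)
from ramanpath.core import CLASS_CODES
from ramanpath.synthgen import SyntheticTissueSpec, generate_tissue_map, generate_training_set


class TestPrepareDataset:
    def test_70_30_split_of_1000_spectra(self):
        spectra = generate_training_set(n_per_class=200, seed=0)
        ds = prepare_dataset(spectra, CNNConfig(seed=0))
        assert ds.X_train.shape == (700, 2, 512)
        assert ds.X_test.shape == (300, 2, 512)

    def test_one_hot_rows_valid(self):
        spectra = generate_training_set(n_per_class=10, seed=0)
        ds = prepare_dataset(spectra, CNNConfig(seed=0))
        for block in (ds.y_train, ds.y_test):
            assert np.all(block.sum(axis=1) == 1.0)
            assert np.all((block == 0) | (block == 1))

    def test_split_is_stratified_within_one_sample(self):
        spectra = generate_training_set(n_per_class=99, seed=1)
        ds = prepare_dataset(spectra, CNNConfig(seed=1))
        for c in range(5):
            n_train = int(np.sum(ds.labels_train == c))
            assert abs(n_train - 0.7 * 99) <= 1

    def test_same_seed_same_shuffle(self):
        spectra = generate_training_set(n_per_class=20, seed=2)
        a = prepare_dataset(spectra, CNNConfig(seed=5))
        b = prepare_dataset(spectra, CNNConfig(seed=5))
        assert np.array_equal(a.X_train, b.X_train)
        assert np.array_equal(a.labels_test, b.labels_test)

    def test_wavenumber_row_carries_axis(self, axis):
        spectra = generate_training_set(n_per_class=3, seed=0)
        tensors, axis512 = spectra_to_tensors(spectra.spectra, axis, 512)
        assert tensors.shape[1:] == (2, 512)
        assert np.allclose(tensors[0, 1], axis512.wavenumbers)

    def test_missing_class_warns_empty_raises(self):
        spectra = generate_training_set(classes=["AVAC"], n_per_class=8, seed=0)
        with pytest.warns(UserWarning):
            prepare_dataset(spectra, CNNConfig(seed=0))


class TestArchitecture:
    def test_layer_census_18_conv_4_dense(self):
        model = build_model(CNNConfig(seed=0))
        assert model.n_conv_layers == 18
        assert model.n_dense_layers == 4

    def test_probabilities_sum_to_one(self, rng):
        model = build_model(CNNConfig(seed=0))
        X = rng.normal(0, 1, (4, 2, 512)).astype(np.float32)
        probs = model.predict_proba(X)
        assert probs.shape == (4, 5)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_accepts_2x512_input_without_reshape(self, rng):
        model = build_model(CNNConfig(seed=0))
        one = rng.normal(0, 1, (2, 512)).astype(np.float32)
        probs = model.predict_proba(one)
        assert probs.shape == (1, 5)

    def test_wrong_input_shape_rejected(self, rng):
        model = build_model(CNNConfig(seed=0))
        with pytest.raises(ValueError):
            model.predict_proba(rng.normal(0, 1, (4, 2, 100)))

    def test_last_dense_size_must_be_five(self):
        with pytest.raises(ValueError):
            CNNConfig(dense_sizes=(512, 256, 128, 4))


class TestTraining:
    def test_separable_classes_reach_high_training_accuracy(self, trained_model):
        _, _, history = trained_model
        assert history["accuracy"][-1] >= 0.99

    def test_loss_finite_every_epoch(self, trained_model):
        _, _, history = trained_model
        assert np.all(np.isfinite(history["loss"]))
        assert np.all(np.isfinite(history["val_loss"]))

    def test_history_has_one_entry_per_epoch(self, trained_model):
        model, _, history = trained_model
        for key in ("loss", "accuracy", "val_loss", "val_accuracy"):
            assert len(history[key]) == model.config.epochs

    def test_heldout_accuracy_high_on_marker_separated_classes(self, trained_model):
        """Classes differ chiefly in amide I position and methylation band;
        the classifier must read those markers from raw spectra."""
        model, dataset, history = trained_model
        assert history["val_accuracy"][-1] >= 0.94
        loss, acc = evaluate(model, dataset.X_test, dataset.y_test)
        assert acc == pytest.approx(history["val_accuracy"][-1], abs=1e-9)


class TestPredictionMap:
    @pytest.mark.parametrize("class_name", ["AVAC", "cPDAC"])
    def test_pure_template_map_classified_correctly(self, trained_model, class_name):
        model, _, _ = trained_model
        spec = SyntheticTissueSpec(
            map_width=12, map_height=12, class_name=class_name,
            baseline_coeffs=(0.0, 0.0, 0.0, 0.0), noise_sd=0.0, seed=3,
        )
        hmap = generate_tissue_map(spec)
        pred = predict_map(model, hmap)
        assert pred.classes.shape == hmap.shape
        agreement = np.mean(pred.classes == hmap.class_labels)
        assert agreement >= 0.99

    def test_codes_and_probabilities_valid(self, trained_model, rng):
        model, _, _ = trained_model
        spec = SyntheticTissueSpec(map_width=6, map_height=5, seed=0)
        pred = predict_map(model, generate_tissue_map(spec))
        assert pred.classes.shape == (5, 6)
        assert set(np.unique(pred.classes)) <= set(range(5))
        assert np.allclose(pred.probabilities.sum(axis=2), 1.0, atol=1e-6)


class TestFeatureExtraction:
    @pytest.mark.parametrize("stage,length", [("begin", 512), ("middle", 256), ("end", 128)])
    def test_stage_vector_lengths(self, trained_model, stage, length):
        model, dataset, _ = trained_model
        vec = extract_dense_features(model, dataset.X_test[0], stage)
        assert vec.shape == (length,)
        assert np.all(vec >= 0.0)  # post-ReLU activations

    def test_deterministic_per_spectrum(self, trained_model):
        model, dataset, _ = trained_model
        a = extract_dense_features(model, dataset.X_test[1], "middle")
        b = extract_dense_features(model, dataset.X_test[1], "middle")
        assert np.array_equal(a, b)

    def test_unknown_stage_rejected(self, trained_model):
        model, dataset, _ = trained_model
        with pytest.raises(ValueError):
            extract_dense_features(model, dataset.X_test[0], "final")


class TestSerialization:
    def test_round_trip_preserves_predictions(self, trained_model, tmp_path):
        model, dataset, _ = trained_model
        save_model(model, tmp_path / "model")
        restored = load_model(tmp_path / "model")
        a = model.predict_proba(dataset.X_test[:8])
        b = restored.predict_proba(dataset.X_test[:8])
        assert np.array_equal(a, b)
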