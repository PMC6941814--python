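"""Variant geometry, shape audits, training contract and ranking metrics."""

import warnings

import numpy as np
import pytest

from motifcnn.architectures import (TrainConfig, build_model, evaluate,
                                    load_checkpoint, make_variant,
                                    save_checkpoint, train, variant_names,
                                    TrainedModel)
from motifcnn.simulate import SyntheticDataset

COUPLED = ["CNN-1", "CNN-2", "CNN-4", "CNN-10", "CNN-25", "CNN-50", "CNN-100"]


class TestVariantFactory:
    def test_cnn25_geometry(self):
        spec = make_variant("CNN-25")
        (b1, b2) = spec.conv_layers
        assert (b1.pool_size, b2.pool_size) == (25, 4)
        assert (b1.filter_size, b2.filter_size) == (19, 5)
        assert (b1.n_filters, b2.n_filters) == (30, 128)
        assert spec.dense_units == 512 and spec.n_classes == 12

    def test_coupled_pools_multiply_to_100(self):
        for name in COUPLED:
            b1, b2 = make_variant(name).conv_layers
            assert b1.pool_size * b2.pool_size == 100

    def test_special_variants(self):
        assert make_variant("CNN_9-25").conv_layers[0].filter_size == 9
        assert make_variant("CNN_3-50").conv_layers[0].filter_size == 3
        s = make_variant("CNN-50-2").conv_layers[0]
        assert (s.pool_size, s.pool_stride) == (50, 2)
        assert make_variant("CNN_19-1-2").conv_layers[1].filter_size == 1
        three = make_variant("CNN-1-1-100")
        assert len(three.conv_layers) == 3
        assert [b.pool_size for b in three.conv_layers] == [1, 1, 100]

    def test_unknown_variant_error_lists_valid_names(self):
        with pytest.raises(ValueError, match="CNN-25"):
            make_variant("CNN-37")


class TestModelShapes:
    def test_feature_map_lengths_and_dense_input(self):
        m = build_model(make_variant("CNN-25"), 200, seed=0)
        assert m.flat_size == 2 * 128  # 200 -> 8 -> 2 feature positions
        m2 = build_model(make_variant("CNN-2"), 200, seed=0)
        assert m2.flat_size == 2 * 128  # 200 -> 100 -> 2

    def test_first_layer_filter_tensor_is_30_filters_of_19_by_4(self):
        m = build_model(make_variant("CNN-25"), 200, seed=0)
        assert m.layers[0].params["W"].shape == (30, 19, 4)

    @pytest.mark.parametrize("name", variant_names())
    def test_forward_pass_shape_audit(self, name, rng):
        m = build_model(make_variant(name), 200, seed=0)
        x = rng.random((2, 200, 4)).astype(np.float32)
        assert m.forward(x).shape == (2, 12)

    def test_coupled_variants_have_identical_parameter_counts(self):
        counts = {n: build_model(make_variant(n), 200, seed=0).n_parameters()
                  for n in COUPLED}
        assert len(set(counts.values())) == 1

    def test_cnn50_2_matches_cnn2_geometry(self):
        a = build_model(make_variant("CNN-50-2"), 200, seed=0)
        b = build_model(make_variant("CNN-2"), 200, seed=0)
        assert a.flat_size == b.flat_size
        assert a.n_parameters() == b.n_parameters()

    def test_filter_count_override(self):
        m = build_model(make_variant("CNN-25", n_filters1=120), 200, seed=0)
        assert m.layers[0].params["W"].shape[0] == 120


class TestTraining:
    def test_smoke_two_epochs_records_history(self, pool, tiny_dataset):
        m = build_model(make_variant("CNN-10"), 200, seed=0)
        tm = train(m, tiny_dataset, TrainConfig(max_epochs=2, seed=0))
        assert len(tm.history["train_loss"]) == 2
        assert len(tm.history["val_loss"]) == 2
        assert 0 <= tm.best_epoch < 2

    def test_all_zero_labels_drive_predictions_to_zero(self, tiny_dataset):
        ds = SyntheticDataset(tiny_dataset.sequences,
                              np.zeros_like(tiny_dataset.labels),
                              [], tiny_dataset.split, 0,
                              tiny_dataset.class_names)
        m = build_model(make_variant("CNN-10"), 200, seed=0)
        tm = train(m, ds, TrainConfig(max_epochs=4, seed=0))
        assert tm.history["train_loss"][-1] < tm.history["train_loss"][0]
        X = np.transpose(ds.sequences[:32], (0, 2, 1))
        assert m.predict(np.ascontiguousarray(X)).mean() < 0.2

    def test_best_epoch_minimises_validation_loss(self, tiny_dataset):
        m = build_model(make_variant("CNN-10"), 200, seed=1)
        tm = train(m, tiny_dataset, TrainConfig(max_epochs=3, seed=1))
        assert tm.best_epoch == int(np.argmin(tm.history["val_loss"]))

    def test_checkpoint_round_trip_preserves_predictions(self, tiny_dataset,
                                                         tmp_path):
        m = build_model(make_variant("CNN-10"), 200, seed=2)
        tm = train(m, tiny_dataset, TrainConfig(max_epochs=1, seed=2))
        save_checkpoint(tm, str(tmp_path / "ckpt"))
        back = load_checkpoint(str(tmp_path / "ckpt"))
        X = np.ascontiguousarray(
            np.transpose(tiny_dataset.sequences[:16], (0, 2, 1)))
        np.testing.assert_array_equal(m.predict(X), back.model.predict(X))
        assert back.best_epoch == tm.best_epoch

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0)


def _brute_force_auroc(scores, labels):
    """Mann-Whitney pair counting with midrank tie handling."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def _fake_trained(self, probs):
        class _M:
            def predict(self, X, batch_size=512):
                return probs[:X.shape[0]]
        return TrainedModel(_M(), None)

    def _ds(self, labels):
        n = labels.shape[0]
        return SyntheticDataset(
            np.zeros((n, 4, 8), dtype=np.float32), labels, [],
            {"test": np.arange(n)}, 0, [])

    def test_perfect_predictions_score_auroc_1(self):
        y = np.tile([1, 0], (6, 1)).astype(np.uint8)[:, :2]
        y = np.concatenate([y, 1 - y])  # both classes have pos and neg
        tm = self._fake_trained(y.astype(float))
        out = evaluate(tm, self._ds(y))
        np.testing.assert_allclose(out["auroc"], 1.0)

    def test_constant_predictions_score_half(self):
        y = np.array([[1, 0], [0, 1], [1, 1], [0, 0]], dtype=np.uint8)
        tm = self._fake_trained(np.full((4, 2), 0.3))
        out = evaluate(tm, self._ds(y))
        np.testing.assert_allclose(out["auroc"], 0.5)

    def test_single_inversion_matches_pair_counting_oracle(self):
        # ranking with one inversion among 4 examples -> AU-ROC 0.75
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert _brute_force_auroc(scores, labels) == 0.75
        y = labels[:, None].astype(np.uint8)
        tm = self._fake_trained(scores[:, None])
        out = evaluate(tm, self._ds(y))
        np.testing.assert_allclose(out["auroc"], [0.75])

    def test_degenerate_class_flagged_and_excluded(self):
        y = np.array([[1, 1], [1, 0], [1, 1], [1, 0]], dtype=np.uint8)
        tm = self._fake_trained(np.random.default_rng(0).random((4, 2)))
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            out = evaluate(tm, self._ds(y))
        assert np.isnan(out["auroc"][0]) and not np.isnan(out["auroc"][1])
        assert any("undefined" in str(x.message) for x in w)
        assert out["mean_auroc"] == out["auroc"][1]
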