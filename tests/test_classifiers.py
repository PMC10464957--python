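"""Maximum-likelihood and neural-net classifier behaviour against
independent oracles and closed-form limits."""

import numpy as np
import pytest

from reddmap import (MLCConfig, NNConfig, NNModel, RGBImage, ROISet,
                     classify_maximum_likelihood, classify_neural_net,
                     train_neural_net)
from reddmap.raster import ClassScheme
from reddmap.training import ClassStatistics, compute_class_statistics

from oracles import mlc_brute_force, nn_forward_by_hand


def make_stats(means, covs):
    return ClassStatistics(
        n={c: 100 for c in means},
        mean={c: np.asarray(m, float) for c, m in means.items()},
        cov={c: np.asarray(v, float) for c, v in covs.items()},
        singular={c for c, v in covs.items()
                  if np.linalg.matrix_rank(np.asarray(v)) < 3})


def scheme_k(k):
    return ClassScheme([(i + 1, f"class {i + 1}", (i, i, i))
                        for i in range(k)])


class TestMaximumLikelihood:
    def test_pixel_at_class_mean_gets_that_class(self):
        cov = 0.01 * np.eye(3)
        stats = make_stats({1: (0.2, 0.2, 0.2), 2: (0.8, 0.8, 0.8)},
                           {1: cov, 2: cov})
        img = RGBImage(np.full((1, 1, 3), round(0.2 * 255), dtype=np.uint8))
        cmap = classify_maximum_likelihood(img, stats, scheme_k(2))
        assert cmap.labels[0, 0] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_discriminant(self, seed):
        rng = np.random.default_rng(seed)
        img = RGBImage(rng.integers(0, 256, size=(5, 5, 3)).astype(np.uint8))
        means, covs = {}, {}
        for c in (1, 2, 3):
            means[c] = rng.random(3)
            a = rng.random((3, 3)) - 0.5
            covs[c] = a @ a.T + 0.05 * np.eye(3)
        stats = make_stats(means, covs)
        cmap = classify_maximum_likelihood(img, stats, scheme_k(3))
        expected = mlc_brute_force(img.as_unit_float(), stats, [1, 2, 3])
        np.testing.assert_array_equal(cmap.labels, expected)

    def test_no_threshold_classifies_every_pixel(self, survey_scene):
        stats = compute_class_statistics(survey_scene.image,
                                         survey_scene.training_rois)
        cmap = classify_maximum_likelihood(
            survey_scene.image, stats, survey_scene.truth.scheme)
        assert (cmap.labels != 0).all()

    def test_threshold_leaves_uncertain_pixels_unclassified(self):
        cov = 0.02 * np.eye(3)
        stats = make_stats({1: (0.3, 0.3, 0.3), 2: (0.7, 0.7, 0.7)},
                           {1: cov, 2: cov})
        # one pixel exactly between the two means: posterior 0.5 per class
        img = RGBImage(np.array([[[128, 128, 128]],
                                 [[64, 64, 64]]], dtype=np.uint8))
        cmap = classify_maximum_likelihood(
            img, stats, scheme_k(2), MLCConfig(probability_threshold=0.9))
        assert cmap.labels[0, 0] == 0  # ambiguous pixel dropped
        assert cmap.labels[1, 0] == 1  # confident pixel kept

    def test_equal_priors_identity_covariance_is_nearest_mean(self):
        rng = np.random.default_rng(23)
        means = {c: rng.random(3) for c in (1, 2, 3, 4)}
        stats = make_stats(means, {c: np.eye(3) for c in means})
        img = RGBImage(rng.integers(0, 256, size=(6, 6, 3)).astype(np.uint8))
        cmap = classify_maximum_likelihood(img, stats, scheme_k(4))
        unit = img.as_unit_float()
        dists = np.stack([((unit - means[c]) ** 2).sum(axis=2)
                          for c in (1, 2, 3, 4)])
        np.testing.assert_array_equal(cmap.labels, dists.argmin(axis=0) + 1)

    def test_relabeling_classes_permutes_output(self):
        rng = np.random.default_rng(31)
        img = RGBImage(rng.integers(0, 256, size=(7, 7, 3)).astype(np.uint8))
        means = {c: rng.random(3) for c in (1, 2, 3)}
        covs = {c: 0.05 * np.eye(3) for c in (1, 2, 3)}
        base = classify_maximum_likelihood(
            img, make_stats(means, covs), scheme_k(3))
        # relabel 1->3, 2->1, 3->2
        perm = {1: 3, 2: 1, 3: 2}
        swapped = classify_maximum_likelihood(
            img,
            make_stats({perm[c]: means[c] for c in means},
                       {perm[c]: covs[c] for c in covs}),
            scheme_k(3))
        lut = np.zeros(4, dtype=np.int64)
        for old, new in perm.items():
            lut[old] = new
        np.testing.assert_array_equal(swapped.labels, lut[base.labels])

    def test_singular_covariance_is_regularized_not_fatal(self):
        stats = make_stats({1: (0.2, 0.2, 0.2), 2: (0.8, 0.8, 0.8)},
                           {1: np.zeros((3, 3)), 2: np.zeros((3, 3))})
        img = RGBImage(np.array([[[230, 230, 230]]], dtype=np.uint8))
        cmap = classify_maximum_likelihood(img, stats, scheme_k(2))
        assert cmap.labels[0, 0] == 2

    def test_missing_class_statistics_rejected(self):
        stats = make_stats({1: (0.2, 0.2, 0.2)}, {1: np.eye(3)})
        img = RGBImage(np.zeros((2, 2, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="missing statistics"):
            classify_maximum_likelihood(img, stats, scheme_k(2))

    def test_priors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MLCConfig(priors={1: 0.7, 2: 0.7})


def separable_fixture():
    """Two tight colour clusters on opposite corners of the cube."""
    rng = np.random.default_rng(7)
    px = np.zeros((20, 2, 3), dtype=np.uint8)
    px[:, 0] = np.clip(rng.normal(40, 5, size=(20, 3)), 0, 255)
    px[:, 1] = np.clip(rng.normal(215, 5, size=(20, 3)), 0, 255)
    img = RGBImage(px)
    rois = ROISet({
        1: np.column_stack([np.arange(20), np.zeros(20, int)]),
        2: np.column_stack([np.arange(20), np.ones(20, int)]),
    }, (20, 2))
    return img, rois


class TestNeuralNet:
    def test_separable_clusters_reach_full_training_accuracy(self):
        img, rois = separable_fixture()
        model = train_neural_net(img, rois, NNConfig(rng_seed=1))
        cmap = classify_neural_net(model, img, scheme_k(2))
        assert (cmap.labels[:, 0] == 1).all()
        assert (cmap.labels[:, 1] == 2).all()

    def test_forward_pass_matches_hand_computation(self):
        w1 = np.array([[0.1, -0.2], [0.3, 0.05], [-0.4, 0.2]])
        b1 = np.array([0.01, -0.02])
        w2 = np.array([[0.5, -0.3, 0.1], [-0.2, 0.4, 0.6]])
        b2 = np.array([0.0, 0.1, -0.1])
        model = NNModel(w_hidden=w1, b_hidden=b1, w_output=w2, b_output=b2,
                        class_ids=[1, 2, 3], config=NNConfig())
        x = np.array([0.25, 0.5, 0.75])
        np.testing.assert_allclose(model.forward(x)[0],
                                   nn_forward_by_hand(x, w1, b1, w2, b2),
                                   rtol=1e-12)

    def test_fixed_weight_classification_is_output_argmax(self):
        rng = np.random.default_rng(3)
        w1 = rng.normal(size=(3, 4)) * 0.5
        b1 = rng.normal(size=4) * 0.1
        w2 = rng.normal(size=(4, 3)) * 0.5
        b2 = rng.normal(size=3) * 0.1
        model = NNModel(w_hidden=w1, b_hidden=b1, w_output=w2, b_output=b2,
                        class_ids=[1, 2, 3], config=NNConfig())
        img = RGBImage(rng.integers(0, 256, size=(4, 4, 3)).astype(np.uint8))
        cmap = classify_neural_net(model, img, scheme_k(3))
        assert cmap.labels.shape == (4, 4)
        for r in range(4):
            for c in range(4):
                out = nn_forward_by_hand(img.as_unit_float()[r, c],
                                         w1, b1, w2, b2)
                assert cmap.labels[r, c] == out.argmax() + 1
        assert (cmap.labels != 0).all()

    def test_same_seed_gives_bit_identical_weights(self):
        img, rois = separable_fixture()
        m1 = train_neural_net(img, rois, NNConfig(rng_seed=42,
                                                  max_iterations=50))
        m2 = train_neural_net(img, rois, NNConfig(rng_seed=42,
                                                  max_iterations=50))
        np.testing.assert_array_equal(m1.w_hidden, m2.w_hidden)
        np.testing.assert_array_equal(m1.w_output, m2.w_output)
        np.testing.assert_array_equal(m1.b_hidden, m2.b_hidden)
        np.testing.assert_array_equal(m1.b_output, m2.b_output)

    def test_loss_history_finite_and_improving_on_separable_data(self):
        img, rois = separable_fixture()
        model = train_neural_net(img, rois, NNConfig(rng_seed=5))
        rms = np.array(model.rms_history)
        assert len(rms) >= 1
        assert np.isfinite(rms).all()
        assert rms[-1] <= rms[0]

    def test_training_stops_at_rms_exit(self):
        img, rois = separable_fixture()
        model = train_neural_net(img, rois, NNConfig(rng_seed=5,
                                                     rms_exit=0.45))
        assert model.converged
        assert model.rms_history[-1] <= 0.45
        assert len(model.rms_history) < 1000

    def test_non_convergence_returns_model_with_warning(self, caplog):
        img, rois = separable_fixture()
        import logging
        with caplog.at_level(logging.WARNING, logger="reddmap.classify"):
            model = train_neural_net(img, rois,
                                     NNConfig(rng_seed=5, max_iterations=3))
        assert not model.converged
        assert len(model.rms_history) == 3
        assert any("did not reach" in r.message for r in caplog.records)

    def test_model_file_roundtrip_preserves_predictions(self, tmp_path):
        img, rois = separable_fixture()
        model = train_neural_net(img, rois, NNConfig(rng_seed=8,
                                                     max_iterations=100))
        path = tmp_path / "model.json"
        model.save(path)
        back = NNModel.load(path)
        np.testing.assert_array_equal(
            classify_neural_net(back, img, scheme_k(2)).labels,
            classify_neural_net(model, img, scheme_k(2)).labels)
        np.testing.assert_array_equal(back.w_hidden, model.w_hidden)

    def test_empty_training_set_rejected(self):
        img, _ = separable_fixture()
        with pytest.raises(ValueError, match="empty"):
            train_neural_net(img, ROISet({}, (20, 2)))

    def test_band_mismatch_rejected(self):
        model = NNModel(w_hidden=np.zeros((4, 2)), b_hidden=np.zeros(2),
                        w_output=np.zeros((2, 2)), b_output=np.zeros(2),
                        class_ids=[1, 2], config=NNConfig())
        with pytest.raises(ValueError, match="bands"):
            model.forward(np.zeros((1, 3)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NNConfig(training_rate=0.0)
        with pytest.raises(ValueError):
            NNConfig(momentum=1.5)
        with pytest.raises(ValueError):
            NNConfig(max_iterations=0)
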