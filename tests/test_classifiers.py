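"""Classifier contract tests: grids, the nearest-shrunken-centroid
construction (hand-checked soft-thresholding), k-NN tie rules and the fast
error-curve sweep, and limit behaviours of the wrapped learners."""

import numpy as np
import pytest

from poolsim import (
    CASE,
    CONTROL,
    KNearestNeighbors,
    NearestShrunkenCentroid,
    OmicsDataset,
    default_spec,
    nsc_shrink_centroids,
    predict,
    train,
)
from poolsim.classifiers import grid_points, knn_error_curve


def _dataset(values, labels):
    values = np.asarray(values, dtype=float)
    return OmicsDataset(values=values, bio_values=values, labels=labels,
                        marker_indices=[], gamma_values=[])


class TestGridPoints:
    def test_radial_grid_enumerates_gamma_within_cost(self):
        pts = grid_points(default_spec("svm_radial"), n_features=100, n_train=120)
        assert len(pts) == 35
        assert pts[0] == {"c": 0.1, "gamma": 0.25}
        assert pts[1] == {"c": 0.1, "gamma": 0.5}  # gamma varies fastest
        assert pts[5] == {"c": 1.0, "gamma": 0.25}

    def test_knn_grid_is_capped_by_features_and_training_size(self):
        pts = grid_points(default_spec("knn"), n_features=1000, n_train=24)
        assert [p["k"] for p in pts] == list(range(1, 25))
        pts = grid_points(default_spec("knn"), n_features=10, n_train=120)
        assert [p["k"] for p in pts] == list(range(1, 11))

    def test_forest_feature_counts_capped_and_deduplicated(self):
        pts = grid_points(default_spec("random_forest"), n_features=10, n_train=120)
        assert [p["mtry"] for p in pts] == [4, 8, 10]

    def test_unknown_classifier_name_is_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            default_spec("naive_bayes")


class TestKNearestNeighbors:
    def test_one_nn_memorizes_distinct_training_points(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.where(rng.random(12) < 0.5, CASE, CONTROL)
        model = KNearestNeighbors(1).fit(X, y)
        np.testing.assert_array_equal(model.predict(X), y)

    def test_split_vote_falls_to_the_nearest_neighbor(self):
        X = np.array([[0.0], [1.0], [3.0], [4.0]])
        y = np.array([CONTROL, CONTROL, CASE, CASE])
        model = KNearestNeighbors(4).fit(X, y)
        # all neighbors vote 2-2; the single nearest one decides
        assert model.predict([[0.4]])[0] == CONTROL
        assert model.predict([[3.6]])[0] == CASE

    def test_error_curve_matches_per_k_prediction(self, rng):
        Xtr, Xte = rng.normal(size=(20, 4)), rng.normal(size=(15, 4))
        ytr = np.where(rng.random(20) < 0.5, CASE, CONTROL)
        yte = np.where(rng.random(15) < 0.5, CASE, CONTROL)
        ks = list(range(1, 21))
        curve = knn_error_curve(Xtr, ytr, Xte, yte, ks)
        brute = [
            np.sum(KNearestNeighbors(k).fit(Xtr, ytr).predict(Xte) != yte)
            for k in ks
        ]
        np.testing.assert_array_equal(curve, brute)

    def test_k_larger_than_training_set_is_rejected(self):
        with pytest.raises(ValueError):
            KNearestNeighbors(5).fit(np.zeros((3, 2)), np.array([CASE, CASE, CONTROL]))


class TestNearestShrunkenCentroid:
    # one feature; controls (0, 2), cases (3, 5):
    #   class means 1 and 4, overall 2.5, pooled within-class sd s = sqrt(2),
    #   s0 = median(s) = sqrt(2), m_k = sqrt(1/2 - 1/4) = 1/2,
    #   standardized difference d = -+1.5 / (0.5 * 2*sqrt(2)) = -+1.0606602
    X1 = np.array([[0.0], [2.0], [3.0], [5.0]])
    y1 = np.array([CONTROL, CONTROL, CASE, CASE])

    def test_soft_threshold_of_a_hand_computed_difference(self):
        model = NearestShrunkenCentroid(delta=0.5).fit(self.X1, self.y1)
        assert model.raw_differences_[0, 0] == pytest.approx(-1.0606601717798212)
        assert model.shrunken_differences_[0, 0] == pytest.approx(-0.5606601717798212)
        # de-standardized: 2.5 - 0.5606602 * 0.5 * 2*sqrt(2) = 1.7071068
        assert model.shrunken_centroids_[0, 0] == pytest.approx(1.7071067811865475)
        assert model.shrunken_centroids_[1, 0] == pytest.approx(5.0 - 1.7071067811865475)

    def test_zero_delta_keeps_raw_class_means(self):
        model = NearestShrunkenCentroid(delta=0.0).fit(self.X1, self.y1)
        np.testing.assert_allclose(model.shrunken_centroids_[:, 0], [1.0, 4.0])
        assert model.n_surviving_features == 1

    def test_total_shrinkage_collapses_to_overall_centroid(self):
        model = NearestShrunkenCentroid(delta=50.0).fit(self.X1, self.y1)
        np.testing.assert_allclose(model.shrunken_centroids_, 2.5)
        assert model.n_surviving_features == 0
        # every point is now equidistant; the tie goes to the control class
        assert (model.predict([[0.0], [10.0]]) == CONTROL).all()

    def test_zero_delta_is_plain_nearest_centroid(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.where(rng.random(30) < 0.5, CASE, CONTROL)
        model = NearestShrunkenCentroid(0.0).fit(X, y)
        c0, c1 = X[y == CONTROL].mean(axis=0), X[y == CASE].mean(axis=0)
        denom = model.s_ + model.s0_
        q = rng.normal(size=(20, 5))
        d0 = (((q - c0) / denom) ** 2).sum(axis=1)
        d1 = (((q - c1) / denom) ** 2).sum(axis=1)
        np.testing.assert_array_equal(model.predict(q), np.where(d1 < d0, CASE, CONTROL))

    def test_feature_survival_is_nonincreasing_in_delta(self, small_dataset):
        counts = [
            nsc_shrink_centroids(small_dataset, np.arange(40), d).n_surviving_features
            for d in (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 40

    def test_negative_delta_is_rejected(self):
        with pytest.raises(ValueError):
            NearestShrunkenCentroid(-0.1)


class TestTrainPredict:
    def test_linear_svm_separates_a_separable_toy_set(self):
        values = np.array([[0.0, 0.0], [0.2, 0.1], [3.0, 3.0], [2.8, 3.1]])
        ds = _dataset(values, [CONTROL, CONTROL, CASE, CASE])
        model = train(default_spec("svm_linear"), {"c": 500.0}, ds, [0, 1])
        np.testing.assert_array_equal(predict(model, ds), ds.labels)

    def test_nearest_centroid_labels_match_hand_distances(self):
        train_ds = _dataset([[0.0, 0.0], [0.0, 2.0], [4.0, 0.0], [4.0, 2.0]],
                            [CONTROL, CONTROL, CASE, CASE])
        model = train(default_spec("pam"), {"delta": 0.0}, train_ds, [0, 1])
        # centroids (0,1) and (4,1): x-coordinate decides
        test_ds = _dataset([[0.5, 1.0], [3.5, 1.0], [1.9, 0.0]],
                           [CONTROL, CONTROL, CONTROL])
        np.testing.assert_array_equal(predict(model, test_ds), [CONTROL, CASE, CONTROL])

    def test_model_is_restricted_to_selected_features(self, small_dataset, rng):
        model = train(default_spec("knn"), {"k": 3}, small_dataset, [7, 2, 11], rng)
        np.testing.assert_array_equal(model.selected_features, [7, 2, 11])
        slim = _dataset(small_dataset.values[:, :12], small_dataset.labels)
        preds = predict(model, slim)  # only needs features up to index 11
        assert preds.shape == (small_dataset.n_samples,)

    def test_feature_mismatch_is_rejected(self, small_dataset):
        model = train(default_spec("pam"), {"delta": 0.1}, small_dataset, [35])
        tiny = _dataset(small_dataset.values[:, :10], small_dataset.labels)
        with pytest.raises(ValueError, match="lacks features"):
            predict(model, tiny)

    def test_single_class_training_data_is_rejected(self):
        ds = _dataset(np.zeros((4, 2)), [CASE] * 4)
        with pytest.raises(ValueError):
            train(default_spec("plr"), {"lambda": 1.0}, ds, [0, 1])

    def test_random_forest_is_reproducible_given_a_seed(self, small_dataset):
        spec = default_spec("random_forest")
        out = []
        for _ in range(2):
            model = train(spec, {"mtry": 4}, small_dataset, np.arange(10),
                          np.random.default_rng(5))
            out.append(predict(model, small_dataset))
        np.testing.assert_array_equal(out[0], out[1])

    def test_deterministic_learners_need_no_rng(self, small_dataset):
        for name, params in [("svm_linear", {"c": 1.0}), ("knn", {"k": 5}),
                             ("plr", {"lambda": 1.0}), ("pam", {"delta": 0.5})]:
            a = predict(train(default_spec(name), params, small_dataset, np.arange(8)),
                        small_dataset)
            b = predict(train(default_spec(name), params, small_dataset, np.arange(8)),
                        small_dataset)
            np.testing.assert_array_equal(a, b)
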