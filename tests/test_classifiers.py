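"""Classifier trainers, prediction, evaluation protocol and persistence."""

import numpy as np
import pytest

from serumpep import classify as clf
from serumpep.classify import (ClassifierModel, CVResult, GAParams,
                               ModelPersistenceError, UNCLASSIFIABLE,
                               classify, cross_validate, load_model,
                               predict_features, save_model, train_ga_knn,
                               train_qc, train_snn)
from serumpep.simulate import MUTANT, WILD

FAST_GA = GAParams(population=16, generations=8)


def blobs(n_per_class=20, n_noise=8, sep=4.0, seed=0, n_informative=2):
    """Two informative columns separating the classes + pure-noise columns."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = np.abs(rng.normal(10, 1.5, size=(n, n_informative + n_noise)))
    X[:n_per_class, :n_informative] += sep
    labels = np.array([MUTANT] * n_per_class + [WILD] * n_per_class)
    centroids = 1000.0 + 100.0 * np.arange(X.shape[1])
    return X, centroids, labels


def knn_oracle(Xtr, ytr, Xte, k):
    """Independent brute-force k-NN with the same tie conventions."""
    preds = []
    for x in Xte:
        d = [(float(np.sum((x - Xtr[j]) ** 2)), j) for j in range(len(Xtr))]
        d.sort(key=lambda t: (t[0], t[1]))  # stable under distance ties
        votes = [ytr[j] for _, j in d[:k]]
        frac = votes.count(MUTANT) / k
        preds.append(MUTANT if frac > 0.5 else WILD)
    return np.array(preds)


class TestKnnCore:
    def test_matches_brute_force_oracle(self, rng):
        for trial in range(10):
            Xtr = rng.normal(size=(30, 4))
            ytr = np.array([MUTANT, WILD])[rng.integers(0, 2, 30)]
            if len(set(ytr)) < 2:
                continue
            Xte = rng.normal(size=(12, 4))
            for k in (1, 3, 7):
                got = clf._knn_predict(Xtr, ytr, Xte, k)
                np.testing.assert_array_equal(got, knn_oracle(Xtr, ytr, Xte, k))

    def test_tie_breaks_toward_wild(self):
        # equidistant neighbors, k=1: index order decides; vote tie at k=2
        Xtr = np.array([[0.0], [2.0]])
        ytr = np.array([MUTANT, WILD])
        got = clf._knn_predict(Xtr, ytr, np.array([[1.0]]), 2)
        assert got[0] == WILD  # 50/50 vote is not a majority for mutant


class TestTrainers:
    def test_qc_selects_informative_peaks_first(self):
        X, centroids, labels = blobs(seed=1)
        model = train_qc(X, centroids, labels, max_peaks=3)
        assert set(model.selected_peaks) >= {1000.0, 1100.0}
        pred = predict_features(model, X, centroids)
        assert (pred == labels).mean() >= 0.9

    def test_snn_separable(self):
        X, centroids, labels = blobs(seed=2)
        model = train_snn(X, centroids, labels, seed=0)
        pred = predict_features(model, X, centroids)
        assert (pred == labels).mean() >= 0.95

    def test_ga_selects_planted_informative_columns(self):
        X, centroids, labels = blobs(seed=3, n_noise=30, sep=3.0)
        model, cv = train_ga_knn(X, centroids, labels, k=3,
                                 ga_params=FAST_GA, seed=0)
        assert {1000.0, 1100.0} <= set(model.selected_peaks)
        assert cv.cross_validation_pct >= 90.0
        assert GAParams().subset_min <= len(model.selected_peaks) \
            <= GAParams().subset_max

    def test_ga_is_deterministic(self):
        X, centroids, labels = blobs(seed=4, n_noise=10)
        m1, cv1 = train_ga_knn(X, centroids, labels, k=3,
                               ga_params=FAST_GA, seed=5)
        m2, cv2 = train_ga_knn(X, centroids, labels, k=3,
                               ga_params=FAST_GA, seed=5)
        assert m1.selected_peaks == m2.selected_peaks
        assert cv1.cross_validation_pct == cv2.cross_validation_pct
        assert cv1.per_iteration == cv2.per_iteration

    def test_ga_rejects_even_k(self):
        X, centroids, labels = blobs()
        with pytest.raises(ValueError, match="odd"):
            train_ga_knn(X, centroids, labels, k=4, ga_params=FAST_GA)

    def test_trainers_reject_single_class(self):
        X, centroids, _ = blobs()
        labels = np.array([MUTANT] * len(X))
        for trainer in (train_qc, train_snn):
            with pytest.raises(ValueError, match=">= 3"):
                trainer(X, centroids, labels)

    def test_null_features_give_chance_level_cv(self, rng):
        """Pure noise with random labels: CV must sit near 50%."""
        X = np.abs(rng.normal(10, 2, size=(30, 6)))
        labels = np.array([MUTANT, WILD] * 15)
        cv = cross_validate(lambda Xt, ct, yt: train_qc(Xt, ct, yt),
                            X, 1000.0 + 100 * np.arange(6), labels, seed=0)
        assert 20.0 <= cv.cross_validation_pct <= 80.0

    def test_scale_invariance_of_standardized_models(self):
        X, centroids, labels = blobs(seed=6)
        scale = np.full(X.shape[1], 1000.0)
        for trainer in (lambda A: train_qc(A, centroids, labels),
                        lambda A: train_snn(A, centroids, labels, seed=0)):
            pred_raw = predict_features(trainer(X), X, centroids)
            pred_scaled = predict_features(trainer(X * scale), X * scale, centroids)
            np.testing.assert_array_equal(pred_raw, pred_scaled)


class TestClassify:
    def _model(self):
        X, centroids, labels = blobs(seed=7)
        return train_qc(X, centroids, labels), X, centroids

    def test_invalid_qc_flag_is_unclassifiable(self):
        model, X, centroids = self._model()
        assert classify(model, X[0], centroids, qc_flag="invalid") == UNCLASSIFIABLE

    def test_missing_areas_are_unclassifiable(self):
        model, X, centroids = self._model()
        x = X[0].copy()
        x[0] = np.nan
        assert classify(model, x, centroids, qc_flag="ok") == UNCLASSIFIABLE

    def test_missing_column_is_an_error(self):
        model, X, centroids = self._model()
        with pytest.raises(KeyError):
            classify(model, X[0, :2], centroids[:2] + 5000.0)

    def test_centroid_matching_tolerates_small_shift(self):
        model, X, centroids = self._model()
        a = predict_features(model, X, centroids)
        b = predict_features(model, X, centroids + 0.8)  # within 1.5 Da
        np.testing.assert_array_equal(a, b)


class TestEvaluation:
    def test_recognition_is_resubstitution_accuracy(self):
        X, centroids, labels = blobs(seed=8)
        trainer = lambda Xt, ct, yt: train_qc(Xt, ct, yt)
        cv = cross_validate(trainer, X, centroids, labels, seed=1)
        model = trainer(X, centroids, labels)
        resub = 100.0 * (predict_features(model, X, centroids) == labels).mean()
        assert cv.recognition_capability_pct == pytest.approx(resub)
        assert len(cv.per_iteration) == 10
        assert cv.cross_validation_pct == pytest.approx(
            np.mean(cv.per_iteration))

    def test_split_sizes_are_stratified(self):
        X, centroids, labels = blobs(n_per_class=10, seed=9)
        seen = []
        def spy(Xt, ct, yt):
            seen.append((list(yt).count(MUTANT), list(yt).count(WILD)))
            return train_qc(Xt, ct, yt)
        cross_validate(spy, X, centroids, labels, leave_out_pct=20.0,
                       iterations=4, seed=0)
        for nm, nw in seen[:-1]:  # last fit is the full-data refit
            assert (nm, nw) == (8, 8)
        assert seen[-1] == (10, 10)

    def test_unstratified_unsupported(self):
        X, centroids, labels = blobs()
        with pytest.raises(ValueError, match="stratified"):
            cross_validate(lambda *a: None, X, centroids, labels,
                           stratified=False)

    def test_cv_result_bounds_validated(self):
        with pytest.raises(ValueError):
            CVResult(cross_validation_pct=120.0,
                     recognition_capability_pct=50.0, per_iteration=[])


class TestPersistence:
    def test_round_trip_preserves_predictions(self, tmp_path):
        X, centroids, labels = blobs(seed=10)
        for model in (train_qc(X, centroids, labels),
                      train_snn(X, centroids, labels, seed=0)):
            path = save_model(model, tmp_path / f"{model.kind}.json")
            back = load_model(path)
            np.testing.assert_array_equal(
                predict_features(model, X, centroids),
                predict_features(back, X, centroids))
            assert back.kind == model.kind
            assert back.selected_peaks == model.selected_peaks

    def test_tampering_detected(self, tmp_path):
        X, centroids, labels = blobs(seed=11)
        path = save_model(train_qc(X, centroids, labels), tmp_path / "m.json")
        text = path.read_text().replace("QC", "GA", 1)
        path.write_text(text)
        with pytest.raises(ModelPersistenceError, match="checksum"):
            load_model(path)

    def test_unreadable_file_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text("not json {")
        with pytest.raises(ModelPersistenceError, match="unreadable"):
            load_model(path)

    def test_wrong_version_rejected(self, tmp_path):
        import json
        X, centroids, labels = blobs(seed=12)
        path = save_model(train_qc(X, centroids, labels), tmp_path / "m.json")
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelPersistenceError, match="version"):
            load_model(path)

    def test_ga_model_validates_k(self):
        with pytest.raises(ValueError, match="odd"):
            ClassifierModel(kind="GA", selected_peaks=[1000.0],
                            decision_data={"k": 2}, scaling={})
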