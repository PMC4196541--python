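"""LDA training, LooCV window selection and class-pair auto-selection."""

from itertools import combinations

import numpy as np
import pytest

from adaptbci.calibration import (
    CalibrationDeferred,
    analysis_window,
    auto_select_classes,
    auto_select_classes_features,
    calibrate,
    calibrate_features,
    train_lda,
)
from adaptbci.features import DEFAULT_BANDS, FeatureTimecourse, log_bandpower_features
from adaptbci.montage import derive_epochs, parse_derivation
from adaptbci.preprocessing import TrialTiming
from adaptbci.synthetic import GeneratorSpec, generate_session

from conftest import small_spec

TIMING = TrialTiming()


class TestTrainLDA:
    def test_1d_symmetric_boundary_at_zero(self):
        X = np.array([[-1.2], [-0.8], [0.8], [1.2]])
        y = np.array([0, 0, 1, 1])
        w, b = train_lda(X, y)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert w[0] > 0

    def test_duplicating_trials_preserves_sign_pattern(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3)) + np.repeat([[0], [1]], 10, axis=0)
        y = np.repeat([0, 1], 10)
        w1, b1 = train_lda(X, y)
        w2, b2 = train_lda(np.vstack([X, X]), np.concatenate([y, y]))
        s1 = np.sign(X @ w1 + b1)
        s2 = np.sign(X @ w2 + b2)
        np.testing.assert_array_equal(s1, s2)

    def test_agrees_with_sklearn_on_gaussian_fixture(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(12)
        X = np.vstack(
            [rng.normal([0, 0], 1.0, (40, 2)), rng.normal([1.5, 0.5], 1.0, (40, 2))]
        )
        y = np.repeat([0, 1], 40)
        w, b = train_lda(X, y)
        ours = (X @ w + b) > 0
        ref = sklearn.LinearDiscriminantAnalysis(solver="svd").fit(X, y).predict(X)
        np.testing.assert_array_equal(ours.astype(int), ref)

    def test_singular_covariance_is_ridge_stabilized(self):
        X = np.tile([[1.0, 2.0]], (6, 1)) + np.array([[0], [0], [0], [1], [1], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        w, b = train_lda(X, y)  # duplicate columns: pooled covariance singular
        assert np.all(np.isfinite(w)) and np.isfinite(b)

    def test_too_few_trials_defers(self):
        with pytest.raises(CalibrationDeferred):
            train_lda(np.zeros((3, 1)), np.array([0, 1, 1]))


def _noise_features(rng, n_trials, n_feat=5, n_samples=2560, scale=1.0):
    values = rng.normal(scale=scale, size=(n_trials, n_feat, n_samples))
    index = [("D", b) for b in range(n_feat)]
    return FeatureTimecourse(values, index, valid_from=1.0, fs=256.0)


def _separable_features(rng, labels, delta=6.0):
    """One derivation whose band-1 feature separates the two labels."""
    n = len(labels)
    feat = _noise_features(rng, n)
    shift = np.where(np.asarray(labels) == sorted(set(labels))[1], delta, 0.0)
    feat.values[:, 1, :] += shift[:, None]
    return feat


class TestCalibrateFeatures:
    def test_perfectly_separable_reaches_loocv_one(self):
        rng = np.random.default_rng(0)
        labels = np.array(["A", "B"] * 10)
        feat = _separable_features(rng, labels, delta=8.0)
        clf, rep = calibrate_features(feat, labels, ("A", "B"), TIMING)
        assert clf.loocv_median_accuracy == 1.0
        assert clf.selected_features == [("D", 1)]
        assert len(rep.window_accuracies) == 8

    def test_shuffled_labels_near_chance_at_n60(self):
        rng = np.random.default_rng(1)
        labels = np.asarray(rng.permutation(["A", "B"] * 30))
        feat = _noise_features(rng, 60)
        clf, _ = calibrate_features(feat, labels, ("A", "B"), TIMING)
        assert clf.loocv_median_accuracy == pytest.approx(0.5, abs=0.1)

    def test_all_windows_tied_chooses_first(self):
        labels = np.array(["A", "B"] * 6)
        values = np.zeros((12, 5, 2560))
        values[:, 0, :] = np.where(np.asarray(labels) == "B", 5.0, 0.0)[:, None]
        feat = FeatureTimecourse(values, [("D", b) for b in range(5)], 1.0, 256.0)
        clf, rep = calibrate_features(feat, labels, ("A", "B"), TIMING)
        assert rep.chosen_window == 0
        assert clf.train_window == (4.0, 4.5)

    def test_window_constraints(self):
        rng = np.random.default_rng(2)
        labels = np.array(["A", "B"] * 8)
        feat = _separable_features(rng, labels)
        clf, rep = calibrate_features(feat, labels, ("A", "B"), TIMING)
        start, end = clf.train_window
        assert end - start == pytest.approx(0.5)
        assert 4.0 <= start < 8.0
        # chosen window's accuracy is maximal by construction
        assert rep.window_accuracies[rep.chosen_window] == max(rep.window_accuracies)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        labels = np.array(["A", "B"] * 8)
        feat = _separable_features(rng, labels, delta=1.0)
        out1 = calibrate_features(feat, labels, ("A", "B"), TIMING)
        out2 = calibrate_features(feat, labels, ("A", "B"), TIMING)
        np.testing.assert_array_equal(out1[0].weights, out2[0].weights)
        assert out1[0].train_window == out2[0].train_window

    def test_insufficient_class_defers(self):
        rng = np.random.default_rng(6)
        labels = np.array(["A"] * 10 + ["B"])
        with pytest.raises(CalibrationDeferred):
            calibrate_features(_noise_features(rng, 11), labels, ("A", "B"), TIMING)


class TestAutoSelectClasses:
    def _four_class_features(self, rng, n_per_class=8, best=("Hand", "Word"), delta=6.0):
        classes = ["Feet", "Hand", "Math", "Word"]
        labels = np.asarray(classes * n_per_class)
        feat = _noise_features(rng, len(labels))
        # designated pair moves in opposite directions on one feature, so its
        # contrast doubles that of every other pair
        feat.values[:, 2, :] += np.where(
            labels == best[0], delta, np.where(labels == best[1], -delta, 0.0)
        )[:, None]
        return feat, labels, classes

    def test_evaluates_exactly_six_pairs(self):
        rng = np.random.default_rng(0)
        feat, labels, classes = self._four_class_features(rng)
        _, _, rep = auto_select_classes_features(feat, labels, classes, TIMING)
        assert len(rep.per_pair) == 6

    def test_designated_pair_wins(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            feat, labels, classes = self._four_class_features(rng)
            pair, clf, _ = auto_select_classes_features(feat, labels, classes, TIMING)
            assert pair == ("Hand", "Word")
            assert clf.loocv_median_accuracy == 1.0

    def test_matches_external_calibrate_and_sort_oracle(self):
        rng = np.random.default_rng(7)
        feat, labels, classes = self._four_class_features(rng, delta=1.2)
        pair, clf, _ = auto_select_classes_features(feat, labels, classes, TIMING)
        best = None
        for p in combinations(sorted(classes), 2):
            c, _ = calibrate_features(feat, labels, p, TIMING)
            key = (c.loocv_median_accuracy, c.best_feature_fisher)
            if best is None or key > best[0]:
                best = (key, p)
        assert pair == best[1]

    def test_accuracy_tie_broken_by_fisher(self):
        # two perfectly separable pairs; one with twice the feature contrast
        classes = ["A", "B", "C", "D"]
        labels = np.asarray(classes * 6)
        values = np.zeros((24, 5, 2560))
        values[:, 0, :] += np.where(labels == "A", 4.0, 0.0)[:, None]
        values[:, 1, :] += np.where(
            labels == "C", 8.0, np.where(labels == "D", -8.0, 0.0)
        )[:, None]
        noise = np.random.default_rng(8).normal(scale=0.05, size=values.shape)
        feat = FeatureTimecourse(values + noise, [("D", b) for b in range(5)], 1.0, 256.0)
        pair, clf, rep = auto_select_classes_features(feat, labels, classes, TIMING)
        accs = {k: v["loocv_median_accuracy"] for k, v in rep.per_pair.items()}
        assert accs["A|B"] == accs["C|D"] == 1.0
        assert pair == ("C", "D")


class TestSessionLevelAPI:
    def test_calibrate_on_synthetic_session(self, small_grid):
        session, _ = generate_session(small_spec(seed=30))
        derivs = [parse_derivation(small_grid, "FCz-CPz"),
                  parse_derivation(small_grid, "P1-P2")]
        clf, rep = calibrate(session, derivs, DEFAULT_BANDS)
        assert clf.class_pair == ("Hand", "Word")
        assert clf.loocv_median_accuracy > 0.9
        assert len(clf.weights) == 2  # one selected feature per derivation

    def test_auto_select_on_four_class_session(self, small_grid):
        spec = small_spec(
            seed=31,
            classes=("Feet", "Hand", "Word", "Math"),
            runs=2,
            trials_per_class_per_run=4,
            effect_matrix={
                ("Hand", "FCz", 1): -0.85,
                ("Word", "P1", 3): -0.8,
                ("Feet", "FCz", 1): -0.4,
                ("Math", "P1", 3): -0.35,
            },
        )
        session, truth = generate_session(spec)
        derivs = [parse_derivation(small_grid, "FCz-CPz"),
                  parse_derivation(small_grid, "P1-P2")]
        pair, clf, rep = auto_select_classes(session, derivs, DEFAULT_BANDS)
        assert truth.designed_best_pair == ("Hand", "Word")
        assert pair == ("Hand", "Word")
        assert rep.chosen_pair == pair
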