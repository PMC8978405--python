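import numpy as np
import pytest

from dtlink import (
    ClassifierSpec,
    LinkFeatureSet,
    f_beta,
    grid_search,
    make_cv_split,
    precision_recall,
    ranking_metrics,
    run_cv,
    train_classifier,
)

from oracles import aupr_stepwise, auc_pair_counting, confusion_precision_recall


def _separable(n=100, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 2.0, -2.0)
    return X, y


class TestTrainClassifier:
    def test_separable_data_fits_perfectly(self):
        X, y = _separable()
        model = train_classifier(X, y, ClassifierSpec(n_estimators=50, seed=0))
        assert ((model.predict_proba(X) >= 0.5).astype(int) == y).all()

    def test_deterministic_under_seed(self):
        X, y = _separable(seed=1)
        spec = ClassifierSpec(n_estimators=50, seed=7)
        p1 = train_classifier(X, y, spec).predict_proba(X)
        p2 = train_classifier(X, y, spec).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(X, np.ones(10), ClassifierSpec())

    def test_wrong_feature_dimension_rejected(self):
        X, y = _separable()
        model = train_classifier(X, y, ClassifierSpec(n_estimators=10))
        with pytest.raises(ValueError, match="2-column"):
            model.predict_proba(np.zeros((3, 5)))

    def test_label_shuffle_gives_chance_auc(self):
        """Mean held-out AUC over 20 label shuffles sits at chance level."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((200, 10))
        y = np.array([0, 1] * 100)
        aucs = []
        for rep in range(20):
            y_shuf = rng.permutation(y)
            model = train_classifier(
                X[:150], y_shuf[:150], ClassifierSpec(n_estimators=30, seed=rep)
            )
            auc, _ = ranking_metrics(y_shuf[150:], model.predict_proba(X[150:]))
            aucs.append(auc)
        assert 0.4 <= np.mean(aucs) <= 0.6


class TestThresholdMetrics:
    def test_perfect_scores(self):
        assert precision_recall([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]) == (1.0, 1.0)

    def test_hand_confusion_matrix(self):
        # TP=2, FP=1, FN=1 -> P=2/3, R=2/3
        p, r = precision_recall([1, 1, 1, 0], [0.9, 0.8, 0.1, 0.7])
        assert (p, r) == (pytest.approx(2 / 3), pytest.approx(2 / 3))

    def test_no_positive_predictions_convention(self):
        assert precision_recall([1, 0], [0.1, 0.2]) == (0.0, 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            precision_recall([1, 0], [0.5])

    def test_fbeta_equals_p_when_p_equals_r(self):
        for beta in (0.5, 1, 2):
            assert f_beta(0.9, 0.9, beta) == pytest.approx(0.9)

    def test_fbeta_zero_precision(self):
        assert f_beta(0.0, 1.0, 2) == 0.0
        assert f_beta(0.0, 0.0, 1) == 0.0

    def test_f2_weights_recall_higher(self):
        # recall-heavy operating point: f2 close to recall, f1 in between
        p, r = 0.8813, 0.9263
        f2 = f_beta(p, r, 2)
        assert f2 == pytest.approx(0.917, abs=5e-4)
        assert f_beta(p, r, 1) < f2 < r

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            f_beta(0.5, 0.5, 0)


class TestRankingMetrics:
    def test_perfect_separation(self):
        auc, aupr = ranking_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert (auc, aupr) == (1.0, 1.0)

    def test_reversed_scores(self):
        auc, _ = ranking_metrics([0, 0, 1, 1], [0.9, 0.8, 0.2, 0.1])
        assert auc == 0.0

    def test_six_point_toy_vs_pair_counting(self):
        y = [1, 0, 1, 1, 0, 0]
        s = [0.9, 0.8, 0.7, 0.4, 0.4, 0.2]
        auc, _ = ranking_metrics(y, s)
        assert auc == pytest.approx(auc_pair_counting(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ranking_metrics([1, 1], [0.5, 0.6])


def test_metrics_agree_with_oracles_on_random_instances():
    """Precision/recall, AUC and AUPR match independent brute-force oracles
    on hundreds of random small score vectors (with ties)."""
    rng = np.random.default_rng(11)
    for _ in range(500):
        n = int(rng.integers(4, 25))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        s = np.round(rng.random(n), 1)  # coarse grid forces ties
        p, r = precision_recall(y, s)
        po, ro = confusion_precision_recall(y, s)
        assert (p, r) == (pytest.approx(po), pytest.approx(ro))
        auc, aupr = ranking_metrics(y, s)
        assert auc == pytest.approx(auc_pair_counting(y, s))
        assert aupr == pytest.approx(aupr_stepwise(y, s))


def test_metrics_invariant_to_joint_permutation():
    rng = np.random.default_rng(12)
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    s = rng.random(50)
    perm = rng.permutation(50)
    assert ranking_metrics(y, s) == ranking_metrics(y[perm], s[perm])
    assert precision_recall(y, s) == precision_recall(y[perm], s[perm])


def _xor_feature_set(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, (n, 2)).astype(float)
    y = (X[:, 0] != X[:, 1]).astype(int)
    X += rng.normal(0, 0.05, X.shape)
    pairs = [(f"d{i}", f"t{i}") for i in range(n)]
    return LinkFeatureSet(pairs=pairs, features=X, labels=y)


def _simple_folds(n, k=2):
    idx = np.arange(n)
    return [(idx[idx % k != f], idx[idx % k == f]) for f in range(k)]


class TestGridSearch:
    def test_singleton_grid_returned(self):
        fs = _xor_feature_set()
        spec = ClassifierSpec(n_estimators=20, grid={"max_depth": [3]})
        best, table, _ = grid_search(fs, spec, _simple_folds(len(fs.labels)), beta=1.0, seed=0)
        assert best.max_depth == 3
        assert len(table) == 1

    def test_xor_needs_depth(self):
        """Depth-1 stumps cannot represent XOR; the deeper candidate wins."""
        fs = _xor_feature_set()
        spec = ClassifierSpec(n_estimators=30, grid={"max_depth": [1, 3]})
        best, table, _ = grid_search(fs, spec, _simple_folds(len(fs.labels)), beta=1.0, seed=0)
        assert best.max_depth == 3
        assert len(table) == 2

    def test_candidate_order_irrelevant(self):
        fs = _xor_feature_set()
        g1 = {"max_depth": [1, 3], "learning_rate": [0.1, 0.3]}
        g2 = {"learning_rate": [0.3, 0.1], "max_depth": [3, 1]}
        folds = _simple_folds(len(fs.labels))
        b1, _, _ = grid_search(fs, ClassifierSpec(n_estimators=20, grid=g1), folds, 1.0, 0)
        b2, _, _ = grid_search(fs, ClassifierSpec(n_estimators=20, grid=g2), folds, 1.0, 0)
        assert (b1.max_depth, b1.learning_rate) == (b2.max_depth, b2.learning_rate)


class TestRunCv:
    def _feature_set(self, signal=True, n=240, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        if signal:
            X = rng.standard_normal((n, 4)) + y[:, None] * 1.5
        else:
            X = np.ones((n, 4))
        pairs = [(f"d{i}", f"t{i}") for i in range(n)]
        return LinkFeatureSet(pairs=pairs, features=X, labels=y)

    def test_bookkeeping_row_counts(self):
        fs = self._feature_set()
        split = make_cv_split(fs.labels, folds=5, repeats=3, seed=0)
        report, model = run_cv(fs, split, ClassifierSpec(n_estimators=30), seed=0)
        assert len(report.internal) == 15
        assert len(report.external) == 3
        assert model.n_features == 4

    def test_signal_recovered(self):
        fs = self._feature_set(signal=True)
        split = make_cv_split(fs.labels, folds=5, repeats=2, seed=1)
        report, _ = run_cv(fs, split, ClassifierSpec(n_estimators=50), seed=1)
        assert report.external["auc"].mean() > 0.85

    def test_constant_features_give_chance_auc(self):
        fs = self._feature_set(signal=False)
        split = make_cv_split(fs.labels, folds=5, repeats=1, seed=2)
        report, _ = run_cv(fs, split, ClassifierSpec(n_estimators=10), seed=2)
        assert report.external["auc"].mean() == pytest.approx(0.5)

    def test_beta_follows_provenance(self):
        fs = self._feature_set()
        fs.provenance = "sampled-unknown-negative"
        split = make_cv_split(fs.labels, folds=5, repeats=1, seed=3)
        report, _ = run_cv(fs, split, ClassifierSpec(n_estimators=10), seed=3)
        assert report.beta == 2.0
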