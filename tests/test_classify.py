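import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervitex.classify import (
    METRIC_COLUMNS,
    ConfusionCounts,
    compute_metrics,
    cross_validate,
    results_frame,
    run_experiment,
    stratified_folds,
)
from cervitex.exceptions import (
    DegenerateLabelError,
    ParameterError,
    StratificationError,
)
from cervitex.fusion import extract_features
from cervitex.models import CLASSIFIER_NAMES, train_classifier
from cervitex.synthetic import NORMAL_SPEC, make_texture_dataset


class TestStratifiedFolds:
    def test_exact_divisibility_gives_balanced_folds(self):
        labels = np.array(["abnormal"] * 60 + ["normal"] * 40)
        folds = stratified_folds(labels, k=10, seed=0)
        for test_idx in folds:
            assert (labels[test_idx] == "abnormal").sum() == 6
            assert (labels[test_idx] == "normal").sum() == 4

    def test_folds_partition_the_data(self):
        labels = np.array(["abnormal"] * 23 + ["normal"] * 31)
        folds = stratified_folds(labels, k=10, seed=1)
        joined = np.concatenate(folds)
        assert len(joined) == 54
        assert len(np.unique(joined)) == 54

    def test_seed_reproducibility(self):
        labels = np.array(["abnormal"] * 20 + ["normal"] * 20)
        a = stratified_folds(labels, k=10, seed=5)
        b = stratified_folds(labels, k=10, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_small_class_rejected(self):
        labels = np.array(["abnormal"] * 5 + ["normal"] * 50)
        with pytest.raises(StratificationError, match="abnormal"):
            stratified_folds(labels, k=10)


class TestComputeMetrics:
    def test_hand_derived_toy_counts(self):
        m = compute_metrics(ConfusionCounts(tp=50, tn=30, fp=10, fn=10))
        assert m.accuracy == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(50 / 60)
        assert m.specificity == pytest.approx(0.75)
        assert m.precision == pytest.approx(50 / 60)
        assert m.f1 == pytest.approx(50 / 60)

    def test_perfect_hard_classifier(self):
        truth = np.array([1, 1, 0, 0])
        m = compute_metrics(
            ConfusionCounts(tp=2, tn=2, fp=0, fn=0), probs=truth.astype(float),
            truth=truth,
        )
        for v in (m.accuracy, m.sensitivity, m.specificity, m.precision, m.f1):
            assert v == pytest.approx(1.0)
        assert m.mae == pytest.approx(0.0)

    def test_zero_denominator_flagged_not_raised(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert m.precision == 0.0
        assert "precision" in m.degenerate

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 100), tn=st.integers(0, 100),
        fp=st.integers(0, 100), fn=st.integers(0, 100),
    )
    def test_identities_on_random_counts(self, tp, tn, fp, fn):
        """sensitivity == recall always; F1 between precision and recall."""
        if tp + tn + fp + fn == 0:
            return
        m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert m.sensitivity == m.recall
        if "f1" not in m.degenerate:
            assert min(m.precision, m.recall) - 1e-12 <= m.f1
            assert m.f1 <= max(m.precision, m.recall) + 1e-12

    def test_relabeling_swaps_sensitivity_and_specificity(self):
        a = compute_metrics(ConfusionCounts(tp=40, tn=25, fp=15, fn=20))
        b = compute_metrics(ConfusionCounts(tp=25, tn=40, fp=20, fn=15))
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)


class TestTrainClassifier:
    def test_unknown_name_rejected(self, rng):
        with pytest.raises(ParameterError):
            train_classifier("svm", rng.random((10, 2)), [0, 1] * 5)

    def test_single_class_rejected(self, rng):
        with pytest.raises(DegenerateLabelError):
            train_classifier("logistic", rng.random((10, 2)), [1] * 10)

    def test_logistic_separable_data(self, rng):
        X = np.vstack([rng.normal(-3, 0.1, (20, 2)), rng.normal(3, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        model = train_classifier("logistic", X, y)
        assert (model.predict(X) == y).all()

    def test_gaussian_nb_approaches_bayes_rate(self, rng):
        """Two unit-variance Gaussians at means +/-3: Bayes accuracy is
        Phi(3) ~ 0.9987, so test accuracy should exceed 0.95 at n=500."""
        n = 500
        X = np.concatenate([rng.normal(-3, 1, n // 2), rng.normal(3, 1, n // 2)])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        model = train_classifier("naive_bayes", X[:, None], y)
        Xt = np.concatenate([rng.normal(-3, 1, 250), rng.normal(3, 1, 250)])
        yt = np.array([0] * 250 + [1] * 250)
        assert (model.predict(Xt[:, None]) == yt).mean() > 0.95

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_seeded_determinism_and_probability_output(self, rng, name):
        X = rng.random((60, 5))
        y = (X[:, 0] + 0.3 * rng.random(60) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            y[:5] = 1 - y[:5]
        a = train_classifier(name, X, y, seed=3)
        b = train_classifier(name, X, y, seed=3)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))
        proba = a.predict_proba(X)
        assert proba.shape == (60, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)


@pytest.fixture(scope="module")
def small_tables():
    data = make_texture_dataset(n_per_class=15, seed=42)
    return extract_features(data)


class TestCrossValidation:
    def test_pooled_counts_sum_to_dataset_size(self, small_tables):
        res = cross_validate(small_tables, "naive_bayes", "glrlm", k_folds=10, seed=0)
        assert res.pooled_counts.total == len(small_tables)
        assert len(res.fold_metrics) == 10

    def test_results_grid_layout(self, small_tables):
        results = run_experiment(
            small_tables,
            classifiers=("naive_bayes", "logistic"),
            feature_sets=("glrlm", "hybrid"),
            k_folds=10,
            seed=0,
        )
        assert len(results) == 4
        grids = results_frame(results)
        for frame in grids.values():
            assert tuple(frame.columns) == METRIC_COLUMNS
            assert frame.shape == (2, 7)

    def test_shuffled_labels_give_chance_accuracy(self, small_tables):
        """With labels randomly permuted the pooled accuracy must sit within
        3 binomial standard deviations of 0.5."""
        import dataclasses

        rng = np.random.default_rng(4)
        shuffled = dataclasses.replace(
            small_tables, labels=rng.permutation(small_tables.labels)
        )
        res = cross_validate(shuffled, "random_forest", "glcm", k_folds=10, seed=0)
        n = len(shuffled)
        assert abs(res.pooled.accuracy - 0.5) <= 3 * np.sqrt(0.25 / n)
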