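"""Splitting, MLP training mechanics, SOM dynamics and sensitivity analysis."""

import numpy as np
import pytest

from cartspec.neural import (
    MLP,
    MLPConfig,
    SOM,
    SOMConfig,
    SplitConfig,
    classify,
    confusion_table,
    gain_curve,
    map_clusters,
    one_hot,
    quantization_error,
    recognition_rate,
    sensitivity,
    split_data,
    train_mlp,
)


def _six_class_labels(per_class=75):
    return np.repeat([f"class{i}" for i in range(6)], per_class)


class TestSplit:
    def test_default_ratio_sizes_on_450_rows(self):
        split = split_data(_six_class_labels(), SplitConfig(seed=0))
        assert (split.train.size, split.test.size, split.validation.size) == (321, 64, 65)

    def test_partition_disjoint_and_exhaustive(self):
        labels = _six_class_labels()
        split = split_data(labels, SplitConfig(seed=3))
        allidx = np.concatenate(list(split))
        assert np.array_equal(np.sort(allidx), np.arange(labels.size))

    def test_stratification_within_one_case(self):
        labels = _six_class_labels()
        split = split_data(labels, SplitConfig(seed=5))
        for part, target in zip(split, (321, 64, 65)):
            counts = np.unique(labels[part], return_counts=True)[1]
            ideal = 75 * target / 450
            assert np.all(np.abs(counts - ideal) <= 1.0)

    def test_all_rows_to_train_when_ratio_degenerate(self):
        split = split_data(_six_class_labels(), SplitConfig(ratios=(1.0, 0.0, 0.0), seed=1))
        assert split.train.size == 450
        assert split.test.size == 0 and split.validation.size == 0

    def test_same_seed_same_partition(self):
        labels = _six_class_labels()
        a = split_data(labels, SplitConfig(seed=7))
        b = split_data(labels, SplitConfig(seed=7))
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_class_smaller_than_partitions_rejected(self):
        labels = np.array(["a", "a", "b", "b", "b", "b"])
        with pytest.raises(ValueError):
            split_data(labels, SplitConfig(seed=0))


def _toy_data(n=60, seed=0):
    """Two linearly separable 2-class clouds in 4-D."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal(-2.0, 0.4, size=(n // 2, 4))
    x1 = rng.normal(2.0, 0.4, size=(n // 2, 4))
    X = np.vstack([x0, x1])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestMLP:
    def test_gradient_matches_finite_differences(self):
        """Analytic backprop vs central differences on a 4-3-2 toy net."""
        rng = np.random.default_rng(1)
        cfg = MLPConfig(n_inputs=4, n_hidden=3, n_outputs=2, seed=1)
        model = MLP(cfg)
        X = rng.normal(size=(7, 4))
        D = one_hot(rng.integers(0, 2, size=7), 2)
        theta = model._init_params() + rng.normal(0, 0.1, size=model._init_params().size)
        _, grad = model.loss_and_grad(theta, X, D)
        eps = 1e-6
        num = np.empty_like(theta)
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num[i] = (model.loss_and_grad(tp, X, D)[0] - model.loss_and_grad(tm, X, D)[0]) / (2 * eps)
        assert np.max(np.abs(grad - num)) < 1e-6

    def test_softmax_outputs_sum_to_one(self):
        X, y = _toy_data()
        cfg = MLPConfig(n_inputs=4, n_hidden=3, n_outputs=2, epochs=20, seed=0)
        model = MLP(cfg)
        model.fit(X, y)
        proba = model.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_training_loss_decreases_on_separable_data(self, seed):
        X, y = _toy_data(seed=seed)
        cfg = MLPConfig(n_inputs=4, n_hidden=4, n_outputs=2, epochs=60, seed=seed)
        model = MLP(cfg)
        history = model.fit(X, y)
        assert history[-1] < history[0]
        proba = model.predict_proba(X)
        assert recognition_rate(proba, y) == 1.0

    def test_momentum_trainer_also_learns(self):
        X, y = _toy_data(seed=2)
        cfg = MLPConfig(
            n_inputs=4, n_hidden=4, n_outputs=2, optimizer="momentum",
            epochs=300, learning_rate=0.01, momentum=0.80, seed=2,
        )
        history = MLP(cfg).fit(X, y)
        assert history[-1] < history[0]

    def test_missing_class_rejected(self):
        X, y = _toy_data()
        with pytest.raises(ValueError):
            MLP(MLPConfig(n_inputs=4, n_hidden=3, n_outputs=3, seed=0)).fit(X, y)


class TestThresholds:
    def test_confident_output_assigned(self):
        p = np.array([[0.99, 0.002, 0.002, 0.002, 0.002, 0.002]])
        assert classify(p)[0] == 0

    def test_ambiguous_output_undecided(self):
        p = np.array([[0.6, 0.4, 0.0, 0.0, 0.0, 0.0]])
        assert classify(p)[0] == -1

    def test_paper_range_activations_decided(self):
        p = np.array([[0.97, 0.03 / 5, 0.03 / 5, 0.03 / 5, 0.03 / 5, 0.03 / 5]])
        assert classify(p)[0] == 0

    def test_undecided_counts_as_incorrect(self):
        p = np.array([[0.6, 0.4], [0.99, 0.01]])
        assert recognition_rate(p, np.array([0, 0])) == 0.5

    def test_confusion_rows_sum_to_class_counts(self):
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(3), size=30)
        y = rng.integers(0, 3, size=30)
        table = confusion_table(p, y, ["a", "b", "c"])
        counts = np.bincount(y, minlength=3)
        assert np.array_equal(table.sum(axis=1).to_numpy(), counts)


class TestGainCurve:
    def test_perfect_classifier_captures_class_early(self):
        y = np.repeat(np.arange(6), 10)
        proba = one_hot(y, 6) * 0.98 + 0.001
        curve = gain_curve(proba, y, target_class=2)
        idx = np.searchsorted(curve["fraction_cases"], 1.0 / 6.0 + 1e-9)
        assert curve["fraction_captured"].iloc[idx - 1] == pytest.approx(1.0)

    def test_random_scores_near_diagonal(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=4000)
        proba = rng.dirichlet(np.ones(2), size=4000)
        curve = gain_curve(proba, y, 0)
        gap = np.abs(curve["fraction_captured"] - curve["baseline"])
        assert gap.max() < 0.06

    def test_monotone_and_ends_at_one(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 3, size=200)
        proba = rng.dirichlet(np.ones(3), size=200)
        curve = gain_curve(proba, y, 1)
        assert np.all(np.diff(curve["fraction_captured"]) >= 0)
        assert curve["fraction_captured"].iloc[-1] == pytest.approx(1.0)

    def test_absent_class_rejected(self):
        with pytest.raises(ValueError):
            gain_curve(np.array([[1.0, 0.0]]), np.array([0]), target_class=1)


class TestSOM:
    def test_capacity_case_quantization_error_vanishes(self):
        """25 inputs arranged like the 5x5 map itself: after long training
        every input ends up with its own matching unit and QE ~ 0."""
        yy, xx = np.meshgrid(np.arange(5.0), np.arange(5.0), indexing="ij")
        X = np.column_stack([yy.ravel(), xx.ravel()]) * 2.0
        som = SOM(SOMConfig(epochs=2000, seed=0)).fit(X)
        assert quantization_error(som, X) < 0.01

    def test_radius_zero_updates_only_the_winners(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(2, 5))
        cfg = SOMConfig(epochs=1, radius_start=0.0, radius_end=0.0, alpha_start=0.5, alpha_end=0.5, seed=1)
        som = SOM(cfg)
        # replicate the seeded initialization, then one winner-takes-all pass
        init_rng = np.random.default_rng(cfg.seed)
        lo, hi = X.min(axis=0), X.max(axis=0)
        W0 = init_rng.uniform(lo, hi, size=(som.n_neurons, X.shape[1]))
        som.fit(X)
        changed = np.flatnonzero(np.any(som.weights != W0, axis=1))
        assert 1 <= changed.size <= 2  # only the winning units moved

    def test_single_input_attracts_all_weights(self):
        x = np.array([[1.0, -2.0, 0.5]])
        som = SOM(SOMConfig(epochs=600, seed=2)).fit(np.repeat(x, 4, axis=0))
        assert np.max(np.abs(som.weights - x)) < 0.05

    def test_training_reduces_quantization_error(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 8))
        for seed in range(5):
            cfg = SOMConfig(epochs=150, seed=seed)
            som = SOM(cfg)
            init_rng = np.random.default_rng(seed)
            lo, hi = X.min(axis=0), X.max(axis=0)
            W0 = init_rng.uniform(lo, hi, size=(som.n_neurons, X.shape[1]))
            untrained = SOM(cfg)
            untrained.weights = W0
            som.fit(X)
            assert quantization_error(som, X) < quantization_error(untrained, X)

    def test_weights_converge_when_schedules_decay_to_zero(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 4))
        cfg = SOMConfig(epochs=300, alpha_end=1e-9, radius_end=0.0, seed=4)
        som = SOM(cfg).fit(X)
        assert som.final_max_update_ < 1e-6

    def test_quantization_error_centroid_case(self):
        """One neuron at the data centroid of unit-variance 1-D data gives
        QE = mean |x - xbar| ~ sqrt(2/pi)."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200000, 1))
        som = SOM(SOMConfig(grid_shape=(1, 1), epochs=1, seed=0))
        som.weights = X.mean(axis=0, keepdims=True)
        assert quantization_error(som, X) == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)
        assert quantization_error(som, X) >= 0

    def test_cluster_map_labels_by_majority(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(-5, 0.2, size=(30, 3)), rng.normal(5, 0.2, size=(30, 3))])
        labels = np.repeat(["lo", "hi"], 30)
        som = SOM(SOMConfig(grid_shape=(2, 2), epochs=200, radius_start=1.0, seed=0)).fit(X)
        cmap = map_clusters(som, X, labels)
        assert cmap.n_clusters == 2
        assert set(cmap.clusters) == {"lo", "hi"}
        # clusters are disjoint by construction: a neuron has one majority label
        assert not (set(cmap.clusters["lo"]) & set(cmap.clusters["hi"]))

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            SOM().fit(np.empty((0, 4)))


class TestSensitivity:
    def _trained_toy(self):
        rng = np.random.default_rng(0)
        n = 80
        informative = np.repeat([-1.0, 1.0], n // 2) + rng.normal(0, 0.1, n)
        constant = np.zeros(n)
        noise = rng.normal(size=n)
        X = np.column_stack([informative, constant + rng.normal(0, 1e-6, n), noise])
        y = np.repeat([0, 1], n // 2)
        cfg = MLPConfig(n_inputs=3, n_hidden=4, n_outputs=2, epochs=80, seed=0)
        model = MLP(cfg)
        model.fit(X, y)
        return model, X, y

    def test_discriminative_variable_ratio_above_one(self):
        model, X, y = self._trained_toy()
        res = sensitivity(model, X, y)
        assert res.ratios[0] > 1.0
        assert res.important[0]

    def test_uninformative_variable_ratio_near_one(self):
        model, X, y = self._trained_toy()
        res = sensitivity(model, X, y)
        assert res.ratios[1] == pytest.approx(1.0, abs=0.05)

    def test_all_ratios_returned_with_ranges(self):
        model, X, y = self._trained_toy()
        res = sensitivity(model, X, y, wavenumbers=np.array([1660.0, 1550.0, 1080.0]))
        assert res.ratios.shape == (3,)
        assert res.count_important == int(res.important.sum())
        for hi, lo in res.ranges:
            assert hi >= lo

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(MLP(MLPConfig(n_inputs=3, n_hidden=2, n_outputs=2)), np.zeros((4, 3)), np.zeros(4, int))
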