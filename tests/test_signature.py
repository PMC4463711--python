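"""Linear SVM, cost grid search, and the leave-one-out signature wrapper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kbdsig import (
    ConfusionTable,
    SimulationConfig,
    evaluate,
    finalize_signature,
    generate_cohort,
    grid_search_c,
    loocv_size_sweep,
    train_svm,
)


def df(X, prefix="g"):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return pd.DataFrame(X, columns=[f"{prefix}{i}" for i in range(X.shape[1])])


class TestTrainSvm:
    def test_symmetric_1d_boundary_at_zero(self):
        X = df([[-1.0], [-1.0], [1.0], [1.0]])
        y = ["control", "control", "case", "case"]
        model = train_svm(X, y, cost_c=1e3)
        assert list(model.predict(X)) == y
        # decision value at the midpoint of the classes is zero
        assert model.decision_values(df([[0.0]]))[0] == pytest.approx(0.0, abs=1e-6)

    def test_separable_cohort_perfect_training_accuracy(self):
        cfg = SimulationConfig(n_pairs=20, n_genes=10, log_ratio_sd=0.1, sample_sd=0.2,
                               planted_effects=tuple((g, 4.0) for g in range(5)), seed=3)
        cohort = generate_cohort(cfg)
        model = train_svm(cohort.sample_expression, cohort.labels.to_numpy())
        acc = np.mean(model.predict(cohort.sample_expression) == cohort.labels.to_numpy())
        assert acc == 1.0

    def test_primal_objective_beats_random_candidates(self, rng):
        """The fitted (w, b) must have a hinge primal objective no worse than
        1000 random candidates on the standardized features."""
        X = rng.normal(0, 1, size=(30, 2))
        y = (X[:, 0] + 0.5 * rng.normal(size=30) > 0).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        C = 1.0
        model = train_svm(df(X), y, cost_c=C)
        Xs = (X - model.center) / model.scale
        ypm = np.where(np.asarray(y) == model.positive_label, 1.0, -1.0)

        def objective(w, b):
            margins = ypm * (Xs @ w + b)
            return 0.5 * w @ w + C * np.sum(np.maximum(0.0, 1.0 - margins))

        fitted = objective(model.weights, model.bias)
        for _ in range(1000):
            w = rng.normal(0, 2, size=2)
            b = rng.normal(0, 2)
            assert fitted <= objective(w, b) + 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            train_svm(df([[0.0], [1.0]]), ["case", "case"])

    def test_missing_model_gene_in_test_data_raises(self):
        model = train_svm(df([[0.0, 1.0], [1.0, 0.0]]), ["case", "control"])
        bad = pd.DataFrame({"g0": [1.0]})
        with pytest.raises(KeyError, match="g1"):
            model.predict(bad)


class TestGridSearch:
    def _data(self):
        cfg = SimulationConfig(n_pairs=10, n_genes=6, log_ratio_sd=0.1, sample_sd=0.2,
                               planted_effects=((0, 4.0), (1, 0.25)), seed=6)
        cohort = generate_cohort(cfg)
        return cohort.sample_expression, cohort.labels.to_numpy()

    def test_single_element_grid_returned(self):
        X, y = self._data()
        assert grid_search_c(X, y, grid=[2.0]) == 2.0

    def test_tie_broken_to_smallest_c(self):
        X, y = self._data()  # separable: all C values give the same accuracy
        assert grid_search_c(X, y, grid=[0.5, 1.0, 2.0], seed=1) == 0.5

    def test_empty_grid_rejected(self):
        X, y = self._data()
        with pytest.raises(ValueError, match="grid"):
            grid_search_c(X, y, grid=[])

    def test_deterministic_under_seed(self, rng):
        X = df(rng.normal(size=(40, 4)))
        y = rng.integers(0, 2, size=40)
        a = grid_search_c(X, y, grid=[0.1, 1.0, 10.0], seed=9)
        b = grid_search_c(X, y, grid=[0.1, 1.0, 10.0], seed=9)
        assert a == b


class TestEvaluate:
    def test_published_test_split_metrics(self):
        ct = ConfusionTable(tp=17, fn=3, tn=19, fp=1)
        assert ct.accuracy == pytest.approx(0.90)
        assert ct.sensitivity == pytest.approx(0.85)
        assert ct.specificity == pytest.approx(0.95)

    def test_all_correct(self):
        X = df([[-1.0], [1.0]])
        y = ["control", "case"]
        model = train_svm(X, y, cost_c=10.0)
        ct = evaluate(model, X, y)
        assert ct.accuracy == 1.0

    def test_inverted_predictions_complement_sensitivity_specificity(self, rng):
        for _ in range(20):
            y_true = rng.integers(0, 2, size=50)
            y_pred = rng.integers(0, 2, size=50)
            ct = ConfusionTable.from_predictions(y_true, y_pred, positive=1)
            inv = ConfusionTable.from_predictions(y_true, 1 - y_pred, positive=1)
            if ct.tp + ct.fn and ct.tn + ct.fp:
                assert inv.sensitivity == pytest.approx(1 - ct.sensitivity)
                assert inv.specificity == pytest.approx(1 - ct.specificity)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_confusion_identities(self, tp, fn, tn, fp):
        if tp + fn + tn + fp == 0:
            return
        ct = ConfusionTable(tp=tp, fn=fn, tn=tn, fp=fp)
        assert ct.accuracy == pytest.approx((tp + tn) / (tp + fn + tn + fp))
        if tp + fn:
            assert ct.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert ct.specificity == pytest.approx(tn / (tn + fp))


class TestLoocvSweep:
    def test_models_built_is_samples_times_nmax(self):
        cfg = SimulationConfig(n_pairs=6, n_genes=12, planted_effects=((0, 4.0), (1, 0.25)),
                               log_ratio_sd=0.1, sample_sd=0.3, seed=4)
        cohort = generate_cohort(cfg)
        curve = loocv_size_sweep(cohort.sample_expression, cohort.labels.to_numpy(), n_max=4)
        assert curve.models_built == 12 * 4
        assert set(curve.accuracy_by_n) == {1, 2, 3, 4}
        assert len(curve.per_fold_selections) == 12

    def test_strong_signal_perfect_accuracy(self):
        cfg = SimulationConfig(n_pairs=15, n_genes=30, log_ratio_sd=0.2, sample_sd=0.3,
                               planted_effects=tuple((g, 5.0) for g in range(10)), seed=5)
        cohort = generate_cohort(cfg)
        curve = loocv_size_sweep(cohort.sample_expression, cohort.labels.to_numpy(), n_max=10)
        assert curve.accuracy_by_n[10] == 1.0

    def test_permuted_labels_accuracy_near_half(self):
        cfg = SimulationConfig(n_pairs=20, n_genes=25, seed=10,
                               planted_effects=tuple((g, 3.0) for g in range(8)))
        cohort = generate_cohort(cfg)
        rng = np.random.default_rng(0)
        y = rng.permutation(cohort.labels.to_numpy())
        n = len(y)
        curve = loocv_size_sweep(cohort.sample_expression, y, n_max=5)
        tol = 3 * np.sqrt(0.25 / n)
        for acc in curve.accuracy_by_n.values():
            assert abs(acc - 0.5) <= tol

    def test_selection_never_sees_held_out_sample(self, rng):
        """Leakage guard: with pure-noise features, honest per-fold selection
        stays at chance while a deliberately leaky wrapper (features chosen on
        the full data including the held-out sample) inflates accuracy."""
        n, g, k = 40, 300, 5
        X = pd.DataFrame(rng.normal(size=(n, g)), columns=[f"g{i}" for i in range(g)])
        y = np.array(["case", "control"] * (n // 2))
        curve = loocv_size_sweep(X, y, n_max=k)
        honest = curve.accuracy_by_n[k]
        assert abs(honest - 0.5) <= 3 * np.sqrt(0.25 / n)

        # leaky reference: pick top-k |t| genes once, on ALL samples
        from scipy import stats as sps
        case = X[y == "case"].to_numpy()
        ctrl = X[y == "control"].to_numpy()
        t = np.abs(sps.ttest_ind(case, ctrl, axis=0).statistic)
        feats = list(X.columns[np.argsort(-t)[:k]])
        correct = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = train_svm(X.iloc[mask][feats], y[mask])
            correct += model.predict(X.iloc[[i]][feats])[0] == y[i]
        leaky = correct / n
        assert leaky > honest  # selection bias must show up only in the leaky wrapper
        assert leaky > 0.5 + 2 * np.sqrt(0.25 / n)


class TestFinalize:
    def test_recovers_planted_signature(self):
        """20 strong planted genes among 50: the final 20-gene signature must
        recover at least 18 of them."""
        planted = tuple((g, 4.0 if g % 2 else 0.25) for g in range(20))
        cfg = SimulationConfig(n_pairs=40, n_genes=50, log_ratio_sd=0.2, sample_sd=0.4,
                               planted_effects=planted, seed=14)
        cohort = generate_cohort(cfg)
        genes, model = finalize_signature(
            cohort.sample_expression, cohort.labels.to_numpy(), n=20)
        planted_names = {cohort.truth.index[g] for g, _ in planted}
        assert len(set(genes) & planted_names) >= 18

    def test_signature_equals_pool_when_n_is_pool_size(self):
        cfg = SimulationConfig(n_pairs=10, n_genes=5, planted_effects=((0, 4.0),),
                               log_ratio_sd=0.1, seed=2)
        cohort = generate_cohort(cfg)
        genes, _ = finalize_signature(cohort.sample_expression, cohort.labels.to_numpy(),
                                      n=5, de_first=False, c_grid=None)
        assert sorted(genes) == sorted(cohort.sample_expression.columns)

    def test_deterministic(self):
        cfg = SimulationConfig(n_pairs=12, n_genes=15, planted_effects=((0, 3.0), (1, 0.3)),
                               seed=8)
        cohort = generate_cohort(cfg)
        X, y = cohort.sample_expression, cohort.labels.to_numpy()
        a = finalize_signature(X, y, n=4, seed=1)
        b = finalize_signature(X, y, n=4, seed=1)
        assert a[0] == b[0]
        assert np.allclose(a[1].weights, b[1].weights)
        assert a[1].cost_c == b[1].cost_c
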