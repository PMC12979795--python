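"""Network training, patient-level splitting, hyperparameter search and
posterior-based class calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime
from sklearn.metrics import roc_auc_score

from mptexture import classify
from mptexture.classify import (
    Candidate,
    SearchSpace,
    TrainConfig,
    TrainingError,
    fit_network,
    fold_standardization,
    make_split,
    tune_hyperparameters,
)
from mptexture.features import fov_feature_names


def blobs(n_per_class, separation, rng, dim=2):
    """Two Gaussian blobs with the given separation in units of their sd."""
    X = np.vstack([
        rng.standard_normal((n_per_class, dim)),
        rng.standard_normal((n_per_class, dim)) + separation / np.sqrt(dim),
    ])
    y = np.repeat([0, 1], n_per_class)
    return X, y


def manifest_frame(patients, border_patients=()):
    rows = []
    for p in patients:
        rows.append({"patient_id": p, "sample": "liver"})
        rows.append({"patient_id": p, "sample": "tumor"})
    for p in border_patients:
        rows.append({"patient_id": p, "sample": "border"})
    return pd.DataFrame(rows)


class TestMakeSplit:
    def test_counts_and_disjointness(self):
        split = make_split(manifest_frame([f"P{i}" for i in range(10)]), 6, seed=0)
        assert len(split.train_patients) == 6 and len(split.test_patients) == 4
        assert not set(split.train_patients) & set(split.test_patients)

    def test_deterministic(self):
        m = manifest_frame([f"P{i}" for i in range(10)])
        assert make_split(m, 5, seed=3) == make_split(m, 5, seed=3)
        assert make_split(m, 5, seed=3) != make_split(m, 5, seed=4)

    def test_border_patients_excluded_from_both_sides(self):
        m = manifest_frame([f"P{i}" for i in range(6)], border_patients=["P1", "P4"])
        split = make_split(m, 2, seed=1)
        members = set(split.train_patients) | set(split.test_patients)
        assert "P1" not in members and "P4" not in members
        assert len(members) == 4

    def test_insufficient_patients_errors(self):
        with pytest.raises(TrainingError):
            make_split(manifest_frame(["P0", "P1"]), 2, seed=0)


class TestFitNetwork:
    def test_separable_blobs_high_training_accuracy(self, rng):
        X, y = blobs(100, separation=6.0, rng=rng)
        model = fit_network(X, y, Candidate(hidden_layers=(10,)), max_epochs=500, seed=0)
        acc = np.mean((model.posterior_tumor(X) > 0.5).astype(int) == y)
        assert acc >= 0.99

    def test_loss_trace_monotone_non_increasing(self, rng):
        X, y = blobs(60, separation=2.0, rng=rng)
        model = fit_network(X, y, Candidate(hidden_layers=(8,)), max_epochs=300, seed=1)
        trace = np.array(model.loss_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-8)

    def test_iteration_cap_flagged(self, rng):
        X, y = blobs(60, separation=1.0, rng=rng)
        model = fit_network(X, y, Candidate(hidden_layers=(8,)), max_epochs=3, seed=0)
        assert model.hit_iteration_cap
        assert len(model.loss_trace) <= 3

    def test_permuted_labels_give_null_auc(self):
        """With labels independent of features, held-out AUC stays in
        [0.4, 0.6] in at least 95% of 50 replicates."""
        in_band = 0
        for rep in range(50):
            rng = np.random.default_rng(1000 + rep)
            X_train = rng.standard_normal((200, 2))
            y_train = rng.permutation(np.repeat([0, 1], 100))
            X_test = rng.standard_normal((2000, 2))
            y_test = np.repeat([0, 1], 1000)
            model = fit_network(X_train, y_train, Candidate(hidden_layers=(5,)), max_epochs=150, seed=rep)
            auc = roc_auc_score(y_test, model.posterior_tumor(X_test))
            in_band += 0.4 <= auc <= 0.6
        assert in_band >= 45

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(TrainingError):
            fit_network(X, np.zeros(10, dtype=int))

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(TrainingError):
            fit_network(X, np.array([0, 1]))

    def test_string_labels_accepted(self, rng):
        X, y = blobs(50, separation=5.0, rng=rng)
        labels = np.where(y == 1, "tumor", "liver")
        model = fit_network(X, labels, Candidate(hidden_layers=(5,)), max_epochs=200, seed=0)
        assert np.mean((model.posterior_tumor(X) > 0.5).astype(int) == y) > 0.95

    def test_deterministic_given_seed(self, rng):
        X, y = blobs(40, separation=2.0, rng=rng)
        a = fit_network(X, y, Candidate(hidden_layers=(6,)), max_epochs=100, seed=5)
        b = fit_network(X, y, Candidate(hidden_layers=(6,)), max_epochs=100, seed=5)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    @pytest.mark.parametrize("activation", ["relu", "tanh", "logistic"])
    def test_analytic_gradient_matches_numeric(self, activation, rng):
        from mptexture.classify import _glorot_init, _loss_and_grad, _pack

        X = rng.standard_normal((12, 3))
        y = rng.integers(0, 2, 12)
        widths = (3, 4, 2)
        weights = _glorot_init(widths, rng)
        biases = [rng.standard_normal(w) * 0.1 for w in widths[1:]]
        theta = _pack(weights, biases)
        args = (X, y, widths, activation, 1e-3)
        _, grad = _loss_and_grad(theta, *args)
        numeric = approx_fprime(theta, lambda t: _loss_and_grad(t, *args)[0], 1e-6)
        assert np.max(np.abs(grad - numeric)) < 1e-4

    def test_posteriors_sum_to_one(self, rng):
        X, y = blobs(30, separation=2.0, rng=rng)
        model = fit_network(X, y, Candidate(hidden_layers=(5,)), max_epochs=100, seed=0)
        from mptexture.classify import _forward

        Xs = (X - model.scaler_mean) / model.scaler_sd
        probs = _forward(Xs, model.weights, model.biases, model.activation)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_folding_standardization_preserves_posteriors(self, rng):
        X, y = blobs(40, separation=3.0, rng=rng)
        X = X * np.array([10.0, 0.1]) + np.array([5.0, -2.0])
        model = fit_network(X, y, Candidate(hidden_layers=(6,)), max_epochs=200, seed=2)
        folded = fold_standardization(model)
        np.testing.assert_allclose(model.posterior_tumor(X), folded.posterior_tumor(X), atol=1e-10)
        assert np.all(folded.scaler_sd == 1.0)

    def test_agrees_with_sklearn_mlp_on_separable_data(self, rng):
        """Independent cross-check: sklearn's lbfgs-trained MLP and this
        implementation both solve the same separable problem."""
        from sklearn.neural_network import MLPClassifier

        X, y = blobs(150, separation=4.0, rng=rng)
        X_test, y_test = blobs(150, separation=4.0, rng=rng)
        ours = fit_network(X, y, Candidate(hidden_layers=(10,)), max_epochs=500, seed=0)
        ref = MLPClassifier(hidden_layer_sizes=(10,), solver="lbfgs", max_iter=500, random_state=0).fit(X, y)
        acc_ours = np.mean((ours.posterior_tumor(X_test) > 0.5).astype(int) == y_test)
        acc_ref = ref.score(X_test, y_test)
        assert acc_ours >= 0.95 and acc_ref >= 0.95


class TestTuneHyperparameters:
    def _data(self, rng, n_patients=10, per_patient=12):
        X, y, patients = [], [], []
        for i in range(n_patients):
            Xi, yi = blobs(per_patient // 2, separation=3.0, rng=rng)
            X.append(Xi)
            y.append(yi)
            patients += [f"P{i}"] * per_patient
        return np.vstack(X), np.concatenate(y), np.array(patients)

    def test_single_candidate_space_returns_it(self, rng):
        X, y, patients = self._data(rng)
        space = SearchSpace(n_layers=(1,), widths=(7,), activations=("tanh",), l2_range=(1e-3, 1e-3))
        config = TrainConfig(max_epochs=50, n_search_steps=2, search_space=space, seed=0)
        best, history = tune_hyperparameters(X, y, patients, config)
        assert best == Candidate(hidden_layers=(7,), activation="tanh", l2=1e-3)

    def test_history_length_equals_n_search_steps(self, rng):
        X, y, patients = self._data(rng)
        config = TrainConfig(max_epochs=50, n_search_steps=5,
                             search_space=SearchSpace(n_layers=(1,), widths=(4, 8)), seed=1)
        _, history = tune_hyperparameters(X, y, patients, config)
        assert len(history) == 5

    def test_best_no_worse_than_first_candidate(self, rng):
        X, y, patients = self._data(rng)
        config = TrainConfig(max_epochs=50, n_search_steps=6,
                             search_space=SearchSpace(n_layers=(1, 2), widths=(4, 8)), seed=2)
        best, history = tune_hyperparameters(X, y, patients, config)
        best_loss = min(loss for _, loss in history)
        assert best_loss <= history[0][1]
        assert any(cand == best and loss == best_loss for cand, loss in history)

    def test_deterministic(self, rng):
        X, y, patients = self._data(rng)
        config = TrainConfig(max_epochs=50, n_search_steps=3, seed=9,
                             search_space=SearchSpace(n_layers=(1,), widths=(4, 8)))
        a = tune_hyperparameters(X, y, patients, config)
        b = tune_hyperparameters(X, y, patients, config)
        assert a[0] == b[0] and [l for _, l in a[1]] == [l for _, l in b[1]]

    def test_empty_space_errors(self, rng):
        X, y, patients = self._data(rng)
        config = TrainConfig(search_space=SearchSpace(widths=()), n_search_steps=1)
        with pytest.raises(TrainingError):
            tune_hyperparameters(X, y, patients, config)


@pytest.fixture(scope="module")
def feature_table():
    """Synthetic 51-column feature table: labels depend on the TPEF and SHG
    columns so every combination is learnable to a different degree."""
    rng = np.random.default_rng(0)
    names = fov_feature_names()
    rows = []
    for i in range(8):
        for sample, label in (("liver", "liver"), ("tumor", "tumor")):
            shift = 0.0 if label == "liver" else 2.0
            for _ in range(10):
                vec = rng.standard_normal(51)
                vec[17:51] += shift  # TPEF and SHG blocks carry the signal
                rows.append({"patient_id": f"P{i}", "sample": sample, "true_label": label,
                             **dict(zip(names, vec))})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def models(feature_table):
    split = make_split(feature_table, 5, seed=0)
    space = SearchSpace(n_layers=(1,), widths=(8,), activations=("relu",), l2_range=(1e-4, 1e-4))
    config = TrainConfig(max_epochs=150, n_search_steps=1, search_space=space, seed=0)
    return classify.train_channel_models(feature_table, split, config)


class TestChannelModels:
    def test_seven_models_trained(self, models):
        assert len(models) == 7
        assert set(models) == {"CARS", "TPEF", "SHG", "CARS-TPEF", "CARS-SHG", "TPEF-SHG", "CARS-TPEF-SHG"}

    @pytest.mark.parametrize(
        "name, width",
        [("CARS", 17), ("TPEF", 17), ("SHG", 17),
         ("CARS-TPEF", 34), ("CARS-SHG", 34), ("TPEF-SHG", 34), ("CARS-TPEF-SHG", 51)],
    )
    def test_input_widths(self, models, name, width):
        assert models[name].input_width == width

    def test_predict_adds_calls_and_flags(self, models, feature_table):
        preds = classify.predict(models["TPEF-SHG"], feature_table.head(20))
        assert {"posterior_tumor", "predicted", "inconclusive"} <= set(preds.columns)
        assert preds["posterior_tumor"].between(0, 1).all()

    def test_predict_width_mismatch_errors(self, models, feature_table):
        wrong = feature_table.copy()
        with pytest.raises(TrainingError):
            models["TPEF-SHG"].posterior_tumor(np.zeros((3, 51)))


class TestClassCalls:
    @pytest.mark.parametrize(
        "posterior, predicted, inconclusive",
        [
            (0.70, "tumor", True),   # closed band: 0.70 is inconclusive yet called tumor
            (0.50, "liver", True),   # tumor requires strictly exceeding 0.5
            (0.99, "tumor", False),
            (0.30, "liver", True),
            (0.29, "liver", False),
        ],
    )
    def test_thresholds(self, posterior, predicted, inconclusive):
        row = classify.classify_posteriors([posterior]).iloc[0]
        assert row["predicted"] == predicted
        assert bool(row["inconclusive"]) is inconclusive
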