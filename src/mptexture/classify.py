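"""Feedforward network classification of texture features.

Mirrors the study design: a fully connected network per channel combination
(7 models: CARS, TPEF, SHG, CARS-TPEF, CARS-SHG, TPEF-SHG, CARS-TPEF-SHG),
trained full-batch with an L-BFGS quasi-Newton optimizer on a cross-entropy
loss with L2 penalty, capped at 1000 iterations, weights Glorot-initialized,
hyperparameters chosen by a seeded search over architecture/activation/L2,
and strictly patient-disjoint train/test splits. The network and its
optimization are implemented directly on numpy + scipy so the per-iteration
loss trace and the iteration-cap convergence flag are part of the model.

Class encoding is 0 = liver, 1 = tumor throughout; the model's posterior is
the tumor-class softmax output. A FoV is called tumor only when its posterior
strictly exceeds 0.5, and is flagged inconclusive when the posterior falls in
the closed band [0.3, 0.7].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fov_io import CHANNEL_ORDER
from .features import fov_feature_names

#: The seven channel combinations, in fixed order.
CHANNEL_COMBOS: tuple[tuple[str, ...], ...] = (
    ("CARS",),
    ("TPEF",),
    ("SHG",),
    ("CARS", "TPEF"),
    ("CARS", "SHG"),
    ("TPEF", "SHG"),
    ("CARS", "TPEF", "SHG"),
)

POSTERIOR_THRESHOLD = 0.5
INCONCLUSIVE_BAND = (0.3, 0.7)  # closed interval

LABEL_TO_CODE = {"liver": 0, "tumor": 1}
CODE_TO_LABEL = {0: "liver", 1: "tumor"}


class TrainingError(ValueError):
    """Raised for invalid training inputs (single class, non-finite values)."""


def combo_name(channel_set: Sequence[str]) -> str:
    ordered = [c for c in CHANNEL_ORDER if c in set(channel_set)]
    return "-".join(ordered)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    """Patient-disjoint partition; every FoV inherits its patient's side."""

    train_patients: tuple[str, ...]
    test_patients: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_patients) & set(self.test_patients):
            raise ValueError("train and test patients overlap")


def make_split(manifest: pd.DataFrame, n_train_patients: int, seed: int) -> SplitPlan:
    """Randomly partition patients into train/test, excluding border-sample
    patients from both sides (they are held out for probability mapping).

    Deterministic given ``seed``.
    """
    border_patients = set(manifest.loc[manifest["sample"] == "border", "patient_id"])
    eligible = sorted(set(manifest["patient_id"]) - border_patients)
    if n_train_patients >= len(eligible):
        raise TrainingError(
            f"need n_train_patients < {len(eligible)} eligible patients, got {n_train_patients}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    shuffled = [eligible[i] for i in order]
    return SplitPlan(
        train_patients=tuple(sorted(shuffled[:n_train_patients])),
        test_patients=tuple(sorted(shuffled[n_train_patients:])),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    """One concrete network configuration evaluated during the search."""

    hidden_layers: tuple[int, ...] = (25,)
    activation: str = "relu"  # relu | tanh | logistic
    l2: float = 1e-4
    standardize: bool = True


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter search space: layer counts, widths, activations and a
    log-uniform L2 range. Standardization is always on."""

    n_layers: tuple[int, ...] = (1, 2, 3)
    widths: tuple[int, ...] = (5, 10, 25, 50, 100)
    activations: tuple[str, ...] = ("relu", "tanh", "logistic")
    l2_range: tuple[float, float] = (1e-6, 1e-1)

    def is_empty(self) -> bool:
        return not (self.n_layers and self.widths and self.activations)

    def sample(self, rng: np.random.Generator) -> Candidate:
        n = int(rng.choice(self.n_layers))
        hidden = tuple(int(rng.choice(self.widths)) for _ in range(n))
        activation = str(rng.choice(self.activations))
        lo, hi = self.l2_range
        l2 = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if hi > lo else float(lo)
        return Candidate(hidden_layers=hidden, activation=activation, l2=l2)

    def single_candidate(self) -> Candidate | None:
        """If the space contains exactly one configuration, return it."""
        if (
            len(self.n_layers) == 1
            and len(self.widths) == 1
            and len(self.activations) == 1
            and self.l2_range[0] == self.l2_range[1]
        ):
            return Candidate(
                hidden_layers=(self.widths[0],) * self.n_layers[0],
                activation=self.activations[0],
                l2=self.l2_range[0],
            )
        return None


@dataclass(frozen=True)
class TrainConfig:
    """Training and search configuration (defaults mirror the study setup:
    1000 full-batch L-BFGS iterations, cross-entropy loss, 100 search steps)."""

    max_epochs: int = 1000
    n_search_steps: int = 100
    search_space: SearchSpace = field(default_factory=SearchSpace)
    validation_fraction: float = 0.2  # patient-disjoint holdout for tuning
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise TrainingError("max_epochs must be >= 1")
        if self.n_search_steps < 1:
            raise TrainingError("n_search_steps must be >= 1")


# ---------------------------------------------------------------------------
# Network internals
# ---------------------------------------------------------------------------


def _activation(name: str):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(np.float64)
    if name == "tanh":
        return np.tanh, lambda z, a: 1.0 - a**2
    if name == "logistic":
        sig = lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return sig, lambda z, a: a * (1.0 - a)
    raise TrainingError(f"unknown activation {name!r}")


def _glorot_init(widths: Sequence[int], rng: np.random.Generator) -> list[np.ndarray]:
    weights = []
    for fan_in, fan_out in itertools.pairwise(widths):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
    return weights


def _pack(weights: list[np.ndarray], biases: list[np.ndarray]) -> np.ndarray:
    return np.concatenate([w.ravel() for w in weights] + [b.ravel() for b in biases])


def _unpack(theta: np.ndarray, widths: Sequence[int]) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    pos = 0
    for fan_in, fan_out in itertools.pairwise(widths):
        weights.append(theta[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out))
        pos += fan_in * fan_out
    for _, fan_out in itertools.pairwise(widths):
        biases.append(theta[pos : pos + fan_out])
        pos += fan_out
    return weights, biases


def _forward(X: np.ndarray, weights, biases, activation: str) -> np.ndarray:
    act, _ = _activation(activation)
    a = X
    for w, b in zip(weights[:-1], biases[:-1]):
        a = act(a @ w + b)
    logits = a @ weights[-1] + biases[-1]
    logits = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(logits)
    return expz / expz.sum(axis=1, keepdims=True)


def _loss_and_grad(theta, X, Y, widths, activation, l2):
    n = X.shape[0]
    act, dact = _activation(activation)
    weights, biases = _unpack(theta, widths)
    activations = [X]
    pre = []
    a = X
    for w, b in zip(weights[:-1], biases[:-1]):
        z = a @ w + b
        a = act(z)
        pre.append(z)
        activations.append(a)
    logits = a @ weights[-1] + biases[-1]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)
    eps = 1e-12
    ce = -np.mean(np.log(probs[np.arange(n), Y] + eps))
    reg = 0.5 * l2 * sum(float(np.sum(w * w)) for w in weights) / n
    loss = ce + reg

    delta = probs.copy()
    delta[np.arange(n), Y] -= 1.0
    delta /= n
    grad_w = [np.zeros_like(w) for w in weights]
    grad_b = [np.zeros_like(b) for b in biases]
    for layer in range(len(weights) - 1, -1, -1):
        grad_w[layer] = activations[layer].T @ delta + (l2 / n) * weights[layer]
        grad_b[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ weights[layer].T) * dact(pre[layer - 1], activations[layer])
    return loss, _pack(grad_w, grad_b)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reproduce its predictions:
    architecture, weights, the train-set standardization, the winning
    hyperparameters and the per-iteration training-loss trace."""

    channel_set: tuple[str, ...]
    feature_names: tuple[str, ...]
    layer_widths: tuple[int, ...]  # input, hidden..., 2
    activation: str
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    candidate: Candidate
    loss_trace: list[float]
    hit_iteration_cap: bool
    n_iterations: int

    @property
    def input_width(self) -> int:
        return self.layer_widths[0]

    def posterior_tumor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.input_width:
            raise TrainingError(
                f"feature width {X.shape[1]} does not match model input width {self.input_width}"
            )
        Xs = (X - self.scaler_mean) / self.scaler_sd
        return _forward(Xs, self.weights, self.biases, self.activation)[:, 1]


def fit_network(
    features: np.ndarray,
    labels: np.ndarray,
    candidate: Candidate = Candidate(),
    max_epochs: int = 1000,
    seed: int = 0,
    channel_set: Sequence[str] = CHANNEL_ORDER,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Train one network with full-batch L-BFGS on cross-entropy + L2.

    ``labels`` may be string labels ('liver'/'tumor') or 0/1 codes. The loss
    trace records the objective at every accepted iterate (monotone
    non-increasing); ``hit_iteration_cap`` reports whether the iteration
    limit, rather than the gradient tolerance, stopped training.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray([LABEL_TO_CODE.get(v, v) for v in np.asarray(labels).ravel()], dtype=np.int64)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError("features must be (n, d) with one label per row")
    if not np.all(np.isfinite(X)):
        raise TrainingError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")

    if candidate.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    Xs = (X - mean) / sd

    widths = (X.shape[1], *candidate.hidden_layers, 2)
    rng = np.random.default_rng(seed)
    weights0 = _glorot_init(widths, rng)
    biases0 = [np.zeros(w) for w in widths[1:]]
    theta0 = _pack(weights0, biases0)

    args = (Xs, y, widths, candidate.activation, candidate.l2)
    trace: list[float] = []

    def _callback(theta_k):
        trace.append(float(_loss_and_grad(theta_k, *args)[0]))

    result = minimize(
        _loss_and_grad,
        theta0,
        args=args,
        jac=True,
        method="L-BFGS-B",
        callback=_callback,
        options={"maxiter": max_epochs, "maxfun": max(10 * max_epochs, 1000)},
    )
    weights, biases = _unpack(result.x, widths)
    names = tuple(feature_names) if feature_names is not None else tuple(fov_feature_names(channel_set))
    return TrainedModel(
        channel_set=tuple(c for c in CHANNEL_ORDER if c in set(channel_set)),
        feature_names=names,
        layer_widths=widths,
        activation=candidate.activation,
        weights=weights,
        biases=biases,
        scaler_mean=mean,
        scaler_sd=sd,
        candidate=candidate,
        loss_trace=trace,
        hit_iteration_cap=result.nit >= max_epochs,
        n_iterations=int(result.nit),
    )


def fold_standardization(model: TrainedModel) -> TrainedModel:
    """Fold the feature standardization into the first layer's weights.

    The returned model applies an identity scaler yet produces identical
    posteriors: W1' = W1 / sd, b1' = b1 − (mean / sd) @ W1.
    """
    w1 = model.weights[0] / model.scaler_sd[:, None]
    b1 = model.biases[0] - (model.scaler_mean / model.scaler_sd) @ model.weights[0]
    return replace(
        model,
        weights=[w1] + [w.copy() for w in model.weights[1:]],
        biases=[b1] + [b.copy() for b in model.biases[1:]],
        scaler_mean=np.zeros_like(model.scaler_mean),
        scaler_sd=np.ones_like(model.scaler_sd),
    )


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------


def _cross_entropy(posterior: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(posterior, eps, 1 - eps)
    return float(-np.mean(np.where(y == 1, np.log(p), np.log(1 - p))))


def tune_hyperparameters(
    features: np.ndarray,
    labels: np.ndarray,
    patients: Sequence[str],
    config: TrainConfig,
) -> tuple[Candidate, list[tuple[Candidate, float]]]:
    """Seeded random search over the configured space.

    Candidates are scored by cross-entropy on a patient-disjoint holdout
    (``validation_fraction`` of the training patients). Returns the argmin
    candidate and the full (candidate, validation loss) history, whose length
    equals ``n_search_steps``. Deterministic given ``config.seed``.
    """
    space = config.search_space
    if space.is_empty():
        raise TrainingError("empty hyperparameter search space")
    rng = np.random.default_rng(config.seed)

    patients = np.asarray(patients)
    unique_patients = np.array(sorted(set(patients.tolist())))
    n_val = max(1, int(round(config.validation_fraction * len(unique_patients))))
    if n_val >= len(unique_patients):
        raise TrainingError("not enough patients for a validation holdout")
    shuffled = unique_patients[rng.permutation(len(unique_patients))]
    val_patients = set(shuffled[:n_val].tolist())
    val_mask = np.isin(patients, list(val_patients))

    X = np.asarray(features, dtype=np.float64)
    y = np.asarray([LABEL_TO_CODE.get(v, v) for v in np.asarray(labels).ravel()], dtype=np.int64)

    single = space.single_candidate()
    history: list[tuple[Candidate, float]] = []
    for step in range(config.n_search_steps):
        candidate = single if single is not None else space.sample(rng)
        model = fit_network(
            X[~val_mask],
            y[~val_mask],
            candidate=candidate,
            max_epochs=config.max_epochs,
            seed=int(rng.integers(2**31)),
        )
        val_loss = _cross_entropy(model.posterior_tumor(X[val_mask]), y[val_mask])
        history.append((candidate, val_loss))
    best = min(history, key=lambda item: item[1])[0]
    return best, history


# ---------------------------------------------------------------------------
# Channel-combination training and prediction
# ---------------------------------------------------------------------------


def train_channel_models(
    feature_table: pd.DataFrame,
    split: SplitPlan,
    config: TrainConfig,
    combos: Sequence[Sequence[str]] = CHANNEL_COMBOS,
) -> dict[str, TrainedModel]:
    """Train one model per channel combination on the training patients.

    ``feature_table`` carries one row per QC-accepted FoV with columns
    patient_id, sample, true_label and the 51 per-channel feature columns.
    For each combination, hyperparameters are tuned on a patient-disjoint
    holdout of the training patients, then the winner is refit on the full
    training set. Input widths are 17 × |channel_set|.
    """
    train_rows = feature_table[
        feature_table["patient_id"].isin(split.train_patients)
        & feature_table["sample"].isin(["liver", "tumor"])
    ]
    models: dict[str, TrainedModel] = {}
    for k, channel_set in enumerate(combos):
        names = fov_feature_names(channel_set)
        missing = [n for n in names if n not in feature_table.columns]
        if missing:
            raise TrainingError(f"feature table lacks columns {missing[:3]}...")
        X = train_rows[names].to_numpy(dtype=np.float64)
        y = train_rows["true_label"].to_numpy()
        sub_config = replace(config, seed=config.seed + k)
        best, _history = tune_hyperparameters(X, y, train_rows["patient_id"].to_numpy(), sub_config)
        model = fit_network(
            X,
            y,
            candidate=best,
            max_epochs=config.max_epochs,
            seed=sub_config.seed,
            channel_set=channel_set,
            feature_names=names,
        )
        models[combo_name(channel_set)] = model
    return models


def predict(model: TrainedModel, feature_table: pd.DataFrame) -> pd.DataFrame:
    """Posterior probabilities and class calls for each FoV row.

    Adds columns ``posterior_tumor``, ``predicted`` (tumor iff posterior
    strictly exceeds 0.5) and ``inconclusive`` (posterior in the closed band
    [0.3, 0.7]).
    """
    X = feature_table[list(model.feature_names)].to_numpy(dtype=np.float64)
    posterior = model.posterior_tumor(X)
    out = feature_table.copy()
    out["posterior_tumor"] = posterior
    out["predicted"] = np.where(posterior > POSTERIOR_THRESHOLD, "tumor", "liver")
    lo, hi = INCONCLUSIVE_BAND
    out["inconclusive"] = (posterior >= lo) & (posterior <= hi)
    return out


def classify_posteriors(posteriors: np.ndarray) -> pd.DataFrame:
    """Class calls and inconclusive flags for raw posterior values."""
    posteriors = np.asarray(posteriors, dtype=np.float64)
    lo, hi = INCONCLUSIVE_BAND
    return pd.DataFrame(
        {
            "posterior_tumor": posteriors,
            "predicted": np.where(posteriors > POSTERIOR_THRESHOLD, "tumor", "liver"),
            "inconclusive": (posteriors >= lo) & (posteriors <= hi),
        }
    )
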