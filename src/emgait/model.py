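"""Multi-layer perceptron for stance/swing classification.

A fully-connected network maps each 200-sample interleaved envelope vector
to a single sigmoid output; ReLU nonlinearities sit between hidden layers.
The default architecture is 200-512-256-128-1 (a single 128-unit hidden
layer is the lightweight variant).  Training is plain stochastic gradient
descent on binary cross-entropy, with early stopping on the accuracy of a
chronological validation tail: training halts when validation accuracy has
not improved for ``patience`` consecutive epochs, and the weights of the
best-validation epoch are restored.

The implementation is pure numpy (float32 matmuls) and bit-reproducible
under the configured seed on a given platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    DegenerateTrainingError,
    ParameterError,
    UndefinedMetricError,
)


@dataclass
class MLPConfig:
    """Architecture and training hyper-parameters.

    ``hidden_sizes`` [512, 256, 128] is the full model; [128] the
    single-hidden-layer variant.  ``val_fraction`` is the chronological
    tail of the training sequence held out for early stopping.  Momentum
    and weight decay are available but off by default (plain SGD).
    """

    hidden_sizes: list[int] = field(default_factory=lambda: [512, 256, 128])
    input_size: int = 200
    learning_rate: float = 0.01
    max_epochs: int = 100
    patience: int = 10
    batch_size: int = 32
    threshold: float = 0.5
    val_fraction: float = 0.10
    momentum: float = 0.0
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ParameterError("hidden_sizes must be non-empty")
        if any(h < 1 for h in self.hidden_sizes):
            raise ParameterError("hidden layer sizes must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ParameterError("threshold must be in (0, 1)")
        if self.patience > self.max_epochs:
            raise ParameterError("patience cannot exceed max_epochs")
        if not 0.0 < self.val_fraction < 1.0:
            raise ParameterError("val_fraction must be in (0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ParameterError("learning_rate > 0 and batch_size >= 1")


@dataclass
class MLPState:
    """Weights and biases, layer by layer (input → hidden... → output)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(
            b.size for b in self.biases
        )

    def copy(self) -> "MLPState":
        return MLPState(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )


@dataclass
class TrainedModel:
    """A trained classifier: best-epoch weights plus the training history."""

    state: MLPState
    config: MLPConfig
    best_epoch: int  # 0-based epoch index of the stored weights
    history: dict[str, list[float]]  # train_loss, val_accuracy per epoch

    @property
    def epochs_run(self) -> int:
        return len(self.history["train_loss"])


def init_model(cfg: MLPConfig) -> MLPState:
    """He-style scaled-uniform initialization, deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    sizes = [cfg.input_size, *cfg.hidden_sizes, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / fan_in)
        weights.append(
            rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(
                np.float32
            )
        )
        biases.append(np.zeros(fan_out, dtype=np.float32))
    return MLPState(weights=weights, biases=biases)


def _forward(state: MLPState, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    """Activations per layer and output logits."""
    acts = [x]
    a = x
    for w, b in zip(state.weights[:-1], state.biases[:-1]):
        a = np.maximum(a @ w + b, 0.0)
        acts.append(a)
    logits = (a @ state.weights[-1] + state.biases[-1]).ravel()
    return acts, logits


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # softplus(z) - y*z is the numerically stable binary cross-entropy
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


def _sgd_step(
    state: MLPState,
    velocity: MLPState,
    x: np.ndarray,
    y: np.ndarray,
    cfg: MLPConfig,
) -> None:
    acts, logits = _forward(state, x)
    delta = ((_sigmoid(logits) - y) / len(y)).astype(np.float32)[:, None]
    for i in range(len(state.weights) - 1, -1, -1):
        grad_w = acts[i].T @ delta
        grad_b = delta.sum(axis=0)
        if cfg.weight_decay > 0:
            grad_w = grad_w + cfg.weight_decay * state.weights[i]
        if i > 0:
            delta = (delta @ state.weights[i].T) * (acts[i] > 0)
        if cfg.momentum > 0:
            velocity.weights[i] *= cfg.momentum
            velocity.weights[i] -= cfg.learning_rate * grad_w
            velocity.biases[i] *= cfg.momentum
            velocity.biases[i] -= cfg.learning_rate * grad_b
            state.weights[i] += velocity.weights[i]
            state.biases[i] += velocity.biases[i]
        else:
            state.weights[i] -= cfg.learning_rate * grad_w
            state.biases[i] -= cfg.learning_rate * grad_b


def train(
    model: MLPState,
    vectors: np.ndarray,
    labels: np.ndarray,
    cfg: MLPConfig,
) -> TrainedModel:
    """SGD with early stopping on a chronological validation tail.

    The last ``val_fraction`` of the (chronological) training sequence is
    held out for validation; mini-batch order is shuffled per epoch under
    the seed, but no data cross the train/validation boundary.  Training
    stops at ``max_epochs`` or once validation accuracy has not exceeded
    its running maximum for ``patience`` consecutive epochs; the weights of
    the best epoch are restored.
    """
    vectors = np.asarray(vectors, dtype=np.float32)
    labels = np.asarray(labels)
    if vectors.ndim != 2 or vectors.shape[1] != cfg.input_size:
        raise ParameterError(
            f"expected vectors of width {cfg.input_size}, "
            f"got shape {vectors.shape}"
        )
    if np.unique(labels).size < 2:
        raise DegenerateTrainingError(
            "training windows contain a single class"
        )
    n = len(vectors)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    if n_val >= n:
        raise ParameterError("validation split leaves no training data")
    x_train, y_train = vectors[: n - n_val], labels[: n - n_val].astype(np.float32)
    x_val, y_val = vectors[n - n_val :], labels[n - n_val :]
    if np.unique(y_train).size < 2:
        raise DegenerateTrainingError(
            "training portion (before validation tail) has a single class"
        )

    state = model.copy()
    velocity = MLPState(
        weights=[np.zeros_like(w) for w in state.weights],
        biases=[np.zeros_like(b) for b in state.biases],
    )
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0x5D]).generate_state(1)[0]
    )
    history: dict[str, list[float]] = {"train_loss": [], "val_accuracy": []}
    best_acc, best_epoch, best_state = -1.0, -1, state.copy()
    since_best = 0
    n_tr = len(x_train)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        losses = []
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            _, logits = _forward(state, xb)
            losses.append(_bce_from_logits(logits, yb) * len(idx))
            _sgd_step(state, velocity, xb, yb, cfg)
        history["train_loss"].append(float(np.sum(losses) / n_tr))
        _, val_logits = _forward(state, x_val)
        val_pred = (_sigmoid(val_logits) > cfg.threshold).astype(np.int8)
        val_acc = float(np.mean(val_pred == y_val))
        history["val_accuracy"].append(val_acc)
        if val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = state.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    return TrainedModel(
        state=best_state, config=cfg, best_epoch=best_epoch, history=history
    )


def predict_labels(
    model: TrainedModel | MLPState,
    vectors: np.ndarray,
    cfg: MLPConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sigmoid probabilities and thresholded binary labels.

    Label 1 is assigned iff the sigmoid output is strictly greater than the
    threshold (an output of exactly 0.5 maps to stance, label 0).
    """
    if isinstance(model, TrainedModel):
        state, cfg = model.state, model.config
    else:
        state = model
        if cfg is None:
            cfg = MLPConfig()
    vectors = np.asarray(vectors, dtype=np.float32)
    if vectors.ndim != 2 or vectors.shape[1] != state.weights[0].shape[0]:
        raise ParameterError(
            f"expected vectors of width {state.weights[0].shape[0]}, "
            f"got shape {vectors.shape}"
        )
    _, logits = _forward(state, vectors)
    probs = _sigmoid(logits.astype(np.float64))
    return probs, (probs > cfg.threshold).astype(np.int8)


def classification_accuracy(
    predicted: np.ndarray,
    true: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Fraction of unmasked windows where prediction equals truth."""
    predicted = np.asarray(predicted)
    true = np.asarray(true)
    if predicted.shape != true.shape:
        raise ParameterError("label arrays must have equal length")
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        predicted, true = predicted[keep], true[keep]
    if predicted.size == 0:
        raise UndefinedMetricError("no unmasked windows to score")
    return float(np.mean(predicted == true))


def single_layer_variant(cfg: MLPConfig) -> MLPConfig:
    """The lightweight one-hidden-layer (128-unit) configuration."""
    return replace(cfg, hidden_sizes=[128])


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to one portable .npz file.

    The config and history travel as a JSON header next to the raw weight
    arrays, so a saved model reloads bit-identically.
    """
    import dataclasses
    import json

    header = json.dumps(
        {
            "config": dataclasses.asdict(model.config),
            "best_epoch": model.best_epoch,
            "history": model.history,
        }
    )
    arrays = {
        f"w{i}": w for i, w in enumerate(model.state.weights)
    } | {f"b{i}": b for i, b in enumerate(model.state.biases)}
    np.savez(path, header=np.array(header), **arrays)


def load_model(path) -> TrainedModel:
    """Inverse of :func:`save_model`."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["header"]))
        n_layers = len(meta["config"]["hidden_sizes"]) + 1
        state = MLPState(
            weights=[data[f"w{i}"] for i in range(n_layers)],
            biases=[data[f"b{i}"] for i in range(n_layers)],
        )
    return TrainedModel(
        state=state,
        config=MLPConfig(**meta["config"]),
        best_epoch=meta["best_epoch"],
        history=meta["history"],
    )
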