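"""Extreme Learning Machine solved through the Moore-Penrose pseudoinverse.

An ELM is a single-hidden-layer feed-forward network whose hidden weights
``a`` and biases ``b`` are drawn at random and never trained.  With N training
samples and N-tilde hidden nodes, the hidden-layer output matrix is

    H[j, i] = f(<a_i, x_j> + b_i),        j = 1..N, i = 1..N-tilde,

and the only learned parameters are the output weights ``beta`` linking hidden
nodes to class outputs.  They are obtained in closed form as the minimum-norm
least-squares solution

    beta = pinv(H) @ T,

where ``pinv`` is the Moore-Penrose generalized inverse and ``T`` is the
one-hot target matrix.  Prediction is ``argmax`` over the columns of
``f(X a + b) beta``, with argmax ties resolved toward the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

__all__ = ["ELMModel", "elm_fit", "elm_predict"]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class ELMModel:
    """Frozen random hidden layer plus closed-form output weights."""

    hidden_weights: np.ndarray  # (d, n_hidden)
    hidden_biases: np.ndarray  # (n_hidden,)
    activation: str
    beta: np.ndarray  # (n_hidden, n_classes)
    classes: np.ndarray
    seed: int

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[1]


def _hidden_matrix(model_or_parts, X: np.ndarray) -> np.ndarray:
    a, b, act = model_or_parts
    return _ACTIVATIONS[act](X @ a + b)


def elm_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_hidden: int,
    activation: str = "sigmoid",
    seed: int = 0,
) -> ELMModel:
    """Fit an ELM: seeded uniform(-1, 1) hidden layer, pseudoinverse solve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InvalidInputError("X must be a non-empty 2-D matrix")
    if n_hidden < 1:
        raise InvalidInputError("n_hidden must be >= 1")
    if activation not in _ACTIVATIONS:
        raise InvalidInputError(f"unknown activation {activation!r}")
    classes = np.unique(y)
    if classes.size < 2:
        raise InvalidInputError("need at least 2 classes")

    rng = np.random.default_rng(seed)
    d = X.shape[1]
    a = rng.uniform(-1.0, 1.0, size=(d, n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)

    # one-hot target matrix T, columns ordered by sorted class label
    T = (y[:, None] == classes[None, :]).astype(float)
    H = _hidden_matrix((a, b, activation), X)
    beta = np.linalg.pinv(H) @ T
    return ELMModel(a, b, activation, beta, classes, seed)


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Predict class labels: argmax of the output layer, lowest index on ties."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.hidden_weights.shape[0]:
        raise InvalidInputError(
            f"feature dimension {X.shape} does not match model input "
            f"dimension {model.hidden_weights.shape[0]}"
        )
    H = _hidden_matrix((model.hidden_weights, model.hidden_biases, model.activation), X)
    scores = H @ model.beta
    return model.classes[np.argmax(scores, axis=1)]


def elm_decision_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw per-class output scores o = f(Xa + b) beta (one row per sample)."""
    H = _hidden_matrix(
        (model.hidden_weights, model.hidden_biases, model.activation), np.asarray(X, dtype=float)
    )
    return H @ model.beta
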