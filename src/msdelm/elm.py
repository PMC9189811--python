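"""Extreme learning machine: a single-hidden-layer feedforward network whose
input-side parameters are random (or supplied by an optimizer) and whose
output weights are solved in closed form by least squares.

The network maps a K-dimensional feature vector x to P class scores

    f(x) = g(x W^T + b) beta

where W (L x K) are input weights, b (L) hidden thresholds, g a bounded
activation (logistic sigmoid by default), and beta (L x P) the output weights.
Training fixes (W, b) and sets beta = H+ Y, the Moore-Penrose pseudoinverse
solution of H beta = Y, with H the N x L hidden-layer output matrix and Y the
one-hot target matrix.  Class labels are 1-based everywhere in the public API.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import lstsq as scipy_lstsq

__all__ = [
    "FeatureTable",
    "ElmModel",
    "one_hot",
    "random_init",
    "hidden_output",
    "solve_beta",
    "train_elm",
    "predict",
    "decision_scores",
    "sigmoid",
    "ACTIVATIONS",
]

# Singular values below RCOND * s_max are treated as zero when inverting H,
# guarding rank-deficient hidden layers.
RCOND = 1e-12

DEFAULT_BOUNDS = (-1.0, 1.0)


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Logistic sigmoid 1/(1+exp(-z)), numerically stable for large |z|."""
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": sigmoid,
    "tanh": np.tanh,
}


@dataclass
class FeatureTable:
    """Labeled sample matrix: N rows of K unitless features, labels in 1..P."""

    X: np.ndarray
    y: np.ndarray
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError(f"X must be a non-empty 2-d matrix, got shape {self.X.shape}")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("y must be one label per row of X")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if np.any(self.y < 1):
            raise ValueError("labels must be 1-based positive integers")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        """P: the largest label present (labels are 1..P)."""
        return int(self.y.max())

    def subset(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.X[idx], self.y[idx], self.class_names)

    def to_csv(self, path: str | Path) -> None:
        """Write as delimited text: header row, feature columns, last column `label`."""
        df = pd.DataFrame(self.X, columns=[f"f{i}" for i in range(self.n_features)])
        df["label"] = self.y
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError(f"{path}: feature CSV must have a `label` column")
        y = df["label"].to_numpy()
        X = df.drop(columns=["label"]).to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError(f"{path}: non-finite feature cells")
        return cls(X, y)


@dataclass
class ElmModel:
    """Trained network: input weights W (L x K), thresholds b (L), output
    weights beta (L x P)."""

    W: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise ValueError("W must be L x K with b of length L")
        if self.beta.shape[0] != self.W.shape[0]:
            raise ValueError("beta must have L rows")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def L(self) -> int:
        return self.W.shape[0]

    @property
    def K(self) -> int:
        return self.W.shape[1]

    @property
    def P(self) -> int:
        return self.beta.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to a single JSON file (arrays base64-encoded, bit-exact)."""
        payload = {
            "format": "msdelm-elm-v1",
            "L": self.L,
            "K": self.K,
            "P": self.P,
            "activation": self.activation,
            "arrays": {
                name: _encode_array(getattr(self, name)) for name in ("W", "b", "beta")
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "ElmModel":
        payload = json.loads(Path(path).read_text())
        arrays = {k: _decode_array(v) for k, v in payload["arrays"].items()}
        return cls(arrays["W"], arrays["b"], arrays["beta"], payload["activation"])


def _encode_array(a: np.ndarray) -> dict:
    a = np.ascontiguousarray(a, dtype="<f8")
    return {"shape": list(a.shape), "data": base64.b64encode(a.tobytes()).decode()}


def _decode_array(d: dict) -> np.ndarray:
    buf = base64.b64decode(d["data"])
    return np.frombuffer(buf, dtype="<f8").reshape(d["shape"]).copy()


def one_hot(labels: Sequence[int] | np.ndarray, P: int) -> np.ndarray:
    """One-hot encode 1-based labels into an N x P {0,1} matrix."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-d vector")
    if np.any(labels < 1) or np.any(labels > P):
        raise ValueError(f"labels must lie in 1..{P}")
    Y = np.zeros((labels.size, P))
    Y[np.arange(labels.size), labels - 1] = 1.0
    return Y


def random_init(
    K: int,
    L: int,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw input weights W (L x K) and thresholds b (L) i.i.d. uniform in bounds."""
    if L < 1 or K < 1:
        raise ValueError("K and L must be positive")
    lo, hi = bounds
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError(f"bounds must be finite with lower < upper, got {bounds}")
    rng = np.random.default_rng(rng)
    W = rng.uniform(lo, hi, size=(L, K))
    b = rng.uniform(lo, hi, size=L)
    return W, b


def hidden_output(
    W: np.ndarray, b: np.ndarray, X: np.ndarray, activation: str = "sigmoid"
) -> np.ndarray:
    """Hidden-layer output matrix H with H[i, j] = g(w_j . x_i + b_j)."""
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != W.shape[1]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match model K={W.shape[1]}"
        )
    g = ACTIVATIONS[activation]
    return g(X @ W.T + b)


def solve_beta(H: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights beta = H+ Y."""
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(H)):
        raise ValueError("hidden output matrix contains non-finite values")
    if H.shape[0] != Y.shape[0]:
        raise ValueError("H and Y must have the same number of rows")
    # Complete orthogonal factorization (gelsy): the same minimum-norm
    # least-squares solution as pinv(H) @ Y, at a fraction of the SVD cost.
    beta, *_ = scipy_lstsq(H, Y, cond=RCOND, lapack_driver="gelsy")
    return beta


def train_elm(
    train: FeatureTable,
    L: int,
    rng: np.random.Generator | int | None = None,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    activation: str = "sigmoid",
    n_classes: int | None = None,
) -> ElmModel:
    """Train with random (W, b) and least-squares beta.

    `n_classes` widens the output layer beyond max(train.y) when a split
    happens to miss the highest class.
    """
    rng = np.random.default_rng(rng)
    W, b = random_init(train.n_features, L, bounds, rng)
    P = n_classes or train.n_classes
    H = hidden_output(W, b, train.X, activation)
    beta = solve_beta(H, one_hot(train.y, P))
    return ElmModel(W, b, beta, activation)


def decision_scores(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """Raw N x P network outputs h(x) beta."""
    return hidden_output(model.W, model.b, X, model.activation) @ model.beta


def predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    """1-based predicted labels; argmax over class scores, ties to the
    smallest class index."""
    return np.argmax(decision_scores(model, X), axis=1) + 1
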