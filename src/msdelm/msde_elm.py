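"""Couples the DE optimizer to the ELM: the input weights W and hidden
thresholds b are flattened into one D = L*(K+1) search vector, the output
weights beta are recomputed in closed form inside the fitness function, and
the objective is the training-set RMSE against the one-hot targets.

RMSE (rather than 0/1 misclassification rate) keeps the objective continuous,
which differential evolution handles far better, and is compatible with an
early-stop fitness threshold of 1e-6.  A misclassification-rate objective is
available via ``fitness_kind="error_rate"``.
"""

from __future__ import annotations

from typing import Literal

import numpy as np

from .de import DeConfig, DeTrace, msde_optimize
from .elm import ElmModel, FeatureTable, hidden_output, one_hot, solve_beta

__all__ = ["encode", "decode", "fitness", "train_msde_elm"]

FitnessKind = Literal["rmse", "error_rate"]


def encode(W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Flatten (W, b) into one vector: W row-major (each hidden unit's K
    weights contiguous) followed by the L thresholds."""
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if W.ndim != 2 or b.shape != (W.shape[0],):
        raise ValueError("W must be L x K with b of length L")
    return np.concatenate([W.ravel(order="C"), b])


def decode(v: np.ndarray, K: int, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`encode`."""
    v = np.asarray(v, dtype=float)
    if v.shape != (L * (K + 1),):
        raise ValueError(f"encoding must have length L*(K+1)={L * (K + 1)}, got {v.shape}")
    return v[: L * K].reshape(L, K), v[L * K :]


def fitness(
    v: np.ndarray,
    train: FeatureTable,
    L: int,
    activation: str = "sigmoid",
    kind: FitnessKind = "rmse",
    n_classes: int | None = None,
) -> float:
    """Objective for one candidate (W, b): solve beta by least squares on the
    training set, then score the fitted network (lower is better)."""
    K = train.n_features
    P = n_classes or train.n_classes
    W, b = decode(v, K, L)
    H = hidden_output(W, b, train.X, activation)
    Y = one_hot(train.y, P)
    beta = solve_beta(H, Y)
    out = H @ beta
    if kind == "rmse":
        return float(np.sqrt(np.mean((out - Y) ** 2)))
    pred = np.argmax(out, axis=1) + 1
    return float(np.mean(pred != train.y))


def train_msde_elm(
    train: FeatureTable,
    L: int,
    de_cfg: DeConfig | None = None,
    rng: np.random.Generator | int | None = None,
    activation: str = "sigmoid",
    fitness_kind: FitnessKind = "rmse",
    n_classes: int | None = None,
) -> tuple[ElmModel, DeTrace]:
    """Train an ELM whose (W, b) are tuned by multi-strategy DE.

    The DE searches [Xmin, Xmax]^D with D = L*(K+1); beta is never part of
    the search space — it is determined by the pseudoinverse given (W, b) and
    recomputed once from the best individual for the returned model.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    de_cfg = de_cfg or DeConfig()
    K = train.n_features
    P = n_classes or train.n_classes
    D = L * (K + 1)

    def objective(v: np.ndarray) -> float:
        return fitness(v, train, L, activation, fitness_kind, P)

    best_v, _, trace = msde_optimize(objective, D, de_cfg, rng)
    W, b = decode(best_v, K, L)
    H = hidden_output(W, b, train.X, activation)
    beta = solve_beta(H, one_hot(train.y, P))
    return ElmModel(W, b, beta, activation), trace
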