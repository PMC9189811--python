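"""Experiment harness: a registry of the named model configurations (plain,
DE-optimized with every strategy subset, and their ensembles) plus the
repeated-run protocol that scores each one.

Model ids follow the strategy-subset naming convention:

========== =====================================================
id          meaning
========== =====================================================
ELM         plain random-feature ELM
DE_B_ELM    ELM tuned by single-strategy DE, DE/best/2
DE_R_ELM    single-strategy, DE/rand/2
DE_C_ELM    single-strategy, DE/current to best/1
DE_BC_ELM   dual-strategy, {DE/best/2, DE/current to best/1}
DE_RC_ELM   dual-strategy, {DE/rand/2, DE/current to best/1}
DE_BR_ELM   dual-strategy, {DE/best/2, DE/rand/2}
M-SDE_ELM   multi-strategy (all three)
EnELM       majority-vote ensemble of plain ELMs
M-SDE_EnELM ensemble of multi-strategy-tuned ELMs
========== =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .de import DeConfig
from .elm import FeatureTable, train_elm
from .ensemble import train_ensemble
from .evaluation import RunReport, repeated_runs
from .msde_elm import train_msde_elm

__all__ = ["MODEL_REGISTRY", "ModelSpec", "make_train_fn", "run_experiment"]

_B = "DE/best/2"
_R = "DE/rand/2"
_C = "DE/current to best/1"


@dataclass(frozen=True)
class ModelSpec:
    """(base learner, strategy subset, ensemble?) triple behind a model id."""

    base: str  # "elm" | "msde_elm"
    strategies: tuple[str, ...] = ()
    ensemble: bool = False


MODEL_REGISTRY: dict[str, ModelSpec] = {
    "ELM": ModelSpec("elm"),
    "DE_B_ELM": ModelSpec("msde_elm", (_B,)),
    "DE_R_ELM": ModelSpec("msde_elm", (_R,)),
    "DE_C_ELM": ModelSpec("msde_elm", (_C,)),
    "DE_BC_ELM": ModelSpec("msde_elm", (_B, _C)),
    "DE_RC_ELM": ModelSpec("msde_elm", (_R, _C)),
    "DE_BR_ELM": ModelSpec("msde_elm", (_B, _R)),
    "M-SDE_ELM": ModelSpec("msde_elm", (_R, _B, _C)),
    "EnELM": ModelSpec("elm", (), True),
    "M-SDE_EnELM": ModelSpec("msde_elm", (_R, _B, _C), True),
}


class _SingleModelWrapper:
    """Adapts an ElmModel to the report harness's predict() contract."""

    def __init__(self, model):
        self.model = model

    def predict(self, X: np.ndarray) -> np.ndarray:
        from .elm import predict

        return predict(self.model, X)


def make_train_fn(
    model_id: str,
    hidden_size: int | None = None,
    n_members: int = 10,
    de_cfg: DeConfig | None = None,
    n_classes: int | None = None,
):
    """Build a ``train_fn(train_table, seed) -> model`` for a registry id.

    ``hidden_size`` defaults to 4x the feature dimension for single models;
    ensembles use the 4x..10x grid regardless.
    """
    if model_id not in MODEL_REGISTRY:
        raise ValueError(f"unknown model id {model_id!r}; known: {list(MODEL_REGISTRY)}")
    spec = MODEL_REGISTRY[model_id]
    base_cfg = de_cfg or DeConfig()
    if spec.strategies:
        base_cfg = replace(base_cfg, strategies=spec.strategies)

    def train_fn(train: FeatureTable, seed: int):
        L = hidden_size or 4 * train.n_features
        if spec.ensemble:
            return train_ensemble(
                train, base=spec.base, n_members=n_members,
                de_cfg=base_cfg, seed=seed, n_classes=n_classes,
            )
        if spec.base == "elm":
            return _SingleModelWrapper(
                train_elm(train, L, np.random.default_rng(seed), n_classes=n_classes)
            )
        model, _ = train_msde_elm(
            train, L, base_cfg, np.random.default_rng(seed), n_classes=n_classes
        )
        return _SingleModelWrapper(model)

    return train_fn


def run_experiment(
    model_id: str,
    table: FeatureTable,
    runs: int = 10,
    master_seed: int = 0,
    hidden_size: int | None = None,
    n_members: int = 10,
    de_cfg: DeConfig | None = None,
) -> RunReport:
    """Repeated-run evaluation of one registry model on a feature table."""
    fn = make_train_fn(
        model_id, hidden_size, n_members, de_cfg, n_classes=table.n_classes
    )
    return repeated_runs(
        fn, table, n=runs, master_seed=master_seed, model_name=model_id
    )
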