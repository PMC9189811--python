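"""Majority-vote ensemble of ELMs with structurally diverse hidden layers.

A single ELM is unstable: its random (or DE-tuned) hidden layer makes accuracy
fluctuate run to run, and the best hidden size is hard to pick.  The ensemble
sidesteps both by training n base ELMs (default 10) whose hidden sizes span
four to ten times the feature dimension and combining their predictions by
majority vote

    H(x) = argmax_j  sum_i  [member i votes class j],

ties broken towards the smallest class index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .de import DeConfig
from .elm import ElmModel, FeatureTable, predict, train_elm
from .msde_elm import train_msde_elm

__all__ = ["EnsembleModel", "hidden_size_grid", "majority_vote", "train_ensemble"]

BaseKind = Literal["elm", "msde_elm"]


def hidden_size_grid(df: int, n: int = 10) -> list[int]:
    """n hidden sizes evenly spaced over [4*df, 10*df], endpoints included."""
    if df < 1:
        raise ValueError("feature dimension must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return [int(round(v)) for v in np.linspace(4 * df, 10 * df, n)]


def majority_vote(votes: np.ndarray, P: int | None = None) -> np.ndarray:
    """Combine an n x N matrix of 1-based member votes into N labels."""
    votes = np.atleast_2d(np.asarray(votes, dtype=int))
    if votes.size == 0:
        raise ValueError("vote matrix is empty")
    if np.any(votes < 1):
        raise ValueError("votes must be 1-based labels")
    P = P or int(votes.max())
    # counts[j, s] = number of members voting class j+1 for sample s
    counts = np.zeros((P, votes.shape[1]), dtype=int)
    for member in votes:
        counts[member - 1, np.arange(votes.shape[1])] += 1
    return np.argmax(counts, axis=0) + 1  # argmax ties -> smallest class


@dataclass
class EnsembleModel:
    members: list[ElmModel]
    hidden_sizes: list[int] = field(default_factory=list)
    base: str = "elm"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if not self.hidden_sizes:
            self.hidden_sizes = [m.L for m in self.members]
        Ks = {m.K for m in self.members}
        Ps = {m.P for m in self.members}
        if len(Ks) != 1 or len(Ps) != 1:
            raise ValueError("all members must share K and P")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def P(self) -> int:
        return self.members[0].P

    def predict(self, X: np.ndarray) -> np.ndarray:
        votes = np.stack([predict(m, X) for m in self.members])
        return majority_vote(votes, self.P)

    def save(self, dirpath: str | Path) -> None:
        """Directory of member model files plus a manifest JSON."""
        d = Path(dirpath)
        d.mkdir(parents=True, exist_ok=True)
        for i, m in enumerate(self.members):
            m.save(d / f"member_{i:02d}.json")
        manifest = {
            "format": "msdelm-ensemble-v1",
            "n_members": self.n_members,
            "hidden_sizes": self.hidden_sizes,
            "base": self.base,
        }
        (d / "manifest.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, dirpath: str | Path) -> "EnsembleModel":
        d = Path(dirpath)
        manifest = json.loads((d / "manifest.json").read_text())
        members = [
            ElmModel.load(d / f"member_{i:02d}.json")
            for i in range(manifest["n_members"])
        ]
        return cls(members, manifest["hidden_sizes"], manifest["base"])


def train_ensemble(
    train: FeatureTable,
    base: BaseKind = "elm",
    n_members: int = 10,
    hidden_sizes: Sequence[int] | None = None,
    de_cfg: DeConfig | None = None,
    seed: int | None = None,
    n_classes: int | None = None,
) -> EnsembleModel:
    """Train one member per hidden size with per-member seeds derived from the
    master seed (seed + member index), so members differ but the ensemble is
    reproducible.

    With ``base="elm"`` the members are plain random-feature ELMs; with
    ``base="msde_elm"`` each member's (W, b) is tuned by multi-strategy DE
    (or whatever strategy subset ``de_cfg`` specifies).
    """
    if hidden_sizes is None:
        if n_members == 1:
            hidden_sizes = [4 * train.n_features]
        else:
            hidden_sizes = hidden_size_grid(train.n_features, n_members)
    members: list[ElmModel] = []
    base_seed = 0 if seed is None else seed
    for i, L in enumerate(hidden_sizes):
        member_rng = np.random.default_rng(base_seed + i)
        if base == "elm":
            m = train_elm(train, L, member_rng, n_classes=n_classes)
        elif base == "msde_elm":
            m, _ = train_msde_elm(train, L, de_cfg, member_rng, n_classes=n_classes)
        else:
            raise ValueError(f"unknown base learner {base!r}")
        members.append(m)
    return EnsembleModel(members, list(hidden_sizes), base)
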