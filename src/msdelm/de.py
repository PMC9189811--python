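"""Differential evolution with multi-strategy mutation and adaptive controls.

Classic DE evolves a population of NP real D-vectors by mutation (weighted
vector differences), binomial crossover, boundary regeneration and greedy
selection.  The multi-strategy variant (M-SDE) draws, each generation, one
mutation strategy uniformly from a configured set — by default
{DE/rand/2, DE/best/2, DE/current to best/1} — and uses

    F(t)  = F0 * 2 ** exp(1 - T / (T + 1 - t))      (decays from 2*F0 to F0)
    CR    ~ U(0.5, 1.0)                              (redrawn per generation)

Random-draw order (one seeded numpy Generator per optimize call; fixed so
traces are exactly reproducible and externally replayable):

  1. initial population: ``rng.random((NP, D))`` scaled to the bounds;
  2. per generation: one strategy index ``rng.integers(n_strategies)``,
     then one CR value ``rng.random()``;
  3. per individual i (in index order): partner indices via
     ``rng.choice(candidates, size=k, replace=False)`` where candidates are
     all indices except i; forced crossover index ``rng.integers(D)``;
     crossover mask ``rng.random(D)``; then one ``rng.random(n_oob)`` draw
     for the out-of-bounds components (component order), if any.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STRATEGIES",
    "MSDE_STRATEGIES",
    "DeConfig",
    "DeTrace",
    "Population",
    "init_population",
    "mutate",
    "crossover",
    "enforce_bounds",
    "select",
    "adaptive_F",
    "adaptive_CR",
    "msde_optimize",
]

#: Canonical strategy names mapped to the number of mutually distinct random
#: partners each formula consumes.
STRATEGIES: dict[str, int] = {
    "DE/rand/1": 3,
    "DE/best/1": 2,
    "DE/current to best/1": 2,
    "DE/best/2": 4,
    "DE/rand/2": 5,
}

#: The multi-strategy set: global search (rand/2), fast local convergence
#: (best/2) and diversity with precision (current to best/1).
MSDE_STRATEGIES: tuple[str, ...] = (
    "DE/rand/2",
    "DE/best/2",
    "DE/current to best/1",
)


@dataclass
class DeConfig:
    """Optimizer configuration.  Defaults follow the standard tuned setting
    for ELM parameter search: NP=100, T=30, F0=0.4, adaptive CR, bounds
    [-1, 1], early stop when best fitness drops below y=1e-6."""

    NP: int = 100
    T: int = 30
    Xmin: float = -1.0
    Xmax: float = 1.0
    strategies: tuple[str, ...] = MSDE_STRATEGIES
    F0: float = 0.4
    CR: float | None = None  # None -> adaptive U(0.5, 1); else fixed value
    y: float = 1e-6
    seed: int | None = None
    per_individual_strategy: bool = False

    def __post_init__(self) -> None:
        self.strategies = tuple(self.strategies)
        if not self.strategies:
            raise ValueError("strategy set must be non-empty")
        unknown = [s for s in self.strategies if s not in STRATEGIES]
        if unknown:
            raise ValueError(f"unknown strategies {unknown}; known: {list(STRATEGIES)}")
        if not (self.Xmin <= self.Xmax):
            raise ValueError(f"need Xmin <= Xmax, got [{self.Xmin}, {self.Xmax}]")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if not 0.0 <= self.F0 <= 2.0:
            raise ValueError("F0 must lie in [0, 2]")
        needed = 1 + max(STRATEGIES[s] for s in self.strategies)
        if self.NP < needed:
            raise ValueError(
                f"NP={self.NP} too small: strategies {self.strategies} need "
                f"{needed} individuals (target + distinct partners)"
            )

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "NP": self.NP, "T": self.T, "Xmin": self.Xmin, "Xmax": self.Xmax,
            "strategies": list(self.strategies), "F0": self.F0, "CR": self.CR,
            "y": self.y, "seed": self.seed,
            "per_individual_strategy": self.per_individual_strategy,
        }
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["strategies"] = tuple(d.get("strategies", MSDE_STRATEGIES))
        return cls(**d)


@dataclass
class Population:
    """NP individuals (rows of x) with their fitness values (lower is better)."""

    x: np.ndarray
    fitness: np.ndarray

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))


@dataclass
class DeTrace:
    """Per-generation audit trail; supports convergence-curve export."""

    best_fitness: list[float] = field(default_factory=list)
    strategy: list[str] = field(default_factory=list)
    F: list[float] = field(default_factory=list)
    CR: list[float] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "generation": np.arange(1, len(self.best_fitness) + 1),
                "strategy": self.strategy,
                "F": self.F,
                "CR": self.CR,
                "best_fitness": self.best_fitness,
            }
        ).to_csv(path, index=False)


def init_population(
    cfg: DeConfig, D: int, rng: np.random.Generator
) -> np.ndarray:
    """NP x D matrix, each component Xmin + u*(Xmax - Xmin), u ~ U(0, 1)."""
    if D < 1:
        raise ValueError("D must be >= 1")
    return cfg.Xmin + rng.random((cfg.NP, D)) * (cfg.Xmax - cfg.Xmin)


def mutate(
    pop: np.ndarray,
    strategy: str,
    F: float,
    i: int,
    best: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mutant vector for target i under the named strategy.

    Partners r1..rk are sampled without replacement from all indices except i,
    so they are mutually distinct and distinct from the target.
    """
    k = STRATEGIES[strategy]
    candidates = np.delete(np.arange(pop.shape[0]), i)
    if candidates.size < k:
        raise ValueError(f"population too small for {strategy}")
    r = rng.choice(candidates, size=k, replace=False)
    x = pop
    if strategy == "DE/rand/1":
        return x[r[0]] + F * (x[r[1]] - x[r[2]])
    if strategy == "DE/best/1":
        return best + F * (x[r[0]] - x[r[1]])
    if strategy == "DE/current to best/1":
        return x[i] + F * (best - x[i]) + F * (x[r[0]] - x[r[1]])
    if strategy == "DE/best/2":
        return best + F * (x[r[0]] - x[r[1]]) + F * (x[r[2]] - x[r[3]])
    if strategy == "DE/rand/2":
        return x[r[0]] + F * (x[r[1]] - x[r[2]]) + F * (x[r[3]] - x[r[4]])
    raise ValueError(f"unknown strategy {strategy!r}")


def crossover(
    target: np.ndarray, mutant: np.ndarray, CR: float, rng: np.random.Generator
) -> np.ndarray:
    """Binomial crossover: each component comes from the mutant with
    probability CR; one forced index j_rand always takes the mutant component,
    so the trial differs from the target wherever the mutant does there."""
    if target.shape != mutant.shape:
        raise ValueError("target and mutant must have the same length")
    if not 0.0 <= CR <= 1.0:
        raise ValueError("CR must lie in [0, 1]")
    D = target.size
    j_rand = int(rng.integers(D))
    mask = rng.random(D) < CR
    mask[j_rand] = True
    return np.where(mask, mutant, target)


def enforce_bounds(
    trial: np.ndarray, cfg: DeConfig, rng: np.random.Generator
) -> np.ndarray:
    """Regenerate each out-of-bounds component uniformly in [Xmin, Xmax];
    in-bounds components pass through untouched."""
    oob = (trial < cfg.Xmin) | (trial > cfg.Xmax)
    if not np.any(oob):
        return trial
    out = trial.copy()
    out[oob] = cfg.Xmin + rng.random(int(oob.sum())) * (cfg.Xmax - cfg.Xmin)
    return out


def select(
    target_x: np.ndarray,
    target_f: float,
    trial_x: np.ndarray,
    trial_f: float,
) -> tuple[np.ndarray, float]:
    """Greedy selection: the trial survives iff strictly fitter (f_u < f_x)."""
    if not (np.isfinite(target_f) and np.isfinite(trial_f)):
        raise ValueError("both fitness values must be evaluated and finite")
    if trial_f < target_f:
        return trial_x, trial_f
    return target_x, target_f


def adaptive_F(t: int, T: int, F0: float) -> float:
    """Scaling factor schedule F0 * 2**exp(1 - T/(T+1-t)).

    F(1) = 2*F0 and F decays monotonically towards F0 at t = T, staying in
    [F0, 2*F0] throughout; with F0 <= 1 this respects the 0 <= F <= 2 bound.
    """
    if not 1 <= t <= T:
        raise ValueError(f"generation t={t} outside 1..{T}")
    return F0 * 2.0 ** math.exp(1.0 - T / (T + 1.0 - t))


def adaptive_CR(rng: np.random.Generator) -> float:
    """Crossover probability CR = 0.5 * (1 + u), u ~ U(0,1): uniform on [0.5, 1]."""
    return 0.5 * (1.0 + rng.random())


def _evaluate(fitness: Callable[[np.ndarray], float], x: np.ndarray) -> np.ndarray:
    return np.array([float(fitness(row)) for row in x])


def msde_optimize(
    fitness: Callable[[np.ndarray], float],
    D: int,
    cfg: DeConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, float, DeTrace]:
    """Minimize `fitness` over D-vectors in [Xmin, Xmax]^D.

    Runs up to cfg.T generations, stopping early once the best fitness drops
    below the threshold cfg.y.  Returns (best_x, best_f, trace); the best-ever
    individual always survives in the population (greedy selection), so the
    trace's best-fitness series is non-increasing.
    """
    if rng is None:
        rng = cfg.seed
    if not (hasattr(rng, "random") and hasattr(rng, "integers")):
        rng = np.random.default_rng(rng)

    pop = init_population(cfg, D, rng)
    fit = _evaluate(fitness, pop)
    trace = DeTrace()

    for t in range(1, cfg.T + 1):
        if fit.min() < cfg.y:
            break
        F = adaptive_F(t, cfg.T, cfg.F0)
        if cfg.per_individual_strategy:
            gen_strategy = None
        else:
            gen_strategy = cfg.strategies[int(rng.integers(len(cfg.strategies)))]
        CR = adaptive_CR(rng) if cfg.CR is None else cfg.CR

        best = pop[int(np.argmin(fit))].copy()
        new_pop = pop.copy()
        new_fit = fit.copy()
        for i in range(cfg.NP):
            strategy = (
                cfg.strategies[int(rng.integers(len(cfg.strategies)))]
                if gen_strategy is None
                else gen_strategy
            )
            v = mutate(pop, strategy, F, i, best, rng)
            u = crossover(pop[i], v, CR, rng)
            u = enforce_bounds(u, cfg, rng)
            new_pop[i], new_fit[i] = select(pop[i], fit[i], u, float(fitness(u)))
        pop, fit = new_pop, new_fit

        trace.best_fitness.append(float(fit.min()))
        trace.strategy.append(gen_strategy if gen_strategy is not None else "mixed")
        trace.F.append(F)
        trace.CR.append(CR)

    i_best = int(np.argmin(fit))
    return pop[i_best].copy(), float(fit[i_best]), trace
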