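"""Experimental protocol: stratified 7:3 split, repeated runs with derived
seeds, confusion-matrix metrics (accuracy, macro precision / F1), and paired
model comparison by pooled-variance t-test plus variance-ratio F-test.

The pooled t-test (not Welch) is the classical companion of an F-test of
variance equality: the F-test checks the equal-variance assumption the pooled
t relies on, and the pair together supports both a difference-of-means and a
difference-of-stability reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

from .elm import FeatureTable

__all__ = [
    "RunMetrics",
    "RunReport",
    "ComparisonReport",
    "split_train_test",
    "score",
    "repeated_runs",
    "compare_models",
]


def split_train_test(
    table: FeatureTable,
    train_fraction: float = 0.7,
    rng: np.random.Generator | int | None = None,
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified split: per class, round(train_fraction * n_c) samples go to
    the training set; the rest to the test set.  Reproducible by seed."""
    rng = np.random.default_rng(rng)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for c in np.unique(table.y):
        idx = np.flatnonzero(table.y == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 samples; cannot split")
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)  # both sides non-empty
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return table.subset(np.concatenate(train_idx)), table.subset(np.concatenate(test_idx))


@dataclass
class RunMetrics:
    """Metrics of one train/test cycle, all derived from the confusion matrix
    M[i, j] = count(true class i+1, predicted class j+1)."""

    confusion: np.ndarray
    accuracy: float
    f1: float
    precision: float
    seed: int | None = None


def score(
    y_true: np.ndarray, y_pred: np.ndarray, P: int | None = None,
    average: str = "macro",
) -> RunMetrics:
    """Confusion matrix and the derived accuracy / precision / F1.

    Per class j: precision = M[j,j] / column-sum (0 on an empty column),
    recall = M[j,j] / row-sum, F1 their harmonic mean.  `average` is "macro"
    (unweighted class mean, default) or "weighted" (by class support).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    P = P or int(max(y_true.max(), y_pred.max()))
    M = _sk_confusion(y_true, y_pred, labels=np.arange(1, P + 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        col = M.sum(axis=0)
        row = M.sum(axis=1)
        diag = np.diag(M)
        prec = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        rec = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        denom = prec + rec
        f1 = np.where(denom > 0, 2 * prec * rec / np.maximum(denom, 1e-300), 0.0)

    if average == "weighted":
        w = row / row.sum()
    elif average == "macro":
        w = np.full(P, 1.0 / P)
    else:
        raise ValueError(f"unknown average {average!r}")
    return RunMetrics(
        confusion=M,
        accuracy=float(diag.sum() / M.sum()),
        f1=float(np.sum(w * f1)),
        precision=float(np.sum(w * prec)),
    )


@dataclass
class RunReport:
    """Repeated-run results: per-run metrics plus mean +/- sample std."""

    model: str
    runs: list[RunMetrics]

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.runs])

    def aggregate(self) -> dict[str, tuple[float, float]]:
        out = {}
        for name in ("accuracy", "f1", "precision"):
            vals = np.array([getattr(r, name) for r in self.runs])
            std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[name] = (float(vals.mean()), std)
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "run": np.arange(1, len(self.runs) + 1),
                "seed": [r.seed for r in self.runs],
                "accuracy": [r.accuracy for r in self.runs],
                "f1": [r.f1 for r in self.runs],
                "precision": [r.precision for r in self.runs],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, model: str = "") -> "RunReport":
        df = pd.read_csv(path)
        runs = [
            RunMetrics(
                confusion=np.zeros((0, 0), dtype=int),
                accuracy=row.accuracy, f1=row.f1, precision=row.precision,
                seed=None if pd.isna(row.seed) else int(row.seed),
            )
            for row in df.itertuples()
        ]
        return cls(model or str(path), runs)


def repeated_runs(
    train_fn: Callable[[FeatureTable, int], "object"],
    table: FeatureTable,
    n: int = 10,
    master_seed: int = 0,
    train_fraction: float = 0.7,
    model_name: str = "model",
) -> RunReport:
    """n independent split/train/test cycles with seeds master_seed + run index.

    ``train_fn(train_table, seed)`` must return an object with a
    ``predict(X) -> labels`` method (EnsembleModel) or be wrapped so it does;
    plain ElmModels are handled via their module-level predict.
    """
    if n < 2:
        raise ValueError("need at least 2 runs for a mean +/- std")
    from .elm import ElmModel, predict as _elm_predict

    P = table.n_classes
    runs = []
    for r in range(n):
        seed = master_seed + r
        train, test = split_train_test(table, train_fraction, seed)
        model = train_fn(train, seed)
        if isinstance(model, ElmModel):
            y_pred = _elm_predict(model, test.X)
        else:
            y_pred = model.predict(test.X)
        m = score(test.y, y_pred, P)
        m.seed = seed
        runs.append(m)
    return RunReport(model_name, runs)


@dataclass
class ComparisonReport:
    model_a: str
    model_b: str
    mean_a: float
    mean_b: float
    std_a: float
    std_b: float
    t_pvalue: float
    f_pvalue: float
    alpha: float = 0.05

    @property
    def means_differ(self) -> bool:
        return self.t_pvalue < self.alpha

    @property
    def variances_differ(self) -> bool:
        return self.f_pvalue < self.alpha

    def summary(self) -> str:
        t_verdict = "differ" if self.means_differ else "are consistent"
        f_verdict = "differs" if self.variances_differ else "is consistent"
        return (
            f"{self.model_a} vs {self.model_b}: "
            f"means {self.mean_a:.4f} vs {self.mean_b:.4f} {t_verdict} "
            f"(t-test p={self.t_pvalue:.4g}); stability {f_verdict} "
            f"(F-test p={self.f_pvalue:.4g}) at alpha={self.alpha}"
        )


def compare_models(
    acc_a: np.ndarray,
    acc_b: np.ndarray,
    names: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
) -> ComparisonReport:
    """Two-sided pooled-variance t-test on the means and two-sided F-test on
    the variance ratio (larger sample variance in the numerator)."""
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per model")

    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        t_p = 1.0 if a.mean() == b.mean() else 0.0
        f_p = float("nan")  # degenerate: no variance on either side
    else:
        t_p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        if va >= vb:
            F, dfn, dfd = va / max(vb, 1e-300), a.size - 1, b.size - 1
        else:
            F, dfn, dfd = vb / max(va, 1e-300), b.size - 1, a.size - 1
        f_p = float(min(1.0, 2.0 * stats.f.sf(F, dfn, dfd)))

    return ComparisonReport(
        model_a=names[0], model_b=names[1],
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        std_a=float(a.std(ddof=1)), std_b=float(b.std(ddof=1)),
        t_pvalue=t_p, f_pvalue=f_p, alpha=alpha,
    )
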