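"""Imbalance-aware evaluation: confusion counts, the six metrics, ROC/AUC,
and bootstrap stratified k-fold cross-validation for tuning.

The positive class is the minority.  bACC = (SENS + SPEC)/2 holds exactly on
every report; AUC uses the midrank (Mann–Whitney) convention so tied scores
contribute half a concordance.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = ("bACC", "AUC", "SENS", "SPEC", "PPV", "NPV")


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclasses.dataclass
class EvalReport:
    """The six metrics plus zero-denominator flags; context = train_cv | test."""

    bACC: float
    AUC: float | None
    SENS: float
    SPEC: float
    PPV: float
    NPV: float
    flags: tuple[str, ...] = ()
    context: str = "test"

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRIC_NAMES}


def metrics(c: ConfusionCounts, context: str = "test") -> EvalReport:
    """SENS/SPEC/PPV/NPV/bACC from confusion counts; zero denominators -> 0 + flag."""
    flags = []

    def safe(num: int, den: int, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    sens = safe(c.tp, c.tp + c.fn, "SENS")
    spec = safe(c.tn, c.tn + c.fp, "SPEC")
    ppv = safe(c.tp, c.tp + c.fp, "PPV")
    npv = safe(c.tn, c.tn + c.fn, "NPV")
    return EvalReport(
        bACC=(sens + spec) / 2.0,
        AUC=None,
        SENS=sens,
        SPEC=spec,
        PPV=ppv,
        NPV=npv,
        flags=tuple(flags),
        context=context,
    )


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC via the midrank/Mann–Whitney identity, plus the ROC staircase.

    Equals the trapezoidal area under the threshold-swept ROC; ties in the
    scores contribute half a concordant pair.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    ranks = stats.rankdata(scores)  # midranks
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] == 0)
    # collapse tied thresholds
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), len(scores) - 1]
    points = np.vstack(
        [
            np.r_[0.0, fps[distinct] / n_neg],
            np.r_[0.0, tps[distinct] / n_pos],
        ]
    ).T
    return float(auc), points


def evaluate_model(model, X, y, threshold: float = 0.0, context: str = "test") -> EvalReport:
    """Confusion-count metrics plus AUC from the model's continuous score."""
    score = model.score(X)
    report = metrics(ConfusionCounts.from_labels(y, (score > threshold).astype(int)), context)
    report.AUC = roc_auc(score, y)[0]
    return report


@dataclasses.dataclass
class CVResult:
    mean: dict
    std: dict
    best_params: dict
    model: object  # refit on the full training set with the winners

    def summary(self) -> dict:
        return {
            m: {"mean": self.mean[m], "std": self.std[m]} for m in METRIC_NAMES
        }


def _stratified_bootstrap(idx: np.ndarray, y: np.ndarray, rng) -> np.ndarray:
    """Bootstrap resample within each class so both classes stay present."""
    out = []
    for cls in np.unique(y[idx]):
        members = idx[y[idx] == cls]
        out.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(out)


def bootstrap_kfold_cv(
    trainer: Callable,
    X,
    y,
    k: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
    param_grid: dict | None = None,
    bootstrap: bool = True,
    threshold: float = 0.0,
) -> CVResult:
    """Stratified k-fold CV with within-fold bootstrap resampling.

    ``trainer(X, y, seed=..., **params) -> model`` with a ``.score`` method.
    Per repeat, each training fold is bootstrap-resampled (stratified, same
    size) before fitting; metrics are computed on the held-out fold.  When a
    ``param_grid`` is given, every combination is cross-validated and the one
    with the best mean bACC wins; the returned model is refit on the full set
    with the winning parameters.  ``bootstrap=False`` gives plain repeated
    stratified k-fold.
    """
    X = np.asarray(X, dtype=float) if not hasattr(X, "to_numpy") else X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < k:
        raise ValueError(
            f"smallest class has {class_counts.min()} members < k={k}; use a smaller k"
        )
    if k >= len(y):
        raise ValueError("k must be < n (per-fold sensitivity undefined otherwise)")

    grid = [dict()] if not param_grid else [
        dict(zip(param_grid.keys(), combo))
        for combo in itertools.product(*param_grid.values())
    ]

    best = None
    for params in grid:
        rng = np.random.default_rng(seed)
        per_fold = {m: [] for m in METRIC_NAMES}
        for rep in range(n_repeats):
            skf = StratifiedKFold(n_splits=k, shuffle=True,
                                  random_state=int(rng.integers(2**31 - 1)))
            for train_idx, test_idx in skf.split(X, y):
                fit_idx = (
                    _stratified_bootstrap(train_idx, y, rng) if bootstrap else train_idx
                )
                model = trainer(
                    X[fit_idx], y[fit_idx], seed=int(rng.integers(2**31 - 1)), **params
                )
                report = evaluate_model(model, X[test_idx], y[test_idx], threshold)
                for m in METRIC_NAMES:
                    per_fold[m].append(getattr(report, m))
        mean = {m: float(np.mean(v)) for m, v in per_fold.items()}
        std = {m: float(np.std(v)) for m, v in per_fold.items()}
        if best is None or mean["bACC"] > best[0]["bACC"]:
            best = (mean, std, params)
    mean, std, params = best
    final_rng = np.random.default_rng(seed + 1)
    model = trainer(X, y, seed=int(final_rng.integers(2**31 - 1)), **params)
    return CVResult(mean=mean, std=std, best_params=params, model=model)
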