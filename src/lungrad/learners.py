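"""Samplers and classifiers for the imbalanced few-shot comparison.

Positive class is the minority (label 1).  All stochastic operations take an
explicit seed.  Boosting is discrete two-class AdaBoost.M1 with decision-tree
base learners; RUSBoost/SMOTEBoost re-sample inside each boosting round but
keep the boosting weights on the original training samples.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

_EPS = 1e-10


@dataclasses.dataclass
class SamplerSpec:
    method: str = "adasyn"  # adasyn | smote | rus
    ratio: float = 1.0  # target minority:majority ratio
    k: int = 5  # neighbours for the oversamplers
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ratio <= 1:
            raise ValueError("ratio must be in (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclasses.dataclass
class WeakLearnerSpec:
    max_depth: int = 3
    min_leaf: int = 2

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max depth must be >= 1")

    def build(self, random_state: int) -> DecisionTreeClassifier:
        return DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_leaf,
            random_state=random_state,
        )


def _split_classes(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y)
    minority = np.flatnonzero(y == 1)
    majority = np.flatnonzero(y == 0)
    if minority.size == 0 or majority.size == 0:
        raise ValueError("both classes must be present")
    return minority, majority


def _interpolate(X_min: np.ndarray, counts: np.ndarray, k: int, rng) -> np.ndarray:
    """SMOTE-style interpolation: counts[i] synthetics on segments from point i
    to one of its k nearest minority neighbours."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(X_min))).fit(X_min)
    neighbours = nn.kneighbors(X_min, return_distance=False)[:, 1:]
    out = []
    for i, g in enumerate(counts):
        for _ in range(int(g)):
            j = neighbours[i, rng.integers(neighbours.shape[1])]
            lam = rng.random()
            out.append(X_min[i] + lam * (X_min[j] - X_min[i]))
    if not out:
        return np.empty((0, X_min.shape[1]))
    return np.vstack(out)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation proportional to weights, summing exactly to total."""
    if total == 0:
        return np.zeros_like(weights, dtype=int)
    w = weights / weights.sum()
    raw = w * total
    alloc = np.floor(raw).astype(int)
    remainder = total - alloc.sum()
    if remainder > 0:
        order = np.argsort(-(raw - alloc), kind="stable")
        alloc[order[:remainder]] += 1
    return alloc


def _synthetic_total(n_majority: int, n_minority: int, ratio: float) -> int:
    return int(round((n_majority - n_minority) * ratio))


def adasyn(X: np.ndarray, y: np.ndarray, spec: SamplerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive synthetic oversampling of the minority class.

    Per-point allocation is proportional to the fraction of majority points
    among each minority point's k nearest neighbours (in the full dataset);
    synthetics are drawn on segments to random minority neighbours.  Falls
    back to uniform allocation (with a warning) when no minority point has a
    majority neighbour.
    """
    X = np.asarray(X, dtype=float)
    minority, majority = _split_classes(y)
    if minority.size < spec.k + 1:
        raise ValueError(f"need >= {spec.k + 1} minority points for k={spec.k}")
    total = _synthetic_total(majority.size, minority.size, spec.ratio)
    rng = np.random.default_rng(spec.seed)
    nn = NearestNeighbors(n_neighbors=spec.k + 1).fit(X)
    neigh = nn.kneighbors(X[minority], return_distance=False)[:, 1:]
    r = (np.asarray(y)[neigh] == 0).mean(axis=1)
    if r.sum() == 0:
        warnings.warn("no majority neighbours anywhere; uniform ADASYN allocation", stacklevel=2)
        r = np.ones_like(r)
    counts = _largest_remainder(r, total)
    synth = _interpolate(X[minority], counts, spec.k, rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.ones(len(synth), dtype=int)])
    return X_out, y_out


def smote(X: np.ndarray, y: np.ndarray, spec: SamplerSpec) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-allocation minority oversampling by interpolation."""
    X = np.asarray(X, dtype=float)
    minority, majority = _split_classes(y)
    if minority.size < spec.k + 1:
        raise ValueError(f"need >= {spec.k + 1} minority points for k={spec.k}")
    total = _synthetic_total(majority.size, minority.size, spec.ratio)
    rng = np.random.default_rng(spec.seed)
    counts = _largest_remainder(np.ones(minority.size), total)
    synth = _interpolate(X[minority], counts, spec.k, rng)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.ones(len(synth), dtype=int)])
    return X_out, y_out


def random_undersample(
    X: np.ndarray, y: np.ndarray, spec: SamplerSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample the majority without replacement to the target ratio."""
    X = np.asarray(X, dtype=float)
    minority, majority = _split_classes(y)
    target = int(round(minority.size / spec.ratio))
    if target > majority.size:
        raise ValueError(
            f"infeasible ratio {spec.ratio}: needs {target} majority, have {majority.size}"
        )
    rng = np.random.default_rng(spec.seed)
    keep_maj = rng.choice(majority, size=target, replace=False)
    keep = np.sort(np.concatenate([minority, keep_maj]))
    return X[keep], np.asarray(y)[keep]


# ---------------------------------------------------------------------------
# boosting


@dataclasses.dataclass
class BoostedEnsemble:
    """Weak learners with vote weights; score = signed margin for class 1."""

    members: list  # trained weak learners with .predict
    alphas: list[float]
    feature_names: tuple[str, ...] | None = None
    early_stop: bool = False
    weight_sums: list[float] = dataclasses.field(default_factory=list)

    def score(self, X) -> np.ndarray:
        X = self._check(X)
        total = np.zeros(len(X))
        for h, a in zip(self.members, self.alphas):
            total += a * (2.0 * h.predict(X) - 1.0)
        return total

    def predict(self, X, threshold: float = 0.0) -> np.ndarray:
        return (self.score(X) > threshold).astype(int)

    def _check(self, X) -> np.ndarray:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None and tuple(X.columns) != tuple(self.feature_names):
                raise ValueError("feature names do not match training columns")
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


def _boost(
    X: np.ndarray,
    y: np.ndarray,
    T: int,
    weak: WeakLearnerSpec,
    seed: int,
    round_data,
    feature_names=None,
    stochastic_rounds: bool = False,
) -> BoostedEnsemble:
    """Shared AdaBoost.M1 loop; ``round_data(rng, w)`` yields the fitting set.

    ``round_data`` returns (X_fit, y_fit, w_fit); the weighted error and the
    weight update always use the full original training set.  A round whose
    weighted error reaches 0.5 is rejected; with deterministic round data
    (plain AdaBoost) that ends training, while with ``stochastic_rounds``
    (per-round re-sampling) the round is simply redrawn, up to a bounded
    number of consecutive rejections.
    """
    n = len(y)
    w = np.full(n, 1.0 / n)
    members: list = []
    alphas: list[float] = []
    weight_sums: list[float] = []
    early = False
    max_consecutive_rejections = 20
    rejected = 0
    rng = np.random.default_rng(seed)
    t = 0
    while t < T:
        t += 1
        X_fit, y_fit, w_fit = round_data(rng, w)
        tree = weak.build(random_state=int(rng.integers(2**31 - 1)))
        tree.fit(X_fit, y_fit, sample_weight=w_fit)
        pred = tree.predict(X)
        miss = pred != y
        eps = float(w[miss].sum())
        if eps >= 0.5:
            if stochastic_rounds:
                rejected += 1
                if rejected >= max_consecutive_rejections:
                    early = True
                    break
                continue  # redraw the round's sample
            if not members:
                warnings.warn("weak learner cannot beat chance; single-member ensemble",
                              stacklevel=2)
                members.append(tree)
                alphas.append(0.0)
            early = True
            break
        rejected = 0
        eps = max(eps, _EPS)
        alpha = 0.5 * np.log((1.0 - eps) / eps)
        members.append(tree)
        alphas.append(float(alpha))
        if eps <= _EPS:
            early = True
            break
        w = w * np.exp(np.where(miss, alpha, -alpha))
        w /= w.sum()
        weight_sums.append(float(w.sum()))
    return BoostedEnsemble(members, alphas, feature_names, early, weight_sums)


def _as_array(X):
    import pandas as pd

    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    return np.asarray(X, dtype=float), None


def train_adaboost(
    X, y, T: int = 100, weak: WeakLearnerSpec | None = None, seed: int = 0
) -> BoostedEnsemble:
    """Discrete two-class AdaBoost.M1 with decision-tree base learners."""
    X, names = _as_array(X)
    y = np.asarray(y)
    _split_classes(y)
    if T < 1:
        raise ValueError("T must be >= 1")
    weak = weak or WeakLearnerSpec()

    def round_data(rng, w):
        return X, y, w * len(y)

    return _boost(X, y, T, weak, seed, round_data, names)


def train_rusboost(
    X,
    y,
    T: int = 100,
    weak: WeakLearnerSpec | None = None,
    sampler_ratio: float = 1.0,
    seed: int = 0,
) -> BoostedEnsemble:
    """AdaBoost.M1 with per-round random undersampling of the majority.

    Each round fits its tree on all minority samples plus a random majority
    subset at ``sampler_ratio``, weighted by the current boosting weights;
    error and weight updates use the full training set.
    """
    X, names = _as_array(X)
    y = np.asarray(y)
    minority, majority = _split_classes(y)
    if minority.size < 2:
        raise ValueError("need >= 2 minority samples")
    weak = weak or WeakLearnerSpec()
    target = min(int(round(minority.size / sampler_ratio)), majority.size)

    def round_data(rng, w):
        # undersample the majority from the current weighted distribution;
        # the draw itself encodes the boosting weights, so the reduced set is
        # fitted flat (boosting-by-resampling on the majority side)
        p = w[majority] / w[majority].sum()
        keep_maj = rng.choice(majority, size=target, replace=False, p=p)
        keep = np.concatenate([minority, keep_maj])
        return X[keep], y[keep], np.ones(len(keep))

    return _boost(X, y, T, weak, seed, round_data, names, stochastic_rounds=True)


def train_smoteboost(
    X,
    y,
    T: int = 100,
    weak: WeakLearnerSpec | None = None,
    k: int = 5,
    seed: int = 0,
) -> BoostedEnsemble:
    """AdaBoost.M1 with per-round SMOTE of the minority.

    Synthetics exist only inside each round's fit; the boosting weight vector
    stays on the original samples.
    """
    X, names = _as_array(X)
    y = np.asarray(y)
    minority, majority = _split_classes(y)
    if minority.size < k + 1:
        raise ValueError(f"need >= {k + 1} minority samples for k={k}")
    weak = weak or WeakLearnerSpec()
    total = majority.size - minority.size

    def round_data(rng, w):
        counts = _largest_remainder(np.ones(minority.size), total)
        synth = _interpolate(X[minority], counts, k, rng)
        X_fit = np.vstack([X, synth])
        y_fit = np.concatenate([y, np.ones(len(synth), dtype=int)])
        w_min_mean = w[minority].mean()
        w_fit = np.concatenate([w, np.full(len(synth), w_min_mean)])
        w_fit = w_fit / w_fit.sum() * len(w_fit)
        return X_fit, y_fit, w_fit

    return _boost(X, y, T, weak, seed, round_data, names, stochastic_rounds=True)


# ---------------------------------------------------------------------------
# margin classifiers


@dataclasses.dataclass
class MarginClassifier:
    """RBF-kernel maximum-margin classifier with optional class cost ratio."""

    svc: SVC
    feature_names: tuple[str, ...] | None = None
    cost_ratio: float = 1.0

    def score(self, X) -> np.ndarray:
        X = self._check(X)
        return self.svc.decision_function(X)

    def predict(self, X, threshold: float = 0.0) -> np.ndarray:
        return (self.score(X) > threshold).astype(int)

    def _check(self, X) -> np.ndarray:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            if self.feature_names is not None and tuple(X.columns) != tuple(self.feature_names):
                raise ValueError("feature names do not match training columns")
            X = X.to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


def train_margin_classifier(
    X,
    y,
    cost_ratio: float = 1.0,
    C: float = 1.0,
    gamma: str | float = "scale",
    kernel: str = "rbf",
    seed: int = 0,
) -> MarginClassifier:
    """SVM with per-class penalties C+ = C*cost_ratio (minority), C- = C.

    ``cost_ratio=1`` is the plain variant; the decision value is exposed for
    ROC construction.
    """
    X, names = _as_array(X)
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs >= 2 samples for a margin classifier")
    svc = SVC(
        C=C,
        kernel=kernel,
        gamma=gamma,
        class_weight={0: 1.0, 1: float(cost_ratio)},
        random_state=seed,
    )
    svc.fit(X, y)
    return MarginClassifier(svc=svc, feature_names=names, cost_ratio=float(cost_ratio))


def predict_score(model, X) -> np.ndarray:
    """Continuous positive-class score (ensemble margin / decision value)."""
    return model.score(X)


def predict_label(model, X, threshold: float = 0.0) -> np.ndarray:
    return (predict_score(model, X) > threshold).astype(int)


# ---------------------------------------------------------------------------
# serialization


def _tree_to_dict(tree: DecisionTreeClassifier) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value[:, 0, :].tolist(),
        "classes": tree.classes_.tolist(),
    }


class _SerializedTree:
    def __init__(self, d: dict):
        self.left = np.asarray(d["children_left"])
        self.right = np.asarray(d["children_right"])
        self.feature = np.asarray(d["feature"])
        self.threshold = np.asarray(d["threshold"])
        self.value = np.asarray(d["value"])
        self.classes = np.asarray(d["classes"])

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X), dtype=self.classes.dtype)
        for i, x in enumerate(X):
            node = 0
            while self.left[node] != -1:
                node = (
                    self.left[node]
                    if x[self.feature[node]] <= self.threshold[node]
                    else self.right[node]
                )
            out[i] = self.classes[int(np.argmax(self.value[node]))]
        return out


def ensemble_to_json(model: BoostedEnsemble) -> str:
    return json.dumps(
        {
            "kind": "boosted_ensemble",
            "alphas": model.alphas,
            "feature_names": list(model.feature_names) if model.feature_names else None,
            "early_stop": model.early_stop,
            "trees": [_tree_to_dict(h) for h in model.members],
        }
    )


def ensemble_from_json(payload: str) -> BoostedEnsemble:
    d = json.loads(payload)
    if d.get("kind") != "boosted_ensemble":
        raise ValueError("not a serialized boosted ensemble")
    members = [_SerializedTree(td) for td in d["trees"]]
    names = tuple(d["feature_names"]) if d["feature_names"] else None
    return BoostedEnsemble(members, d["alphas"], names, d["early_stop"])
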