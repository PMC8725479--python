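"""Feature-table assembly, train-bound normalization, screening, selection.

The table has 382 columns: the two clinical covariates (GA continuous, GDM
categorical) followed by 380 continuous radiomics features.  Normalization
bounds, p-values and the importance ranking are all computed on the training
partition only.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .radiomics.registry import ALL_FEATURE_NAMES, CLINICAL_NAMES, RADIOMICS_NAMES

POSITIVE_LABEL = "NRM"


class ColumnMismatchError(ValueError):
    pass


@dataclasses.dataclass
class FeatureTable:
    """Subjects x features matrix with labels and per-feature kinds."""

    data: pd.DataFrame
    labels: pd.Series  # values in {"NRM", "normal"}
    kinds: dict  # name -> "continuous" | "categorical"
    norm_bounds: pd.DataFrame | None = None  # per-feature (min, max), train provenance

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.labels.index):
            raise ValueError("data and labels must share an index")
        missing = set(self.data.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"kinds missing for columns: {sorted(missing)[:5]} ...")

    @property
    def y(self) -> np.ndarray:
        return (self.labels == POSITIVE_LABEL).to_numpy(dtype=int)

    def continuous_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == "continuous"]

    def radiomics_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in set(RADIOMICS_NAMES)]

    def subset(self, index) -> "FeatureTable":
        return FeatureTable(
            self.data.loc[index], self.labels.loc[index], self.kinds, self.norm_bounds
        )


def assemble_table(
    radiomics: pd.DataFrame,
    clinical: pd.DataFrame,
    labels: pd.Series,
    drop_degenerate: bool = True,
) -> FeatureTable:
    """Join clinical covariates (ga, gdm) with the radiomics block.

    ``radiomics`` may carry a boolean ``degenerate`` column; flagged subjects
    are dropped by default.
    """
    rad = radiomics.copy()
    if "degenerate" in rad.columns:
        flags = rad.pop("degenerate").astype(bool)
        if drop_degenerate and flags.any():
            rad = rad.loc[~flags]
    keep = rad.index
    data = pd.concat([clinical.loc[keep, list(CLINICAL_NAMES)], rad], axis=1)
    if tuple(data.columns) != ALL_FEATURE_NAMES:
        raise ColumnMismatchError("assembled columns do not match the registry order")
    kinds = {name: "continuous" for name in ALL_FEATURE_NAMES}
    kinds["gdm"] = "categorical"
    return FeatureTable(data=data, labels=labels.loc[keep], kinds=kinds)


def normalize_features(train: FeatureTable, apply_to: FeatureTable) -> FeatureTable:
    """Min–max scale continuous columns using *train* bounds; no clipping.

    Test values outside the train range may map outside [0, 1] — the bounds
    of unseen samples are unknown in deployment, so they are not clipped.
    Constant train columns map to 0; categorical columns pass through.
    """
    if list(train.data.columns) != list(apply_to.data.columns):
        diff = set(train.data.columns) ^ set(apply_to.data.columns)
        raise ColumnMismatchError(f"column mismatch: {sorted(diff)[:10]}")
    lo = train.data.min(axis=0)
    hi = train.data.max(axis=0)
    out = apply_to.data.copy()
    for col in train.continuous_columns():
        span = hi[col] - lo[col]
        if span == 0:
            out[col] = 0.0
        else:
            out[col] = (out[col] - lo[col]) / span
    bounds = pd.DataFrame({"min": lo, "max": hi})
    bounds.attrs["provenance"] = "train"
    return FeatureTable(out, apply_to.labels.copy(), dict(apply_to.kinds), bounds)


def univariate_screen(table: FeatureTable, alpha: float = 0.05, welch: bool = True,
                      yates: bool = False) -> pd.DataFrame:
    """Per-feature p-values: Welch t-test (continuous), chi-square (categorical).

    Report-only: selection does not consume these.  Columns: ``p``,
    ``significant`` (p < alpha), ``flagged`` (degenerate: zero within-class
    variance in both groups -> p = 1).
    """
    y = table.y.astype(bool)
    records = {}
    cont = table.continuous_columns()
    if cont:
        a = table.data.loc[y, cont].to_numpy(dtype=float)
        b = table.data.loc[~y, cont].to_numpy(dtype=float)
        res = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
        pvals = np.asarray(res.pvalue, dtype=float)
        degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
        pvals = np.where(degenerate, 1.0, pvals)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        for col, p, flag in zip(cont, pvals, degenerate):
            records[col] = (float(p), bool(flag))
    for col in table.data.columns:
        if table.kinds[col] != "categorical":
            continue
        contingency = pd.crosstab(table.data[col], table.labels)
        if contingency.shape[0] < 2 or contingency.shape[1] < 2:
            records[col] = (1.0, True)
            continue
        _, p, _, _ = stats.chi2_contingency(contingency.to_numpy(), correction=yates)
        records[col] = (float(p), False)
    out = pd.DataFrame.from_dict(records, orient="index", columns=["p", "flagged"])
    out = out.loc[list(table.data.columns)]
    out["significant"] = out["p"] < alpha
    return out


@dataclasses.dataclass
class ImportanceRanking:
    """OOB permutation importances with a deterministic rank order."""

    scores: pd.Series  # per-feature importance, index = feature names
    order: list[str]  # descending importance, ties broken by column index
    n_trees: int
    seed: int
    per_tree: np.ndarray | None = None  # (n_trees, n_features) raw error increases


def rf_oob_importance(
    table: FeatureTable,
    n_trees: int = 500,
    seed: int = 0,
    max_features: str | float = "sqrt",
    normalize: bool = True,
) -> ImportanceRanking:
    """Permutation importance on out-of-bag samples of a bootstrap forest.

    For each of ``n_trees`` trees grown on a bootstrap sample, the OOB error
    is computed before and after permuting each feature's OOB values; the
    importance is the mean error increase over trees, divided by its standard
    deviation across trees when ``normalize`` (scores feed a ranking only, so
    the normalization cannot change selected sets except through ties).
    """
    import warnings

    if n_trees < 50:
        warnings.warn("n_trees < 50 gives an unstable ranking", stacklevel=2)
    X = table.data.to_numpy(dtype=float)
    y = table.y
    n, d = X.shape
    if d < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    increases = np.full((n_trees, d), np.nan)
    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        X_oob = X[oob]
        y_oob = y[oob]
        base_err = float((tree.predict(X_oob) != y_oob).mean())
        for f in range(d):
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, f] = X_oob[perm, f]
            increases[t, f] = float((tree.predict(X_perm) != y_oob).mean()) - base_err
    mean_inc = np.nanmean(increases, axis=0)
    if normalize:
        sd = np.nanstd(increases, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(sd > 0, mean_inc / sd, mean_inc)
    else:
        scores = mean_inc
    series = pd.Series(scores, index=table.data.columns)
    # stable sort: descending score, ties broken by column position
    order = sorted(
        range(d), key=lambda k: (-series.iloc[k], k)
    )
    return ImportanceRanking(
        scores=series,
        order=[table.data.columns[k] for k in order],
        n_trees=n_trees,
        seed=seed,
        per_tree=increases,
    )


def select_top_k(
    ranking: ImportanceRanking,
    k: int = 10,
    restrict_to: Sequence[str] | None = None,
) -> list[str]:
    """Top-k features by importance, restricted to radiomics names by default.

    Clinical covariates are appended downstream unconditionally, so they are
    never part of the ranked selection.
    """
    pool = set(RADIOMICS_NAMES) if restrict_to is None else set(restrict_to)
    candidates = [name for name in ranking.order if name in pool]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds {len(candidates)} candidate features")
    return candidates[:k]
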