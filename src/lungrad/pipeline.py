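"""End-to-end experiment grids from one config.

Simulate (or ingest) -> preprocess -> extract -> select -> train each
method-regime -> evaluate -> report.  The method grid covers seven regimes
(plain SVM / AdaBoost / cost-sensitive SVM on the imbalanced set, SVM /
AdaBoost on the ADASYN-balanced set, SMOTEBoost and RUSBoost); the
feature-set grid covers clinical-only ablations and the full feature set on
irregular and square ROIs.  Everything is deterministic under the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import learners
from .evaluate import METRIC_NAMES, bootstrap_kfold_cv, evaluate_model
from .preprocess import MaskedImage, read_image_and_mask
from .radiomics import ExtractionConfig, extract_cohort
from .select import (
    FeatureTable,
    assemble_table,
    normalize_features,
    rf_oob_importance,
    select_top_k,
    univariate_screen,
)
from .synthdata import CohortSpec, generate_cohort, generate_roi_mask, stratified_split

log = logging.getLogger("lungrad")

METHOD_GRID = (
    ("svm", "original"),
    ("adaboost", "original"),
    ("cost_svm", "original"),
    ("svm", "adasyn"),
    ("adaboost", "adasyn"),
    ("smoteboost", "original"),
    ("rusboost", "original"),
)

FEATURE_SETS = ("ga", "ga_gdm", "full_irregular", "full_square")


class CVSettings(BaseModel):
    k: int = 5
    n_repeats: int = 2
    bootstrap: bool = True


class ExperimentConfig(BaseModel):
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    manifest: str | None = None  # ingest a written cohort instead of simulating
    test_fraction: float = 0.2
    selection_k: int = 10
    importance_trees: int = 100
    boosting_rounds: int = 50
    tree_depth: int = 3
    outlier_sigma: float = 3.0
    cv: CVSettings = Field(default_factory=CVSettings)
    seed: int = 0
    out_dir: str = "results"


def _method_trainer(method: str, regime: str, T: int, depth: int, n_min: int, n_maj: int):
    weak = learners.WeakLearnerSpec(max_depth=depth)

    def balance(X, y, seed):
        spec = learners.SamplerSpec(method="adasyn", seed=seed)
        return learners.adasyn(X, y, spec)

    if method == "svm" and regime == "original":
        return lambda X, y, seed: learners.train_margin_classifier(X, y, seed=seed)
    if method == "cost_svm":
        ratio = n_maj / n_min
        return lambda X, y, seed: learners.train_margin_classifier(
            X, y, cost_ratio=ratio, seed=seed
        )
    if method == "svm" and regime == "adasyn":
        def t(X, y, seed):
            Xb, yb = balance(X, y, seed)
            return learners.train_margin_classifier(Xb, yb, seed=seed)

        return t
    if method == "adaboost" and regime == "original":
        return lambda X, y, seed: learners.train_adaboost(X, y, T=T, weak=weak, seed=seed)
    if method == "adaboost" and regime == "adasyn":
        def t(X, y, seed):
            Xb, yb = balance(X, y, seed)
            return learners.train_adaboost(Xb, yb, T=T, weak=weak, seed=seed)

        return t
    if method == "smoteboost":
        return lambda X, y, seed: learners.train_smoteboost(X, y, T=T, weak=weak, seed=seed)
    if method == "rusboost":
        return lambda X, y, seed: learners.train_rusboost(X, y, T=T, weak=weak, seed=seed)
    raise ValueError(f"unknown method-regime {method}/{regime}")


@dataclasses.dataclass
class ExperimentResult:
    method_table: pd.DataFrame  # 7 method-regimes x metrics
    feature_set_table: pd.DataFrame  # 4 feature sets x metrics
    selected_features: list[str]
    screening: pd.DataFrame
    provenance: dict


def _load_cohort(config: ExperimentConfig):
    if config.manifest:
        manifest = pd.read_csv(config.manifest)
        base = Path(config.manifest).parent
        subjects = []
        from .synthdata import SyntheticSubject

        for rec in manifest.itertuples():
            img = read_image_and_mask(base / rec.image_path, base / rec.mask_path)
            subjects.append(
                SyntheticSubject(
                    subject_id=rec.subject_id,
                    image=img,
                    label=rec.label,
                    ga=float(rec.ga),
                    gdm=int(rec.gdm),
                )
            )
        return subjects
    return generate_cohort(config.cohort)


def _square_view(subject, seed) -> MaskedImage:
    """The same pixels re-delineated with a square ROI of comparable area."""
    mask = generate_roi_mask(subject.image.pixels.shape, "square", seed)
    return MaskedImage(pixels=subject.image.pixels, mask=mask)


def _feature_matrix(table: FeatureTable, selected: list[str], feature_set: str) -> pd.DataFrame:
    if feature_set == "ga":
        return table.data[["ga"]]
    if feature_set == "ga_gdm":
        return table.data[["ga", "gdm"]]
    return table.data[["ga", "gdm"] + selected]


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.resolved.json").write_text(config.model_dump_json(indent=2))

    log.info("generating cohort (n=%d)", config.cohort.n_total)
    subjects = _load_cohort(config)
    train_subj, test_subj = stratified_split(subjects, config.test_fraction, config.seed)
    log.info("split: %d train / %d test", len(train_subj), len(test_subj))

    extraction = ExtractionConfig(outlier_sigma=config.outlier_sigma)
    square_rng = np.random.SeedSequence(config.seed + 1).spawn(len(subjects))
    square_seed = {s.subject_id: square_rng[i] for i, s in enumerate(subjects)}

    def build_tables(mask_kind: str):
        def view(s):
            if mask_kind == "square":
                return _square_view(s, np.random.default_rng(square_seed[s.subject_id]))
            return s.image

        frames = {}
        for part, subs in (("train", train_subj), ("test", test_subj)):
            rad = extract_cohort(((s.subject_id, view(s)) for s in subs), extraction)
            clin = pd.DataFrame(
                {"ga": [s.ga for s in subs], "gdm": [s.gdm for s in subs]},
                index=[s.subject_id for s in subs],
            )
            labels = pd.Series([s.label for s in subs], index=clin.index)
            frames[part] = assemble_table(rad, clin, labels)
        return frames["train"], frames["test"]

    log.info("extracting radiomics features (irregular ROI)")
    train_irr, test_irr = build_tables("irregular")
    norm_train = normalize_features(train_irr, train_irr)
    norm_test = normalize_features(train_irr, test_irr)

    screening = univariate_screen(norm_train)
    ranking = rf_oob_importance(norm_train, n_trees=config.importance_trees, seed=config.seed)
    selected = select_top_k(ranking, k=config.selection_k)
    log.info("selected features: %s", selected)

    y_train = norm_train.y
    y_test = norm_test.y
    n_min = int(y_train.sum())
    n_maj = len(y_train) - n_min

    def run_model(method, regime, X_train, X_test):
        trainer = _method_trainer(
            method, regime, config.boosting_rounds, config.tree_depth, n_min, n_maj
        )
        cv = bootstrap_kfold_cv(
            trainer,
            X_train,
            y_train,
            k=config.cv.k,
            n_repeats=config.cv.n_repeats,
            seed=config.seed,
            bootstrap=config.cv.bootstrap,
        )
        test_report = evaluate_model(cv.model, X_test.to_numpy(dtype=float), y_test)
        row = {}
        for m in METRIC_NAMES:
            row[f"train_{m}_mean"] = cv.mean[m]
            row[f"train_{m}_std"] = cv.std[m]
            row[f"test_{m}"] = getattr(test_report, m)
        return row

    X_train_full = _feature_matrix(norm_train, selected, "full")
    X_test_full = _feature_matrix(norm_test, selected, "full")

    method_rows = {}
    for method, regime in METHOD_GRID:
        key = f"{method}[{regime}]"
        log.info("method grid: %s", key)
        method_rows[key] = run_model(method, regime, X_train_full, X_test_full)
    method_table = pd.DataFrame.from_dict(method_rows, orient="index")

    fs_rows = {}
    for fs in FEATURE_SETS:
        log.info("feature-set grid: %s", fs)
        if fs == "full_square":
            train_sq, test_sq = build_tables("square")
            norm_train_sq = normalize_features(train_sq, train_sq)
            norm_test_sq = normalize_features(train_sq, test_sq)
            ranking_sq = rf_oob_importance(
                norm_train_sq, n_trees=config.importance_trees, seed=config.seed
            )
            selected_sq = select_top_k(ranking_sq, k=config.selection_k)
            X_tr = _feature_matrix(norm_train_sq, selected_sq, "full")
            X_te = _feature_matrix(norm_test_sq, selected_sq, "full")
        else:
            X_tr = _feature_matrix(norm_train, selected, fs)
            X_te = _feature_matrix(norm_test, selected, fs)
        fs_rows[fs] = run_model("rusboost", "original", X_tr, X_te)
    feature_set_table = pd.DataFrame.from_dict(fs_rows, orient="index")

    provenance = {
        "seed": config.seed,
        "train_counts": {"total": len(train_subj), "minority": n_min},
        "test_counts": {"total": len(test_subj), "minority": int(y_test.sum())},
        "selected_features": selected,
        "normalization_bounds": {
            "min": norm_train.norm_bounds["min"].to_dict() if norm_train.norm_bounds is not None else None,
        },
        "n_significant_features": int(screening["significant"].sum()),
    }

    method_table.to_csv(out_dir / "method_grid.csv")
    feature_set_table.to_csv(out_dir / "feature_set_grid.csv")
    screening.to_csv(out_dir / "screening.csv")
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return ExperimentResult(
        method_table=method_table,
        feature_set_table=feature_set_table,
        selected_features=selected,
        screening=screening,
        provenance=provenance,
    )
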