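"""Classifier fitting, metrics, cross-validation, grid search and ranking."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .containers import AssociationMatrix, PairSet, SimilarityMatrix, TreeNumberMap
from .data_io import Config
from .encoding import EncoderSpec, build_feature_views, combine_features, encode_all
from .sampling import (
    SamplingPlan,
    assemble_training_set,
    build_pair_universe,
    kmeans_negative_sample,
    pair_cluster_features,
)
from .similarity import transformed_similarities

__all__ = [
    "ClassifierSpec",
    "CVReport",
    "RankingTable",
    "register_classifier",
    "fit_classifier",
    "compute_metrics",
    "kfold_cv",
    "grid_search",
    "repeat_experiments",
    "fit_full_model",
    "rank_disease_candidates",
    "ablation_run",
    "format_mean_sd",
]

METRIC_NAMES = ("AUC", "AUPR", "F1", "ACC", "MCC")


@dataclass
class ClassifierSpec:
    """Pluggable classifier seam; only logistic regression ships by default."""

    type: str = "logistic-regression"
    strength: float = 1.0          # inverse regularization (L2)
    max_iter: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.type not in _CLASSIFIERS:
            raise ValueError(
                f"unsupported classifier {self.type!r}; registered: {sorted(_CLASSIFIERS)}"
            )
        if self.strength <= 0:
            raise ValueError("regularization strength must be > 0")


def _make_logistic_regression(spec: ClassifierSpec):
    return LogisticRegression(
        C=spec.strength, max_iter=spec.max_iter, random_state=spec.seed
    )


_CLASSIFIERS: dict[str, Callable[[ClassifierSpec], object]] = {
    "logistic-regression": _make_logistic_regression,
}


def register_classifier(name: str, factory: Callable[[ClassifierSpec], object]) -> None:
    """Register an alternate scikit-learn-style classifier factory."""
    _CLASSIFIERS[name] = factory


class FittedModel:
    """Fitted classifier exposing a probability score in [0, 1]."""

    def __init__(self, estimator) -> None:
        self.estimator = estimator

    def score_pairs(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)[:, 1]


def fit_classifier(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec | None = None
) -> FittedModel:
    spec = spec or ClassifierSpec()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    estimator = _CLASSIFIERS[spec.type](spec)
    estimator.fit(X, y)
    return FittedModel(estimator)


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """AUC, AUPR and thresholded F1/ACC/MCC for one score/label set."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class; metrics undefined")
    pred = (scores >= threshold).astype(int)
    return {
        "AUC": float(roc_auc_score(labels, scores)),
        "AUPR": float(average_precision_score(labels, scores)),
        "F1": float(f1_score(labels, pred, zero_division=0)),
        "ACC": float(accuracy_score(labels, pred)),
        "MCC": float(matthews_corrcoef(labels, pred)),
    }


@dataclass
class CVReport:
    """Per-fold and pooled cross-validation metrics plus run parameters."""

    fold_metrics: list[dict[str, float]]
    pooled: dict[str, float]
    fold_sizes: list[int]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def mean(self) -> dict[str, float]:
        return {
            name: float(np.mean([fm[name] for fm in self.fold_metrics]))
            for name in METRIC_NAMES
        }

    def summary(self) -> str:
        mean = self.mean
        lines = [f"{len(self.fold_metrics)}-fold CV (seed={self.seed})"]
        for name in METRIC_NAMES:
            lines.append(f"  {name}: pooled={self.pooled[name]:.4f} fold-mean={mean[name]:.4f}")
        return "\n".join(lines)


@dataclass
class RankingTable:
    """Ranked unknown-pair candidates for one disease."""

    disease: str
    rows: list[tuple[int, str, float]]  # (rank, miRNA-id, score), descending score

    def top(self, n: int) -> "RankingTable":
        return RankingTable(self.disease, self.rows[:n])


# ---------------------------------------------------------------------------
# pipeline assembly


def _classifier_spec(config: Config, seed: int) -> ClassifierSpec:
    return ClassifierSpec(
        type=config.classifier, strength=config.lr_strength,
        max_iter=config.max_iter, seed=seed,
    )


def _encoder_spec(config: Config, seed: int) -> EncoderSpec:
    return EncoderSpec(
        latent_dim=config.L, hidden=config.hidden, batch_size=config.batch_size,
        epochs=config.epochs, learning_rate=config.learning_rate, seed=seed,
    )


def _similarities(A: AssociationMatrix, FM, tree_map, config: Config):
    return transformed_similarities(
        A, FM, tree_map,
        c=config.c, transform=config.transform,
        gamma_prime=config.gamma_prime, delta=config.delta,
        log_base=config.log_base,
    )


def prepare_training_data(
    A: AssociationMatrix,
    config: Config,
    FM: SimilarityMatrix | None = None,
    tree_map: TreeNumberMap | None = None,
    sample_seed: int | None = None,
):
    """Similarities -> negative sampling -> latent encoding -> pair features.

    Returns (training PairSet, feature matrix, latent dict, (Msim, Dsim)).
    """
    seed = config.seed if sample_seed is None else sample_seed
    Msim, Dsim = _similarities(A, FM, tree_map, config)
    positives, negatives = build_pair_universe(A)
    features = pair_cluster_features(negatives, Msim, Dsim)
    plan = SamplingPlan(
        k_clusters=config.k_clusters, per_cluster=config.per_cluster, seed=seed,
        n_init=config.kmeans_n_init, algorithm=config.kmeans_algorithm,
    )
    sampled = kmeans_negative_sample(negatives, features, plan)
    training = assemble_training_set(positives, sampled, seed=seed)
    views = build_feature_views(A, Msim, Dsim)
    latents = encode_all(views, _encoder_spec(config, seed))
    X = combine_features(training, latents, mode=config.feature_mode)
    return training, X, latents, (Msim, Dsim)


def _masked_latents(A, test_pairs, test_labels, FM, tree_map, config, seed):
    """Leakage-safe per-fold views: zero the test-fold positives in A first."""
    A_fold = A.copy()
    pos = test_pairs[test_labels == 1]
    A_fold.values[pos[:, 0], pos[:, 1]] = 0
    Msim, Dsim = _similarities(A_fold, FM, tree_map, config)
    views = build_feature_views(A_fold, Msim, Dsim)
    return encode_all(views, _encoder_spec(config, seed))


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    """Stratified split; re-draw (new seed) if a fold degenerates to one class."""
    for attempt in range(10):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(splitter.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2 for tr, te in splits):
            return splits
    raise ValueError("could not build folds with both classes present")


def kfold_cv(
    A: AssociationMatrix,
    config: Config,
    FM: SimilarityMatrix | None = None,
    tree_map: TreeNumberMap | None = None,
    sample_seed: int | None = None,
) -> CVReport:
    """Full pipeline under stratified k-fold cross-validation.

    Headline metrics are computed on the pooled held-out scores; per-fold
    metrics (and their mean) are reported alongside.
    """
    training, X, latents, _ = prepare_training_data(A, config, FM, tree_map, sample_seed)
    y = training.labels.astype(int)
    splits = _stratified_folds(y, config.folds, config.seed)
    pooled_scores = np.empty(len(y))
    fold_metrics = []
    fold_sizes = []
    for tr_idx, te_idx in splits:
        if config.leakage_safe:
            fold_latents = _masked_latents(
                A, training.pairs[te_idx], y[te_idx], FM, tree_map, config, config.seed
            )
            X_tr = combine_features(training.subset(tr_idx), fold_latents, config.feature_mode)
            X_te = combine_features(training.subset(te_idx), fold_latents, config.feature_mode)
        else:
            X_tr, X_te = X[tr_idx], X[te_idx]
        model = fit_classifier(X_tr, y[tr_idx], _classifier_spec(config, config.seed))
        scores = model.score_pairs(X_te)
        pooled_scores[te_idx] = scores
        fold_metrics.append(compute_metrics(scores, y[te_idx], config.threshold))
        fold_sizes.append(len(te_idx))
    pooled = compute_metrics(pooled_scores, y, config.threshold)
    params = {
        "c": config.c, "L": config.L, "k_clusters": config.k_clusters,
        "per_cluster": config.per_cluster, "folds": config.folds,
        "feature_mode": config.feature_mode, "transform": config.transform,
    }
    return CVReport(fold_metrics, pooled, fold_sizes, config.seed, params)


def grid_search(
    A: AssociationMatrix,
    config: Config,
    c_grid: Sequence[float],
    L_grid: Sequence[int],
    FM: SimilarityMatrix | None = None,
    tree_map: TreeNumberMap | None = None,
    repeats: int = 1,
) -> tuple[tuple[float, int], list[dict]]:
    """Mean fold AUC over a (c, L) grid; returns the argmax and the table."""
    if not c_grid or not L_grid:
        raise ValueError("grids must be non-empty")
    table = []
    for c in c_grid:
        for L in L_grid:
            cfg = dataclasses.replace(config, c=float(c), L=int(L))
            aucs = []
            for r in range(repeats):
                report = kfold_cv(
                    A, dataclasses.replace(cfg, seed=cfg.seed + r), FM, tree_map
                )
                aucs.append(report.mean["AUC"])
            table.append({
                "c": float(c), "L": int(L),
                "mean_AUC": float(np.mean(aucs)), "sd_AUC": float(np.std(aucs)),
            })
    best = max(table, key=lambda row: row["mean_AUC"])
    return (best["c"], best["L"]), table


def repeat_experiments(
    A: AssociationMatrix,
    config: Config,
    n_repeats: int = 10,
    FM: SimilarityMatrix | None = None,
    tree_map: TreeNumberMap | None = None,
) -> dict:
    """Repeat CV with fresh seeds; report mean and sd per metric.

    Negatives are re-drawn per repeat unless ``config.resample_per_repeat``
    is off, in which case the first repeat's sampling seed is reused.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    reports = []
    for r in range(n_repeats):
        cfg = dataclasses.replace(config, seed=config.seed + r)
        sample_seed = None if config.resample_per_repeat else config.seed
        reports.append(kfold_cv(A, cfg, FM, tree_map, sample_seed=sample_seed))
    summary = {}
    for name in METRIC_NAMES:
        vals = np.array([rep.mean[name] for rep in reports])
        summary[name] = (float(vals.mean()), float(vals.std(ddof=0)))
    return {"metrics": summary, "reports": reports,
            "formatted": {k: format_mean_sd(*v) for k, v in summary.items()}}


def format_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.4f} ± {sd:.4f}"


def fit_full_model(
    A: AssociationMatrix,
    config: Config,
    FM: SimilarityMatrix | None = None,
    tree_map: TreeNumberMap | None = None,
) -> tuple[FittedModel, dict[str, np.ndarray]]:
    """Fit the classifier on the complete assembled training set."""
    training, X, latents, _ = prepare_training_data(A, config, FM, tree_map)
    model = fit_classifier(X, training.labels.astype(int), _classifier_spec(config, config.seed))
    return model, latents


def rank_disease_candidates(
    disease_id: str,
    model: FittedModel,
    latents: dict[str, np.ndarray],
    A: AssociationMatrix,
    feature_mode: str = "combined",
    top: int | None = None,
) -> RankingTable:
    """Score every unknown pair of one disease, descending score.

    Ties are broken by miRNA catalog order so the ranking is deterministic.
    """
    j = A.diseases.position(disease_id)
    unknown = np.flatnonzero(A.values[:, j] == 0)
    if len(unknown) == 0:
        return RankingTable(disease_id, [])
    pairs = PairSet(
        np.column_stack([unknown, np.full(len(unknown), j)]),
        np.zeros(len(unknown), dtype=np.int8),
    )
    X = combine_features(pairs, latents, mode=feature_mode)
    scores = model.score_pairs(X)
    order = np.lexsort((unknown, -scores))
    rows = [
        (rank + 1, A.mirnas[unknown[k]], float(scores[k]))
        for rank, k in enumerate(order)
    ]
    if top is not None:
        rows = rows[:top]
    return RankingTable(disease_id, rows)


def ablation_run(
    A: AssociationMatrix,
    config: Config,
    feature_mode: str = "combined",
    transform: bool = True,
    FM: SimilarityMatrix | None = None,
    tree_map: TreeNumberMap | None = None,
) -> CVReport:
    """CV with a feature-subset and/or transform switch applied."""
    cfg = dataclasses.replace(config, feature_mode=feature_mode, transform=transform)
    return kfold_cv(A, cfg, FM, tree_map)
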