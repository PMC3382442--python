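"""Random-forest classification of DNA-binding propensity from ball histograms.

Pipeline per training set: discover templates on the training proteins only,
marginalize each protein's full-pool histogram onto them, propositionalize,
and fit a seeded random forest. Hyperparameters (sampling-ball radius and
number of templates) are chosen by internal stratified cross-validation on
the training portion; generalization is estimated by stratified outer k-fold
cross-validation reporting rank-based AUC and accuracy. Nothing computed
from a held-out fold ever reaches template discovery, attribute collection
or hyperparameter selection.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .ball_histogram import (
    BallHistogram,
    Template,
    marginalize,
    master_count_vectors,
    protein_seed,
)
from .exceptions import DataError
from .featurize import AttributeSpace, collect_attributes, feature_matrix, vectorize
from .structures import PropertyTable, ProteinStructure
from .template_search import SearchConfig, discover_templates

#: Default grids: sampling-ball radii in Angstroms and template counts.
DEFAULT_RADIUS_GRID: tuple[float, ...] = (4.0, 8.0, 12.0)
DEFAULT_TEMPLATE_GRID: tuple[int, ...] = (1, 3, 5, 7)

MODEL_FORMAT_VERSION = 1


def default_pool(table: PropertyTable | None = None) -> tuple[str, ...]:
    """20 identity properties plus Positive, Negative, Neutral, Polar."""
    table = table if table is not None else PropertyTable.default()
    names = [n for n in table.property_names]
    return tuple(names)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the training pipeline needs besides the data.

    n_samples : Monte-Carlo draws per protein per radius.
    n_trees : random-forest size.
    internal_folds : folds of the hyperparameter-selection CV.
    search : template-search settings (n_templates therein is overridden by
        the grid during selection).
    """

    search: SearchConfig
    n_samples: int = 10_000
    n_trees: int = 500
    internal_folds: int = 5
    threshold: float = 0.5

    @classmethod
    def default(cls, table: PropertyTable | None = None, **kwargs) -> "PipelineConfig":
        return cls(search=SearchConfig(pool=default_pool(table)), **kwargs)


@dataclass
class TrainedModel:
    forest: RandomForestClassifier
    space: AttributeSpace
    radius: float
    templates: tuple[Template, ...]
    n_samples: int
    seed: int
    pool: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.templates:
            raise DataError("a trained model must hold at least one template")


@dataclass
class EvaluationReport:
    fold_auc: list[float]
    fold_accuracy: list[float]
    fold_hyperparameters: list[dict]
    n_folds: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return (
            float(np.std(self.fold_accuracy, ddof=1)) if len(self.fold_accuracy) > 1 else 0.0
        )

    def to_dict(self) -> dict:
        return {
            "n_folds": self.n_folds,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "fold_auc": self.fold_auc,
            "fold_accuracy": self.fold_accuracy,
            "fold_hyperparameters": self.fold_hyperparameters,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_table(self) -> str:
        lines = [f"{'fold':>4}  {'AUC':>6}  {'acc':>6}  hyperparameters"]
        for i, (a, acc, hp) in enumerate(
            zip(self.fold_auc, self.fold_accuracy, self.fold_hyperparameters)
        ):
            lines.append(f"{i:>4}  {a:6.3f}  {acc:6.3f}  {hp}")
        lines.append(
            f"mean  {self.mean_auc:6.3f}  {self.mean_accuracy:6.3f}  "
            f"(sd {self.sd_auc:.3f} / {self.sd_accuracy:.3f})"
        )
        return "\n".join(lines)


def auc_score(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based AUC (Mann-Whitney statistic with midranks for ties)."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC requires both classes among the true labels")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


class HistogramCache:
    """Per-(structure, radius) full-pool histograms, computed once per run.

    Histograms depend only on a protein's own coordinates and the sampling
    seed derived from (global seed, structure id); they carry no label
    information, so sharing them across folds and grid cells leaks nothing.
    """

    def __init__(
        self,
        table: PropertyTable,
        pool: Sequence[str],
        n_samples: int,
        global_seed: int,
    ):
        self.table = table
        self.pool = tuple(pool)
        self.n_samples = int(n_samples)
        self.global_seed = int(global_seed)
        self._store: dict[tuple[str, float], BallHistogram] = {}

    def master(self, structure: ProteinStructure, radius: float) -> BallHistogram:
        key = (structure.id, float(radius))
        if key not in self._store:
            self._store[key] = master_count_vectors(
                structure,
                self.pool,
                R=radius,
                n_samples=self.n_samples,
                seed=protein_seed(self.global_seed, structure.id),
                table=self.table,
            )
        return self._store[key]


def _check_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DataError("training requires both classes present")


def train(
    structures: Sequence[ProteinStructure],
    labels: Sequence[int],
    radius: float,
    n_templates: int,
    config: PipelineConfig,
    seed: int = 0,
    cache: HistogramCache | None = None,
    table: PropertyTable | None = None,
) -> TrainedModel:
    """Fit the full pipeline on one training set; deterministic given seed."""
    y = np.asarray(labels, dtype=int)
    _check_classes(y)
    table = table if table is not None else PropertyTable.default()
    if cache is None:
        cache = HistogramCache(table, config.search.pool, config.n_samples, seed)
    masters = [cache.master(s, radius) for s in structures]
    templates = discover_templates(
        [m for m, l in zip(masters, y) if l == 1],
        [m for m, l in zip(masters, y) if l == 0],
        replace(config.search, n_templates=n_templates),
    )
    hist_sets = [[marginalize(m, t) for t in templates] for m in masters]
    space = collect_attributes(hist_sets)
    X = feature_matrix(hist_sets, space)
    if not np.any(X):
        raise DataError("degenerate all-zero feature matrix")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=seed % (2**31), n_jobs=1
    )
    forest.fit(X, y)
    return TrainedModel(
        forest=forest,
        space=space,
        radius=float(radius),
        templates=tuple(templates),
        n_samples=cache.n_samples,
        seed=cache.global_seed,
        pool=cache.pool,
    )


def predict(
    model: TrainedModel,
    structure: ProteinStructure,
    table: PropertyTable | None = None,
) -> tuple[float, int]:
    """Forest vote fraction for the binding class and the 0.5-threshold label."""
    table = table if table is not None else PropertyTable.default()
    master = master_count_vectors(
        structure,
        model.pool,
        R=model.radius,
        n_samples=model.n_samples,
        seed=protein_seed(model.seed, structure.id),
        table=table,
    )
    hists = [marginalize(master, t) for t in model.templates]
    x = vectorize(hists, model.space)[None, :]
    classes = list(model.forest.classes_)
    score = float(model.forest.predict_proba(x)[0][classes.index(1)])
    return score, int(score >= 0.5)


def select_hyperparameters(
    structures: Sequence[ProteinStructure],
    labels: Sequence[int],
    radius_grid: Sequence[float] = DEFAULT_RADIUS_GRID,
    template_grid: Sequence[int] = DEFAULT_TEMPLATE_GRID,
    config: PipelineConfig | None = None,
    seed: int = 0,
    cache: HistogramCache | None = None,
    table: PropertyTable | None = None,
) -> tuple[float, int]:
    """Grid search by internal stratified CV on the training set only.

    Returns the (radius, n_templates) cell with the highest mean internal
    AUC; ties prefer the smaller radius, then fewer templates. A single-cell
    grid is returned directly without internal CV.
    """
    y = np.asarray(labels, dtype=int)
    _check_classes(y)
    config = config if config is not None else PipelineConfig.default(table)
    table = table if table is not None else PropertyTable.default()
    radius_grid = sorted(float(r) for r in radius_grid)
    template_grid = sorted(int(t) for t in template_grid)
    if len(radius_grid) == 1 and len(template_grid) == 1:
        return radius_grid[0], template_grid[0]
    if cache is None:
        cache = HistogramCache(table, config.search.pool, config.n_samples, seed)

    n_folds = min(config.internal_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        raise DataError("a class is too small for internal stratified CV")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    splits = list(skf.split(np.zeros(len(y)), y))

    best: tuple[float, int] | None = None
    best_auc = -math.inf
    for radius in radius_grid:
        for n_templates in template_grid:
            aucs = []
            for tr, va in splits:
                model = train(
                    [structures[i] for i in tr], y[tr], radius, n_templates,
                    config, seed=seed, cache=cache, table=table,
                )
                scores = [
                    _predict_cached(model, structures[i], cache, table)[0] for i in va
                ]
                aucs.append(auc_score(y[va], scores))
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc:
                best, best_auc = (radius, n_templates), mean_auc
    assert best is not None
    return best


def _predict_cached(
    model: TrainedModel,
    structure: ProteinStructure,
    cache: HistogramCache,
    table: PropertyTable,
) -> tuple[float, int]:
    """predict() sharing the run's histogram cache (identical result)."""
    master = cache.master(structure, model.radius)
    hists = [marginalize(master, t) for t in model.templates]
    x = vectorize(hists, model.space)[None, :]
    classes = list(model.forest.classes_)
    score = float(model.forest.predict_proba(x)[0][classes.index(1)])
    return score, int(score >= 0.5)


def cross_validate(
    structures: Sequence[ProteinStructure],
    labels: Sequence[int],
    k: int = 10,
    radius_grid: Sequence[float] = DEFAULT_RADIUS_GRID,
    template_grid: Sequence[int] = DEFAULT_TEMPLATE_GRID,
    config: PipelineConfig | None = None,
    seed: int = 0,
    table: PropertyTable | None = None,
) -> EvaluationReport:
    """Stratified outer k-fold CV with per-fold hyperparameter selection."""
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise DataError("k must be >= 2")
    if int(np.bincount(y).min() if y.size else 0) < k:
        raise DataError(f"each class needs at least {k} members for stratified {k}-fold CV")
    config = config if config is not None else PipelineConfig.default(table)
    table = table if table is not None else PropertyTable.default()
    cache = HistogramCache(table, config.search.pool, config.n_samples, seed)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    fold_auc, fold_acc, fold_hp = [], [], []
    for tr, te in skf.split(np.zeros(len(y)), y):
        tr_structs = [structures[i] for i in tr]
        radius, n_templates = select_hyperparameters(
            tr_structs, y[tr], radius_grid, template_grid, config,
            seed=seed, cache=cache, table=table,
        )
        model = train(
            tr_structs, y[tr], radius, n_templates, config,
            seed=seed, cache=cache, table=table,
        )
        preds = [_predict_cached(model, structures[i], cache, table) for i in te]
        scores = [p[0] for p in preds]
        hard = np.array([p[1] for p in preds])
        fold_auc.append(auc_score(y[te], scores))
        fold_acc.append(float(np.mean(hard == y[te])))
        fold_hp.append({"radius": radius, "n_templates": n_templates})
    return EvaluationReport(
        fold_auc=fold_auc, fold_accuracy=fold_acc, fold_hyperparameters=fold_hp, n_folds=k
    )


def save_model(model: TrainedModel, path: str) -> None:
    """Persist a trained model to a single versioned archive file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "forest": model.forest,
        "space": model.space,
        "radius": model.radius,
        "templates": model.templates,
        "n_samples": model.n_samples,
        "seed": model.seed,
        "pool": model.pool,
    }
    joblib.dump(payload, path)


def load_model(path: str) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise DataError(f"unsupported model format version {version!r}")
    return TrainedModel(
        forest=payload["forest"],
        space=payload["space"],
        radius=payload["radius"],
        templates=payload["templates"],
        n_samples=payload["n_samples"],
        seed=payload["seed"],
        pool=payload["pool"],
    )
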