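"""Per-region classifier training: candidate model families, 5-fold
cross-validated grid search over hyperparameters and feature configurations,
final retraining, best-model selection and bundle persistence.

Six families are searched: logistic regression, linear SVM, Gaussian-kernel
SVM, decision tree, random forest and Bernoulli naive Bayes (binary features
only, an assumption of that model).  Inside cross-validation the n-gram
feature space is refitted on each fold's training portion, so validation-only
vocabulary never leaks into the fitted model.
"""

from __future__ import annotations

import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import joblib
import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.svm import SVC, LinearSVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .corpus import REGIONS, LabeledReport
from .evaluation import ConfusionMatrix, MetricsReport, confusion, metrics
from .features import (FeatureConfig, FeatureSpace, extract_ngrams,
                       fit_feature_space, vectorize_all)
from .preprocess import NormalizationConfig, preprocess_report

__all__ = [
    "ALGORITHMS",
    "ModelCandidate",
    "CVResult",
    "GridSearchResult",
    "RegionClassifier",
    "cross_validate",
    "grid_search",
    "train_final",
    "select_best_region_model",
    "predict",
    "feature_configs",
    "paper_grid",
    "compact_grid",
    "run_experiment",
    "ExperimentResult",
    "RegionResult",
    "AlgorithmOutcome",
    "save_bundle",
    "load_bundle",
    "Bundle",
]

logger = logging.getLogger(__name__)

#: Candidate algorithm families, in fixed enumeration (tie-break) order.
ALGORITHMS: tuple[str, ...] = (
    "logistic_regression", "svm_linear", "svm_gaussian",
    "decision_tree", "random_forest", "naive_bayes",
)


@dataclass(frozen=True, eq=True)
class ModelCandidate:
    """One point of the search lattice: algorithm + hyperparameters + features."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    feature_config: FeatureConfig = FeatureConfig()

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if (self.algorithm == "naive_bayes"
                and self.feature_config.value_mode != "binary"):
            raise ValueError("naive_bayes requires binary feature vectors")


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def _sparse_variance(X: sparse.spmatrix) -> float:
    mean = X.mean()
    mean_sq = X.multiply(X).mean()
    return float(mean_sq - mean * mean)


def _fit_estimator(candidate: ModelCandidate, X: sparse.spmatrix,
                   y: np.ndarray, seed: int):
    """Instantiate and fit the sklearn estimator behind a candidate.

    C (SVM cost) and l (logistic-regression regularization cost) are both
    inverse regularization strengths: larger values mean weaker penalties.
    """
    hp = candidate.hyperparameters
    algo = candidate.algorithm
    if algo == "logistic_regression":
        est = LogisticRegression(C=float(hp.get("l", 1.0)), solver="liblinear",
                                 max_iter=2000, random_state=seed)
    elif algo == "svm_linear":
        est = LinearSVC(C=float(hp.get("C", 1.0)), random_state=seed,
                        max_iter=20000)
    elif algo == "svm_gaussian":
        # kernel width: sklearn's "scale" heuristic times a grid multiplier
        var = _sparse_variance(X)
        scale = 1.0 / (X.shape[1] * var) if var > 0 else 1.0
        gamma = float(hp.get("gamma_mult", 1.0)) * scale
        est = SVC(C=float(hp.get("C", 1.0)), kernel="rbf", gamma=gamma,
                  random_state=seed)
    elif algo == "decision_tree":
        est = DecisionTreeClassifier(max_depth=hp.get("max_depth"),
                                     random_state=seed)
    elif algo == "random_forest":
        est = RandomForestClassifier(n_estimators=int(hp.get("n_trees", 100)),
                                     random_state=seed, n_jobs=1)
    elif algo == "naive_bayes":
        est = BernoulliNB(binarize=None)
    else:  # pragma: no cover - guarded by ModelCandidate
        raise ValueError(algo)
    est.fit(X, y)
    return est


def _scores_from(estimator, X: sparse.spmatrix) -> np.ndarray:
    """Continuous abnormality score, monotone in P(abnormal)."""
    if hasattr(estimator, "predict_proba"):
        return np.asarray(estimator.predict_proba(X))[:, 1]
    return np.asarray(estimator.decision_function(X))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def _check_classes(y: np.ndarray, folds: int) -> None:
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training labels contain a single class")
    if min(n_pos, n_neg) < folds:
        raise ValueError(
            f"each class needs at least {folds} members for {folds}-fold CV")


def _cv_folds(y: np.ndarray, folds: int, seed: int):
    """Stratified, seeded, shuffled-once fold assignment."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


@dataclass(frozen=True)
class _Fitted:
    """A candidate fitted on some document set (internal helper)."""

    candidate: ModelCandidate
    feature_space: FeatureSpace
    estimator: object

    def predict_docs(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        X = vectorize_all(docs, self.feature_space)
        return np.asarray(self.estimator.predict(X), dtype=bool)

    def score_docs(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        X = vectorize_all(docs, self.feature_space)
        return _scores_from(self.estimator, X)


def _fit_candidate_on(candidate: ModelCandidate, docs: Sequence[Sequence[str]],
                      labels: Sequence[bool], seed: int) -> _Fitted:
    space = fit_feature_space(docs, candidate.feature_config)
    X = vectorize_all(docs, space)
    y = np.asarray(labels, dtype=bool)
    est = _fit_estimator(candidate, X, y, seed)
    return _Fitted(candidate=candidate, feature_space=space, estimator=est)


@dataclass(frozen=True)
class CVResult:
    """Fold accuracies of one candidate under k-fold cross-validation."""

    candidate: ModelCandidate
    fold_accuracies: tuple
    fold_vocabularies: tuple | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def cross_validate(candidate: ModelCandidate, docs: Sequence[Sequence[str]],
                   labels: Sequence[bool], folds: int = 5, seed: int = 0,
                   collect_vocabularies: bool = False) -> CVResult:
    """Stratified k-fold CV of one candidate over normalized documents.

    The feature space and the model are fitted on each fold's training
    portion only; accuracy is measured on the held-out fold.  Deterministic
    for a fixed seed.  With ``collect_vocabularies`` the per-fold fitted
    vocabularies are returned for leakage inspection.
    """
    y = np.asarray(labels, dtype=bool)
    if len(docs) != len(y):
        raise ValueError("docs and labels differ in length")
    _check_classes(y, folds)
    accs = []
    vocabs = []
    for fit_idx, val_idx in _cv_folds(y, folds, seed):
        fitted = _fit_candidate_on(candidate, [docs[i] for i in fit_idx],
                                   y[fit_idx], seed=seed)
        pred = fitted.predict_docs([docs[i] for i in val_idx])
        accs.append(float(np.mean(pred == y[val_idx])))
        if collect_vocabularies:
            vocabs.append(fitted.feature_space.vocabulary)
    return CVResult(candidate=candidate, fold_accuracies=tuple(accs),
                    fold_vocabularies=tuple(vocabs) if collect_vocabularies else None)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSearchResult:
    """Exhaustive CV table over a candidate grid, with the selected best."""

    results: tuple  # of CVResult, in grid enumeration order
    best: ModelCandidate

    @property
    def best_mean_accuracy(self) -> float:
        for r in self.results:
            if r.candidate == self.best:
                return r.mean_accuracy
        raise LookupError("best candidate missing from results")


def grid_search(algorithm: str | None, grid: Sequence[ModelCandidate],
                docs: Sequence[Sequence[str]], labels: Sequence[bool],
                seed: int = 0, folds: int = 5) -> GridSearchResult:
    """Exhaustive cross-validated evaluation of a candidate grid.

    Equivalent to calling :func:`cross_validate` on every candidate and
    taking the argmax of mean accuracy (ties broken by grid order), but
    shares per-fold feature spaces between candidates with the same n-gram
    configuration for speed.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("candidate grid is empty")
    if algorithm is not None:
        for cand in grid:
            if cand.algorithm != algorithm:
                raise ValueError(
                    f"grid contains {cand.algorithm!r}, expected {algorithm!r}")
    y = np.asarray(labels, dtype=bool)
    _check_classes(y, folds)
    fold_idx = _cv_folds(y, folds, seed)

    # (unit, n_min, n_max) x fold -> fitted space + count matrices; a binary
    # candidate uses the indicator of the same count matrix.
    fold_cache: dict = {}

    def fold_data(cfg: FeatureConfig, f: int):
        key = (cfg.unit, cfg.n_min, cfg.n_max, f)
        if key not in fold_cache:
            count_cfg = FeatureConfig(unit=cfg.unit, n_min=cfg.n_min,
                                      n_max=cfg.n_max, value_mode="count")
            fit_idx, val_idx = fold_idx[f]
            space = fit_feature_space([docs[i] for i in fit_idx], count_cfg)
            Xtr = vectorize_all([docs[i] for i in fit_idx], space)
            Xva = vectorize_all([docs[i] for i in val_idx], space)
            fold_cache[key] = (space, Xtr, Xva)
        return fold_cache[key]

    results = []
    best: ModelCandidate | None = None
    best_mean = -np.inf
    for cand in grid:
        accs = []
        for f, (fit_idx, val_idx) in enumerate(fold_idx):
            space, Xtr, Xva = fold_data(cand.feature_config, f)
            if cand.feature_config.value_mode == "binary":
                Xtr = (Xtr > 0).astype(np.float64)
                Xva = (Xva > 0).astype(np.float64)
            est = _fit_estimator(cand, Xtr, y[fit_idx], seed)
            pred = np.asarray(est.predict(Xva), dtype=bool)
            accs.append(float(np.mean(pred == y[val_idx])))
        result = CVResult(candidate=cand, fold_accuracies=tuple(accs))
        results.append(result)
        if result.mean_accuracy > best_mean:  # strict: ties keep earlier
            best_mean = result.mean_accuracy
            best = cand
    return GridSearchResult(results=tuple(results), best=best)


# ---------------------------------------------------------------------------
# Candidate grids
# ---------------------------------------------------------------------------

_COST_GRID = (0.01, 0.0333, 0.1, 0.333, 1.0, 3.33, 10.0)


def feature_configs(units: Sequence[str] = ("word", "character"),
                    ranges: Sequence[tuple] = ((1, 1), (1, 2), (1, 3)),
                    modes: Sequence[str] = ("binary", "count")) -> list[FeatureConfig]:
    """The feature lattice: n-gram ranges x word/character x value modes."""
    return [FeatureConfig(unit=u, n_min=lo, n_max=hi, value_mode=m)
            for u in units for (lo, hi) in ranges for m in modes]


def paper_grid(algorithm: str) -> list[ModelCandidate]:
    """The full default search grid for one algorithm family.

    Covers the published optima (C in {0.1, 0.333}, l = 0.1, max_depth = 2,
    word and character n-grams with n in [1, 3], binary and count values).
    """
    configs = feature_configs()
    nb_configs = feature_configs(modes=("binary",))
    if algorithm == "logistic_regression":
        return [ModelCandidate(algorithm, {"l": c}, fc)
                for c in _COST_GRID for fc in configs]
    if algorithm == "svm_linear":
        return [ModelCandidate(algorithm, {"C": c}, fc)
                for c in _COST_GRID for fc in configs]
    if algorithm == "svm_gaussian":
        return [ModelCandidate(algorithm, {"C": 1.0, "gamma_mult": g}, fc)
                for g in (0.1, 1.0, 10.0) for fc in configs]
    if algorithm == "decision_tree":
        return [ModelCandidate(algorithm, {"max_depth": d}, fc)
                for d in range(1, 11) for fc in configs]
    if algorithm == "random_forest":
        return [ModelCandidate(algorithm, {"n_trees": t}, fc)
                for t in (10, 50, 100) for fc in configs]
    if algorithm == "naive_bayes":
        return [ModelCandidate(algorithm, {}, fc) for fc in nb_configs]
    raise ValueError(f"unknown algorithm {algorithm!r}")


def compact_grid(algorithm: str) -> list[ModelCandidate]:
    """A reduced grid for routine runs; still spans the published optima
    (C in {0.1, 0.333}, l in {0.1, 1}, max_depth in {2, 5}) and all three
    n-gram range/unit shapes that win per region."""
    count_cfgs = [FeatureConfig("word", 1, 1, "count"),
                  FeatureConfig("word", 1, 2, "count"),
                  FeatureConfig("character", 1, 3, "binary")]
    nb_cfgs = [FeatureConfig("word", 1, 1, "binary"),
               FeatureConfig("word", 1, 2, "binary"),
               FeatureConfig("character", 1, 3, "binary")]
    if algorithm == "logistic_regression":
        return [ModelCandidate(algorithm, {"l": c}, fc)
                for c in (0.1, 1.0) for fc in count_cfgs]
    if algorithm == "svm_linear":
        return [ModelCandidate(algorithm, {"C": c}, fc)
                for c in (0.1, 0.333) for fc in count_cfgs]
    if algorithm == "svm_gaussian":
        return [ModelCandidate(algorithm, {"C": 1.0, "gamma_mult": 1.0}, fc)
                for fc in count_cfgs]
    if algorithm == "decision_tree":
        return [ModelCandidate(algorithm, {"max_depth": d}, fc)
                for d in (2, 5) for fc in count_cfgs]
    if algorithm == "random_forest":
        return [ModelCandidate(algorithm, {"n_trees": 50}, fc)
                for fc in count_cfgs]
    if algorithm == "naive_bayes":
        return [ModelCandidate(algorithm, {}, fc) for fc in nb_cfgs]
    raise ValueError(f"unknown algorithm {algorithm!r}")


GRID_PRESETS: dict[str, Callable[[str], list[ModelCandidate]]] = {
    "paper": paper_grid,
    "compact": compact_grid,
}


# ---------------------------------------------------------------------------
# Final training and prediction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionClassifier:
    """A trained, persistable binary classifier for one ear region."""

    region: str
    candidate: ModelCandidate
    feature_space: FeatureSpace
    estimator: object
    has_scores: bool = True
    seed: int = 0

    def predict_docs(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        X = vectorize_all(docs, self.feature_space)
        return np.asarray(self.estimator.predict(X), dtype=bool)

    def score_docs(self, docs: Sequence[Sequence[str]]) -> np.ndarray:
        X = vectorize_all(docs, self.feature_space)
        return _scores_from(self.estimator, X)


def train_final(candidate: ModelCandidate, docs: Sequence[Sequence[str]],
                labels: Sequence[bool], seed: int = 0,
                region: str = "any") -> RegionClassifier:
    """Refit feature space and model on the entire training set."""
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    fitted = _fit_candidate_on(candidate, docs, y, seed=seed)
    return RegionClassifier(region=region, candidate=candidate,
                            feature_space=fitted.feature_space,
                            estimator=fitted.estimator, seed=seed)


def select_best_region_model(test_metrics: dict) -> str:
    """Pick the winning algorithm: highest test accuracy, ties broken by F1,
    residual ties by the fixed algorithm enumeration order."""
    if not test_metrics:
        raise ValueError("no candidate metrics to select from")
    rank = {a: i for i, a in enumerate(ALGORITHMS)}
    ordered = sorted(test_metrics, key=lambda a: rank.get(a, len(rank)))
    best = ordered[0]
    for algo in ordered[1:]:
        m, b = test_metrics[algo], test_metrics[best]
        if (m.accuracy, m.f1) > (b.accuracy, b.f1):
            best = algo
    return best


def predict(classifier: RegionClassifier, report_text: str,
            norm_config: NormalizationConfig | None = None):
    """Classify one raw report: preprocess, vectorize against the
    classifier's own feature space, decide.  Returns (label, score)."""
    tokens = preprocess_report(report_text, norm_config)
    label = bool(classifier.predict_docs([tokens])[0])
    score = float(classifier.score_docs([tokens])[0]) if classifier.has_scores else None
    return label, score


# ---------------------------------------------------------------------------
# End-to-end experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlgorithmOutcome:
    """One family's best candidate and its held-out test performance."""

    candidate: ModelCandidate
    cv_mean_accuracy: float
    classifier: RegionClassifier
    confusion: ConfusionMatrix
    metrics: MetricsReport
    predictions: tuple
    scores: tuple


@dataclass(frozen=True)
class RegionResult:
    region: str
    outcomes: dict  # algorithm -> AlgorithmOutcome
    best_algorithm: str

    @property
    def best(self) -> AlgorithmOutcome:
        return self.outcomes[self.best_algorithm]


@dataclass(frozen=True)
class ExperimentResult:
    regions: dict  # region -> RegionResult
    seed: int

    def best_classifiers(self) -> dict:
        return {r: res.best.classifier for r, res in self.regions.items()}


def run_experiment(train_reports: Sequence[LabeledReport],
                   test_reports: Sequence[LabeledReport],
                   seed: int = 0,
                   grid: str | Callable[[str], list[ModelCandidate]] = "compact",
                   algorithms: Sequence[str] = ALGORITHMS,
                   folds: int = 5,
                   norm_config: NormalizationConfig | None = None) -> ExperimentResult:
    """The full pipeline on a labeled split.

    For every region and algorithm family: grid-search hyperparameters and
    feature configuration by stratified 5-fold CV on the training set,
    retrain the winner on all training reports, evaluate on the test set;
    then pick the region's best family by test accuracy (F1 on ties).
    """
    grid_fn = GRID_PRESETS[grid] if isinstance(grid, str) else grid
    t0 = time.time()
    train_docs = [preprocess_report(r.text, norm_config) for r in train_reports]
    test_docs = [preprocess_report(r.text, norm_config) for r in test_reports]
    logger.info("preprocessed %d train / %d test reports in %.1fs",
                len(train_docs), len(test_docs), time.time() - t0)

    regions: dict[str, RegionResult] = {}
    for region in REGIONS:
        y_train = np.asarray([r.labels[region] for r in train_reports], bool)
        y_test = np.asarray([r.labels[region] for r in test_reports], bool)
        outcomes: dict[str, AlgorithmOutcome] = {}
        for algo in algorithms:
            t1 = time.time()
            gs = grid_search(algo, grid_fn(algo), train_docs, y_train,
                             seed=seed, folds=folds)
            clf = train_final(gs.best, train_docs, y_train, seed=seed,
                              region=region)
            pred = clf.predict_docs(test_docs)
            scores = clf.score_docs(test_docs)
            cm = confusion(pred.tolist(), y_test.tolist())
            outcomes[algo] = AlgorithmOutcome(
                candidate=gs.best, cv_mean_accuracy=gs.best_mean_accuracy,
                classifier=clf, confusion=cm, metrics=metrics(cm),
                predictions=tuple(bool(p) for p in pred),
                scores=tuple(float(s) for s in scores))
            logger.info("region=%s algo=%s grid=%d cv_acc=%.3f test_acc=%.3f "
                        "(%.1fs)", region, algo, len(gs.results),
                        gs.best_mean_accuracy, outcomes[algo].metrics.accuracy,
                        time.time() - t1)
        best_algo = select_best_region_model(
            {a: o.metrics for a, o in outcomes.items()})
        regions[region] = RegionResult(region=region, outcomes=outcomes,
                                       best_algorithm=best_algo)
        logger.info("region=%s best=%s acc=%.3f", region, best_algo,
                    regions[region].best.metrics.accuracy)
    return ExperimentResult(regions=regions, seed=seed)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_BUNDLE_VERSION = 1


@dataclass(frozen=True)
class Bundle:
    """A loaded model bundle: four region classifiers plus manifest metadata."""

    classifiers: dict
    manifest: dict


def save_bundle(classifiers: dict, path: str | Path, seed: int | None = None,
                region_metrics: dict | None = None) -> None:
    """Persist per-region classifiers to a directory bundle.

    Layout: ``manifest.json`` (version, seed, per-region candidate and
    metrics), and per region a feature-space JSON plus joblib'd estimator.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": _BUNDLE_VERSION, "seed": seed, "regions": {}}
    for region, clf in classifiers.items():
        manifest["regions"][region] = {
            "algorithm": clf.candidate.algorithm,
            "hyperparameters": clf.candidate.hyperparameters,
            "feature_config": clf.candidate.feature_config.as_dict(),
            "metrics": (region_metrics or {}).get(region),
        }
        (path / f"{region}.space.json").write_text(clf.feature_space.to_json(),
                                                   encoding="utf-8")
        joblib.dump(clf.estimator, path / f"{region}.model.joblib")
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                        encoding="utf-8")


def load_bundle(path: str | Path) -> Bundle:
    """Load a bundle saved by :func:`save_bundle`.

    Raises
    ------
    ValueError
        If the manifest is missing or a region's artifacts are absent.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ValueError(f"no manifest.json in bundle {path}")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    classifiers: dict[str, RegionClassifier] = {}
    for region, meta in manifest.get("regions", {}).items():
        space_path = path / f"{region}.space.json"
        model_path = path / f"{region}.model.joblib"
        if not space_path.exists() or not model_path.exists():
            raise ValueError(f"bundle {path} missing artifacts for {region!r}")
        space = FeatureSpace.from_json(space_path.read_text(encoding="utf-8"))
        estimator = joblib.load(model_path)
        candidate = ModelCandidate(
            algorithm=meta["algorithm"],
            hyperparameters=meta.get("hyperparameters", {}),
            feature_config=FeatureConfig.from_dict(meta["feature_config"]))
        classifiers[region] = RegionClassifier(
            region=region, candidate=candidate, feature_space=space,
            estimator=estimator, seed=manifest.get("seed") or 0)
    return Bundle(classifiers=classifiers, manifest=manifest)
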