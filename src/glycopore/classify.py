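"""Repeated stratified classification of glycan feature sets.

The evaluation protocol: each glycan's feature rows form one stratum; every
cycle draws a fresh stratified 80/20 train/test split (with 20 rows per
class that is 16 train / 4 test), trains a fresh classifier, and predicts
the held-out rows. One experiment accumulates 100 such cycles — 400 test-set
predictions per class — and the whole evaluation repeats the experiment over
10 replicates, summing confusion counts (4,000 accumulated predictions per
class) and averaging the macro F1 / Precision / Recall over replicates.

Five model families are used, each with fixed hyperparameters:
SVM (RBF kernel, C = 1), multinomial naive Bayes (Laplace smoothing 1.0,
features rescaled to pseudo-counts), random forest (25 trees, or 80 for
hard-to-separate panels), AdaBoost (100 decision-tree weak learners), and
L2 logistic regression (C = 1, liblinear solver).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .events import EventTable
from .features import FeatureMatrix, build_feature_matrix

__all__ = [
    "ModelSpec",
    "SplitPlan",
    "EvaluationReport",
    "ALGORITHMS",
    "default_model_specs",
    "stratified_split",
    "run_experiment",
    "run_replicates",
    "tune_features",
]

ALGORITHMS = ("SVM", "NaiveBayes", "RandomForest", "AdaBoost", "LogisticRegression")


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus its fixed hyperparameters."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def build(self, random_state: int | None = None):
        """Instantiate an unfitted scikit-learn estimator for this spec."""
        hp = self.hyperparameters
        if self.algorithm == "SVM":
            return SVC(
                kernel=hp.get("kernel", "rbf"),
                C=hp.get("C", 1.0),
                max_iter=hp.get("max_iter", -1),
                random_state=random_state,
            )
        if self.algorithm == "NaiveBayes":
            return MultinomialNB(alpha=hp.get("alpha", 1.0))
        if self.algorithm == "RandomForest":
            return RandomForestClassifier(
                n_estimators=hp.get("n_estimators", 25), random_state=random_state
            )
        if self.algorithm == "AdaBoost":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(
                    max_depth=hp.get("base_max_depth", 1), random_state=random_state
                ),
                n_estimators=hp.get("n_estimators", 100),
                random_state=random_state,
            )
        if self.algorithm == "LogisticRegression":
            # ridge (L2) regularisation is the liblinear solver's default;
            # liblinear is binary-only, so multiclass goes one-vs-rest
            est = LogisticRegression(
                C=hp.get("C", 1.0),
                solver=hp.get("solver", "liblinear"),
                random_state=random_state,
            )
            return OneVsRestClassifier(est)
        raise AssertionError(self.algorithm)


def default_model_specs(hard: bool = False) -> list[ModelSpec]:
    """The five standard model specs.

    ``hard=True`` switches the random forest to 80 trees, the setting used
    for hard-to-classify panels; the default is 25 trees.
    """
    return [
        ModelSpec("SVM", {"kernel": "rbf", "C": 1.0, "max_iter": -1}),
        ModelSpec("NaiveBayes", {"alpha": 1.0}),
        ModelSpec("RandomForest", {"n_estimators": 80 if hard else 25}),
        ModelSpec("AdaBoost", {"n_estimators": 100, "base_max_depth": 1}),
        ModelSpec("LogisticRegression", {"penalty": "l2", "C": 1.0, "solver": "liblinear"}),
    ]


@dataclass(frozen=True)
class SplitPlan:
    """Per-class train/test row indices of one stratified split."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test indices overlap")


def stratified_split(matrix: FeatureMatrix, test_fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Stratified random train/test split of the feature matrix.

    Each class is a stratum; ceil(test_fraction * n_class) rows go to test
    (exactly n_class * test_fraction when divisible: 4 of 20). Deterministic
    per seed.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(matrix.labels)
    train, test = [], []
    for cls in matrix.classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 5:
            raise ValueError(f"class {cls!r} has {idx.size} rows; need >= 5 for a 20% test split")
        n_test = math.ceil(test_fraction * idx.size)
        perm = rng.permutation(idx)
        test.append(perm[:n_test])
        train.append(perm[n_test:])
    return SplitPlan(
        train_idx=np.sort(np.concatenate(train)),
        test_idx=np.sort(np.concatenate(test)),
        seed=seed,
    )


@dataclass
class EvaluationReport:
    """Accumulated classification metrics for one model.

    ``confusion`` counts predictions over all cycles and replicates
    (rows = true class, columns = predicted class, order = ``classes``);
    ``f1``/``precision``/``recall`` are macro averages over the accumulated
    predictions, averaged across replicates.
    """

    algorithm: str
    classes: list[str]
    f1: float
    precision: float
    recall: float
    confusion: np.ndarray
    cycles: int
    replicates: int
    seed: int
    per_replicate_f1: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in ("f1", "precision", "recall"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if (self.confusion < 0).any():
            raise ValueError("confusion counts must be non-negative")

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "classes": self.classes,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "confusion": self.confusion.astype(int).tolist(),
            "cycles": self.cycles,
            "replicates": self.replicates,
            "seed": self.seed,
        }


def _prepare_X(matrix: FeatureMatrix, spec: ModelSpec) -> np.ndarray:
    # multinomial NB expects count-like features; rescale proportions by
    # the subset size into pseudo-counts
    if spec.algorithm == "NaiveBayes":
        return matrix.X * matrix.subset_size
    return matrix.X


def run_experiment(
    matrix: FeatureMatrix, spec: ModelSpec, cycles: int = 100, seed: int = 0
) -> EvaluationReport:
    """One experiment: ``cycles`` train/test cycles with fresh splits.

    Every cycle uses seed + cycle index for both the stratified split and
    the estimator, trains from scratch, and predicts the held-out rows;
    predictions accumulate into one confusion matrix from which the macro
    scores are computed.
    """
    X = _prepare_X(matrix, spec)
    y = np.asarray(matrix.labels)
    classes = matrix.classes
    cls_to_col = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    y_true_all, y_pred_all = [], []
    for c in range(cycles):
        cyc_seed = seed + c
        plan = stratified_split(matrix, seed=cyc_seed)
        est = spec.build(random_state=cyc_seed % (2**31))
        est.fit(X[plan.train_idx], y[plan.train_idx])
        pred = est.predict(X[plan.test_idx])
        truth = y[plan.test_idx]
        for t, p in zip(truth, pred):
            confusion[cls_to_col[t], cls_to_col[p]] += 1
        y_true_all.append(truth)
        y_pred_all.append(pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        np.concatenate(y_true_all),
        np.concatenate(y_pred_all),
        labels=classes,
        average="macro",
        zero_division=0,
    )
    return EvaluationReport(
        algorithm=spec.algorithm,
        classes=classes,
        f1=float(f1),
        precision=float(prec),
        recall=float(rec),
        confusion=confusion,
        cycles=cycles,
        replicates=1,
        seed=seed,
    )


def run_replicates(
    tables: Mapping[str, EventTable],
    specs: Sequence[ModelSpec],
    k: int = 3,
    subset_size: int = 2000,
    replicates: int = 10,
    cycles: int = 100,
    base_seed: int = 0,
) -> list[EvaluationReport]:
    """Full evaluation: ``replicates`` experiments per model spec.

    Replicate r rebuilds the feature matrix with seed base_seed + r (a fresh
    random subset partition) and runs one experiment per spec; confusion
    matrices are summed across replicates and the macro scores averaged. In
    the canonical 4-glycan configuration each class accumulates
    4 x 100 x 10 = 4,000 test-set predictions.
    """
    reports: dict[str, list[EvaluationReport]] = {s.algorithm: [] for s in specs}
    for r in range(replicates):
        rep_seed = base_seed + r
        matrix = build_feature_matrix(tables, k=k, subset_size=subset_size, seed=rep_seed)
        for spec in specs:
            rep = run_experiment(matrix, spec, cycles=cycles, seed=rep_seed * 100_003)
            reports[spec.algorithm].append(rep)
    out = []
    for spec in specs:
        reps = reports[spec.algorithm]
        out.append(
            EvaluationReport(
                algorithm=spec.algorithm,
                classes=reps[0].classes,
                f1=float(np.mean([x.f1 for x in reps])),
                precision=float(np.mean([x.precision for x in reps])),
                recall=float(np.mean([x.recall for x in reps])),
                confusion=np.sum([x.confusion for x in reps], axis=0),
                cycles=cycles,
                replicates=replicates,
                seed=base_seed,
                per_replicate_f1=tuple(x.f1 for x in reps),
            )
        )
    return out


def tune_features(
    tables: Mapping[str, EventTable],
    k_range: Sequence[int],
    size_range: Sequence[int],
    spec: ModelSpec,
    seed: int = 0,
    cycles: int = 10,
) -> tuple[tuple[int, int], list[dict]]:
    """Grid search over (bins per axis, subset size) by mean macro F1.

    Evaluates one reduced experiment (``cycles`` cycles, default 10) per grid
    point; returns the argmax (ties broken toward smaller k then smaller
    size) plus the full score table. Infeasible points (subset size larger
    than a table, or fewer than 5 subsets per class) are skipped with a
    warning entry.
    """
    if not k_range or not size_range:
        raise ValueError("k_range and size_range must be non-empty")
    results = []
    best: tuple[int, int] | None = None
    best_f1 = -1.0
    for k in sorted(k_range):
        for size in sorted(size_range):
            feasible = all(t.n_events // size >= 5 for t in tables.values())
            if not feasible:
                results.append({"k": k, "subset_size": size, "f1": None, "skipped": True})
                continue
            matrix = build_feature_matrix(tables, k=k, subset_size=size, seed=seed)
            rep = run_experiment(matrix, spec, cycles=cycles, seed=seed)
            results.append({"k": k, "subset_size": size, "f1": rep.f1, "skipped": False})
            if rep.f1 > best_f1 + 1e-12:  # strict improvement: ties keep smaller k/size
                best_f1, best = rep.f1, (k, size)
    if best is None:
        raise ValueError("no feasible grid point")
    return best, results
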