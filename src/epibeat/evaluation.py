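"""Model selection and validation for the pressure-bin classifier.

Metrics
-------
* accuracy = fraction of exactly correct bin estimates,
* loss     = mean squared bin-index discrepancy, which penalizes a
  two-bin miss four times as hard as a one-bin miss.

Validation modes are stratified k-fold cross-validation (10-fold by
default, optionally repeated), a stratified ~5% holdout whose per-class
draw shrinks when a class is scarce, and leave-one-subject-out (LOSO)
generalization where one animal is removed from training entirely.

Feature selection is a greedy wrapper: evaluate every single feature by
cross-validated metric, then try adding and replacing features (never
more than three in a model) accepting only strict improvements.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trees import TreeEnsemble, fit_bagged_ensemble, predict_matrix

__all__ = [
    "ValidationReport",
    "SearchTrace",
    "accuracy_and_loss",
    "confusion_matrix",
    "stratified_fold_indices",
    "kfold_validate",
    "greedy_feature_search",
    "stratified_holdout_split",
    "leave_one_subject_out",
    "anova_one_way",
]

log = logging.getLogger(__name__)

DEFAULT_K = 10
DEFAULT_N_TREES = 50
MIN_TRAIN_PER_CLASS = 10


@dataclass
class ValidationReport:
    accuracy: float
    loss: float
    fold_accuracies: list[float]
    fold_losses: list[float]
    confusion: np.ndarray
    scheme_name: str
    feature_subset: tuple[str, ...]
    mode: str                               # "kfold" | "holdout" | "loso"
    n_samples: int = 0
    subject: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.loss < 0:
            raise ValueError("loss must be non-negative")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "loss": self.loss,
            "fold_accuracies": self.fold_accuracies,
            "fold_losses": self.fold_losses,
            "confusion": self.confusion.tolist(),
            "scheme": self.scheme_name,
            "features": list(self.feature_subset),
            "mode": self.mode,
            "n_samples": self.n_samples,
            "subject": self.subject,
        }


@dataclass
class SearchTrace:
    steps: list[dict] = field(default_factory=list)

    def record(self, subset: tuple[str, ...], accuracy: float,
               loss: float, action: str) -> None:
        if len(subset) > 3:
            raise ValueError("subsets are capped at 3 features")
        self.steps.append({
            "subset": list(subset), "cv_accuracy": accuracy,
            "cv_loss": loss, "action": action,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def accuracy_and_loss(true_bins, pred_bins) -> tuple[float, float]:
    """Exact-match accuracy and mean squared bin-index error."""
    y = np.asarray(true_bins, int)
    yhat = np.asarray(pred_bins, int)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("need equal-length, non-empty label arrays")
    acc = float(np.mean(y == yhat))
    loss = float(np.mean((y - yhat) ** 2))
    return acc, loss


def confusion_matrix(true_bins, pred_bins, n_bins: int) -> np.ndarray:
    """``counts[true, predicted]``; trace/total equals the accuracy."""
    y = np.asarray(true_bins, int)
    yhat = np.asarray(pred_bins, int)
    if np.any((y < 0) | (y >= n_bins) | (yhat < 0) | (yhat >= n_bins)):
        raise ValueError("bin index out of range")
    cm = np.zeros((n_bins, n_bins), int)
    np.add.at(cm, (y, yhat), 1)
    return cm


def stratified_fold_indices(y: np.ndarray, k: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Fold label per sample, stratified by class.

    Within each class the (shuffled) members are dealt round-robin
    across folds; a class with fewer members than folds simply misses
    from some folds (warned once).
    """
    y = np.asarray(y, int)
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = np.empty(len(y), int)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            log.warning("class %d has %d < k=%d members", c, len(idx), k)
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


def _fit_predict(
    X: np.ndarray, y: np.ndarray, train: np.ndarray, test: np.ndarray,
    codes, n_classes: int, n_trees: int, max_splits: int | None, seed: int,
) -> np.ndarray:
    ens = fit_bagged_ensemble(
        X[train], y[train], codes, n_trees=n_trees, max_splits=max_splits,
        seed=seed, n_classes=n_classes,
    )
    return predict_matrix(ens, X[test])


def kfold_validate(
    table: pd.DataFrame,
    feature_subset: tuple[str, ...] | list[str],
    label_column: str,
    n_classes: int,
    k: int = DEFAULT_K,
    repeats: int = 1,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    max_splits: int | None = None,
    scheme_name: str = "",
) -> ValidationReport:
    """Stratified (repeated) k-fold cross-validation of a bagged model.

    The reported accuracy/loss are fold means; the confusion matrix
    pools all out-of-fold predictions.  Deterministic for a fixed seed.
    """
    codes = tuple(feature_subset)
    X = table[list(codes)].to_numpy(float)
    y = table[label_column].to_numpy(int)
    rng = np.random.default_rng(seed)
    accs, losses = [], []
    cm = np.zeros((n_classes, n_classes), int)
    for r in range(repeats):
        folds = stratified_fold_indices(y, k, rng)
        for f in range(k):
            test = np.flatnonzero(folds == f)
            train = np.flatnonzero(folds != f)
            if test.size == 0 or train.size == 0:
                continue
            pred = _fit_predict(
                X, y, train, test, codes, n_classes, n_trees, max_splits,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            a, l = accuracy_and_loss(y[test], pred)
            accs.append(a)
            losses.append(l)
            cm += confusion_matrix(y[test], pred, n_classes)
    return ValidationReport(
        accuracy=float(np.mean(accs)),
        loss=float(np.mean(losses)),
        fold_accuracies=accs,
        fold_losses=losses,
        confusion=cm,
        scheme_name=scheme_name,
        feature_subset=codes,
        mode="kfold",
        n_samples=len(y),
    )


def greedy_feature_search(
    table: pd.DataFrame,
    candidate_features: tuple[str, ...] | list[str],
    label_column: str,
    n_classes: int,
    metric: str = "accuracy",
    k: int = DEFAULT_K,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    max_splits: int | None = None,
    max_features: int = 3,
) -> tuple[tuple[str, ...], SearchTrace]:
    """Greedy wrapper feature selection capped at three features.

    Stage 1 cross-validates every single candidate; later stages try
    adding each unused feature, then swapping each member for each
    unused feature, accepting only strict improvements of the chosen
    metric until no step helps.  Folds are fixed once (seeded) so all
    subsets are compared on identical splits; ties break
    lexicographically by feature code.
    """
    if metric not in ("accuracy", "loss"):
        raise ValueError("metric must be 'accuracy' or 'loss'")
    candidates = tuple(sorted(candidate_features))
    if not candidates:
        raise ValueError("need at least one candidate feature")
    y = table[label_column].to_numpy(int)
    X_all = {c: table[c].to_numpy(float) for c in candidates}
    rng = np.random.default_rng(seed)
    folds = stratified_fold_indices(y, k, rng)
    tree_seeds = rng.integers(0, 2**31 - 1, k)
    cache: dict[tuple[str, ...], tuple[float, float]] = {}

    def evaluate(subset: tuple[str, ...]) -> tuple[float, float]:
        subset = tuple(subset)
        if subset in cache:
            return cache[subset]
        X = np.column_stack([X_all[c] for c in subset])
        accs, losses = [], []
        for f in range(k):
            test = np.flatnonzero(folds == f)
            train = np.flatnonzero(folds != f)
            if test.size == 0 or train.size == 0:
                continue
            pred = _fit_predict(X, y, train, test, subset, n_classes,
                                n_trees, max_splits, int(tree_seeds[f]))
            a, l = accuracy_and_loss(y[test], pred)
            accs.append(a)
            losses.append(l)
        out = (float(np.mean(accs)), float(np.mean(losses)))
        cache[subset] = out
        return out

    def better(new: tuple[float, float], old: tuple[float, float]) -> bool:
        if metric == "accuracy":
            return new[0] > old[0]
        return new[1] < old[1]

    trace = SearchTrace()
    best_subset: tuple[str, ...] | None = None
    best_score: tuple[float, float] | None = None
    for c in candidates:
        score = evaluate((c,))
        if best_score is None or better(score, best_score):
            best_subset, best_score = (c,), score
    trace.record(best_subset, *best_score, action="add")

    improved = True
    while improved:
        improved = False
        unused = [c for c in candidates if c not in best_subset]
        if len(best_subset) < max_features:
            for c in unused:
                trial = tuple(sorted(best_subset + (c,)))
                score = evaluate(trial)
                if better(score, best_score):
                    best_subset, best_score = trial, score
                    trace.record(trial, *score, action="add")
                    improved = True
                    break
            if improved:
                continue
        for member in best_subset:
            for c in unused:
                trial = tuple(sorted(
                    [f for f in best_subset if f != member] + [c]))
                score = evaluate(trial)
                if better(score, best_score):
                    best_subset, best_score = trial, score
                    trace.record(trial, *score, action="replace")
                    improved = True
                    break
            if improved:
                break
    trace.record(best_subset, *best_score, action="stop")
    return best_subset, trace


def stratified_holdout_split(
    table: pd.DataFrame,
    label_column: str,
    fraction: float = 0.05,
    min_train_per_class: int = MIN_TRAIN_PER_CLASS,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class holdout draw with scarce-class reduction.

    For a class with ``n_c`` members the holdout count is
    ``min(ceil(fraction * n_c), max(0, n_c - min_train_per_class))`` so
    sparse pressure bins keep a robust training presence.  Sampling is
    without replacement and seeded.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    y = table[label_column].to_numpy(int)
    rng = np.random.default_rng(seed)
    hold_mask = np.zeros(len(table), bool)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        n_c = len(idx)
        n_hold = min(int(np.ceil(fraction * n_c)),
                     max(0, n_c - min_train_per_class))
        if n_hold > 0:
            hold_mask[rng.choice(idx, n_hold, replace=False)] = True
    return table.loc[~hold_mask], table.loc[hold_mask]


def holdout_validate(
    train: pd.DataFrame,
    holdout: pd.DataFrame,
    feature_subset: tuple[str, ...],
    label_column: str,
    n_classes: int,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    max_splits: int | None = None,
    scheme_name: str = "",
    subject: str | None = None,
) -> tuple[ValidationReport, TreeEnsemble]:
    """Fit on ``train``, score on ``holdout``; returns report and model."""
    codes = tuple(feature_subset)
    ens = fit_bagged_ensemble(
        train[list(codes)].to_numpy(float),
        train[label_column].to_numpy(int),
        codes, n_trees=n_trees, max_splits=max_splits, seed=seed,
        n_classes=n_classes, scheme_name=scheme_name,
    )
    y = holdout[label_column].to_numpy(int)
    pred = predict_matrix(ens, holdout[list(codes)].to_numpy(float))
    acc, loss = accuracy_and_loss(y, pred)
    report = ValidationReport(
        accuracy=acc, loss=loss, fold_accuracies=[acc], fold_losses=[loss],
        confusion=confusion_matrix(y, pred, n_classes),
        scheme_name=scheme_name, feature_subset=codes, mode="holdout",
        n_samples=len(y), subject=subject,
    )
    return report, ens


def leave_one_subject_out(
    table: pd.DataFrame,
    candidate_features: tuple[str, ...] | list[str],
    label_column: str,
    n_classes: int,
    subject_column: str = "subject",
    metric: str = "accuracy",
    k: int = DEFAULT_K,
    seed: int = 0,
    n_trees: int = DEFAULT_N_TREES,
    search_n_trees: int | None = None,
    max_splits: int | None = None,
    scheme_name: str = "",
) -> list[ValidationReport]:
    """Generalized (leave-one-subject-out) validation.

    For each subject, the greedy feature search and the final model see
    only the other subjects' beats; the held-out subject is scored
    holdout-style.  Returns one report per subject.
    """
    subjects = sorted(table[subject_column].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    reports = []
    rng = np.random.default_rng(seed)
    for s in subjects:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        train = table[table[subject_column] != s]
        test = table[table[subject_column] == s]
        subset, _ = greedy_feature_search(
            train, candidate_features, label_column, n_classes,
            metric=metric, k=k, seed=sub_seed,
            n_trees=search_n_trees or n_trees, max_splits=max_splits,
        )
        report, _ = holdout_validate(
            train, test, subset, label_column, n_classes, seed=sub_seed,
            n_trees=n_trees, max_splits=max_splits,
            scheme_name=scheme_name, subject=str(s),
        )
        report.mode = "loso"
        reports.append(report)
    return reports


def anova_one_way(groups: list[np.ndarray | list[float]]
                  ) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value.

    ``F = MS_between / MS_within`` on (g-1, N-g) degrees of freedom.
    Requires >=2 groups of >=2 values each with positive within-group
    variance.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("every group needs at least 2 values")
    ssw = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    if ssw <= 0:
        raise ValueError("zero within-group variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
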