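"""Accuracy metrics, cross-validation strategies and hyperparameter search.

Two metrics are implemented on the classifier's probabilistic answers:

* **overall accuracy** — the fraction of windows whose argmax-probability
  class equals the true class;
* **threshold accuracy** — each window is recoded against a probability
  threshold tau using the probability of the *predicted* class: correct and
  confident (p >= tau) is a true positive, correct but unconfident a false
  negative, incorrect and confident a false positive, incorrect and
  unconfident a true negative; the metric is (TP+TN)/(TP+TN+FP+FN).

Two data-splitting strategies are implemented: window-level random splits
(repeated shuffle splits or k-fold), which let one individual contribute to
both sides, and per-individual folds (leave-one-subject-out over whole
animals), which never do.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, ShuffleSplit

from .errors import EmptyDatasetError, UnknownBehaviourError, ValidationError
from .ethogram import chance_level, sorted_classes
from .features import FeatureDataset
from .model import (
    GridSpec,
    HyperParams,
    TrainedModel,
    fit,
    predict_from_proba,
    predict_proba,
)

# ---------------------------------------------------------------------------
# metrics


def overall_accuracy(predicted, true) -> float:
    predicted = np.asarray(predicted, dtype=object)
    true = np.asarray(true, dtype=object)
    if len(predicted) != len(true):
        raise ValidationError(
            f"length mismatch: {len(predicted)} predictions, {len(true)} truths"
        )
    if len(true) == 0:
        raise EmptyDatasetError("cannot compute accuracy of zero segments")
    return float(np.mean(predicted == true))


@dataclass(frozen=True)
class ThresholdCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ThresholdConfig:
    thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)

    def __post_init__(self):
        if not self.thresholds:
            raise ValidationError("at least one candidate threshold required")
        if any(not 0.0 < t < 1.0 for t in self.thresholds):
            raise ValidationError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValidationError("thresholds must be strictly increasing")


def _associated_probability(proba, predicted, classes) -> np.ndarray:
    index = {c: j for j, c in enumerate(classes)}
    cols = np.array([index[p] for p in predicted])
    return proba[np.arange(len(predicted)), cols]


def threshold_counts(proba, predicted, true, tau: float,
                     classes) -> ThresholdCounts:
    """Recode each segment as TP/FN/FP/TN against threshold ``tau``.

    The associated probability of a segment is the probability of its
    predicted (argmax) class; equality with the threshold counts as above.
    """
    if not 0.0 < tau < 1.0:
        raise ValidationError(f"threshold must lie in (0, 1), got {tau}")
    predicted = np.asarray(predicted, dtype=object)
    true = np.asarray(true, dtype=object)
    proba = np.asarray(proba, dtype=float)
    if not (len(predicted) == len(true) == proba.shape[0]):
        raise ValidationError("probability/prediction/truth lengths differ")
    p = _associated_probability(proba, predicted, classes)
    correct = predicted == true
    confident = p >= tau
    return ThresholdCounts(
        tp=int(np.sum(correct & confident)),
        tn=int(np.sum(~correct & ~confident)),
        fp=int(np.sum(~correct & confident)),
        fn=int(np.sum(correct & ~confident)),
    )


def threshold_accuracy(counts: ThresholdCounts) -> float:
    if counts.total == 0:
        raise EmptyDatasetError("cannot compute threshold accuracy of 0 segments")
    return (counts.tp + counts.tn) / counts.total


def choose_best_threshold(proba, predicted, true,
                          config: ThresholdConfig = ThresholdConfig(),
                          classes=None) -> tuple[float, float]:
    """Candidate threshold maximizing threshold accuracy; ties → smallest tau."""
    if classes is None:
        classes = sorted_classes(np.concatenate([np.asarray(predicted),
                                                 np.asarray(true)]))
    best_tau, best_val = None, -math.inf
    for tau in config.thresholds:
        val = threshold_accuracy(
            threshold_counts(proba, predicted, true, tau, classes))
        if val > best_val:
            best_tau, best_val = tau, val
    return best_tau, best_val


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class Fold:
    name: str
    train_idx: np.ndarray
    test_idx: np.ndarray


@dataclass(frozen=True)
class CVConfig:
    strategy: str = "per_individual"    # or "random"
    mode: str = "shuffle"               # random strategy: "shuffle" | "kfold"
    test_fraction: float = 0.30
    n_repeats: int = 7
    k: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("per_individual", "random"):
            raise ValidationError(f"unknown CV strategy {self.strategy!r}")
        if self.mode not in ("shuffle", "kfold"):
            raise ValidationError(f"unknown random-CV mode {self.mode!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValidationError("test_fraction must lie in (0, 1)")


def make_individual_folds(dataset: FeatureDataset) -> list[Fold]:
    """One fold per individual: its whole data is the test side."""
    individuals = dataset.individuals
    if len(individuals) < 2:
        raise ValidationError(
            f"per-individual CV needs >= 2 individuals, got {individuals}"
        )
    folds = []
    for ind in individuals:
        mask = dataset.individual_id == ind
        folds.append(Fold(f"individual={ind}",
                          np.flatnonzero(~mask), np.flatnonzero(mask)))
    return folds


def make_random_folds(dataset: FeatureDataset,
                      config: CVConfig = CVConfig(strategy="random")
                      ) -> list[Fold]:
    """Window-level random splits: repeated shuffle splits or k-fold."""
    if dataset.n == 0:
        raise EmptyDatasetError("cannot split an empty dataset")
    if config.mode == "shuffle":
        n_test = int(round(dataset.n * config.test_fraction))
        if n_test == 0 or n_test == dataset.n:
            raise ValidationError(
                f"test_fraction {config.test_fraction} leaves an empty side "
                f"for n={dataset.n}"
            )
        splitter = ShuffleSplit(n_splits=config.n_repeats,
                                test_size=config.test_fraction,
                                random_state=config.seed)
    else:
        if config.k > dataset.n:
            raise ValidationError(f"k={config.k} exceeds n={dataset.n}")
        splitter = KFold(n_splits=config.k, shuffle=True,
                         random_state=config.seed)
    return [Fold(f"random-{i}", tr, te)
            for i, (tr, te) in enumerate(splitter.split(dataset.X))]


def make_folds(dataset: FeatureDataset, config: CVConfig) -> list[Fold]:
    if config.strategy == "per_individual":
        return make_individual_folds(dataset)
    return make_random_folds(dataset, config)


# ---------------------------------------------------------------------------
# confusion matrices


@dataclass
class ConfusionMatrix:
    """Raw counts; entry (i, j) = true class i predicted as class j."""

    counts: np.ndarray
    classes: tuple[str, ...]

    @property
    def empty_rows(self) -> tuple[str, ...]:
        return tuple(c for c, s in zip(self.classes,
                                       self.counts.sum(axis=1)) if s == 0)

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized fractions; rows without true examples stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        sums[sums == 0] = 1.0
        return self.counts / sums

    @property
    def diagonal_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


def confusion_matrix(predicted, true, classes) -> ConfusionMatrix:
    predicted = np.asarray(predicted, dtype=object)
    true = np.asarray(true, dtype=object)
    if len(true) == 0:
        raise EmptyDatasetError("cannot tally an empty confusion matrix")
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(predicted) | set(true)) - set(classes)
    if unknown:
        raise UnknownBehaviourError(f"labels outside class list: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, t in zip(predicted, true):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(classes))


def merge_classes(conf: ConfusionMatrix,
                  merge_map: dict[str, tuple[str, ...]]) -> ConfusionMatrix:
    """Sum confusion counts over merged classes, then renormalize.

    ``merge_map`` maps each new class name to the tuple of old classes it
    absorbs and must partition the existing class list.
    """
    covered = [c for members in merge_map.values() for c in members]
    if sorted(covered) != sorted(conf.classes) or \
            len(set(covered)) != len(covered):
        raise ValidationError(
            "merge map must partition the class list exactly"
        )
    new_classes = tuple(sorted(merge_map))
    old_index = {c: i for i, c in enumerate(conf.classes)}
    counts = np.zeros((len(new_classes), len(new_classes)), dtype=int)
    for i, ni in enumerate(new_classes):
        for j, nj in enumerate(new_classes):
            rows = [old_index[c] for c in merge_map[ni]]
            cols = [old_index[c] for c in merge_map[nj]]
            counts[i, j] = conf.counts[np.ix_(rows, cols)].sum()
    return ConfusionMatrix(counts, new_classes)


# ---------------------------------------------------------------------------
# cross-validation and grid search


def mean_ci(values, level: float = 0.95, method: str = "normal"
            ) -> tuple[float, float, float]:
    """Mean with a symmetric CI over folds.

    ``normal`` uses mean +/- z * sd/sqrt(n) (z = 1.96 at 95%); ``t`` uses
    the small-sample t quantile instead.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, mean, mean
    sem = float(np.std(values, ddof=1) / math.sqrt(n))
    if method == "t":
        from scipy.stats import t as t_dist
        q = float(t_dist.ppf(0.5 + level / 2.0, df=n - 1))
    else:
        from scipy.stats import norm
        q = float(norm.ppf(0.5 + level / 2.0))
    return mean, mean - q * sem, mean + q * sem


@dataclass
class EvaluationReport:
    metric: str
    fold_values: list[float]
    mean: float
    ci_low: float
    ci_high: float
    params: HyperParams
    threshold: float | None
    confusion: ConfusionMatrix
    classes: tuple[str, ...]
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "fold_values": list(map(float, self.fold_values)),
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "params": {"C": self.params.C, "gamma": self.params.gamma},
            "threshold": self.threshold,
            "classes": list(self.classes),
            "confusion_counts": self.confusion.counts.tolist(),
            "confusion_normalized": self.confusion.normalized.tolist(),
            "extras": self.extras,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _validate_folds(dataset: FeatureDataset, folds) -> None:
    for fold in folds:
        train_classes = set(dataset.y[fold.train_idx])
        if len(train_classes) < 2:
            raise ValidationError(
                f"fold {fold.name!r}: training side has classes "
                f"{sorted(train_classes)}; need >= 2"
            )


def cross_validate(dataset: FeatureDataset, params: HyperParams, folds,
                   metric: str = "overall",
                   threshold_config: ThresholdConfig | None = None,
                   seed: int = 0,
                   ci_method: str = "normal") -> EvaluationReport:
    """Per-fold fit/predict with fold-local standardization.

    For the threshold metric, one threshold is chosen per evaluation: the
    candidate maximizing the mean over folds of the threshold accuracy.
    The confusion matrix accumulates all folds' test predictions.
    """
    if metric not in ("overall", "threshold"):
        raise ValidationError(f"unknown metric {metric!r}")
    folds = list(folds)
    if not folds:
        raise ValidationError("no folds supplied")
    _validate_folds(dataset, folds)
    if metric == "threshold" and threshold_config is None:
        threshold_config = ThresholdConfig()

    classes = dataset.classes
    conf_counts = np.zeros((len(classes), len(classes)), dtype=int)
    per_fold = []  # (proba, predicted, true, model_classes)
    for fold in folds:
        train = dataset.subset(fold.train_idx)
        test = dataset.subset(fold.test_idx)
        model = fit(train, params, seed=seed)
        proba = predict_proba(model, test)
        predicted = predict_from_proba(proba, model.classes)
        per_fold.append((proba, predicted, test.y, model.classes))
        conf_counts += confusion_matrix(predicted, test.y, classes).counts

    chosen_tau = None
    if metric == "overall":
        fold_values = [overall_accuracy(pred, true)
                       for _, pred, true, _ in per_fold]
    else:
        best_tau, best_mean, best_values = None, -math.inf, None
        for tau in threshold_config.thresholds:
            values = [
                threshold_accuracy(
                    threshold_counts(proba, pred, true, tau, mclasses))
                for proba, pred, true, mclasses in per_fold
            ]
            m = float(np.mean(values))
            if m > best_mean:
                best_tau, best_mean, best_values = tau, m, values
        chosen_tau, fold_values = best_tau, best_values

    mean, lo, hi = mean_ci(fold_values, method=ci_method)
    y_list = list(dataset.y)
    majority = max(set(y_list), key=y_list.count)
    return EvaluationReport(
        metric=metric,
        fold_values=fold_values,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        params=params,
        threshold=chosen_tau,
        confusion=ConfusionMatrix(conf_counts, classes),
        classes=classes,
        extras={
            "n_folds": len(folds),
            "fold_sizes": [int(len(f.test_idx)) for f in folds],
            "chance_level": chance_level(len(classes)),
            "majority_baseline": y_list.count(majority) / len(y_list),
            "ci_method": ci_method,
        },
    )


@dataclass
class GridSearchResult:
    best_params: HyperParams
    best_report: EvaluationReport
    table: pd.DataFrame

    def save_table(self, path) -> None:
        self.table.to_csv(path, index=False)


def grid_search(dataset: FeatureDataset, grid: GridSpec, folds,
                metric: str = "overall",
                threshold_config: ThresholdConfig | None = None,
                seed: int = 0) -> GridSearchResult:
    """Evaluate every (C, gamma) pair with ``cross_validate``.

    When the metric is threshold accuracy, the probability threshold is
    optimized within each parameter pair. Ties break toward smaller C, then
    smaller gamma (the enumeration order of :meth:`GridSpec.points`).
    """
    folds = list(folds)
    rows = []
    best = None  # (mean, params, report)
    for params in grid.points():
        report = cross_validate(dataset, params, folds, metric,
                                threshold_config, seed=seed)
        row = {"C": params.C, "gamma": params.gamma,
               "threshold": report.threshold, "metric_value": report.mean}
        for i, v in enumerate(report.fold_values):
            row[f"fold_{i}"] = v
        rows.append(row)
        if best is None or report.mean > best[0]:
            best = (report.mean, params, report)
    table = pd.DataFrame(rows)
    return GridSearchResult(best[1], best[2], table)
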