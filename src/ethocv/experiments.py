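"""The three experiment designs, run end-to-end on synthetic cohorts.

* ``run_group_matrix`` — optimize a model per group (grid search under
  per-individual CV) and cross-apply each to every other group, once
  optimizing overall accuracy and once threshold accuracy, reporting both
  metrics for each panel.
* ``run_cv_comparison`` — the random-vs-per-individual accuracy gap per
  group at identical hyperparameters.
* ``run_transfer_confusion`` — train on a source super-group (hyper-
  parameters chosen without any target data), predict a held-out target
  group, and report the full and the passive/feeding-merged confusion
  matrices.

Every runner is deterministic given its configuration and master seed, and
asserts internally that no test individual or target group ever reaches a
training side.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .ethogram import DEFAULT_MERGE_MAP
from .evaluation import (
    ConfusionMatrix,
    CVConfig,
    ThresholdConfig,
    choose_best_threshold,
    confusion_matrix,
    cross_validate,
    grid_search,
    make_folds,
    make_individual_folds,
    merge_classes,
    overall_accuracy,
    threshold_accuracy,
    threshold_counts,
)
from .features import FeatureConfig, build_feature_dataset, concat_datasets
from .model import GridSpec, HyperParams, fit, predict_from_proba, predict_proba
from .segmentation import SegmentationConfig, dataset_windows
from .synth import EthogramScript, GroupProfile, generate_cohort


@dataclass(frozen=True)
class GroupSpec:
    profile: GroupProfile
    n_individuals: int = 7


@dataclass
class ExperimentConfig:
    groups: list[GroupSpec]
    individual_effect: float = 0.5
    seconds_per_behaviour: float = 8.0
    script_repeats: int = 1
    seed: int = 0
    grid: GridSpec = field(default_factory=GridSpec.desk_scale)
    threshold_config: ThresholdConfig = field(default_factory=ThresholdConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    params: HyperParams | None = None  # fixed hyperparameters, if no search
    behaviour_models: dict | None = None  # custom signal registry

    def __post_init__(self):
        ids = [g.profile.group_id for g in self.groups]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate group ids: {ids}")


def _assert_disjoint_individuals(train_ids, test_ids) -> None:
    leak = set(train_ids) & set(test_ids)
    if leak:  # pragma: no cover - guard against internal bugs
        raise AssertionError(f"individual leakage across folds: {sorted(leak)}")


def build_group_dataset(spec: GroupSpec, config: ExperimentConfig,
                        seed: int):
    """Cohort → windows → features for one group."""
    script = EthogramScript.uniform(config.seconds_per_behaviour,
                                    repeats=config.script_repeats)
    cohort = generate_cohort(spec.n_individuals, spec.profile, script,
                             config.individual_effect, seed,
                             models=config.behaviour_models)
    windows = dataset_windows(cohort, config.segmentation)
    return build_feature_dataset(windows, config.features)


def _group_seed(master_seed: int, group_id: str) -> int:
    # stable per-group stream independent of group ordering; zlib.crc32 is
    # process-stable, unlike the salted builtin hash()
    h = np.random.SeedSequence(
        [master_seed, zlib.crc32(group_id.encode("utf-8"))])
    return int(h.generate_state(1)[0])


def _both_metrics(proba, predicted, true, classes,
                  threshold_config: ThresholdConfig,
                  tau: float | None) -> dict:
    """Overall and threshold accuracy of one evaluated prediction set.

    If ``tau`` is None the threshold is chosen from the candidates at
    evaluation time (the rule used whenever no threshold was fixed during
    optimization).
    """
    oa = overall_accuracy(predicted, true)
    if tau is None:
        tau, ta = choose_best_threshold(proba, predicted, true,
                                        threshold_config, classes)
    else:
        ta = threshold_accuracy(
            threshold_counts(proba, predicted, true, tau, classes))
    return {"overall": oa, "threshold": ta, "tau": tau}


def run_group_matrix(config: ExperimentConfig) -> dict:
    """G x G accuracy matrices under both optimization metrics.

    Diagonal (g, g): mean per-individual cross-validated accuracy within
    group g at the grid-search-chosen hyperparameters. Off-diagonal (g, h):
    the model refit on all of group g's data predicting all of group h.
    """
    if len(config.groups) < 2:
        raise ValidationError("group matrix needs >= 2 groups")
    group_ids = [g.profile.group_id for g in config.groups]
    datasets = {
        g.profile.group_id: build_group_dataset(
            g, config, _group_seed(config.seed, g.profile.group_id))
        for g in config.groups
    }
    out: dict = {"group_ids": group_ids, "panels": {}}
    for opt_metric in ("overall", "threshold"):
        G = len(group_ids)
        matrices = {"overall": np.full((G, G), np.nan),
                    "threshold": np.full((G, G), np.nan)}
        chosen: dict[str, dict] = {}
        for i, gid in enumerate(group_ids):
            ds = datasets[gid]
            folds = make_individual_folds(ds)
            for f in folds:
                _assert_disjoint_individuals(ds.individual_id[f.train_idx],
                                             ds.individual_id[f.test_idx])
            result = grid_search(ds, config.grid, folds, opt_metric,
                                 config.threshold_config, seed=config.seed)
            report = result.best_report
            tau = report.threshold
            # diagonal: both metrics of the optimized CV evaluation
            diag = cross_validate(ds, result.best_params, folds, "overall",
                                  seed=config.seed)
            matrices["overall"][i, i] = diag.mean
            ta_report = report if opt_metric == "threshold" else \
                cross_validate(ds, result.best_params, folds, "threshold",
                               config.threshold_config, seed=config.seed)
            matrices["threshold"][i, i] = ta_report.mean
            chosen[gid] = {"C": result.best_params.C,
                           "gamma": result.best_params.gamma,
                           "tau": tau}
            # off-diagonal: refit on all of group g, predict group h
            model = fit(ds, result.best_params, seed=config.seed)
            for j, hid in enumerate(group_ids):
                if hid == gid:
                    continue
                target = datasets[hid]
                _assert_disjoint_individuals(ds.individual_id,
                                             target.individual_id)
                proba = predict_proba(model, target)
                predicted = predict_from_proba(proba, model.classes)
                m = _both_metrics(proba, predicted, target.y, model.classes,
                                  config.threshold_config, tau)
                matrices["overall"][i, j] = m["overall"]
                matrices["threshold"][i, j] = m["threshold"]
        out["panels"][f"optimized_{opt_metric}"] = {
            "overall": matrices["overall"].tolist(),
            "threshold": matrices["threshold"].tolist(),
            "chosen_params": chosen,
        }
    return out


def run_cv_comparison(config: ExperimentConfig,
                      cv_random: CVConfig | None = None) -> dict:
    """Random-split vs per-individual accuracy, per group.

    Hyperparameters are identical for both strategies within a group:
    ``config.params`` when given, otherwise chosen once by grid search
    under per-individual CV.
    """
    if cv_random is None:
        cv_random = CVConfig(strategy="random", seed=config.seed)
    out: dict = {"groups": {}}
    for g in config.groups:
        gid = g.profile.group_id
        ds = build_group_dataset(g, config, _group_seed(config.seed, gid))
        ind_folds = make_individual_folds(ds)
        if config.params is not None:
            params = config.params
        else:
            params = grid_search(ds, config.grid, ind_folds, "overall",
                                 seed=config.seed).best_params
        rand_folds = make_folds(ds, cv_random)
        rep_ind = cross_validate(ds, params, ind_folds, "overall",
                                 seed=config.seed)
        rep_rand = cross_validate(ds, params, rand_folds, "overall",
                                  seed=config.seed)
        gap = rep_rand.mean - rep_ind.mean
        out["groups"][gid] = {
            "params": {"C": params.C, "gamma": params.gamma},
            "per_individual": {"mean": rep_ind.mean,
                               "ci": [rep_ind.ci_low, rep_ind.ci_high],
                               "fold_values": rep_ind.fold_values},
            "random": {"mean": rep_rand.mean,
                       "ci": [rep_rand.ci_low, rep_rand.ci_high],
                       "fold_values": rep_rand.fold_values,
                       "mode": cv_random.mode},
            "gap_random_minus_individual": gap,
        }
    return out


def run_transfer_confusion(config: ExperimentConfig,
                           source_group_ids: list[str],
                           target_group_id: str,
                           merge_map: dict | None = None) -> dict:
    """Cross-group transfer: fit on a source super-group, score the target.

    Hyperparameters are chosen by per-individual CV on the source only;
    the model is then refit on all source data.
    """
    if target_group_id in source_group_ids:
        raise ValidationError(
            f"target group {target_group_id!r} overlaps the source groups"
        )
    by_id = {g.profile.group_id: g for g in config.groups}
    for gid in [*source_group_ids, target_group_id]:
        if gid not in by_id:
            raise ValidationError(f"unknown group id {gid!r}")
    if merge_map is None:
        merge_map = DEFAULT_MERGE_MAP
    source = concat_datasets([
        build_group_dataset(by_id[gid], config,
                            _group_seed(config.seed, gid))
        for gid in source_group_ids
    ])
    target = build_group_dataset(by_id[target_group_id], config,
                                 _group_seed(config.seed, target_group_id))
    _assert_disjoint_individuals(source.individual_id, target.individual_id)

    folds = make_individual_folds(source)
    if config.params is not None:
        params = config.params
    else:
        params = grid_search(source, config.grid, folds, "overall",
                             seed=config.seed).best_params
    model = fit(source, params, seed=config.seed)
    proba = predict_proba(model, target)
    predicted = predict_from_proba(proba, model.classes)
    conf = confusion_matrix(predicted, target.y, model.classes)
    merged = merge_classes(conf, merge_map)
    return {
        "params": {"C": params.C, "gamma": params.gamma},
        "overall_accuracy": overall_accuracy(predicted, target.y),
        "classes": list(conf.classes),
        "confusion_counts": conf.counts.tolist(),
        "confusion_normalized": conf.normalized.tolist(),
        "merged_classes": list(merged.classes),
        "merged_counts": merged.counts.tolist(),
        "merged_normalized": merged.normalized.tolist(),
        "merged_overall_accuracy": merged.diagonal_accuracy,
    }


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
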