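"""End-to-end decoding experiments on epoched data.

Four analyses, each repeated ``n_runs`` times with medians reported:

* task classification — can a decoder tell scene-memory from
  spatial-memory epochs (k = 2)?
* goal decoding — retrieve the learned goal direction (k = 3) from
  correct spatial-memory trials with a fixed door count;
* affordance generalization — train a door-configuration decoder (k = 7)
  on one task, score it on held-out same-task trials and on all trials of
  the other task;
* color generalization — the same transfer design for wall color (k = 8),
  the control feature expected to generalize across tasks.

Every run re-balances, re-splits (80/20 pooled, stratified by subject and
class), re-normalizes with training-partition statistics only, trains a
fresh network, scores per-subject five-fold accuracies on the holdout,
tests them against the binomial null, and computes the Grad-CAM grand-mean
map. Train/test trial sets are asserted disjoint everywhere.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .epochs import EpochSet
from .gradcam import AttributionMap, grad_cam, run_median, subject_then_grand_mean
from .model import (
    ModelConfig,
    TrainConfig,
    build_model,
    evaluate_per_subject_cv,
    pooled_split,
    predict,
)
from .nn.network import train as train_network
from .preprocess import PreprocessConfig, balance_classes, normalize_subject, standard_pipeline
from .schedule import TASK_SCENE, TASK_SPATIAL
from .stats import ChanceModel, bootstrap_vs_chance, chance_level
from .utils import child_seed

EXPERIMENT_NAMES = ("task_classification", "goal_decoding",
                    "affordance_generalization", "color_generalization")


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    label_field: str
    k_classes: int
    train_task: str | None = None  # None: pool both tasks
    test_tasks: tuple[str, ...] = ()
    trial_filter: str | None = None  # pandas query on metadata
    n_runs: int = 5
    n_bootstrap: int = 100_000
    alpha: float = 0.05
    chance_k_override: int | None = None

    def __post_init__(self) -> None:
        for t in (self.train_task, *self.test_tasks):
            if t is not None and t not in (TASK_SCENE, TASK_SPATIAL):
                raise ValueError(f"unknown task {t!r}")


@dataclass
class RunResult:
    accuracies: np.ndarray  # per-subject %, same-task holdout
    chance_test: dict
    attribution: AttributionMap | None
    cross_task: dict = field(default_factory=dict)  # task -> {accuracies, chance_test}
    n_train: int = 0
    n_holdout: int = 0
    seed: int = 0

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


@dataclass
class ExperimentReport:
    spec: ExperimentSpec
    runs: list[RunResult]
    notes: list[str] = field(default_factory=list)

    @property
    def run_accuracies(self) -> np.ndarray:
        return np.array([r.mean_accuracy for r in self.runs])

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.run_accuracies))

    @property
    def median_attribution(self) -> AttributionMap | None:
        maps = [r.attribution for r in self.runs if r.attribution is not None]
        return run_median(maps) if maps else None

    def median_cross_task_accuracy(self, task: str) -> float:
        vals = [float(np.mean(r.cross_task[task]["accuracies"])) for r in self.runs]
        return float(np.median(vals))

    def to_dict(self) -> dict:
        out = {
            "name": self.spec.name,
            "label_field": self.spec.label_field,
            "k_classes": self.spec.k_classes,
            "chance_level_pct": chance_level(
                self.spec.chance_k_override or self.spec.k_classes),
            "n_runs": len(self.runs),
            "median_accuracy_pct": self.median_accuracy,
            "run_accuracies_pct": self.run_accuracies.tolist(),
            "runs": [],
            "notes": self.notes,
        }
        for r in self.runs:
            rd = {
                "seed": r.seed,
                "subject_accuracies_pct": np.asarray(r.accuracies).tolist(),
                "mean_accuracy_pct": r.mean_accuracy,
                "chance_test": r.chance_test,
                "n_train": r.n_train,
                "n_holdout": r.n_holdout,
                "cross_task": {
                    t: {
                        "subject_accuracies_pct": np.asarray(v["accuracies"]).tolist(),
                        "mean_accuracy_pct": float(np.mean(v["accuracies"])),
                        "chance_test": v["chance_test"],
                    } for t, v in r.cross_task.items()
                },
            }
            out["runs"].append(rd)
        if self.spec.test_tasks:
            out["median_cross_task_accuracy_pct"] = {
                t: self.median_cross_task_accuracy(t) for t in self.spec.test_tasks}
        return out


def _single_run(epochs: EpochSet, spec: ExperimentSpec, run_seed: int,
                model_config: ModelConfig, train_config: TrainConfig,
                compute_gradcam: bool = True) -> RunResult:
    """One balance/split/train/score/attribute cycle on preprocessed epochs."""
    work = epochs
    if spec.trial_filter:
        work = work.query(spec.trial_filter)
        if work.n_trials == 0:
            raise ValueError(f"trial filter {spec.trial_filter!r} left no trials")
    if spec.train_task is not None:
        train_pool = work.query(f"task == '{spec.train_task}'")
        if train_pool.n_trials == 0:
            raise ValueError(f"no trials for train task {spec.train_task!r}")
    else:
        train_pool = work
        missing = {TASK_SCENE, TASK_SPATIAL} - set(work.metadata["task"].unique())
        if spec.label_field == "task" and missing:
            raise ValueError(f"missing task(s) {sorted(missing)} in the data")

    labels = np.unique(train_pool.labels(spec.label_field))
    if len(labels) != spec.k_classes:
        raise ValueError(
            f"{spec.name}: {len(labels)} classes in {spec.label_field!r}, "
            f"expected {spec.k_classes}")

    balanced = balance_classes(train_pool, spec.label_field,
                               seed=child_seed(run_seed, "balance"))
    train_set, holdout = pooled_split(balanced, spec.label_field, 0.8,
                                      seed=child_seed(run_seed, "split"))

    # leakage audit: train and holdout must be disjoint trial sets
    key_cols = ["participant_id", "trial_index"]
    tr_keys = set(map(tuple, train_set.metadata[key_cols].to_numpy()))
    ho_keys = set(map(tuple, holdout.metadata[key_cols].to_numpy()))
    assert not tr_keys & ho_keys, "train/holdout trial sets overlap"

    # per-subject z-score with statistics fit on the training partition only
    train_norm, norm_stats = normalize_subject(train_set)
    holdout_norm, _ = normalize_subject(holdout, stats=norm_stats)

    mc = replace(model_config,
                 n_channels=train_norm.n_channels,
                 n_samples=train_norm.n_samples,
                 n_classes=spec.k_classes,
                 seed=child_seed(run_seed, "init"))
    tc = replace(train_config, seed=child_seed(run_seed, "train"))
    clf = build_model(mc, labels=labels)
    clf = train_network(clf, train_norm.data, train_norm.labels(spec.label_field),
                        tc=tc)

    cv = evaluate_per_subject_cv(clf, holdout_norm, spec.label_field, k=5,
                                 seed=child_seed(run_seed, "cv"))
    accuracies = 100.0 * cv["accuracies"]
    chance_k = spec.chance_k_override or spec.k_classes
    cm = ChanceModel(chance_k, max(1, int(round(cv["mean_n_trials"]))), spec.alpha)
    ctest = bootstrap_vs_chance(accuracies, cm, n_iter=spec.n_bootstrap,
                                seed=child_seed(run_seed, "bootstrap"))

    attribution = None
    if compute_gradcam:
        maps = grad_cam(clf, holdout_norm)
        attribution = subject_then_grand_mean(
            maps, holdout_norm.labels("participant_id"))

    cross: dict = {}
    for test_task in spec.test_tasks:
        test_set = work.query(f"task == '{test_task}'")
        te_keys = set(map(tuple, test_set.metadata[key_cols].to_numpy()))
        assert not tr_keys & te_keys, "cross-task test set overlaps training trials"
        test_norm, _ = normalize_subject(test_set, stats=norm_stats)
        tcv = evaluate_per_subject_cv(clf, test_norm, spec.label_field, k=5,
                                      seed=child_seed(run_seed, "cv_cross"))
        tacc = 100.0 * tcv["accuracies"]
        tcm = ChanceModel(chance_k, max(1, int(round(tcv["mean_n_trials"]))),
                          spec.alpha)
        tres = bootstrap_vs_chance(tacc, tcm, n_iter=spec.n_bootstrap,
                                   seed=child_seed(run_seed, "bootstrap_cross"))
        cross[test_task] = {"accuracies": tacc, "chance_test": tres.to_dict()}

    return RunResult(accuracies=accuracies, chance_test=ctest.to_dict(),
                     attribution=attribution, cross_task=cross,
                     n_train=train_norm.n_trials, n_holdout=holdout_norm.n_trials,
                     seed=run_seed)


def _run_experiment(epochs: EpochSet, spec: ExperimentSpec, seed: int,
                    model_config: ModelConfig, train_config: TrainConfig,
                    compute_gradcam: bool = True,
                    preprocessed: bool = False) -> ExperimentReport:
    if preprocessed:
        conditioned = epochs
        report = {}
    else:
        conditioned, report = standard_pipeline(epochs)
    runs = [
        _single_run(conditioned, spec, child_seed(seed, "run", r),
                    model_config, train_config, compute_gradcam)
        for r in range(spec.n_runs)
    ]
    notes = []
    if report:
        notes.append(f"preprocessing: {report['n_in']} -> {report['n_out']} trials, "
                     f"dropped {report['channels_dropped']}")
    if spec.chance_k_override and spec.chance_k_override != spec.k_classes:
        notes.append(
            f"chance tested against 1/{spec.chance_k_override} although the decoder "
            f"has {spec.k_classes} classes (reported-analysis inconsistency, kept "
            f"parameterized rather than resolved)")
    return ExperimentReport(spec=spec, runs=runs, notes=notes)


# ---- the four experiments --------------------------------------------------

def run_task_classification(epochs: EpochSet, seed: int = 0, n_runs: int = 5,
                            model_config: ModelConfig = ModelConfig(),
                            train_config: TrainConfig = TrainConfig(),
                            n_bootstrap: int = 100_000,
                            compute_gradcam: bool = True,
                            preprocessed: bool = False) -> ExperimentReport:
    """Scene-memory vs spatial-memory classification (k = 2) on pooled data."""
    spec = ExperimentSpec("task_classification", "task", 2, n_runs=n_runs,
                          n_bootstrap=n_bootstrap)
    return _run_experiment(epochs, spec, seed, model_config, train_config,
                           compute_gradcam, preprocessed)


def run_goal_decoding(epochs: EpochSet, n_doors: int = 2, seed: int = 0,
                      n_runs: int = 5,
                      model_config: ModelConfig = ModelConfig(),
                      train_config: TrainConfig = TrainConfig(),
                      n_bootstrap: int = 100_000,
                      compute_gradcam: bool = True,
                      preprocessed: bool = False) -> ExperimentReport:
    """Goal-direction decoding (k = 3) on correct spatial-memory trials with
    the requested door count."""
    if n_doors not in (2, 3):
        raise ValueError("n_doors must be 2 or 3")
    spec = ExperimentSpec(
        "goal_decoding", "goal_direction", 3,
        train_task=TASK_SPATIAL,
        trial_filter=f"task == '{TASK_SPATIAL}' and n_doors == {n_doors} "
                     "and response_correct",
        n_runs=n_runs, n_bootstrap=n_bootstrap)
    return _run_experiment(epochs, spec, seed, model_config, train_config,
                           compute_gradcam, preprocessed)


def run_affordance_generalization(epochs: EpochSet,
                                  train_task: str = TASK_SCENE,
                                  test_task: str = TASK_SPATIAL,
                                  seed: int = 0, n_runs: int = 5,
                                  model_config: ModelConfig = ModelConfig(),
                                  train_config: TrainConfig = TrainConfig(),
                                  n_bootstrap: int = 100_000,
                                  compute_gradcam: bool = True,
                                  preprocessed: bool = False,
                                  chance_k_override: int | None = None
                                  ) -> ExperimentReport:
    """Door-configuration decoding (k = 7) trained within one task, scored on
    held-out same-task trials and on every trial of the other task."""
    if train_task == test_task:
        raise ValueError("train and test tasks must differ")
    spec = ExperimentSpec(
        "affordance_generalization", "door_configuration", 7,
        train_task=train_task, test_tasks=(test_task,),
        n_runs=n_runs, n_bootstrap=n_bootstrap,
        chance_k_override=chance_k_override)
    return _run_experiment(epochs, spec, seed, model_config, train_config,
                           compute_gradcam, preprocessed)


def run_color_generalization(epochs: EpochSet, seed: int = 0, n_runs: int = 5,
                             model_config: ModelConfig = ModelConfig(),
                             train_config: TrainConfig = TrainConfig(),
                             n_bootstrap: int = 100_000,
                             compute_gradcam: bool = True,
                             preprocessed: bool = False) -> ExperimentReport:
    """Wall-color decoding trained on scene-memory data, transferred to the
    spatial-memory task (the task-invariant control feature)."""
    colors = np.unique(epochs.labels("wall_color"))
    if len(colors) < 2:
        raise ValueError("color decoding needs at least two wall colors")
    spec = ExperimentSpec(
        "color_generalization", "wall_color", int(len(colors)),
        train_task=TASK_SCENE, test_tasks=(TASK_SPATIAL,),
        n_runs=n_runs, n_bootstrap=n_bootstrap)
    return _run_experiment(epochs, spec, seed, model_config, train_config,
                           compute_gradcam, preprocessed)


# ---- full report -----------------------------------------------------------

@dataclass(frozen=True)
class ScaleProfile:
    """Problem sizes for a full report; 'smoke' exists to exercise the whole
    pipeline in well under two minutes, 'desk' is the reduced default, and
    'full' mirrors the complete study design (slow)."""

    name: str
    n_subjects: int
    trials_per_task: int
    n_runs: int
    n_bootstrap: int
    model_config: ModelConfig
    train_config: TrainConfig
    epoch_window: tuple[float, float] = (-0.3, 1.1)
    n_colors_default: int = 7
    n_colors_color_exp: int = 8


SMOKE_MODEL = ModelConfig(f1=4, temporal_kernel_len=16, depth_multiplier=1, f2=4,
                          pool_sizes=(8, 8), sep_kernel_len=8, dropout_rate=0.1)
SMOKE_TRAIN = TrainConfig(max_epochs=3, batch_size=64, learning_rate=5e-3,
                          patience=2, validation_fraction=0.2)
DESK_MODEL = ModelConfig(f1=4, temporal_kernel_len=32, depth_multiplier=2, f2=16,
                         pool_sizes=(4, 8), sep_kernel_len=8, dropout_rate=0.25)
DESK_TRAIN = TrainConfig(max_epochs=30, batch_size=64, learning_rate=2e-3,
                         patience=5, validation_fraction=0.15)
FULL_MODEL = ModelConfig()
FULL_TRAIN = TrainConfig()

SCALE_PROFILES = {
    "smoke": ScaleProfile("smoke", 3, 112, 1, 2_000, SMOKE_MODEL, SMOKE_TRAIN),
    "desk": ScaleProfile("desk", 5, 399, 5, 10_000, DESK_MODEL, DESK_TRAIN),
    "full": ScaleProfile("full", 30, 770, 5, 100_000, FULL_MODEL, FULL_TRAIN,
                         epoch_window=(-1.0, 2.0)),
}


def run_full_report(seed: int = 0, profile: str = "desk",
                    compute_gradcam: bool = True) -> dict:
    """Simulate one cohort per scenario and run all four experiments.

    The affordance cohort uses remapped spatial-memory patterns (the
    condition under which cross-task transfer is expected to fail); the
    color cohort keeps task-invariant patterns (transfer expected to
    succeed). Failures of individual experiments are recorded and the rest
    continue.
    """
    from .simulate import simulate_cohort  # local import to avoid cycle

    prof = SCALE_PROFILES[profile]
    t_start = time.time()
    summary: dict = {"profile": prof.name, "master_seed": int(seed),
                     "experiments": {}, "errors": {}}

    def cohort(scenario: str, remap: bool = False, n_colors: int | None = None):
        return simulate_cohort(
            scenario, n_subjects=prof.n_subjects, seed=child_seed(seed, scenario),
            trials_per_task=prof.trials_per_task,
            n_colors=n_colors or prof.n_colors_default, remap=remap,
            epoch_window=prof.epoch_window)

    jobs = {
        "task_classification": lambda: run_task_classification(
            cohort("task"), seed=child_seed(seed, "e_task"), n_runs=prof.n_runs,
            model_config=prof.model_config, train_config=prof.train_config,
            n_bootstrap=prof.n_bootstrap, compute_gradcam=compute_gradcam),
        "goal_decoding": lambda: run_goal_decoding(
            cohort("goal"), n_doors=2, seed=child_seed(seed, "e_goal"),
            n_runs=prof.n_runs, model_config=prof.model_config,
            train_config=prof.train_config, n_bootstrap=prof.n_bootstrap,
            compute_gradcam=compute_gradcam),
        "affordance_generalization": lambda: run_affordance_generalization(
            cohort("affordance", remap=True), seed=child_seed(seed, "e_afford"),
            n_runs=prof.n_runs, model_config=prof.model_config,
            train_config=prof.train_config, n_bootstrap=prof.n_bootstrap,
            compute_gradcam=compute_gradcam),
        "color_generalization": lambda: run_color_generalization(
            cohort("color", n_colors=prof.n_colors_color_exp),
            seed=child_seed(seed, "e_color"), n_runs=prof.n_runs,
            model_config=prof.model_config, train_config=prof.train_config,
            n_bootstrap=prof.n_bootstrap, compute_gradcam=compute_gradcam),
    }
    reports: dict = {}
    for name, job in jobs.items():
        try:
            rep = job()
            reports[name] = rep
            summary["experiments"][name] = rep.to_dict()
        except Exception as exc:  # record and continue with the others
            summary["errors"][name] = f"{type(exc).__name__}: {exc}"
    summary["runtime_s"] = round(time.time() - t_start, 2)
    summary["_reports"] = reports  # live objects, stripped before JSON dump
    return summary
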