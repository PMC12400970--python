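"""Model-level workflow: splitting, per-subject evaluation, hyperparameter search.

Evaluation follows the pooled-training design: one network is trained on
80% of the pooled multi-subject data, and accuracy is then scored on the
held-out 20% with five-fold cross-validation *per subject* — the folds
re-score the already-trained model (no refitting), yielding one accuracy
per participant for the chance-level statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np

from .epochs import EpochSet
from .nn import (  # noqa: F401  (re-exported surface)
    ClassifierModel,
    ModelConfig,
    TrainConfig,
    build_model,
    class_weights,
    predict,
    train,
)
from .utils import substream


def train_on_epochs(model: ClassifierModel, train_set: EpochSet, label_field: str,
                    val_set: EpochSet | None = None,
                    tc: TrainConfig | None = None) -> ClassifierModel:
    """Label-field-aware wrapper around the array-level training loop."""
    x_val = y_val = None
    if val_set is not None:
        x_val, y_val = val_set.data, val_set.labels(label_field)
    return train(model, train_set.data, train_set.labels(label_field),
                 x_val, y_val, tc)


def pooled_split(epochs: EpochSet, label_field: str, train_fraction: float = 0.8,
                 seed: int = 0) -> tuple[EpochSet, EpochSet]:
    """Disjoint, exhaustive 80/20 split stratified by subject x class."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    subjects = epochs.labels("participant_id")
    labels = epochs.labels(label_field)
    rng = substream(seed, "pooled_split")
    train_idx, hold_idx = [], []
    for s in np.unique(subjects):
        for cls in np.unique(labels):
            idx = np.flatnonzero((subjects == s) & (labels == cls))
            if len(idx) == 0:
                raise ValueError(f"empty stratum: subject {s}, class {cls!r}")
            idx = rng.permutation(idx)
            n_train = int(round(train_fraction * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1) if len(idx) > 1 else len(idx)
            train_idx.append(idx[:n_train])
            hold_idx.append(idx[n_train:])
    return (epochs.select(np.sort(np.concatenate(train_idx))),
            epochs.select(np.sort(np.concatenate(hold_idx))))


def evaluate_per_subject_cv(model: ClassifierModel, holdout: EpochSet,
                            label_field: str, k: int = 5, seed: int = 0
                            ) -> dict:
    """Per-subject k-fold scoring of a single trained model (no refitting).

    Each subject's holdout trials are partitioned into k seeded folds
    (sizes differing by at most one); the subject's accuracy is the mean of
    the fold accuracies. Subjects with fewer than k trials are skipped with
    a warning entry in the result.
    """
    subjects = holdout.labels("participant_id")
    y_true = model.encode_labels(holdout.labels(label_field))
    y_pred_labels, _ = predict(model, holdout.data)
    y_pred = model.encode_labels(y_pred_labels)
    correct = y_pred == y_true

    rng = substream(seed, "subject_cv")
    per_subject: dict = {}
    skipped: list = []
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        if len(idx) < k:
            skipped.append(s)
            continue
        idx = rng.permutation(idx)
        folds = np.array_split(idx, k)
        fold_acc = [float(correct[f].mean()) for f in folds]
        per_subject[s] = {"accuracy": float(np.mean(fold_acc)), "folds": fold_acc,
                          "n_trials": int(len(idx))}
    if skipped:
        import warnings
        warnings.warn(f"subjects with < {k} holdout trials skipped: {skipped}")
    return {
        "per_subject": per_subject,
        "accuracies": np.array([v["accuracy"] for v in per_subject.values()]),
        "mean_n_trials": float(np.mean([v["n_trials"] for v in per_subject.values()]))
        if per_subject else 0.0,
        "skipped": skipped,
    }


DEFAULT_SEARCH_SPACE = {
    "learning_rate": [3e-4, 1e-3, 2e-3, 5e-3],
    "weight_decay": [0.0, 1e-4, 1e-3],
    "batch_size": [32, 64, 128],
    "dropout_rate": [0.1, 0.25, 0.5],
    "f1": [4, 8],
    "depth_multiplier": [1, 2],
    "max_epochs": [40, 60],
    "patience": [4, 8],
}


def hyperparameter_search(space: dict, x_train, y_train, x_val, y_val,
                          base_model: ModelConfig, base_train: TrainConfig,
                          budget: int = 8, seed: int = 0,
                          halving_epochs: tuple[int, ...] = (4, 12, 30)
                          ) -> dict:
    """Seeded random search with successive halving.

    ``budget`` configurations are sampled uniformly from ``space`` (keys may
    name ModelConfig or TrainConfig fields). All candidates train for the
    first rung's epoch budget; the better half survives each rung, training
    longer, until one remains. Returns the winner plus the full trial log.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("empty search space")
    rng = substream(seed, "hyperparameter_search")
    model_fields = set(ModelConfig.__dataclass_fields__)
    train_fields = set(TrainConfig.__dataclass_fields__)

    def sample() -> tuple[ModelConfig, TrainConfig]:
        mc, tc = base_model, base_train
        for key, choices in space.items():
            val = choices[rng.integers(len(choices))]
            if key in model_fields:
                mc = replace(mc, **{key: val})
            elif key in train_fields:
                tc = replace(tc, **{key: val})
            else:
                raise KeyError(f"unknown hyperparameter {key!r}")
        return mc, tc

    candidates = [sample() for _ in range(budget)]
    log: list[dict] = []
    alive = list(range(budget))
    for rung, epochs in enumerate(halving_epochs):
        scores = []
        for ci in alive:
            mc, tc = candidates[ci]
            ep = min(epochs, tc.max_epochs)
            tc_rung = replace(tc, max_epochs=ep, patience=min(tc.patience, max(1, ep - 1)))
            model = build_model(mc)
            model = train(model, x_train, y_train, x_val, y_val, tc_rung)
            val_acc = max((h["val_acc"] for h in model.history if "val_acc" in h),
                          default=0.0)
            scores.append(val_acc)
            log.append({"candidate": ci, "rung": rung, "epochs": ep,
                        "val_acc": val_acc})
        order = np.argsort(scores)[::-1]
        alive = [alive[i] for i in order[: max(1, len(alive) // 2)]]
        if len(alive) == 1:
            break
    best = alive[0]
    mc, tc = candidates[best]
    return {"model_config": mc, "train_config": tc, "log": log,
            "best_candidate": best}


def search_space_grid(space: dict) -> list[dict]:
    """Materialize the full grid of a discrete space (for small audits)."""
    keys = list(space)
    return [dict(zip(keys, combo)) for combo in itertools.product(*space.values())]
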