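"""The compact CNN: architecture arithmetic, training, evaluation, search."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from eegdecode.epochs import EpochSet
from eegdecode.model import (
    DEFAULT_SEARCH_SPACE,
    ModelConfig,
    TrainConfig,
    build_model,
    evaluate_per_subject_cv,
    hyperparameter_search,
    pooled_split,
    predict,
    train,
)
from eegdecode.nn import layers as L
from eegdecode.nn.network import class_weights

from conftest import make_epochs

SMALL = ModelConfig(n_channels=8, n_samples=64, n_classes=2, f1=4,
                    temporal_kernel_len=16, depth_multiplier=2, f2=8,
                    pool_sizes=(4, 4), sep_kernel_len=8, dropout_rate=0.1, seed=0)
FAST = TrainConfig(max_epochs=30, batch_size=32, learning_rate=5e-3,
                   weight_decay=0.0, patience=29, validation_fraction=0.2, seed=0)


def two_class_data(rng, n=120, n_channels=8, n_samples=64, sep=10.0):
    """Noiseless-ish separable set: class 1 carries a bump on channel 2."""
    x = rng.standard_normal((n, n_channels, n_samples)).astype(np.float32)
    y = np.array(["a", "b"])[np.arange(n) % 2]
    bump = sep * np.exp(-0.5 * ((np.arange(n_samples) - 30) / 5.0) ** 2)
    x[y == "b", 2, :] += bump
    return x, y


class TestArchitecture:
    def test_logit_shape_contract(self, rng):
        model = build_model(SMALL)
        x = rng.standard_normal((5, 8, 64)).astype(np.float32)
        _, logits = predict(model, x)
        assert logits.shape == (5, 2)
        p = np.exp(logits - logits.max(1, keepdims=True))
        assert np.allclose((p / p.sum(1, keepdims=True)).sum(1), 1.0)

    def test_parameter_count_matches_layer_arithmetic(self):
        # hand count for the full-scale default: F1=8, L=64, D=2, C=61,
        # F2=16, sep L=16, pools (4,8) on 251 samples, K=2
        cfg = ModelConfig(n_channels=61, n_samples=251, n_classes=2)
        model = build_model(cfg)
        expected = (
            8 * 64          # temporal kernels
            + 8 * 2 * 61    # depthwise spatial
            + 16 * 16       # pointwise block 1
            + 16 + 16       # batch norm 1 (gamma, beta)
            + 16 * 16       # separable depthwise temporal
            + 16 * 16       # separable pointwise
            + 16 + 16       # batch norm 2
            + 2 * (16 * 7)  # dense: 251//4=62, 62//8=7 -> 112 features
            + 2             # dense bias
        )
        total = sum(p.size for _, p, _ in model.network.parameters())
        assert total == expected == 2546

    def test_pooled_lengths_floor_division(self):
        cfg = ModelConfig(n_channels=61, n_samples=251, n_classes=2,
                          pool_sizes=(4, 8))
        model = build_model(cfg)
        assert model.network.pooled_lengths == [62, 7]

    def test_pooled_length_below_one_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_channels=8, n_samples=16, n_classes=2, pool_sizes=(8, 8))

    def test_fused_block_equals_sequential_layers(self, rng):
        """The fused spatial-first block must reproduce the sequential
        temporal -> depthwise-spatial -> pointwise computation exactly."""
        x = rng.standard_normal((6, 11, 48)).astype(np.float32)
        fused = L.FusedConvBlock1(3, 9, 2, 11, 5, np.random.default_rng(7))
        tc = L.TemporalConv(3, 9, np.random.default_rng(0))
        sp = L.DepthwiseSpatialConv(3, 2, 11, np.random.default_rng(0))
        pw = L.PointwiseConv(6, 5, np.random.default_rng(0))
        tc.w, sp.w, pw.w = fused.wt.copy(), fused.ws.copy(), fused.wp.copy()
        y_seq = pw.forward(sp.forward(tc.forward(x, False), False), False)
        y_fused = fused.forward(x, False)
        np.testing.assert_allclose(y_fused, y_seq, atol=1e-5)
        dy = rng.standard_normal(y_seq.shape).astype(np.float32)
        dx_seq = tc.backward(sp.backward(pw.backward(dy)))
        dx_fused = fused.backward(dy)
        np.testing.assert_allclose(dx_fused, dx_seq, atol=1e-4)
        np.testing.assert_allclose(fused.dwt, tc.dw, atol=1e-3)
        np.testing.assert_allclose(fused.dws, sp.dw, atol=1e-3)
        np.testing.assert_allclose(fused.dwp, pw.dw, atol=1e-3)

    def test_three_block_variant_builds_and_runs(self, rng):
        cfg = dataclasses.replace(SMALL, n_samples=128, n_blocks=3,
                                  pool_sizes=(4, 4, 2))
        model = build_model(cfg)
        _, logits = predict(model, rng.standard_normal((3, 8, 128)).astype(np.float32))
        assert logits.shape == (3, 2)


class TestClassWeights:
    def test_stated_formula(self):
        y = np.array([0] * 30 + [1] * 10)
        w = class_weights(y, 2)
        np.testing.assert_allclose(w, [40 / 60, 40 / 20])

    def test_weighted_counts_sum_to_n(self, rng):
        y = rng.integers(0, 3, 200)
        w = class_weights(y, 3)
        counts = np.bincount(y, minlength=3)
        assert np.isclose((counts * w).sum(), 200.0)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            class_weights(np.zeros(10, dtype=int), 2)


class TestTrainPredict:
    def test_learns_separable_two_class_problem(self, rng):
        x, y = two_class_data(rng)
        model = build_model(SMALL)
        model = train(model, x, y, tc=FAST)
        best_val = max(h["val_acc"] for h in model.history if "val_acc" in h)
        assert best_val >= 0.95

    def test_capacity_memorizes_random_labels(self, rng):
        # 64 trials with random labels: the model must be able to overfit
        x = rng.standard_normal((64, 8, 64)).astype(np.float32)
        y = rng.integers(0, 2, 64)
        model = build_model(dataclasses.replace(SMALL, dropout_rate=0.0, f2=16))
        tc = dataclasses.replace(FAST, max_epochs=300, patience=299,
                                 learning_rate=3e-3)
        # validation = the training set itself: this is a pure capacity check
        model = train(model, x, y, x, y, tc=tc)
        _, logits = predict(model, x)
        assert (logits.argmax(1) == y).mean() >= 0.99

    def test_early_stopping_restores_best_epoch(self, rng):
        x, y = two_class_data(rng, n=80)
        model = build_model(SMALL)
        tc = dataclasses.replace(FAST, max_epochs=25, patience=3)
        model = train(model, x, y, tc=tc)
        summary = model.history[-1]
        epochs_run = len(model.history) - 1
        assert summary["best_epoch"] <= epochs_run - 1
        losses = [h["val_loss"] for h in model.history if "val_loss" in h]
        assert np.isclose(min(losses), summary["best_val_loss"])

    def test_runs_all_epochs_when_improving(self, rng):
        x, y = two_class_data(rng, n=80, sep=30.0)
        model = build_model(SMALL)
        tc = dataclasses.replace(FAST, max_epochs=5, patience=4)
        model = train(model, x, y, tc=tc)
        # patience never exceeded before max_epochs on a strongly learnable set
        assert len(model.history) - 1 >= 3

    def test_deterministic_given_seed(self, rng):
        x, y = two_class_data(rng, n=60)
        tc = dataclasses.replace(FAST, max_epochs=4, patience=3)
        runs = []
        for _ in range(2):
            model = train(build_model(SMALL), x, y, tc=tc)
            _, logits = predict(model, x)
            runs.append(logits)
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_tie_breaks_to_lowest_index_and_zeroed_head(self, rng):
        model = build_model(SMALL, labels=["a", "b"])
        dense = model.network.layers[-1]
        dense.w[...] = 0.0
        dense.b[...] = 0.0
        x = rng.standard_normal((7, 8, 64)).astype(np.float32)
        labels, logits = predict(model, x)
        assert np.allclose(logits, logits[:, :1])
        assert (labels == "a").all()

    def test_prediction_order_equivariant(self, rng):
        x, y = two_class_data(rng, n=40)
        model = train(build_model(SMALL), x, y,
                      tc=dataclasses.replace(FAST, max_epochs=3, patience=2))
        perm = rng.permutation(len(x))
        labels, _ = predict(model, x)
        labels_perm, _ = predict(model, x[perm])
        assert (labels_perm == labels[perm]).all()

    def test_shape_mismatch_rejected(self, rng):
        model = build_model(SMALL)
        with pytest.raises(ValueError):
            predict(model, rng.standard_normal((3, 8, 32)).astype(np.float32))


class TestSplitsAndEvaluation:
    SMALL6 = dataclasses.replace(SMALL, n_channels=6, n_samples=32,
                                 temporal_kernel_len=8, pool_sizes=(4, 2),
                                 sep_kernel_len=4)

    def _epochs(self, tiny_montage, rng, n=200, n_subjects=4):
        data = rng.standard_normal((n, 6, 32)).astype(np.float32)
        subjects = np.arange(n) % n_subjects
        labels = np.array(["x", "y"])[(np.arange(n) // n_subjects) % 2]
        return make_epochs(data, tiny_montage, subjects=subjects, condition=labels)

    def test_split_disjoint_exhaustive_stratified(self, tiny_montage, rng):
        es = self._epochs(tiny_montage, rng)
        tr, ho = pooled_split(es, "condition", 0.8, seed=1)
        assert tr.n_trials + ho.n_trials == es.n_trials
        keys = lambda e: set(map(tuple, e.metadata[["participant_id", "trial_index"]].to_numpy()))
        assert not keys(tr) & keys(ho)
        # per-stratum rounding within +-1 of the 80% target
        for (s, c), grp in es.metadata.groupby(["participant_id", "condition"]):
            n_tr = len(tr.metadata.query(f"participant_id == {s} and condition == '{c}'"))
            assert abs(n_tr - 0.8 * len(grp)) <= 1

    def test_split_seeded(self, tiny_montage, rng):
        es = self._epochs(tiny_montage, rng)
        a, _ = pooled_split(es, "condition", seed=9)
        b, _ = pooled_split(es, "condition", seed=9)
        assert list(a.metadata["trial_index"]) == list(b.metadata["trial_index"])

    def test_invalid_fraction(self, tiny_montage, rng):
        es = self._epochs(tiny_montage, rng)
        with pytest.raises(ValueError):
            pooled_split(es, "condition", 1.2)

    def test_perfect_classifier_scores_one(self, tiny_montage, rng):
        es = self._epochs(tiny_montage, rng, n=120)
        model = build_model(self.SMALL6, labels=["x", "y"])
        # force predictions to the true class via a metadata-free oracle:
        # train on trivially separable recoding of the labels
        es.data[:] = 0.0
        es.data[es.metadata["condition"].to_numpy() == "y", 0, :] = 5.0
        model = train(model, es.data, es.labels("condition"),
                      tc=dataclasses.replace(FAST, max_epochs=20, patience=19))
        res = evaluate_per_subject_cv(model, es, "condition", k=5, seed=0)
        assert np.allclose(res["accuracies"], 1.0)
        for subj in res["per_subject"].values():
            sizes = [len(f) for f in np.array_split(np.arange(subj["n_trials"]), 5)]
            assert max(sizes) - min(sizes) <= 1

    def test_k1_equals_plain_accuracy(self, tiny_montage, rng):
        es = self._epochs(tiny_montage, rng, n=80)
        model = build_model(self.SMALL6, labels=["x", "y"])
        res1 = evaluate_per_subject_cv(model, es, "condition", k=1, seed=0)
        labels, _ = predict(model, es.data)
        for s, entry in res1["per_subject"].items():
            mask = es.labels("participant_id") == s
            plain = (labels[mask] == es.labels("condition")[mask]).mean()
            assert np.isclose(entry["accuracy"], plain)

    def test_small_subject_skipped_with_warning(self, tiny_montage, rng):
        es = self._epochs(tiny_montage, rng, n=43, n_subjects=4)
        # subject 3 has fewer than 5 trials after slicing
        few = es.select(np.concatenate([np.flatnonzero(es.labels("participant_id") != 3),
                                        np.flatnonzero(es.labels("participant_id") == 3)[:3]]))
        model = build_model(self.SMALL6, labels=["x", "y"])
        with pytest.warns(UserWarning, match="skipped"):
            res = evaluate_per_subject_cv(model, few, "condition", k=5, seed=0)
        assert 3 in res["skipped"]


class TestHyperparameterSearch:
    def test_budget_one_returns_single_config(self, rng):
        x, y = two_class_data(rng, n=60)
        out = hyperparameter_search({"learning_rate": [1e-3]}, x[:40], y[:40],
                                    x[40:], y[40:], SMALL, FAST, budget=1, seed=0,
                                    halving_epochs=(2,))
        assert out["best_candidate"] == 0
        assert out["train_config"].learning_rate == 1e-3

    def test_dominant_config_wins(self, rng):
        # learning rate 1e3 diverges instantly; the sane rate must win
        x, y = two_class_data(rng, n=100, sep=15.0)
        space = {"learning_rate": [1e3, 5e-3]}
        out = hyperparameter_search(space, x[:70], y[:70], x[70:], y[70:],
                                    SMALL, FAST, budget=6, seed=3,
                                    halving_epochs=(3, 6))
        assert out["train_config"].learning_rate == 5e-3

    def test_search_trajectory_reproducible(self, rng):
        x, y = two_class_data(rng, n=60)
        space = {"learning_rate": [1e-3, 5e-3], "dropout_rate": [0.0, 0.1]}
        a = hyperparameter_search(space, x[:40], y[:40], x[40:], y[40:],
                                  SMALL, FAST, budget=3, seed=5, halving_epochs=(2,))
        b = hyperparameter_search(space, x[:40], y[:40], x[40:], y[40:],
                                  SMALL, FAST, budget=3, seed=5, halving_epochs=(2,))
        assert a["log"] == b["log"]
        assert a["model_config"] == b["model_config"]

    def test_empty_space_rejected(self, rng):
        x, y = two_class_data(rng, n=20)
        with pytest.raises(ValueError):
            hyperparameter_search({}, x, y, x, y, SMALL, FAST, budget=2)
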