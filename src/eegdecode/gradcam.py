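"""Grad-CAM attribution over the second convolutional block.

For each trial the gradient of the predicted class's logit is taken with
respect to the block's post-activation feature maps; each map's weight is
the temporal mean of its gradient, the weighted sum is rectified, and the
result is (a) spread over electrodes through the network's own squared
spatial/pointwise weights (the electrode axis is collapsed by block 1, so
the feature maps have no native channel dimension) and (b) linearly
interpolated from the pooled time axis back to the input's sample grid.
Per-trial maps are min-max normalized to [0, 1]; aggregates (subject means,
grand means) are re-scaled to a maximum of 1, and medians over repeated
runs give the reported map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .nn.network import ClassifierModel, predict


@dataclass
class AttributionMap:
    """Normalized channel x time importance in [0, 1]."""

    importance: np.ndarray  # (n_channels, n_samples)
    target_layer: int = 2
    aggregation: str = "per-trial"
    n_trials_contributing: int = 1

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=np.float64)
        if self.importance.ndim != 2:
            raise ValueError("importance must be (channels, samples)")
        if self.importance.min() < 0 or self.importance.max() > 1 + 1e-9:
            raise ValueError("importance must lie in [0, 1]")


def _minmax(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    if hi - lo <= 0:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def _maxnorm(m: np.ndarray) -> np.ndarray:
    """Scale so the maximum is 1 (zero floor preserved; idempotent)."""
    hi = m.max()
    if hi <= 0:
        return np.zeros_like(m)
    return m / hi


def grad_cam(model: ClassifierModel, epochs: EpochSet, target_block: int = 2,
             use_true_labels: bool = False, label_field: str | None = None,
             batch_size: int = 256) -> list[AttributionMap]:
    """Per-trial Grad-CAM maps on the model-input grid.

    By default the backward pass starts from each trial's *predicted*
    logit; ``use_true_labels`` restricts instead to the true class (callers
    may pre-filter to correctly classified trials).
    """
    net = model.network
    x = np.asarray(epochs.data, dtype=np.float32)
    n_chan, n_samp = model.config.n_channels, model.config.n_samples
    if x.shape[1:] != (n_chan, n_samp):
        raise ValueError(f"epochs shape {x.shape[1:]} != model input ({n_chan}, {n_samp})")

    if use_true_labels:
        if label_field is None:
            raise ValueError("label_field required with use_true_labels")
        class_idx = model.encode_labels(epochs.labels(label_field))
    else:
        pred, _ = predict(model, x)
        class_idx = model.encode_labels(pred)

    proj = net.channel_projection(target_block)  # (f2, n_channels)
    # temporal positions of the block's (pre-pool) activation samples on the
    # input grid: block-2 activations sit after the first pooling stage
    stride = 1
    for p in model.config.pool_sizes[: target_block - 1]:
        stride *= p
    maps: list[AttributionMap] = []
    n_zero = 0
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size]
        cb = class_idx[start:start + batch_size]
        acts, grads = net.block_activations_and_gradients(xb, cb, target_block)
        # per-map weight: mean gradient over the temporal axis
        alpha = grads.mean(axis=2)  # (N, f2)
        t_len = acts.shape[2]
        centers = (np.arange(t_len) + 0.5) * stride - 0.5
        grid = np.arange(n_samp)
        for i in range(len(xb)):
            weighted = alpha[i][:, None] * acts[i]  # (f2, t_len)
            cam = proj.T @ weighted  # (n_channels, t_len)
            cam = np.maximum(cam, 0.0)  # rectification
            full = np.empty((n_chan, n_samp))
            for c in range(n_chan):
                full[c] = np.interp(grid, centers, cam[c])
            if not np.any(full):
                n_zero += 1
            maps.append(AttributionMap(_minmax(full), target_block, "per-trial", 1))
    if n_zero == len(maps) and maps:
        import warnings
        warnings.warn("every attribution map is all-zero (untrained model?)")
    return maps


def aggregate(maps: list[AttributionMap], level: str = "grand-mean",
              subjects=None) -> AttributionMap | dict:
    """Element-wise mean of per-trial maps, re-normalized to [0, 1].

    ``level='grand-mean'`` averages everything into one map;
    ``level='subject-mean'`` requires ``subjects`` (one id per map) and
    returns a dict of per-subject maps.
    """
    if not maps:
        raise ValueError("no maps to aggregate")
    shape = maps[0].importance.shape
    if any(m.importance.shape != shape for m in maps):
        raise ValueError("maps must share shape")
    if level == "grand-mean":
        mean = np.mean([m.importance for m in maps], axis=0)
        return AttributionMap(_maxnorm(mean), maps[0].target_layer, "grand-mean",
                              sum(m.n_trials_contributing for m in maps))
    if level == "subject-mean":
        if subjects is None or len(subjects) != len(maps):
            raise ValueError("subject-mean needs one subject id per map")
        subjects = np.asarray(subjects)
        out = {}
        for s in np.unique(subjects):
            sel = [m for m, ss in zip(maps, subjects) if ss == s]
            mean = np.mean([m.importance for m in sel], axis=0)
            out[s] = AttributionMap(_maxnorm(mean), maps[0].target_layer,
                                    "subject-mean", len(sel))
        return out
    raise ValueError(f"unknown aggregation level {level!r}")


def subject_then_grand_mean(maps: list[AttributionMap], subjects) -> AttributionMap:
    """Average within participants first, then across them (each subject
    contributes equally regardless of trial count)."""
    per_subject = aggregate(maps, "subject-mean", subjects)
    mean = np.mean([m.importance for m in per_subject.values()], axis=0)
    return AttributionMap(_maxnorm(mean), maps[0].target_layer, "grand-mean",
                          sum(m.n_trials_contributing for m in per_subject.values()))


def run_median(maps_across_runs: list[AttributionMap]) -> AttributionMap:
    """Element-wise median across repeated runs (the reported map)."""
    if not maps_across_runs:
        raise ValueError("no maps")
    shape = maps_across_runs[0].importance.shape
    if any(m.importance.shape != shape for m in maps_across_runs):
        raise ValueError("maps must share shape")
    med = np.median([m.importance for m in maps_across_runs], axis=0)
    return AttributionMap(med, maps_across_runs[0].target_layer, "run-median",
                          maps_across_runs[0].n_trials_contributing)


def window_mass(amap: AttributionMap, channel_indices, t0_idx: int, t1_idx: int
                ) -> float:
    """Fraction of total importance inside channels x [t0_idx, t1_idx).

    Compare with the uniform expectation (window cells / total cells) to
    quantify how concentrated attribution is in a hypothesized window.
    """
    imp = amap.importance
    channel_indices = np.asarray(channel_indices, dtype=int)
    if t1_idx <= t0_idx or len(channel_indices) == 0:
        raise ValueError("empty attribution window")
    if t0_idx < 0 or t1_idx > imp.shape[1]:
        raise ValueError("window outside map extent")
    total = imp.sum()
    if total == 0:
        return 0.0
    return float(imp[np.ix_(channel_indices, np.arange(t0_idx, t1_idx))].sum() / total)


def uniform_window_mass(amap: AttributionMap, n_window_channels: int,
                        t0_idx: int, t1_idx: int) -> float:
    """Expected window mass if importance were spread uniformly."""
    n_cells = amap.importance.size
    return n_window_channels * (t1_idx - t0_idx) / n_cells
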