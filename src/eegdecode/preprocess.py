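"""Deterministic epoch conditioning.

The standard chain for single-trial ERP decoding: zero-phase band-pass
filter, baseline correction against the pre-stimulus window, cropping to
the model window (onset to +1 s, inclusive endpoints: 251 samples at
250 Hz), amplitude-threshold artifact rejection, mastoid removal,
per-subject z-scoring (statistics fit on training trials only), and seeded
class balancing by random undersampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .utils import substream


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass: tuple[float, float] = (0.3, 50.0)
    baseline_window: tuple[float, float] = (-200.0, 0.0)  # ms
    model_window: tuple[float, float] = (0.0, 1000.0)  # ms
    reject_threshold: float = 100.0  # µV
    drop_channels: tuple[str, ...] = ("M1", "M2")
    balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_window[1] > self.model_window[0]:
            raise ValueError("baseline window must precede the model window")
        if self.reject_threshold <= 0:
            raise ValueError("reject_threshold must be positive")


def bandpass_filter(epochs: EpochSet, low: float = 0.3, high: float = 50.0,
                    order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass (forward-backward filtering).

    Zero-phase filtering preserves component latencies, which matters for
    any downstream claim about *when* information appears.
    """
    nyq = epochs.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=epochs.sampling_rate,
                        output="sos")
    out = epochs.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1).astype(np.float32)
    return out


def baseline_correct(epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0)
                     ) -> EpochSet:
    """Subtract each trial/channel's mean over the pre-stimulus window (ms)."""
    i0 = epochs.time_to_index(window[0])
    i1 = epochs.time_to_index(window[1])
    if not (0 <= i0 < i1 <= epochs.n_samples):
        raise ValueError(f"baseline window {window} outside epoch or empty")
    out = epochs.copy()
    out.data -= out.data[:, :, i0:i1].mean(axis=-1, keepdims=True)
    return out


def crop_model_window(epochs: EpochSet,
                      window: tuple[float, float] = (0.0, 1000.0)) -> EpochSet:
    """Keep samples from `window[0]` to `window[1]` ms, inclusive at both ends.

    The defaults at 250 Hz keep 251 samples (stimulus onset to +1 s).
    """
    i0 = epochs.time_to_index(window[0])
    i1 = epochs.time_to_index(window[1])
    if i0 < 0 or i1 >= epochs.n_samples or i1 < i0:
        raise ValueError(f"model window {window} exceeds epoch extent")
    out = epochs.copy()
    out.data = np.ascontiguousarray(out.data[:, :, i0:i1 + 1])
    out.time_zero_index = epochs.time_zero_index - i0
    return out


def reject_artifacts(epochs: EpochSet, threshold: float = 100.0
                     ) -> tuple[EpochSet, np.ndarray]:
    """Drop trials with any |amplitude| above `threshold` µV; return (kept, rejected idx)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    bad = np.flatnonzero(peak > threshold)
    if len(bad) == epochs.n_trials:
        raise ValueError("artifact rejection removed every trial")
    keep = np.setdiff1d(np.arange(epochs.n_trials), bad)
    return epochs.select(keep), bad


def drop_channels(epochs: EpochSet, labels) -> EpochSet:
    """Remove named channels (set semantics); montage updated in lockstep."""
    drop = set(labels)
    if not drop:
        return epochs.copy()
    new_montage = epochs.montage.without(drop)  # raises on unknown labels
    keep = [i for i, lb in enumerate(epochs.montage.channel_labels) if lb not in drop]
    return EpochSet(np.ascontiguousarray(epochs.data[:, keep, :]),
                    epochs.sampling_rate, epochs.time_zero_index,
                    epochs.metadata, new_montage, dict(epochs.attrs))


@dataclass
class NormStats:
    """Per-subject, per-channel z-scoring statistics, reusable on held-out data."""

    mean: dict = field(default_factory=dict)  # subject -> (n_channels,)
    sd: dict = field(default_factory=dict)


def normalize_subject(epochs: EpochSet, fit_mask: np.ndarray | None = None,
                      stats: NormStats | None = None, eps: float = 1e-8
                      ) -> tuple[EpochSet, NormStats]:
    """Z-score each subject's channels.

    Statistics are estimated on ``fit_mask`` trials only (default: all) and
    returned so held-out or cross-task data can be transformed with the
    *training* statistics — never refit on test data. Pass ``stats`` to
    apply existing statistics. Zero-variance channels get a small epsilon
    with a warning.
    """
    out = epochs.copy()
    subjects = out.metadata["participant_id"].to_numpy()
    if stats is None:
        stats = NormStats()
        if fit_mask is None:
            fit_mask = np.ones(epochs.n_trials, dtype=bool)
        fit_mask = np.asarray(fit_mask, dtype=bool)
        for s in np.unique(subjects):
            sel = (subjects == s) & fit_mask
            if not sel.any():
                raise ValueError(f"subject {s} has no trials in fit_mask")
            x = epochs.data[sel]
            mu = x.mean(axis=(0, 2))
            sd = x.std(axis=(0, 2))
            if np.any(sd == 0):
                warnings.warn(f"subject {s}: zero-variance channel(s); using epsilon")
                sd = np.where(sd == 0, eps, sd)
            stats.mean[s] = mu
            stats.sd[s] = sd
    for s in np.unique(subjects):
        if s not in stats.mean:
            raise KeyError(f"no normalization statistics for subject {s}")
        sel = subjects == s
        out.data[sel] = (out.data[sel] - stats.mean[s][None, :, None]) \
            / stats.sd[s][None, :, None]
    return out, stats


def balance_classes(epochs: EpochSet, label_field: str, seed: int = 0) -> EpochSet:
    """Seeded random undersampling to the minority-class count, order shuffled."""
    labels = epochs.labels(label_field)
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise ValueError(f"need >= 2 classes in {label_field!r}, got {len(values)}")
    if counts.min() == 0:
        raise ValueError("a class has zero trials")
    n_keep = int(counts.min())
    rng = substream(seed, "balance")
    chosen = []
    for v in values:
        idx = np.flatnonzero(labels == v)
        chosen.append(rng.choice(idx, size=n_keep, replace=False))
    sel = np.concatenate(chosen)
    rng.shuffle(sel)
    return epochs.select(sel)


def standard_pipeline(epochs: EpochSet, config: PreprocessConfig | None = None
                      ) -> tuple[EpochSet, dict]:
    """Filter -> baseline -> crop -> reject -> drop mastoids.

    Baseline correction runs *before* cropping because its window lies in
    the pre-stimulus segment that cropping discards. Normalization and
    balancing are left to the caller, which knows the train/test partition.
    Returns the conditioned epochs plus a report of what was removed.
    """
    cfg = config or PreprocessConfig()
    out = bandpass_filter(epochs, *cfg.bandpass)
    out = baseline_correct(out, cfg.baseline_window)
    out = crop_model_window(out, cfg.model_window)
    out, rejected = reject_artifacts(out, cfg.reject_threshold)
    dropped = [c for c in cfg.drop_channels if c in out.montage.channel_labels]
    out = drop_channels(out, dropped)
    report = {
        "n_in": int(epochs.n_trials),
        "n_out": int(out.n_trials),
        "rejected_indices": [int(i) for i in rejected],
        "channels_dropped": dropped,
    }
    return out, report
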