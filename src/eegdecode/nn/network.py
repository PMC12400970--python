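"""The compact CNN: architecture assembly, loss, optimizer, training loop.

The network follows the compact-CNN family for single-trial EEG
classification: Block 1 applies a temporal convolution (frequency-selective
filters), a depthwise spatial convolution spanning the full electrode axis
(collapsing channels into learned spatial filters) and a pointwise
convolution, then batch norm, ELU, temporal average pooling and
channel-wise dropout. Block 2 (and an optional Block 3) is a separable
convolution — depthwise temporal + pointwise — with the same
norm/activation/pool/dropout tail. A dense head maps the flattened feature
maps to one logit per class.

Training minimizes class-weighted cross-entropy (w_k = N / (K * N_k)) with
Adam and decoupled weight decay, early-stopping on validation loss and
restoring the best-epoch weights. Everything is numpy, single-threaded and
deterministic for a given seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from . import layers as L
from ..utils import substream


@dataclass(frozen=True)
class ModelConfig:
    n_channels: int = 61
    n_samples: int = 251
    n_classes: int = 2
    f1: int = 8
    temporal_kernel_len: int = 64
    depth_multiplier: int = 2
    f2: int = 16
    n_blocks: int = 2
    pool_sizes: tuple[int, ...] = (4, 8)
    sep_kernel_len: int = 16
    dropout_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_blocks not in (2, 3):
            raise ValueError("n_blocks must be 2 or 3")
        if len(self.pool_sizes) < self.n_blocks:
            raise ValueError("need one pool size per block")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        t = self.n_samples
        for p in self.pool_sizes[: self.n_blocks]:
            t //= p
            if t < 1:
                raise ValueError("pooled temporal length fell below 1")


@dataclass(frozen=True)
class TrainConfig:
    max_epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 2e-3
    weight_decay: float = 1e-4
    patience: int = 8
    validation_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be below max_epochs")


class CompactCNN:
    """The assembled network with explicit access to each block's activations."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = substream(config.seed, "init")
        c = config
        self.block1 = L.FusedConvBlock1(
            c.f1, c.temporal_kernel_len, c.depth_multiplier, c.n_channels,
            c.f2, rng)

        self.layers: list[L.Layer] = [
            self.block1,
            L.BatchNorm(c.f2), L.ELU(), L.AvgPool(c.pool_sizes[0]),
            L.Dropout2d(c.dropout_rate),
        ]
        self.block_activation_index: dict[int, int] = {}
        self.sep_pointwise: list[L.PointwiseConv] = []
        for b in range(2, c.n_blocks + 1):
            pw = L.PointwiseConv(c.f2, c.f2, rng)
            self.sep_pointwise.append(pw)
            self.layers += [
                L.DepthwiseTemporalConv(c.f2, c.sep_kernel_len, rng),
                pw, L.BatchNorm(c.f2), L.ELU(),
            ]
            # index of the activation *after* this block's ELU, pre-pooling
            self.block_activation_index[b] = len(self.layers) - 1
            self.layers += [L.AvgPool(c.pool_sizes[b - 1]), L.Dropout2d(c.dropout_rate)]

        t_out = c.n_samples
        for p in c.pool_sizes[: c.n_blocks]:
            t_out //= p
        self.n_features = c.f2 * t_out
        self.pooled_lengths = self._pooled_lengths()
        self.layers += [L.Flatten(), L.Dense(self.n_features, c.n_classes, rng)]

    def _pooled_lengths(self) -> list[int]:
        t = self.config.n_samples
        out = []
        for p in self.config.pool_sizes[: self.config.n_blocks]:
            t //= p
            out.append(t)
        return out

    # ---- forward / backward ------------------------------------------------
    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, L.Dropout2d):
                layer.rng = rng

    def forward(self, x: np.ndarray, training: bool = False,
                capture: int | None = None) -> np.ndarray:
        """Run the network; optionally capture the activation at layer index."""
        self._captured = None
        h = np.asarray(x, dtype=np.float32)
        for i, layer in enumerate(self.layers):
            h = layer.forward(h, training)
            if capture is not None and i == capture:
                self._captured = h
        return h

    def backward(self, dlogits: np.ndarray, stop_at: int | None = None):
        """Backpropagate; if `stop_at` is given, return the gradient flowing
        *into* that layer index's output (and skip earlier layers)."""
        g = dlogits
        for i in range(len(self.layers) - 1, -1, -1):
            if stop_at is not None and i == stop_at:
                return g
            g = self.layers[i].backward(g)
        return g

    # ---- parameter plumbing ------------------------------------------------
    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def state_dict(self) -> list[np.ndarray]:
        state = [p.copy() for _, p, _ in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, L.BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for (_, p, _), v in zip(params, state[: len(params)]):
            p[...] = v
        extra = state[len(params):]
        i = 0
        for layer in self.layers:
            if isinstance(layer, L.BatchNorm):
                layer.running_mean[...] = extra[i]
                layer.running_var[...] = extra[i + 1]
                i += 2

    # ---- grad-cam hooks ----------------------------------------------------
    def block_activations_and_gradients(self, x: np.ndarray, class_idx: np.ndarray,
                                        block: int = 2
                                        ) -> tuple[np.ndarray, np.ndarray]:
        """Activations of `block`'s post-ELU feature maps and the gradient of
        the selected per-trial logit with respect to them (eval mode)."""
        if block not in self.block_activation_index:
            raise KeyError(f"no convolutional block {block} in this model")
        idx = self.block_activation_index[block]
        logits = self.forward(x, training=False, capture=idx)
        acts = self._captured
        onehot = np.zeros_like(logits)
        onehot[np.arange(len(class_idx)), class_idx] = 1.0
        grads = self.backward(onehot, stop_at=idx)
        return acts, grads

    def channel_projection(self, block: int = 2) -> np.ndarray:
        """Map block feature maps back onto electrodes: (f2, n_channels),
        rows normalized to sum 1.

        The electrode axis is collapsed by block 1's depthwise spatial
        convolution, so block-2 maps have no native channel dimension. The
        re-projection chains *squared* convolution weights
        (W_pointwise^2 @ W_spatial^2): a channel's contribution to a spatial
        filter's output variance scales with the squared weight, so the
        energy chain concentrates attribution on the electrodes that
        actually drive each feature map.
        """
        wd = np.square(self.block1.ws)  # (f1, d, C)
        f1, d, n_chan = wd.shape
        wp1 = np.square(self.block1.wp)  # (f2, f1*d)
        proj = wp1 @ wd.reshape(f1 * d, n_chan)  # (f2, C)
        for b in range(2, block + 1):
            wpb = np.square(self.sep_pointwise[b - 2].w)  # (f2, f2)
            proj = wpb @ proj
        norm = proj.sum(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return proj / norm


@dataclass
class ClassifierModel:
    """A trained (or trainable) classifier: network + label map + history."""

    config: ModelConfig
    network: CompactCNN
    label_map: dict = field(default_factory=dict)  # label -> output index
    history: list = field(default_factory=list)
    train_config: TrainConfig | None = None

    @property
    def inverse_label_map(self) -> dict:
        return {v: k for k, v in self.label_map.items()}

    def encode_labels(self, labels) -> np.ndarray:
        try:
            return np.array([self.label_map[lb] for lb in labels])
        except KeyError as e:
            raise ValueError(f"label {e.args[0]!r} not in label map") from None


def build_model(config: ModelConfig, labels=None) -> ClassifierModel:
    """Construct the network with seeded initialization.

    `labels`: optional iterable of class labels fixing the label map
    (sorted order otherwise established at training time).
    """
    net = CompactCNN(config)
    label_map = {}
    if labels is not None:
        uniq = sorted(set(labels), key=str)
        if len(uniq) != config.n_classes:
            raise ValueError(
                f"{len(uniq)} labels for a {config.n_classes}-class model")
        label_map = {lb: i for i, lb in enumerate(uniq)}
    return ClassifierModel(config=config, network=net, label_map=label_map)


def class_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """w_k = N / (K * N_k); satisfies sum_k N_k w_k = N exactly."""
    counts = np.bincount(y, minlength=n_classes)
    if np.any(counts == 0):
        raise ValueError("every class must be present in the training data")
    return len(y) / (n_classes * counts.astype(np.float64))


def _weighted_ce(logits: np.ndarray, y: np.ndarray, w: np.ndarray
                 ) -> tuple[float, np.ndarray]:
    """Class-weighted cross-entropy (normalized by total weight) and dlogits."""
    z = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(z)
    p = expz / expz.sum(axis=1, keepdims=True)
    wi = w[y]
    total = wi.sum()
    nll = -np.log(np.clip(p[np.arange(len(y)), y], 1e-12, None))
    loss = float((wi * nll).sum() / total)
    dlogits = p.copy()
    dlogits[np.arange(len(y)), y] -= 1.0
    dlogits *= (wi / total)[:, None]
    return loss, dlogits.astype(np.float32)


class Adam:
    """Adam with decoupled weight decay (applied to conv/dense weights only)."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in params]
        self.v = [np.zeros_like(p) for _, p, _ in params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (name, p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if self.wd and name.endswith("_w"):
                upd = upd + self.wd * p
            p -= (self.lr * upd).astype(p.dtype)


def stratified_validation_split(y: np.ndarray, fraction: float,
                                rng: np.random.Generator
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split into (train_idx, val_idx); every class keeps >= 1
    training trial and, where possible, >= 1 validation trial."""
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        n_val = int(round(fraction * len(idx)))
        n_val = min(max(n_val, 1 if len(idx) > 1 else 0), len(idx) - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train(model: ClassifierModel, x_train: np.ndarray, y_train,
          x_val: np.ndarray | None = None, y_val=None,
          tc: TrainConfig | None = None, verbose: bool = False
          ) -> ClassifierModel:
    """Fit the classifier; early-stops on validation loss, restores best weights.

    `y_*` are raw labels; the label map is fixed here (sorted unique labels)
    if the model does not already carry one. When no validation set is
    passed, `tc.validation_fraction` is carved from the training data with a
    stratified, seeded split.
    """
    tc = tc or TrainConfig()
    net = model.network
    k = model.config.n_classes

    if not model.label_map:
        uniq = sorted(set(y_train), key=str)
        if len(uniq) != k:
            raise ValueError(f"{len(uniq)} classes in training data, model expects {k}")
        model.label_map = {lb: i for i, lb in enumerate(uniq)}
    y_tr = model.encode_labels(y_train)

    rng = substream(tc.seed, "train")
    if x_val is None:
        tr_idx, va_idx = stratified_validation_split(y_tr, tc.validation_fraction, rng)
        x_val, y_va = x_train[va_idx], y_tr[va_idx]
        x_tr = x_train[tr_idx]
        y_tr = y_tr[tr_idx]
    else:
        x_tr = x_train
        y_va = model.encode_labels(y_val)

    x_tr = np.asarray(x_tr, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    w = class_weights(y_tr, k)
    net.set_dropout_rng(substream(tc.seed, "dropout"))
    opt = Adam(net.parameters(), tc.learning_rate, tc.weight_decay)

    best_loss = np.inf
    best_state = net.state_dict()
    best_epoch = -1
    since_best = 0
    model.history = []
    model.train_config = tc

    n = len(x_tr)
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for start in range(0, n, tc.batch_size):
            bi = order[start:start + tc.batch_size]
            logits = net.forward(x_tr[bi], training=True)
            loss, dlogits = _weighted_ce(logits, y_tr[bi], w)
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(bi)
            ep_correct += int((logits.argmax(axis=1) == y_tr[bi]).sum())

        val_logits = net.forward(x_val, training=False)
        val_loss, _ = _weighted_ce(val_logits, y_va, w)
        val_acc = float((val_logits.argmax(axis=1) == y_va).mean())
        model.history.append({
            "epoch": epoch,
            "train_loss": ep_loss / n,
            "train_acc": ep_correct / n,
            "val_loss": val_loss,
            "val_acc": val_acc,
        })
        if verbose:
            print(f"epoch {epoch}: train_loss={ep_loss / n:.4f} "
                  f"val_loss={val_loss:.4f} val_acc={val_acc:.3f}")
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = net.state_dict()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= tc.patience:
                break

    net.load_state_dict(best_state)
    model.history.append({"best_epoch": best_epoch, "best_val_loss": best_loss})
    return model


def predict(model: ClassifierModel, x: np.ndarray, batch_size: int = 256
            ) -> tuple[np.ndarray, np.ndarray]:
    """(labels, logits); argmax ties break toward the lowest output index."""
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3 or x.shape[1] != model.config.n_channels \
            or x.shape[2] != model.config.n_samples:
        raise ValueError(
            f"input shape {x.shape} incompatible with "
            f"({model.config.n_channels}, {model.config.n_samples}) model")
    chunks = [model.network.forward(x[i:i + batch_size], training=False)
              for i in range(0, len(x), batch_size)]
    logits = np.concatenate(chunks, axis=0) if chunks else np.zeros((0, model.config.n_classes))
    idx = logits.argmax(axis=1)  # np.argmax returns the first (lowest) maximal index
    inv = model.inverse_label_map
    labels = np.array([inv[i] for i in idx]) if inv else idx
    return labels, logits
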