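"""Minimal layer zoo for the compact EEG CNN, in numpy.

Every layer implements ``forward(x, training)`` and ``backward(dy)`` and
exposes its parameters and gradients. Shapes follow the EEG convention:
the network input is ``(N, C, T)`` (trials, electrodes, samples); the
temporal convolution lifts it to ``(N, F, C, T)``, the depthwise spatial
convolution collapses the electrode axis, and everything after runs on
``(N, F, T)`` feature maps.

Convolutions are bias-free (batch norm supplies the affine terms) and use
same-padding along time, implemented via sliding windows + BLAS matmul.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        """(name, value, gradient) triples; empty for stateless layers."""
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _same_pad(length: int) -> tuple[int, int]:
    left = (length - 1) // 2
    return left, length - 1 - left


class TemporalConv(Layer):
    """(N, C, T) -> (N, F, C, T): F temporal kernels shared across channels."""

    decay = True

    def __init__(self, n_filters: int, kernel_len: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(kernel_len)
        self.w = (rng.standard_normal((n_filters, kernel_len)) * scale).astype(np.float32)
        self.dw = np.zeros_like(self.w)

    def params(self):
        return [("temporal_w", self.w, self.dw)]

    def forward(self, x, training):
        self._xshape = x.shape
        n, c, t = x.shape
        f, L = self.w.shape
        pl, pr = _same_pad(L)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, L, axis=-1)  # (N, C, T, L)
        self._cols = win.reshape(-1, L)  # copy
        y = self._cols @ self.w.T  # (N*C*T, F)
        return np.ascontiguousarray(
            y.reshape(n, c, t, f).transpose(0, 3, 1, 2))

    def backward(self, dy):
        n, c, t = self._xshape
        f, L = self.w.shape
        pl, pr = _same_pad(L)
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, f)  # (N*C*T, F)
        self.dw[...] = (dyf.T @ self._cols).astype(np.float32)
        # dx: scatter the per-tap contributions back (correlation transpose)
        dcols = dyf @ self.w  # (N*C*T, L)
        dcols = dcols.reshape(n, c, t, L)
        dxp = np.zeros((n, c, t + L - 1), dtype=np.float32)
        for tap in range(L):
            dxp[:, :, tap:tap + t] += dcols[:, :, :, tap]
        self._cols = None
        return dxp[:, :, pl:pl + t]


class DepthwiseSpatialConv(Layer):
    """(N, F, C, T) -> (N, F*D, T): D spatial filters per temporal filter,
    spanning the full electrode axis (kernel height = n_channels)."""

    decay = True

    def __init__(self, n_filters: int, depth: int, n_channels: int,
                 rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_channels)
        self.w = (rng.standard_normal((n_filters, depth, n_channels)) * scale
                  ).astype(np.float32)
        self.dw = np.zeros_like(self.w)

    def params(self):
        return [("spatial_w", self.w, self.dw)]

    def forward(self, x, training):
        self._x = x
        n, f, c, t = x.shape
        y = np.einsum("nfct,fdc->nfdt", x, self.w, optimize=True)
        return y.reshape(n, -1, t)

    def backward(self, dy):
        n, f, c, t = self._x.shape
        d = self.w.shape[1]
        dyr = dy.reshape(n, f, d, t)
        self.dw[...] = np.einsum("nfdt,nfct->fdc", dyr, self._x, optimize=True)
        dx = np.einsum("nfdt,fdc->nfct", dyr, self.w, optimize=True)
        self._x = None
        return dx


class PointwiseConv(Layer):
    """(N, F_in, T) -> (N, F_out, T): 1x1 mixing of feature maps."""

    decay = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.dw = np.zeros_like(self.w)

    def params(self):
        return [("pointwise_w", self.w, self.dw)]

    def forward(self, x, training):
        self._x = x
        return np.einsum("nft,gf->ngt", x, self.w, optimize=True)

    def backward(self, dy):
        self.dw[...] = np.einsum("ngt,nft->gf", dy, self._x, optimize=True)
        dx = np.einsum("ngt,gf->nft", dy, self.w, optimize=True)
        self._x = None
        return dx


class DepthwiseTemporalConv(Layer):
    """(N, F, T) -> (N, F, T): one temporal kernel per feature map
    (the depthwise half of a separable convolution)."""

    decay = True

    def __init__(self, n_filters: int, kernel_len: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(kernel_len)
        self.w = (rng.standard_normal((n_filters, kernel_len)) * scale).astype(np.float32)
        self.dw = np.zeros_like(self.w)

    def params(self):
        return [("sep_temporal_w", self.w, self.dw)]

    def forward(self, x, training):
        self._xshape = x.shape
        f, L = self.w.shape
        pl, pr = _same_pad(L)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._win = sliding_window_view(xp, L, axis=-1)  # (N, F, T, L)
        return np.einsum("nftl,fl->nft", self._win, self.w, optimize=True)

    def backward(self, dy):
        n, f, t = self._xshape
        L = self.w.shape[1]
        pl, pr = _same_pad(L)
        self.dw[...] = np.einsum("nft,nftl->fl", dy, self._win, optimize=True)
        dxp = np.zeros((n, f, t + L - 1), dtype=np.float32)
        for tap in range(L):
            dxp[:, :, tap:tap + t] += dy * self.w[:, tap][None, :, None]
        self._win = None
        return dxp[:, :, pl:pl + t]


class FusedConvBlock1(Layer):
    """Temporal conv -> depthwise spatial conv -> pointwise conv, fused.

    The three stages are linear, and a shared-across-channels temporal
    convolution commutes with a per-temporal-filter channel mixing, so the
    block is evaluated spatial-first: project the electrodes down to
    F1*D maps, then run each map's temporal kernel, then the pointwise mix.
    Identical outputs and parameter gradients to the sequential form (see
    the equivalence test), at a fraction of the cost — the temporal kernels
    never touch the full electrode axis.

    (N, C, T) -> (N, F2, T). Parameters are exactly those of the three
    separate layers: temporal_w (F1, L), spatial_w (F1, D, C),
    pointwise_w (F2, F1*D).
    """

    decay = True

    def __init__(self, f1: int, kernel_len: int, depth: int, n_channels: int,
                 f2: int, rng: np.random.Generator):
        # draw in the same order as the sequential layers for seed parity
        self.wt = (rng.standard_normal((f1, kernel_len)) / np.sqrt(kernel_len)
                   ).astype(np.float32)
        self.dwt = np.zeros_like(self.wt)
        self.ws = (rng.standard_normal((f1, depth, n_channels)) / np.sqrt(n_channels)
                   ).astype(np.float32)
        self.dws = np.zeros_like(self.ws)
        self.wp = (rng.standard_normal((f2, f1 * depth)) / np.sqrt(f1 * depth)
                   ).astype(np.float32)
        self.dwp = np.zeros_like(self.wp)

    def params(self):
        return [("temporal_w", self.wt, self.dwt),
                ("spatial_w", self.ws, self.dws),
                ("pointwise_w", self.wp, self.dwp)]

    def forward(self, x, training):
        self._x = x
        n, c, t = x.shape
        f1, L = self.wt.shape
        d = self.ws.shape[1]
        pl, pr = _same_pad(L)
        z = np.einsum("nct,fdc->nfdt", x, self.ws, optimize=True)
        zp = np.pad(z, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        self._win = sliding_window_view(zp, L, axis=-1)  # (N, F1, D, T, L)
        u = np.einsum("nfdtl,fl->nfdt", self._win, self.wt, optimize=True)
        self._u = u.reshape(n, f1 * d, t)
        return np.einsum("nmt,gm->ngt", self._u, self.wp, optimize=True)

    def backward(self, dy):
        n, c, t = self._x.shape
        f1, L = self.wt.shape
        d = self.ws.shape[1]
        pl, pr = _same_pad(L)
        self.dwp[...] = np.einsum("ngt,nmt->gm", dy, self._u, optimize=True)
        du = np.einsum("ngt,gm->nmt", dy, self.wp, optimize=True).reshape(n, f1, d, t)
        self.dwt[...] = np.einsum("nfdt,nfdtl->fl", du, self._win, optimize=True)
        dzp = np.zeros((n, f1, d, t + L - 1), dtype=np.float32)
        for tap in range(L):
            dzp[:, :, :, tap:tap + t] += du * self.wt[:, tap][None, :, None, None]
        dz = dzp[:, :, :, pl:pl + t]
        self.dws[...] = np.einsum("nfdt,nct->fdc", dz, self._x, optimize=True)
        dx = np.einsum("nfdt,fdc->nct", dz, self.ws, optimize=True)
        self._x = self._win = self._u = None
        return dx


class BatchNorm(Layer):
    """Per-feature-map batch normalization over the batch and time axes."""

    decay = False

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features, dtype=np.float32)
        self.beta = np.zeros(n_features, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("bn_gamma", self.gamma, self.dgamma),
                ("bn_beta", self.beta, self.dbeta)]

    def forward(self, x, training):
        axes = (0, 2)
        self._training = training
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean[None, :, None]) * self._istd[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dy):
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        g = self.gamma[None, :, None] * self._istd[None, :, None]
        if not self._training:
            return dy * g
        m = dy.shape[0] * dy.shape[2]
        dxhat = dy * self.gamma[None, :, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2), keepdims=True)
              ) * self._istd[None, :, None]
        self._xhat = None
        return dx


class ELU(Layer):
    decay = False

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, training):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._x = x
        self._y = y
        return y.astype(np.float32)

    def backward(self, dy):
        grad = np.where(self._x > 0, 1.0, self._y + self.alpha)
        self._x = None
        return (dy * grad).astype(np.float32)


class AvgPool(Layer):
    """Temporal average pooling with floor division; trailing remainder dropped."""

    decay = False

    def __init__(self, pool: int):
        if pool < 1:
            raise ValueError("pool size must be >= 1")
        self.pool = pool

    def forward(self, x, training):
        n, f, t = x.shape
        self._t_in = t
        t_out = t // self.pool
        if t_out < 1:
            raise ValueError(f"pooled temporal length < 1 (T={t}, pool={self.pool})")
        y = x[:, :, :t_out * self.pool].reshape(n, f, t_out, self.pool).mean(axis=-1)
        return y

    def backward(self, dy):
        n, f, t_out = dy.shape
        dx = np.zeros((n, f, self._t_in), dtype=np.float32)
        expanded = np.repeat(dy / self.pool, self.pool, axis=-1)
        dx[:, :, :t_out * self.pool] = expanded
        return dx


class Dropout2d(Layer):
    """Channel-wise dropout: whole feature maps are zeroed during training."""

    decay = False

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("dropout used in training mode without an RNG")
        keep = 1.0 - self.rate
        self._mask = (self.rng.random((x.shape[0], x.shape[1], 1)) < keep) / keep
        return (x * self._mask).astype(np.float32)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(np.float32)


class Flatten(Layer):
    decay = False

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    decay = True

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in)
        self.w = (rng.standard_normal((n_out, n_in)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("dense_w", self.w, self.dw), ("dense_b", self.b, self.db)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.dw[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        dx = dy @ self.w
        self._x = None
        return dx
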