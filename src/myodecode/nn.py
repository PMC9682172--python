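"""Minimal feed-forward layer engine used by the EMG decoders.

Implements exactly the layer vocabulary the decoders need — 2-D convolution
(valid along the electrode axis, same-padded along time), batch normalization,
randomized rectified linear units (RReLU), max-pooling over time, dropout and
dense layers — together with an Adam optimizer, freeze masks and
checkpoint/early-stopping training.  Forward and backward passes are written
per layer and verified against finite differences and a scipy convolution
oracle in the test suite.

All randomness (weight init, validation split, shuffling, dropout masks,
RReLU slopes) flows through explicitly passed ``numpy.random.Generator``
objects, so training is bit-reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

DTYPE = np.float32

__all__ = [
    "Param", "Layer", "Conv2D", "BatchNorm", "RReLU", "MaxPoolTime",
    "Dropout", "Flatten", "Dense", "Sequential", "Parallel",
    "SoftmaxCrossEntropy", "SigmoidBCE", "Adam", "FitConfig", "fit",
    "count_trainable", "set_trainable", "softmax", "sigmoid", "rrelu",
]


class Param:
    """A weight tensor with its gradient buffer and a trainable flag."""

    __slots__ = ("value", "grad", "trainable", "name")

    def __init__(self, value: np.ndarray, trainable: bool = True, name: str = ""):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable
        self.name = name

    def __repr__(self) -> str:  # pragma: no cover
        return f"Param({self.name}, shape={self.value.shape}, trainable={self.trainable})"


class Layer:
    name: str = "layer"
    #: force this layer into inference behaviour even under train-mode
    #: forward passes (used for fully locked sub-stacks during fine-tuning)
    mode_override: str | None = None

    def params(self) -> list[Param]:
        return []

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (e.g. BN running statistics)."""
        return []

    def forward(self, x, train: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv2D(Layer):
    """Cross-correlation over (electrode, time) maps.

    Padding is 'same' along the time axis and 'valid' along the electrode
    axis, so a (1,k) kernel preserves the channel extent while a (3,k) kernel
    shrinks it by two — the layout the compact EMG nets rely on.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator, name: str = "conv"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kh, self.kw = kernel
        fan_in = in_ch * self.kh * self.kw
        self.W = Param(_glorot_uniform(rng, (out_ch, in_ch, self.kh, self.kw),
                                       fan_in, out_ch * self.kh * self.kw),
                       name=f"{name}.W")
        self.b = Param(np.zeros(out_ch), name=f"{name}.b")
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"{self.name}: expected {self.in_ch} input maps, got {c}")
        pl = (self.kw - 1) // 2
        pr = self.kw - 1 - pl
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (pl, pr)))
        ho, wo = h - self.kh + 1, w
        if ho < 1:
            raise ValueError(f"{self.name}: kernel height {self.kh} exceeds input height {h}")
        # im2col in (n, c*kh*kw, ho*wo) layout + batched GEMM
        dt = np.result_type(x, self.W.value)
        cols = np.empty((n, c * self.kh * self.kw, ho * wo), dtype=dt)
        j = 0
        for ci in range(c):
            for dh in range(self.kh):
                for dw in range(self.kw):
                    cols[:, j, :] = xp[:, ci, dh:dh + ho, dw:dw + wo].reshape(n, -1)
                    j += 1
        Wm = self.W.value.reshape(self.out_ch, -1).astype(dt, copy=False)
        out = np.matmul(Wm[None], cols) + self.b.value.astype(dt)[None, :, None]
        self._cache = (cols, (n, c, h, w), (pl, pr), (ho, wo))
        return out.reshape(n, self.out_ch, ho, wo)

    def backward(self, dout):
        cols, (n, c, h, w), (pl, pr), (ho, wo) = self._cache
        dr = dout.reshape(n, self.out_ch, ho * wo)
        self.W.grad += np.einsum("noj,nkj->ok", dr, cols,
                                 optimize=True).reshape(self.W.value.shape)
        self.b.grad += dr.sum(axis=(0, 2))
        Wm = self.W.value.reshape(self.out_ch, -1).astype(dout.dtype, copy=False)
        dcols = np.matmul(Wm.T[None], dr)
        dxp = np.zeros((n, c, h, w + self.kw - 1), dtype=dout.dtype)
        j = 0
        for ci in range(c):
            for dh in range(self.kh):
                for dw in range(self.kw):
                    dxp[:, ci, dh:dh + ho, dw:dw + wo] += \
                        dcols[:, j, :].reshape(n, ho, wo)
                    j += 1
        return dxp[:, :, :, pl:pl + w]


class BatchNorm(Layer):
    """Batch normalization over the batch (and spatial axes for conv maps).

    Running statistics are updated whenever the layer runs in train mode,
    independently of whether scale/shift are trainable — frozen feature
    extractors therefore keep adapting their inference statistics, which is
    exactly the behaviour the transfer architectures require.
    """

    def __init__(self, n_features: int, conv: bool, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn"):
        self.conv = conv
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(n_features), name=f"{name}.gamma")
        self.beta = Param(np.zeros(n_features), name=f"{name}.beta")
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.name = name

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def _shape(self, v, ndim):
        if ndim == 4:
            return v[None, :, None, None]
        return v[None, :]

    def forward(self, x, train, rng):
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mu.astype(DTYPE) - self.running_mean)
            self.running_var += self.momentum * (var.astype(DTYPE) - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mu, x.ndim)) * self._shape(inv_std, x.ndim)
        self._cache = (xhat, inv_std, axes, train, x.shape)
        return self._shape(self.gamma.value, x.ndim) * xhat + self._shape(self.beta.value, x.ndim)

    def backward(self, dout):
        xhat, inv_std, axes, train, shape = self._cache
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self._shape(self.gamma.value * inv_std, dout.ndim)
        if not train:
            return dout * g
        m = float(np.prod([shape[a] for a in axes]))
        return (g / m) * (m * dout
                          - self._shape(dbeta, dout.ndim)
                          - xhat * self._shape(dgamma, dout.ndim))


class RReLU(Layer):
    """Randomized leaky rectifier: negative slope ~ U[lower, upper] in train
    mode, the interval midpoint at evaluation."""

    def __init__(self, lower: float = 1 / 8, upper: float = 1 / 3, name: str = "rrelu"):
        if not (0 < lower <= upper < 1):
            raise ValueError(f"invalid RReLU bounds ({lower}, {upper})")
        self.lower, self.upper = lower, upper
        self.name = name

    def forward(self, x, train, rng):
        if train:
            if rng is None:
                raise ValueError("RReLU train mode needs an rng")
            u = (rng.random(size=x.shape, dtype=np.float32)
                 if x.dtype == np.float32 else rng.random(size=x.shape))
            slope = (self.lower + (self.upper - self.lower) * u).astype(x.dtype)
        else:
            slope = (self.lower + self.upper) / 2
        mult = np.where(x < 0, slope, np.asarray(1.0, dtype=x.dtype))
        self._mult = mult
        return x * mult

    def backward(self, dout):
        return dout * self._mult


class MaxPoolTime(Layer):
    """Non-overlapping max pooling along the time axis (pool shape (1, p))."""

    def __init__(self, pool: int, name: str = "pool"):
        self.pool = pool
        self.name = name

    def forward(self, x, train, rng):
        n, c, h, w = x.shape
        wo = w // self.pool
        if wo < 1:
            raise ValueError(f"{self.name}: pool {self.pool} collapses time axis of length {w}")
        xt = x[:, :, :, :wo * self.pool].reshape(n, c, h, wo, self.pool)
        idx = xt.argmax(axis=-1)
        self._cache = (idx, x.shape, wo)
        return np.take_along_axis(xt, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        idx, shape, wo = self._cache
        n, c, h, w = shape
        dxt = np.zeros((n, c, h, wo, self.pool), dtype=dout.dtype)
        np.put_along_axis(dxt, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(shape, dtype=dout.dtype)
        dx[:, :, :, :wo * self.pool] = dxt.reshape(n, c, h, wo * self.pool)
        return dx


class Dropout(Layer):
    def __init__(self, p: float, name: str = "dropout"):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.name = name

    def forward(self, x, train, rng):
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout train mode needs an rng")
        u = (rng.random(size=x.shape, dtype=np.float32)
             if x.dtype == np.float32 else rng.random(size=x.shape))
        mask = (u >= self.p).astype(x.dtype) / (1 - self.p)
        self._mask = mask
        return x * mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        self.name = name

    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, name: str = "dense"):
        self.n_in, self.n_out = n_in, n_out
        self.W = Param(_glorot_uniform(rng, (n_in, n_out), n_in, n_out), name=f"{name}.W")
        self.b = Param(np.zeros(n_out), name=f"{name}.b")
        self.name = name

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train, rng):
        if x.shape[1] != self.n_in:
            raise ValueError(f"{self.name}: expected {self.n_in} inputs, got {x.shape[1]}")
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    """An ordered layer stack; usable itself as a layer (for branches)."""

    def __init__(self, layers: list[Layer], name: str = "net"):
        self.layers = list(layers)
        self.name = name

    def params(self):
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def buffers(self):
        out: list[np.ndarray] = []
        for layer in self.layers:
            out.extend(layer.buffers())
        return out

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train and layer.mode_override != "eval", rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def __getitem__(self, sl):
        return Sequential(self.layers[sl], name=f"{self.name}[{sl}]")

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()] + [b.copy() for b in self.buffers()]

    def load_state(self, state: list[np.ndarray]) -> None:
        ps, bs = self.params(), self.buffers()
        if len(state) != len(ps) + len(bs):
            raise ValueError("state length mismatch")
        for p, v in zip(ps, state[:len(ps)]):
            p.value[...] = v
        for b, v in zip(bs, state[len(ps):]):
            b[...] = v


class Parallel(Layer):
    """Run two branches on the same input and concatenate their flat outputs."""

    def __init__(self, branch_a: Sequential, branch_b: Sequential, name: str = "parallel"):
        self.branch_a, self.branch_b = branch_a, branch_b
        self.name = name

    def params(self):
        return self.branch_a.params() + self.branch_b.params()

    def buffers(self):
        return self.branch_a.buffers() + self.branch_b.buffers()

    def forward(self, x, train, rng):
        ya = self.branch_a.forward(x, train, rng)
        yb = self.branch_b.forward(x, train, rng)
        self._wa = ya.shape[1]
        return np.concatenate([ya, yb], axis=1)

    def backward(self, dout):
        da = self.branch_a.backward(dout[:, :self._wa])
        db = self.branch_b.backward(dout[:, self._wa:])
        return da + db


# ---------------------------------------------------------------------------
# losses

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def rrelu(x, lower: float = 1 / 8, upper: float = 1 / 3, mode: str = "eval",
          rng: np.random.Generator | None = None):
    """Functional RReLU on scalars/arrays (mirrors the layer's contract)."""
    if not (0 < lower <= upper < 1):
        raise ValueError(f"invalid RReLU bounds ({lower}, {upper})")
    x = np.asarray(x, dtype=float)
    if mode == "eval":
        slope = (lower + upper) / 2
    elif mode == "train":
        if rng is None:
            raise ValueError("train mode needs an rng")
        slope = rng.uniform(lower, upper, size=x.shape)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.where(x < 0, x * slope, x)


class SoftmaxCrossEntropy:
    """Returns (mean loss, dlogits); targets are integer class indices."""

    def __call__(self, logits, targets):
        n = logits.shape[0]
        p = softmax(logits.astype(np.float64))
        loss = -np.mean(np.log(np.clip(p[np.arange(n), targets], 1e-12, None)))
        d = p
        d[np.arange(n), targets] -= 1.0
        return loss, (d / n).astype(logits.dtype)

    @staticmethod
    def activate(logits):
        return softmax(logits.astype(np.float64))


class SigmoidBCE:
    """Per-unit binary cross-entropy; targets are arrays in [0, 1]."""

    def __call__(self, logits, targets):
        z = logits.astype(np.float64)
        t = np.asarray(targets, dtype=np.float64)
        if t.ndim == 1:
            t = t[:, None]
        zz = z.reshape(t.shape)
        # numerically stable BCE-with-logits
        loss = np.mean(np.maximum(zz, 0) - zz * t + np.log1p(np.exp(-np.abs(zz))))
        d = (sigmoid(zz) - t) / t.size
        return loss, d.reshape(logits.shape).astype(logits.dtype)

    @staticmethod
    def activate(logits):
        return sigmoid(logits.astype(np.float64))


# ---------------------------------------------------------------------------
# optimization

class Adam:
    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.trainable]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float):
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - self.beta1) * (p.grad - m)
            v += (1 - self.beta2) * (p.grad ** 2 - v)
            p.value -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def zero_grads(net: Layer) -> None:
    for p in net.params():
        p.grad[...] = 0


def count_trainable(net: Layer) -> int:
    """Total number of scalar parameters the optimizer would update."""
    return int(sum(p.value.size for p in net.params() if p.trainable))


def set_trainable(target: Layer | list[Layer], flag: bool) -> None:
    layers = target if isinstance(target, list) else [target]
    for layer in layers:
        for p in layer.params():
            p.trainable = flag


# ---------------------------------------------------------------------------
# training loop

@dataclass
class FitConfig:
    epochs: int = 100
    batch_size: int = 128
    lr: float = 1e-3
    lr_end: float | None = None      # exponential decay to this value at last epoch
    val_fraction: float = 0.2
    patience: int | None = None      # epochs without val-loss improvement
    seed: int = 0
    shuffle: bool = True


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    best_epoch: int = -1


def _lr_at(cfg: FitConfig, epoch: int) -> float:
    if cfg.lr_end is None or cfg.epochs <= 1:
        return cfg.lr
    frac = epoch / (cfg.epochs - 1)
    return cfg.lr * (cfg.lr_end / cfg.lr) ** frac


def _forward_batched(net, X, batch: int = 512):
    outs = [net.forward(X[i:i + batch], train=False, rng=None)
            for i in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)


def fit(net: Sequential, loss, X: np.ndarray, y: np.ndarray,
        cfg: FitConfig) -> History:
    """Mini-batch Adam training with a seeded random validation hold-out,
    min-validation-loss checkpointing and optional early stopping.

    The weights restored at the end are those of the epoch with minimum
    validation loss.  Deterministic given ``cfg.seed``.
    """
    n = len(X)
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n))) if cfg.val_fraction > 0 else 0
    if n_val >= n:
        raise ValueError("validation fraction leaves no training data")
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = Adam(net.params())
    hist = History()
    best_state: list[np.ndarray] | None = None
    best_val = math.inf
    wait = 0
    for epoch in range(cfg.epochs):
        lr = _lr_at(cfg, epoch)
        perm = rng.permutation(len(Xtr)) if cfg.shuffle else np.arange(len(Xtr))
        losses = []
        for start in range(0, len(Xtr), cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            zero_grads(net)
            out = net.forward(Xtr[sel], train=True, rng=rng)
            l, dout = loss(out, ytr[sel])
            net.backward(dout)
            opt.step(lr)
            losses.append(l)
        hist.train_loss.append(float(np.mean(losses)))
        if n_val:
            out = _forward_batched(net, Xval)
            vl, _ = loss(out, yval)
            hist.val_loss.append(float(vl))
            if isinstance(loss, SoftmaxCrossEntropy):
                hist.val_acc.append(float(np.mean(out.argmax(axis=1) == yval)))
            if vl < best_val - 1e-12:
                best_val = vl
                best_state = net.state()
                hist.best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if cfg.patience is not None and wait >= cfg.patience:
                    break
    if best_state is not None:
        net.load_state(best_state)
    return hist
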