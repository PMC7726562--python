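"""A small, fully seeded CPU engine for U-net training and inference.

Implements exactly what the segmentation models need — 2D/3D `same`
convolutions, ReLU, 2x max-pooling, nearest-neighbour upsampling, skip
concatenation, sigmoid/softmax heads, smoothed-dice losses and the Adam
optimizer — on plain numpy arrays in channels-last layout.  Convolutions are
evaluated as one matrix product per kernel offset, which is fast enough for
the desk-scale networks used throughout (depth 2–4, 4–16 base filters).

Determinism contract: given the same seed and data, training produces
bit-identical histories and weights on a single CPU thread.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np


# ---------------------------------------------------------------------------
# layers

class Conv:
    """N-D convolution, kernel k (odd), stride 1, `same` zero padding.

    Weight layout: ``(Cin * k**ndim, Cout)`` with columns ordered
    ``(Cin, k, k[, k])``.
    """

    def __init__(self, cin: int, cout: int, k: int, ndim: int, rng: np.random.Generator):
        fan_in = cin * k ** ndim
        self.W = (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, cout))
                  .astype(np.float32))
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.ndim, self.cin, self.cout = k, ndim, cin, cout
        self._cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def _offsets(self):
        from itertools import product
        return list(product(range(self.k), repeat=self.ndim))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        k, nd = self.k, self.ndim
        pad = k // 2
        spatial = x.shape[1:-1]
        n = x.shape[0]
        if k == 1:
            y = x.reshape(-1, self.cin) @ self.W + self.b
            if train:
                self._cache = (x, spatial, x.shape)
            return y.reshape(n, *spatial, self.cout)
        xp = np.pad(x, [(0, 0)] + [(pad, pad)] * nd + [(0, 0)])
        # one GEMM per kernel offset on a view: cheaper than materialized im2col
        Wk = self.W.reshape(self.cin, *(k,) * nd, self.cout)
        y = np.zeros((n, *spatial, self.cout), dtype=np.float32)
        flat = (-1, self.cin)
        for off in self._offsets():
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial)) + (slice(None),)
            w_off = Wk[(slice(None),) + off + (slice(None),)]
            y += (xp[sl].reshape(flat) @ w_off).reshape(n, *spatial, self.cout)
        y += self.b
        if train:
            self._cache = (xp, spatial, xp.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, spatial, padded_shape = self._cache
        n = dy.shape[0]
        k, nd, pad = self.k, self.ndim, self.k // 2
        dyf = dy.reshape(-1, self.cout).astype(np.float32)
        self.db = dyf.sum(axis=0)
        if k == 1:
            self.dW = xp.reshape(-1, self.cin).T @ dyf
            return (dyf @ self.W.T).reshape(n, *spatial, self.cin)
        Wk = self.W.reshape(self.cin, *(k,) * nd, self.cout)
        self.dW = np.zeros_like(self.W)
        dWk = self.dW.reshape(self.cin, *(k,) * nd, self.cout)
        dxp = np.zeros(padded_shape, dtype=np.float32)
        flat = (-1, self.cin)
        for off in self._offsets():
            sl = (slice(None),) + tuple(slice(o, o + s) for o, s in zip(off, spatial)) + (slice(None),)
            xv = xp[sl].reshape(flat)
            idx = (slice(None),) + off + (slice(None),)
            dWk[idx] = xv.T @ dyf
            dxp[sl] += (dyf @ Wk[idx].T).reshape(n, *spatial, self.cin)
        if pad:
            sl = (slice(None),) + (slice(pad, -pad),) * nd + (slice(None),)
            return dxp[sl]
        return dxp

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    params: list = []

    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class InstanceNorm:
    """Per-sample, per-channel normalization over the spatial axes with a
    learned affine (gamma, beta).  Deterministic — no running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.g = np.ones(channels, dtype=np.float32)
        self.b = np.zeros(channels, dtype=np.float32)
        self.eps = eps

    @property
    def params(self):
        return [self.g, self.b]

    def forward(self, x, train=True):
        axes = tuple(range(1, x.ndim - 1))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv, axes)
        return xhat * self.g + self.b

    def backward(self, dy):
        xhat, inv, axes = self._cache
        dyf = dy.astype(np.float32)
        red = (0,) + axes
        self.dg = (dyf * xhat).sum(axis=red)
        self.db = dyf.sum(axis=red)
        dxhat = dyf * self.g
        m = np.prod([xhat.shape[a] for a in axes])
        dx = inv / m * (m * dxhat - dxhat.sum(axis=axes, keepdims=True)
                        - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
        return dx.astype(np.float32)

    @property
    def grads(self):
        return [self.dg, self.db]


class MaxPool:
    """2x max-pooling along every spatial axis (dims must be even)."""

    params: list = []

    def __init__(self, ndim: int):
        self.ndim = ndim

    def forward(self, x, train=True):
        nd = self.ndim
        n, c = x.shape[0], x.shape[-1]
        spatial = x.shape[1:-1]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial dims must be even for 2x pooling, got {spatial}")
        out_sp = tuple(s // 2 for s in spatial)
        shape = (n,) + sum(((s // 2, 2) for s in spatial), ()) + (c,)
        xr = x.reshape(shape)
        # move the window axes (2, 4[, 6]) to the end and flatten them
        win_axes = tuple(range(2, 2 + 2 * nd, 2))
        order = (0,) + tuple(1 + 2 * i for i in range(nd)) + (1 + 2 * nd,) + win_axes
        xw = xr.transpose(order).reshape(n, *out_sp, c, 2 ** nd)
        idx = np.argmax(xw, axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, in_shape = self._cache
        nd = self.ndim
        n, c = in_shape[0], in_shape[-1]
        out_sp = tuple(s // 2 for s in in_shape[1:-1])
        dxw = np.zeros((n, *out_sp, c, 2 ** nd), dtype=np.float32)
        np.put_along_axis(dxw, idx[..., None], dy[..., None].astype(np.float32), axis=-1)
        # invert the forward transpose/reshape
        dxw = dxw.reshape((n,) + out_sp + (c,) + (2,) * nd)
        order = (0,) + tuple(1 + 2 * i for i in range(nd)) + (1 + 2 * nd,) + tuple(range(2, 2 + 2 * nd, 2))
        return dxw.transpose(np.argsort(order)).reshape(in_shape)


class Upsample:
    """Nearest-neighbour 2x upsampling along every spatial axis."""

    params: list = []

    def __init__(self, ndim: int):
        self.ndim = ndim

    def forward(self, x, train=True):
        for ax in range(1, 1 + self.ndim):
            x = np.repeat(x, 2, axis=ax)
        return x

    def backward(self, dy):
        n, c = dy.shape[0], dy.shape[-1]
        sp = dy.shape[1:-1]
        shape = (n,) + sum(((s // 2, 2) for s in sp), ()) + (c,)
        axes = tuple(range(2, 2 + 2 * self.ndim, 2))
        return dy.reshape(shape).sum(axis=axes)


# ---------------------------------------------------------------------------
# the U-net

class UNet:
    """Classic encoder-decoder U-net with skip connections.

    ``depth`` down/up levels, doubling filters per level; two 3^ndim convs
    per block, ReLU activations, nearest-upsample + conv decoding, and a
    final 1x1 conv producing ``out_channels`` logits (sigmoid for binary
    output, softmax over channels for multi-class — applied by the loss /
    ``predict``, not stored in the graph).
    """

    def __init__(self, ndim: int = 2, in_channels: int = 1, out_channels: int = 1,
                 depth: int = 2, base_filters: int = 8, seed: int = 0,
                 norm: str = "none"):
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        if norm not in ("none", "instance"):
            raise ValueError(f"norm must be 'none' or 'instance', got {norm!r}")
        rng = np.random.default_rng(seed)
        self.ndim, self.depth, self.norm = ndim, depth, norm
        self.in_channels, self.out_channels, self.base_filters = in_channels, out_channels, base_filters

        def block(cin, cout):
            layers = []
            for a, b in ((cin, cout), (cout, cout)):
                layers.append(Conv(a, b, 3, ndim, rng))
                if norm == "instance":
                    layers.append(InstanceNorm(b))
                layers.append(ReLU())
            return layers

        f = [base_filters * 2 ** i for i in range(depth + 1)]
        self.enc = []
        cin = in_channels
        for i in range(depth):
            self.enc.append(block(cin, f[i]))
            cin = f[i]
        self.pools = [MaxPool(ndim) for _ in range(depth)]
        self.bottleneck = block(cin, f[depth])
        self.ups = [Upsample(ndim) for _ in range(depth)]
        self.dec = []
        cin = f[depth]
        for i in reversed(range(depth)):
            self.dec.append(block(cin + f[i], f[i]))
            cin = f[i]
        self.head = Conv(cin, out_channels, 1, ndim, rng)

    # -- plumbing -----------------------------------------------------------
    def _layers(self):
        for block in self.enc:
            yield from block
        yield from self.pools
        yield from self.bottleneck
        yield from self.ups
        for block in self.dec:
            yield from block
        yield self.head

    def parameters(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self._layers():
            if layer.params:
                out.extend(layer.grads)
        return out

    def get_weights(self):
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights):
        for p, w in zip(self.parameters(), weights):
            p[...] = w

    def clone(self) -> "UNet":
        return copy.deepcopy(self)

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            for layer in block:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits.astype(np.float32))
        dskips = []
        for up, block, sc in zip(reversed(self.ups), reversed(self.dec),
                                 reversed(self._skip_channels)):
            for layer in reversed(block):
                d = layer.backward(d)
            dskips.append(d[..., :sc])
            d = up.backward(d[..., sc:])
        for layer in reversed(self.bottleneck):
            d = layer.backward(d)
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            d = pool.backward(d)
            d = d + dskip
            for layer in reversed(block):
                d = layer.backward(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass returning probabilities (sigmoid if one output
        channel, softmax over channels otherwise)."""
        logits = self.forward(np.asarray(x, dtype=np.float32), train=False)
        if self.out_channels == 1:
            return sigmoid(logits)
        return softmax(logits)

    def spec_dict(self) -> dict:
        return {"ndim": self.ndim, "in_channels": self.in_channels,
                "out_channels": self.out_channels, "depth": self.depth,
                "base_filters": self.base_filters, "norm": self.norm}


def sigmoid(z):
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60))),
                    np.exp(np.clip(z, -60, 60)) / (1.0 + np.exp(np.clip(z, -60, 60))))


def softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# losses

def dice_binary_loss(logits: np.ndarray, target: np.ndarray, smooth: float = 1.0):
    """Per-sample smoothed dice loss 1 - (2*XY+s)/(X+Y+s) for a sigmoid head.

    Returns (mean loss over the batch, gradient w.r.t. logits).
    """
    p = sigmoid(logits).astype(np.float64)
    y = np.asarray(target, dtype=np.float64)
    axes = tuple(range(1, p.ndim))
    num = 2.0 * (p * y).sum(axis=axes) + smooth
    den = p.sum(axes) + y.sum(axes) + smooth
    d = num / den
    loss = float(np.mean(1.0 - d))
    # d(dice)/dp_i = (2 y_i den - num) / den^2 ; chain through sigmoid
    shape = (-1,) + (1,) * (p.ndim - 1)
    grad_p = -(2.0 * y * den.reshape(shape) - num.reshape(shape)) / (den.reshape(shape) ** 2)
    dlogits = grad_p * p * (1.0 - p) / p.shape[0]
    return loss, dlogits.astype(np.float32)


def dice_multiclass_loss(logits: np.ndarray, onehot: np.ndarray,
                         class_idx=(1, 2, 3, 4, 5), smooth: float = 1.0):
    """1 - mean smoothed dice over the listed classes, for a softmax head.

    The unlabelled class (channel 0) is excluded from the average but still
    participates through the softmax normalisation.
    """
    p = softmax(logits).astype(np.float64)
    y = np.asarray(onehot, dtype=np.float64)
    axes = tuple(range(1, p.ndim - 1))
    grad_p = np.zeros_like(p)
    dices = []
    for c in class_idx:
        pc, yc = p[..., c], y[..., c]
        num = 2.0 * (pc * yc).sum(axis=axes) + smooth
        den = pc.sum(axes) + yc.sum(axes) + smooth
        dices.append(num / den)
        shape = (-1,) + (1,) * (pc.ndim - 1)
        grad_p[..., c] = -(2.0 * yc * den.reshape(shape) - num.reshape(shape)) / (den.reshape(shape) ** 2)
    grad_p /= len(class_idx)
    loss = float(np.mean(1.0 - np.mean(dices, axis=0)))
    # backprop through softmax: dz_k = p_k (g_k - sum_j g_j p_j)
    inner = (grad_p * p).sum(axis=-1, keepdims=True)
    dlogits = p * (grad_p - inner) / p.shape[0]
    return loss, dlogits.astype(np.float32)


# ---------------------------------------------------------------------------
# optimizer and training loop

class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float32)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainResult:
    model: UNet
    history: "object"   # pandas DataFrame: epoch, train_loss, val_metric
    best_epoch: int
    best_val: float


def train_loop(model: UNet, loss_fn, train_xy, val_fn, *, lr: float, max_epochs: int,
               patience: int, batch_size: int, seed: int, shuffle: bool = True):
    """Generic seeded mini-batch training with early stopping.

    ``train_xy`` is (X, Y) arrays with samples on axis 0; ``val_fn(model)``
    returns the validation metric (higher is better).  Training stops after
    ``patience`` epochs without improvement and the best-validation weights
    are restored.  ``max_epochs=0`` returns the model untouched.
    """
    import pandas as pd

    X, Y = train_xy
    n = X.shape[0]
    if n == 0:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    best = val_fn(model)
    best_w = model.get_weights()
    best_epoch = 0
    rows = []
    bad = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n) if shuffle else np.arange(n)
        losses = []
        for start in range(0, n, batch_size):
            sel = order[start:start + batch_size]
            logits = model.forward(X[sel], train=True)
            loss, dlogits = loss_fn(logits, Y[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} (lr={lr}); aborting")
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
        val = val_fn(model)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_metric": float(val)})
        if val > best + 1e-9:
            best, best_epoch, bad = val, epoch, 0
            best_w = model.get_weights()
        else:
            bad += 1
            if bad > patience:
                break
    model.set_weights(best_w)
    return TrainResult(model=model, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_val=float(best))
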