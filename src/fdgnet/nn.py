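"""Minimal neural-network core for 3D volumetric models.

Implements exactly the layers the backbone needs — 3D convolution,
instance/batch normalization, global channel attention, 2x2x2 max pooling,
global average pooling, dropout, and a dense layer — as plain NumPy arrays
with hand-written forward and backward passes.  Tensors use the
(N, C, D, H, W) layout.

Every layer is an object with ``forward(x, training)`` and ``backward(gy)``;
parameters and their gradient accumulators live in ``layer.params`` /
``layer.grads`` keyed by name.  There is no autograd graph: the backbone
composes layers in a fixed order and chains the calls.

Parameters default to float32 (the im2col convolutions are memory-bandwidth
bound and SGD needs no more); computations follow the input dtype, so
casting parameters and inputs up to float64 gives the precision
finite-difference gradient checks need.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def cast_layers(layers, dtype) -> None:
    """Cast every parameter, gradient and optimizer-visible buffer in place."""
    for layer in layers:
        for d in (layer.params, layer.grads):
            for k in d:
                d[k] = d[k].astype(dtype)
        for attr in ("running_mean", "running_var"):
            if hasattr(layer, attr):
                setattr(layer, attr, getattr(layer, attr).astype(dtype))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base layer: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


def _corr3d(x: np.ndarray, w: np.ndarray, pad: tuple[int, int, int]) -> np.ndarray:
    """Cross-correlate (N, Cin, D, H, W) with (Cout, Cin, kd, kh, kw).

    Gathers the kernel-offset slices into a (N, Cin*kd*kh*kw, L) column
    tensor via contiguous sub-block copies (cheaper than a strided im2col
    transpose) and contracts with one batched gemm.  Returns (output,
    columns); the columns are reused for the weight gradient.
    """
    pd, ph, pw = pad
    if pd or ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    n, cin = x.shape[:2]
    kd, kh, kw = w.shape[2:]
    do = x.shape[2] - kd + 1
    ho = x.shape[3] - kh + 1
    wo = x.shape[4] - kw + 1
    L = do * ho * wo
    cols = np.empty((n, cin, kd * kh * kw, L), dtype=x.dtype)
    k = 0
    for a in range(kd):
        for b in range(kh):
            for c in range(kw):
                cols[:, :, k, :] = x[:, :, a:a + do, b:b + ho, c:c + wo] \
                    .reshape(n, cin, L)
                k += 1
    cols = cols.reshape(n, cin * kd * kh * kw, L)
    w2 = w.reshape(w.shape[0], -1).astype(x.dtype, copy=False)
    out = np.matmul(w2[None], cols)  # (N, Cout, L)
    return out.reshape(n, w.shape[0], do, ho, wo), cols


class Conv3d(Layer):
    """3D convolution, stride 1, padding 'same' (odd kernels) or 'valid'."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int, int],
                 padding: str, rng: np.random.Generator) -> None:
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and any(k % 2 == 0 for k in kernel):
            raise ValueError("'same' padding requires odd kernel sizes")
        self.in_ch, self.out_ch, self.kernel, self.padding = in_ch, out_ch, tuple(kernel), padding
        fan_in = in_ch * int(np.prod(kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, *kernel))
        self.params = {"w": w.astype(DTYPE), "b": np.zeros(out_ch, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _pad(self) -> tuple[int, int, int]:
        if self.padding == "same":
            return tuple((k - 1) // 2 for k in self.kernel)
        return (0, 0, 0)

    def out_shape(self, spatial: tuple[int, int, int]) -> tuple[int, int, int]:
        if self.padding == "same":
            return tuple(spatial)
        return tuple(s - k + 1 for s, k in zip(spatial, self.kernel))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out, cols = _corr3d(x, self.params["w"], self._pad())
        self._cols = cols if training else None
        self._xshape = x.shape
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n = gy.shape[0]
        g2 = gy.reshape(n, self.out_ch, -1)  # (N, Cout, L)
        # weights: batched gemm against the cached columns
        gw = np.matmul(g2, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["w"] += gw.reshape(self.params["w"].shape)
        self.grads["b"] += gy.sum(axis=(0, 2, 3, 4))
        # input: full correlation of gy with flipped, channel-swapped kernels
        wflip = self.params["w"][:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        bpad = tuple(k - 1 - p for k, p in zip(self.kernel, self._pad()))
        gx, _ = _corr3d(gy, np.ascontiguousarray(wflip), bpad)
        self._cols = None
        return gx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2, floor semantics (trailing odd voxel dropped)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        do, ho, wo = d // 2, h // 2, w // 2
        if min(do, ho, wo) < 1:
            raise ValueError(f"spatial shape {(d, h, w)} too small to pool")
        xe = x[:, :, : 2 * do, : 2 * ho, : 2 * wo]
        v = xe.reshape(n, c, do, 2, ho, 2, wo, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        v = v.reshape(n, c, do, ho, wo, 8)
        self._arg = v.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(v, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, do, ho, wo = gy.shape
        g = np.zeros((n, c, do, ho, wo, 8), dtype=gy.dtype)
        np.put_along_axis(g, self._arg[..., None], gy[..., None], axis=-1)
        g = g.reshape(n, c, do, ho, wo, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        g = g.reshape(n, c, 2 * do, 2 * ho, 2 * wo)
        gx = np.zeros(self._xshape, dtype=gy.dtype)
        gx[:, :, : 2 * do, : 2 * ho, : 2 * wo] = g
        return gx


class InstanceNorm3d(Layer):
    """Per-(sample, channel) spatial standardization with learned affine."""

    def __init__(self, ch: int, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.params = {"gamma": np.ones(ch, dtype=DTYPE), "beta": np.zeros(ch, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        g = self.params["gamma"][None, :, None, None, None]
        b = self.params["beta"][None, :, None, None, None]
        return self._xhat * g + b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        ax = (2, 3, 4)
        self.grads["gamma"] += (gy * self._xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] += gy.sum(axis=(0, 2, 3, 4))
        g = self.params["gamma"][None, :, None, None, None]
        gh = gy * g
        m = np.prod([gy.shape[i] for i in ax])
        gx = self._istd * (gh - gh.mean(axis=ax, keepdims=True)
                           - self._xhat * (gh * self._xhat).mean(axis=ax, keepdims=True))
        return gx


class BatchNorm3d(Layer):
    """Per-channel standardization over (batch, spatial); running stats for eval."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(ch, dtype=DTYPE), "beta": np.zeros(ch, dtype=DTYPE)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        ax = (0, 2, 3, 4)
        if training:
            mu = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        mu4 = mu[None, :, None, None, None]
        self._istd = 1.0 / np.sqrt(var[None, :, None, None, None] + self.eps)
        self._xhat = (x - mu4) * self._istd
        self._train = training
        g = self.params["gamma"][None, :, None, None, None]
        return self._xhat * g + self.params["beta"][None, :, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        ax = (0, 2, 3, 4)
        self.grads["gamma"] += (gy * self._xhat).sum(axis=ax)
        self.grads["beta"] += gy.sum(axis=ax)
        gh = gy * self.params["gamma"][None, :, None, None, None]
        if not self._train:
            return gh * self._istd
        return self._istd * (gh - gh.mean(axis=ax, keepdims=True)
                             - self._xhat * (gh * self._xhat).mean(axis=ax, keepdims=True))


class ChannelAttention(Layer):
    """Global channel attention: W = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F))).

    Spatial average- and max-pooling reduce the map to per-channel scalars;
    a single shared one-hidden-layer MLP (ReLU hidden, reduction ``ratio``)
    scores both descriptors; the logistic of their sum gates each channel.
    """

    def __init__(self, ch: int, ratio: int, rng: np.random.Generator) -> None:
        super().__init__()
        hidden = max(1, ch // ratio)
        self.ch, self.hidden = ch, hidden
        self.params = {
            "w1": rng.normal(0.0, np.sqrt(2.0 / ch), size=(hidden, ch)).astype(DTYPE),
            "b1": np.zeros(hidden, dtype=DTYPE),
            "w2": rng.normal(0.0, np.sqrt(2.0 / hidden), size=(ch, hidden)).astype(DTYPE),
            "b2": np.zeros(ch, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _mlp(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = z @ self.params["w1"].T + self.params["b1"]
        hr = np.maximum(h, 0.0)
        return hr @ self.params["w2"].T + self.params["b2"], hr

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """The gating vector W in (0,1)^C for each sample, without applying it."""
        avg = x.mean(axis=(2, 3, 4))
        mx = x.max(axis=(2, 3, 4))
        a, _ = self._mlp(avg)
        m, _ = self._mlp(mx)
        return _sigmoid(a + m)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c = x.shape[:2]
        flat = x.reshape(n, c, -1)
        self._m = flat.shape[2]
        avg = flat.mean(axis=2)
        self._argmax = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, self._argmax[:, :, None], axis=2)[:, :, 0]
        a, ha = self._mlp(avg)
        m, hm = self._mlp(mx)
        self._w = _sigmoid(a + m)
        self._cache = (x, avg, mx, ha, hm)
        return x * self._w[:, :, None, None, None]

    def _mlp_backward(self, gs: np.ndarray, z: np.ndarray, hr: np.ndarray) -> np.ndarray:
        self.grads["w2"] += gs.T @ hr
        self.grads["b2"] += gs.sum(axis=0)
        gh = (gs @ self.params["w2"]) * (hr > 0)
        self.grads["w1"] += gh.T @ z
        self.grads["b1"] += gh.sum(axis=0)
        return gh @ self.params["w1"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x, avg, mx, ha, hm = self._cache
        n, c = x.shape[:2]
        gx = gy * self._w[:, :, None, None, None]
        gw = (gy * x).sum(axis=(2, 3, 4))
        gs = gw * self._w * (1.0 - self._w)
        gavg = self._mlp_backward(gs, avg, ha)
        gmx = self._mlp_backward(gs, mx, hm)
        gx += (gavg / self._m)[:, :, None, None, None]
        gflat = np.zeros((n, c, self._m), dtype=gy.dtype)
        np.put_along_axis(gflat, self._argmax[:, :, None], gmx[:, :, None], axis=2)
        gx += gflat.reshape(x.shape)
        self._cache = None
        return gx


class GlobalAvgPool(Layer):
    """(N, C, D, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._shape
        return np.broadcast_to(gy[:, :, None, None, None] / (d * h * w), self._shape).copy()


class Dropout(Layer):
    """Inverted dropout on (N, F) activations; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy if self._mask is None else gy * self._mask


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, np.sqrt(2.0 / in_f), size=(out_f, in_f)).astype(DTYPE),
            "b": np.zeros(out_f, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["w"] += gy.T @ self._x
        self.grads["b"] += gy.sum(axis=0)
        return gy @ self.params["w"]


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                          label_smoothing: float = 0.0) -> tuple[float, np.ndarray]:
    """Mean label-smoothed cross-entropy over a (N, K) logit batch.

    ``targets`` are integer class indices; returns (loss, dL/dlogits).
    With smoothing eps the target distribution is (1-eps) on the true class
    and eps/K spread uniformly.
    """
    n, k = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    q = np.full((n, k), label_smoothing / k)
    q[np.arange(n), targets] += 1.0 - label_smoothing
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    loss = float(-(q * logp).sum() / n)
    return loss, (p - q) / n


class SGD:
    """Plain stochastic gradient descent with optional momentum."""

    def __init__(self, layers: list[Layer], lr: float, momentum: float = 0.0) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.momentum = lr, momentum
        self._vel = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def zero_grad(self) -> None:
        for l in self.layers:
            l.zero_grad()

    def step(self, scale: float = 1.0) -> None:
        """Apply one update; ``scale`` multiplies the accumulated gradients
        (used to average gradients accumulated over several mini-batches)."""
        for l, vel in zip(self.layers, self._vel):
            for k in l.params:
                g = l.grads[k] * scale
                if self.momentum:
                    vel[k] = self.momentum * vel[k] - self.lr * g
                    l.params[k] += vel[k]
                else:
                    l.params[k] -= self.lr * g
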