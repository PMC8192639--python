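"""Minimal CNN layer stack used by the slice-submodule classifier.

Every per-slice submodule shares one architecture (4 x [3x3 conv, batch
norm, ReLU, 2x2 max-pool] -> dense -> sigmoid) but owns independent
weights.  Submodules whose slices share a shape (all slices along one
volume axis) are evaluated together: their parameters are stacked along a
leading "submodule" dimension and each layer works on tensors of shape
``(S, B, H, W, C)`` via batched matrix multiplies, so a whole axis is a
handful of BLAS calls instead of S separate small networks.

Gradients are computed by explicit reverse-mode passes per layer and are
verified against central finite differences in the test suite.

Conventions: float32 arithmetic; convolutions use same-padding (pad 1) and
stride 1, so only pooling reduces resolution; pooling uses floor division
for odd extents; conv layers have no bias (the following batch norm
provides the shift); He initialization for conv weights, Xavier (Glorot
uniform) for dense layers.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "StackedConv3x3",
    "StackedBatchNorm",
    "ReLU",
    "MaxPool2x2",
    "StackedDense",
    "SubmoduleStack",
    "Adam",
    "pooled_shape",
]

DTYPE = np.float32


def pooled_shape(h: int, w: int, n_pools: int = 4) -> tuple[int, int]:
    """In-plane shape after ``n_pools`` 2x2/stride-2 poolings (floor)."""
    for _ in range(n_pools):
        h //= 2
        w //= 2
    return h, w


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class StackedConv3x3:
    """3x3 same-padding convolution for S independent submodules.

    Weight layout: ``(S, 9 * c_in, c_out)`` with the 9*c_in axis ordered as
    (kh, kw, c_in) to match the im2col column layout.
    """

    def __init__(self, n_stack: int, c_in: int, c_out: int, rng: np.random.Generator,
                 first: bool = False):
        fan_in = 9 * c_in
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.w = Param(rng.normal(0.0, std, size=(n_stack, fan_in, c_out)))
        self.first = first  # skip input-gradient computation at the first layer
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.w]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        S, B, H, W, C = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (0, 0)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (S,B,H,W,C,3,3)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 3, 5, 6, 4)).reshape(
            S, B * H * W, 9 * C
        )
        y = np.matmul(cols, self.w.value).reshape(S, B, H, W, -1)
        if training:
            self._cols = cols
            self._xshape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray | None:
        S, B, H, W, Co = dy.shape
        dyf = np.ascontiguousarray(dy).reshape(S, B * H * W, Co)
        self.w.grad += np.matmul(self._cols.transpose(0, 2, 1), dyf)
        self._cols = None
        if self.first:
            return None
        _, _, _, _, C = self._xshape
        dcols = np.matmul(dyf, self.w.value.transpose(0, 2, 1))
        dcols = dcols.reshape(S, B, H, W, 3, 3, C)
        dxp = np.zeros((S, B, H + 2, W + 2, C), dtype=DTYPE)
        for kh in range(3):
            for kw in range(3):
                dxp[:, :, kh:kh + H, kw:kw + W, :] += dcols[:, :, :, :, kh, kw, :]
        return dxp[:, :, 1:-1, 1:-1, :]


class StackedBatchNorm:
    """Per-submodule, per-channel batch normalization over (batch, H, W)."""

    def __init__(self, n_stack: int, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones((n_stack, c)))
        self.beta = Param(np.zeros((n_stack, c)))
        self.running_mean = np.zeros((n_stack, c), dtype=DTYPE)
        self.running_var = np.ones((n_stack, c), dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._xhat: np.ndarray | None = None
        self._invstd: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # x: (S,B,H,W,C); statistics over axes (1,2,3) per (S,C)
        if training:
            mean = x.mean(axis=(1, 2, 3))
            var = x.var(axis=(1, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(DTYPE)
        else:
            mean = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None, None, :]) * invstd[:, None, None, None, :]
        y = self.gamma.value[:, None, None, None, :] * xhat + self.beta.value[:, None, None, None, :]
        if training:
            self._xhat = xhat.astype(DTYPE)
            self._invstd = invstd.astype(DTYPE)
        return y.astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        S, B, H, W, C = dy.shape
        n = B * H * W
        dbeta = dy.sum(axis=(1, 2, 3))
        dgamma = (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        coef = (self.gamma.value * invstd / n)[:, None, None, None, :]
        dx = coef * (
            n * dy
            - dbeta[:, None, None, None, :]
            - xhat * dgamma[:, None, None, None, :]
        )
        self._xhat = None
        return dx.astype(DTYPE)


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2x2:
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._inshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        S, B, H, W, C = x.shape
        H2, W2 = H // 2, W // 2
        xc = x[:, :, : 2 * H2, : 2 * W2, :]
        xr = xc.reshape(S, B, H2, 2, W2, 2, C).transpose(0, 1, 2, 4, 3, 5, 6)
        xr = np.ascontiguousarray(xr).reshape(S, B, H2, W2, 4, C)
        y = xr.max(axis=4)
        if training:
            self._idx = xr.argmax(axis=4)
            self._inshape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        S, B, H, W, C = self._inshape
        H2, W2 = H // 2, W // 2
        dxr = np.zeros((S, B, H2, W2, 4, C), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[:, :, :, :, None, :], dy[:, :, :, :, None, :], axis=4)
        dxc = dxr.reshape(S, B, H2, W2, 2, 2, C).transpose(0, 1, 2, 4, 3, 5, 6)
        dxc = dxc.reshape(S, B, 2 * H2, 2 * W2, C)
        if (H, W) == (2 * H2, 2 * W2):
            dx = dxc
        else:
            dx = np.zeros((S, B, H, W, C), dtype=DTYPE)
            dx[:, :, : 2 * H2, : 2 * W2, :] = dxc
        self._idx = None
        return dx


class StackedDense:
    """Per-submodule affine map ``(S,B,F_in) -> (S,B,F_out)``, Xavier init."""

    def __init__(self, n_stack: int, f_in: int, f_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (f_in + f_out))
        self.w = Param(rng.uniform(-limit, limit, size=(n_stack, f_in, f_out)))
        self.b = Param(np.zeros((n_stack, 1, f_out)))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        y = np.matmul(x, self.w.value) + self.b.value
        if training:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += np.matmul(self._x.transpose(0, 2, 1), dy)
        self.b.grad += dy.sum(axis=1, keepdims=True)
        dx = np.matmul(dy, self.w.value.transpose(0, 2, 1))
        self._x = None
        return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SubmoduleStack:
    """All submodules of one volume axis, trained jointly.

    Input ``(S, B, H, W, 1)``; output per-slice sigmoid probabilities of
    shape ``(S, B)``.
    """

    def __init__(self, n_stack: int, slice_shape: tuple[int, int],
                 conv_filters: tuple[int, int, int, int], rng: np.random.Generator):
        h, w = slice_shape
        hf, wf = pooled_shape(h, w, n_pools=4)
        if hf < 1 or wf < 1:
            bad = "height" if h < 16 else "width"
            raise ValueError(
                f"slice shape {slice_shape} cannot survive 4 poolings "
                f"({bad} dimension too small; each in-plane dim must be >= 16)"
            )
        self.n_stack = n_stack
        self.slice_shape = (h, w)
        self.flat_features = hf * wf * conv_filters[3]
        self.layers: list = []
        c_in = 1
        for li, c_out in enumerate(conv_filters):
            self.layers.append(StackedConv3x3(n_stack, c_in, c_out, rng, first=(li == 0)))
            self.layers.append(StackedBatchNorm(n_stack, c_out))
            self.layers.append(ReLU())
            self.layers.append(MaxPool2x2())
            c_in = c_out
        self.dense = StackedDense(n_stack, self.flat_features, 1, rng)
        self._p: np.ndarray | None = None

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend(self.dense.params())
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = np.ascontiguousarray(x, dtype=DTYPE)
        for layer in self.layers:
            h = layer.forward(h, training)
        S, B = h.shape[:2]
        h = h.reshape(S, B, -1)
        z = self.dense.forward(h, training)[:, :, 0]  # (S,B)
        p = _sigmoid(z)
        if training:
            self._p = p
        return p

    def backward(self, dp: np.ndarray) -> None:
        """Backpropagate d(loss)/d(per-slice probability) of shape (S,B)."""
        dz = dp * self._p * (1.0 - self._p)
        self._p = None
        d = self.dense.backward(dz[:, :, None].astype(DTYPE))
        S, B = d.shape[:2]
        h4, w4 = pooled_shape(*self.slice_shape, n_pools=4)
        d = d.reshape(S, B, h4, w4, -1)
        for layer in reversed(self.layers):
            d = layer.backward(d)


class Adam:
    """Adam optimizer with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * np.square(p.grad)
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
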