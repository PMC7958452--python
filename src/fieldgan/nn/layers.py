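"""Minimal 3D convolutional network layers with explicit backpropagation.

The networks needed here are small stacks of 3D convolution, batch
normalization, rectifier and pooling layers.  Rather than pulling in a full
deep-learning framework, this module implements exactly those layers on top
of numpy with hand-written backward passes (verified against finite
differences in the test suite).

Conventions
-----------
* Tensors are ``float32`` arrays of shape ``(N, C, D, H, W)``.
* Every layer caches what its backward pass needs during ``forward``;
  ``backward`` consumes the cache and returns the gradient w.r.t. the input
  while accumulating parameter gradients in ``Param.grad``.
* Convolution is computed by the shift-and-add method: one ``(C_out, C_in)``
  matmul per kernel offset.  This keeps peak memory at the size of one
  activation (no im2col buffer), which matters for volumetric inputs.
"""

from __future__ import annotations

import numpy as np

from ..types import ShapeError

DTYPE = np.float32


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError("expected scalar or length-3 value")
    return t


class Conv3d(Layer):
    """3D convolution (cross-correlation) with optional bias.

    ``zero_init=True`` zeroes weights and bias, which makes a residual head
    start at the identity mapping.  Otherwise weights are He-scaled normal
    draws from the provided generator.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        padding: int = 0,
        *,
        bias: bool = True,
        zero_init: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = _triple(kernel)
        self.stride = int(stride)
        self.padding = int(padding)
        k = self.kernel
        fan_in = in_channels * k[0] * k[1] * k[2]
        if zero_init:
            w = np.zeros((out_channels, in_channels, *k))
        else:
            if rng is None:
                rng = np.random.default_rng()
            w = rng.standard_normal((out_channels, in_channels, *k)) * np.sqrt(2.0 / fan_in)
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(out_channels), f"{name}.b") if bias else None
        self._cache: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _out_size(self, s: int, axis: int) -> int:
        o = (s + 2 * self.padding - self.kernel[axis]) // self.stride + 1
        if o < 1:
            raise ShapeError(
                f"input side {s} too small for kernel {self.kernel[axis]} "
                f"stride {self.stride} padding {self.padding}"
            )
        return o

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c = x.shape[:2]
        if c != self.in_channels:
            raise ShapeError(f"expected {self.in_channels} input channels, got {c}")
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        out_sp = tuple(self._out_size(x.shape[2 + a], a) for a in range(3))
        do, ho, wo = out_sp
        s = self.stride
        w = self.W.data
        out = np.zeros((n, self.out_channels, do * ho * wo), dtype=DTYPE)
        for i in range(self.kernel[0]):
            for j in range(self.kernel[1]):
                for k in range(self.kernel[2]):
                    xs = xp[:, :, i : i + s * do : s, j : j + s * ho : s, k : k + s * wo : s]
                    xs = np.ascontiguousarray(xs).reshape(n, self.in_channels, -1)
                    out += w[:, :, i, j, k] @ xs
        out = out.reshape(n, self.out_channels, do, ho, wo)
        if self.b is not None:
            out += self.b.data[None, :, None, None, None]
        if train:
            self._cache = xp
        else:
            self._cache = xp  # eval-mode backward is used for generator input grads
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp = self._cache
        if xp is None:
            raise RuntimeError("backward called before forward")
        n = xp.shape[0]
        do, ho, wo = gout.shape[2:]
        s = self.stride
        gflat = np.ascontiguousarray(gout).reshape(n, self.out_channels, -1)
        w = self.W.data
        dxp = np.zeros_like(xp)
        for i in range(self.kernel[0]):
            for j in range(self.kernel[1]):
                for k in range(self.kernel[2]):
                    xs = xp[:, :, i : i + s * do : s, j : j + s * ho : s, k : k + s * wo : s]
                    xs = np.ascontiguousarray(xs).reshape(n, self.in_channels, -1)
                    # (N, C_out, L) @ (N, L, C_in) summed over batch
                    self.W.grad[:, :, i, j, k] += np.matmul(
                        gflat, xs.transpose(0, 2, 1)
                    ).sum(axis=0)
                    dxs = (w[:, :, i, j, k].T @ gflat).reshape(
                        n, self.in_channels, do, ho, wo
                    )
                    dxp[:, :, i : i + s * do : s, j : j + s * ho : s, k : k + s * wo : s] += dxs
        if self.b is not None:
            self.b.grad += gflat.sum(axis=(0, 2))
        p = self.padding
        if p:
            return dxp[:, :, p:-p, p:-p, p:-p]
        return dxp


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, D, H, W).

    Batch statistics in train mode, running statistics in eval mode; running
    stats are frozen outside training.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
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
        xhat = (x - mean[None, :, None, None, None]) * invstd[None, :, None, None, None]
        self._cache = (xhat.astype(DTYPE), invstd.astype(DTYPE), train)
        return (
            self.gamma.data[None, :, None, None, None] * xhat
            + self.beta.data[None, :, None, None, None]
        ).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, invstd, train = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (gout * xhat).sum(axis=axes)
        self.beta.grad += gout.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None]
        dxhat = gout * g
        if not train:
            return (dxhat * invstd[None, :, None, None, None]).astype(DTYPE)
        m = gout.shape[0] * gout.shape[2] * gout.shape[3] * gout.shape[4]
        mean_dxhat = dxhat.mean(axis=axes, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes, keepdims=True)
        dx = invstd[None, :, None, None, None] * (
            dxhat - mean_dxhat - xhat * mean_dxhat_xhat
        )
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, 0.0).astype(DTYPE)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, self.slope * gout).astype(DTYPE)


class AvgPool3d(Layer):
    """Non-overlapping average pooling with kernel = stride = 2.

    Odd trailing rows are dropped (floor semantics); their gradient is zero.
    """

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, d, h, w = x.shape
        do, ho, wo = d // 2, h // 2, w // 2
        if min(do, ho, wo) < 1:
            raise ShapeError(f"input spatial size {(d, h, w)} too small to pool")
        self._in_shape = x.shape
        xc = x[:, :, : 2 * do, : 2 * ho, : 2 * wo]
        return xc.reshape(n, c, do, 2, ho, 2, wo, 2).mean(axis=(3, 5, 7)).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        do, ho, wo = gout.shape[2:]
        dx = np.zeros(self._in_shape, dtype=DTYPE)
        g = (gout / 8.0)[:, :, :, None, :, None, :, None]
        dx[:, :, : 2 * do, : 2 * ho, : 2 * wo] = np.broadcast_to(
            g, (n, c, do, 2, ho, 2, wo, 2)
        ).reshape(n, c, 2 * do, 2 * ho, 2 * wo)
        return dx


class GlobalAvgPool(Layer):
    """Mean over all spatial positions: (N, C, D, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4)).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        return np.broadcast_to(
            (gout / (d * h * w))[:, :, None, None, None], self._in_shape
        ).astype(DTYPE)


class Sequential(Layer):
    """A feed-forward stack of layers with reverse-order backprop."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = list(layers)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All arrays that define the model state (weights + running stats)."""
        out: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params()):
                out[f"layer{li}.p{pi}"] = p.data
            if isinstance(layer, BatchNorm3d):
                out[f"layer{li}.running_mean"] = layer.running_mean
                out[f"layer{li}.running_var"] = layer.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params()):
                p.data = np.asarray(arrays[f"layer{li}.p{pi}"], dtype=DTYPE).copy()
                p.grad = np.zeros_like(p.data)
            if isinstance(layer, BatchNorm3d):
                layer.running_mean = np.asarray(
                    arrays[f"layer{li}.running_mean"], dtype=DTYPE
                ).copy()
                layer.running_var = np.asarray(
                    arrays[f"layer{li}.running_var"], dtype=DTYPE
                ).copy()

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}
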