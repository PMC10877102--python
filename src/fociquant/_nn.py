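"""Minimal CPU neural-network primitives (float32, NCHW layout).

Exactly the layers a Ronneberger-style U-net needs: padded 3×3 and 1×1
convolutions (im2col + BLAS matmul), batch normalization, ReLU, 2×2 max
pooling, 2× nearest-neighbor upsampling, channel concatenation, sigmoid,
and an Adam optimizer.  Each layer exposes ``forward(x, train)`` and
``backward(grad)``; parameter gradients accumulate in ``layer.grads``.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    """Base: stateless unless it declares params/grads."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) → (N, C*9, H*W) patches of the zero-padded 3×3 neighborhood."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 3, 3, h, w), dtype=x.dtype)
    for i in range(3):
        for j in range(3):
            cols[:, :, i, j] = xp[:, :, i : i + h, j : j + w]
    return cols.reshape(n, c * 9, h * w)


def _col2im3(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    n, c, h, w = shape
    d = dcols.reshape(n, c, 3, 3, h, w)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class Conv2d(Layer):
    """Size-preserving convolution (3×3 pad 1, or 1×1), He-normal init."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        assert kernel in (1, 3)
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel * kernel
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(F32),
            "b": np.zeros(c_out, dtype=F32),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x) if self.kernel == 3 else x.reshape(n, c, h * w)
        out = np.matmul(self.params["W"][None], cols)  # (N, c_out, HW)
        out += self.params["b"][None, :, None]
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, self.c_out, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        g = grad.reshape(n, self.c_out, h * w)
        self.grads["W"] += np.einsum("nof,nkf->ok", g, cols, optimize=True)
        self.grads["b"] += g.sum(axis=(0, 2))
        dcols = np.matmul(self.params["W"].T[None], g)
        if self.kernel == 3:
            return _col2im3(dcols, x_shape)
        return dcols.reshape(x_shape)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c, dtype=F32), "beta": np.zeros(c, dtype=F32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.grads["gamma"] += np.sum(grad * xhat, axis=(0, 2, 3))
        self.grads["beta"] += grad.sum(axis=(0, 2, 3))
        gxhat = grad * self.params["gamma"][None, :, None, None]
        # standard batch-norm backward through the batch statistics
        t1 = gxhat - gxhat.mean(axis=(0, 2, 3), keepdims=True)
        t2 = xhat * np.mean(gxhat * xhat, axis=(0, 2, 3), keepdims=True)
        return (t1 - t2) * inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class Adam:
    """Adam over a flat list of (layer, param-name) slots."""

    def __init__(self, layers: list[Layer], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots = [(lay, name) for lay in layers for name in lay.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(lay.params[name]) for lay, name in self.slots]
        self.v = [np.zeros_like(lay.params[name]) for lay, name in self.slots]
        self.t = 0

    def zero_grad(self) -> None:
        for lay, name in self.slots:
            lay.grads[name][...] = 0

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1**self.t
        bc2 = 1 - self.b2**self.t
        for k, (lay, name) in enumerate(self.slots):
            g = lay.grads[name]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            lay.params[name] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)
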