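"""Dense, convolutional, batch-norm and activation layers with backprop."""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

Param = Tuple[np.ndarray, np.ndarray]  # (value, gradient), updated in place


_FLUSH = 1e-30


def flush_subnormals(a: np.ndarray) -> np.ndarray:
    """Zero magnitudes at the edge of the float32 subnormal range, in place.

    Once training saturates (loss ~ 0) the backward signal decays toward
    zero and its products fall into the subnormal range, which x86 cores
    evaluate in slow microcode; flushing costs one pass and perturbs the
    gradient by less than 1e-30.
    """
    np.multiply(a, np.abs(a) > a.dtype.type(_FLUSH), out=a)
    return a


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over the batch -> (loss, probabilities, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(probs[np.arange(n), labels] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n
    return loss, probs, dlogits


class Layer:
    def params(self) -> List[Param]:
        return []


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = glorot_uniform(rng, (d_out, d_in), d_in, d_out, dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W

    def params(self) -> List[Param]:
        return [(self.W, self.dW), (self.b, self.db)]


class Conv3x3Same(Layer):
    """3x3 convolution, stride 1, zero same-padding, NCHW layout (im2col)."""

    _OFFSETS = [(r, c) for r in range(3) for c in range(3)]

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        fan_in, fan_out = c_in * 9, c_out * 9
        self.W = glorot_uniform(rng, (c_out, c_in * 9), fan_in, fan_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out
        self._col: Optional[np.ndarray] = None
        self._shape: Tuple[int, ...] = ()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        xp = np.zeros((B, C, H + 2, W + 2), dtype=x.dtype)
        xp[:, :, 1:-1, 1:-1] = x
        # im2col in (C, 9, B, P) layout so the convolution is one large gemm
        col = np.empty((C, 9, B, H * W), dtype=x.dtype)
        for k, (r0, c0) in enumerate(self._OFFSETS):
            col[:, k] = (
                xp[:, :, r0 : r0 + H, c0 : c0 + W].transpose(1, 0, 2, 3).reshape(C, B, H * W)
            )
        col = col.reshape(C * 9, B * H * W)
        self._col, self._shape = col, (B, C, H, W)
        out = self.W @ col  # (c_out, B*P)
        out += self.b[:, None]
        return out.reshape(self.c_out, B, H, W).transpose(1, 0, 2, 3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        dflat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(self.c_out, B * H * W)
        flush_subnormals(dflat)
        self.db += dflat.sum(axis=1)
        self.dW += dflat @ self._col.T
        dcol = (self.W.T @ dflat).reshape(C, 9, B, H * W)
        dxp = np.zeros((B, C, H + 2, W + 2), dtype=dout.dtype)
        for k, (r0, c0) in enumerate(self._OFFSETS):
            dxp[:, :, r0 : r0 + H, c0 : c0 + W] += (
                dcol[:, k].reshape(C, B, H, W).transpose(1, 0, 2, 3)
            )
        return dxp[:, :, 1:-1, 1:-1]

    def params(self) -> List[Param]:
        return [(self.W, self.dW), (self.b, self.db)]


class Conv1x1(Layer):
    """1x1 convolution (channel projection for residual skips)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = glorot_uniform(rng, (c_out, c_in), c_in, c_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        self._x = x.reshape(B, C, H * W)
        out = np.matmul(self.W, self._x) + self.b[:, None]
        return out.reshape(B, -1, H, W)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, F, H, W = dout.shape
        dflat = dout.reshape(B, F, H * W)
        self.db += dflat.sum(axis=(0, 2))
        self.dW += np.tensordot(dflat, self._x, axes=([0, 2], [0, 2]))
        dx = np.matmul(self.W.T, dflat)
        return dx.reshape(B, -1, H, W)

    def params(self) -> List[Param]:
        return [(self.W, self.dW), (self.b, self.db)]


class BatchNorm(Layer):
    """Batch normalization over the given reduction axes.

    ``axes=(0, 2, 3)`` with NCHW input is per-channel 2-D batch norm;
    ``axes=(0,)`` with (B, F) input is 1-D feature-wise batch norm.
    Training mode normalizes with biased batch statistics and maintains
    running statistics (momentum 0.1) for evaluation mode.
    """

    def __init__(self, n: int, axes: Tuple[int, ...] = (0,), eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(n, dtype=dtype)
        self.beta = np.zeros(n, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n, dtype=dtype)
        self.running_var = np.ones(n, dtype=dtype)
        self.axes = axes
        self.eps = eps
        self.momentum = 0.1
        self._cache = None

    def _bshape(self, ndim: int):
        # broadcastable parameter shape: size n on the one non-reduced axis
        shape = [1] * ndim
        param_axis = [a for a in range(ndim) if a not in self.axes]
        shape[param_axis[0]] = -1
        return tuple(shape)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        shp = self._bshape(x.ndim)
        if training:
            mu = x.mean(axis=self.axes)
            var = x.var(axis=self.axes)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(shp)) * inv_std.reshape(shp)
        self._cache = (xhat, inv_std, shp, training)
        return self.gamma.reshape(shp) * xhat + self.beta.reshape(shp)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, shp, training = self._cache
        self.dgamma += (dout * xhat).sum(axis=self.axes)
        self.dbeta += dout.sum(axis=self.axes)
        dxhat = dout * self.gamma.reshape(shp)
        if not training:
            return dxhat * inv_std.reshape(shp)
        mean_dxhat = dxhat.mean(axis=self.axes).reshape(shp)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=self.axes).reshape(shp)
        return inv_std.reshape(shp) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)

    def params(self) -> List[Param]:
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._pos = x > 0
        self._expm1 = np.expm1(np.minimum(x, 0))
        return np.where(self._pos, x, self.alpha * self._expm1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        grad = np.where(self._pos, 1.0, self.alpha * (self._expm1 + 1.0))
        return dout * grad.astype(dout.dtype)
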