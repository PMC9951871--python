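"""Minimal CPU layers with explicit forward/backward passes.

Only what the U-Net needs: 2D convolution with optional weight
standardization, Group Normalization, ReLU, 2x2 max pooling and 2x2
stride-2 transposed convolution.  Arrays are ``(N, C, H, W)`` float32.
Each layer caches what its backward pass needs during ``forward``;
``backward`` consumes the cache and accumulates parameter gradients into
``self.grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "GroupNorm",
    "ReLU",
    "MaxPool2x2",
    "ConvTranspose2x2",
    "standardize_kernel",
]

#: epsilon in the weight-standardization denominator.  Kept small so that
#: standardized filters have variance 1 to well below 1e-4 even for
#: low-variance (He-initialized) kernels.
WS_EPS = 1e-7


def standardize_kernel(kernel: np.ndarray, eps: float = WS_EPS) -> np.ndarray:
    """Re-parameterize a convolution kernel to zero mean and unit variance
    per output filter (over the input-channel x spatial extent).

    A constant (zero-variance) filter maps to all zeros thanks to the eps
    guard.  Idempotent up to eps effects.
    """
    k = np.asarray(kernel)
    if k.ndim < 2:
        raise ValueError("kernel must have an output-filter axis plus at least one more")
    flat = k.reshape(k.shape[0], -1)
    if flat.shape[1] < 2:
        # degenerate single-element filters: nothing to standardize
        return k.copy()
    mu = flat.mean(axis=1, keepdims=True)
    var = flat.var(axis=1, keepdims=True)
    out = (flat - mu) / np.sqrt(var + eps)
    return out.reshape(k.shape).astype(k.dtype, copy=False)


class Layer:
    """Base class: parameter dict + gradient dict."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv2d(Layer):
    """Same-padded 2D convolution, He (fan-in, normal) initialized.

    When ``weight_standardize`` is on, the kernel actually convolved is the
    per-filter standardized version of the stored weights; gradients are
    chained through the standardization map.
    """

    def __init__(self, cin, cout, ksize=3, rng=None, weight_standardize=True):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * ksize * ksize
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(cout, cin, ksize, ksize)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.ksize = ksize
        self.pad = (ksize - 1) // 2
        self.weight_standardize = weight_standardize and fan_in >= 2
        self.zero_grad()

    def _effective_weight(self):
        W = self.params["W"]
        if not self.weight_standardize:
            return W, None, None
        flat = W.reshape(W.shape[0], -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        sigma = np.sqrt(var + WS_EPS)
        What = ((flat - mu) / sigma).reshape(W.shape)
        return What, What.reshape(W.shape[0], -1), sigma

    def forward(self, x):
        n, cin, h, w = x.shape
        p, k = self.pad, self.ksize
        What, _, sigma = self._effective_weight()
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, Cin, H, W, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, cin * k * k)
        Wm = What.reshape(What.shape[0], -1)
        y = cols @ Wm.T + self.params["b"]
        self._cache = (cols, Wm, sigma, x.shape)
        return np.ascontiguousarray(y.transpose(0, 2, 1).reshape(n, -1, h, w))

    def backward(self, gy):
        cols, Wm, sigma, xshape = self._cache
        n, cin, h, w = xshape
        k, p = self.ksize, self.pad
        cout = Wm.shape[0]
        gym = gy.reshape(n, cout, h * w).transpose(0, 2, 1)  # (N, HW, Cout)
        dWhat = np.einsum("npo,npi->oi", gym, cols, optimize=True)
        if self.weight_standardize:
            What = Wm
            m = What.shape[1]
            dW = (dWhat - dWhat.mean(axis=1, keepdims=True)
                  - What * (dWhat * What).mean(axis=1, keepdims=True)) / sigma
        else:
            dW = dWhat
        self.grads["W"] += dW.reshape(self.params["W"].shape)
        self.grads["b"] += gy.sum(axis=(0, 2, 3))
        gcols = gym @ Wm  # (N, HW, Cin*k*k)
        g6 = gcols.reshape(n, h, w, cin, k, k).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros((n, cin, h + 2 * p, w + 2 * p), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + h, j : j + w] += g6[:, :, :, :, i, j]
        return gxp[:, :, p : p + h, p : p + w]


class GroupNorm(Layer):
    """Group Normalization over (channels/groups x H x W) per sample."""

    def __init__(self, channels, groups, eps=1e-5):
        super().__init__()
        if channels % groups != 0:
            raise ValueError(f"groups {groups} must divide channels {channels}")
        self.groups = groups
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.zero_grad()

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(n, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        sigma = np.sqrt(xg.var(axis=2, keepdims=True) + self.eps)
        xhat = ((xg - mu) / sigma).reshape(n, c, h, w)
        self._cache = (xhat, sigma, x.shape)
        return xhat * self.params["gamma"][:, None, None] + self.params["beta"][:, None, None]

    def backward(self, gy):
        xhat, sigma, xshape = self._cache
        n, c, h, w = xshape
        g = self.groups
        self.grads["gamma"] += (gy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] += gy.sum(axis=(0, 2, 3))
        dxhat = (gy * self.params["gamma"][:, None, None]).reshape(n, g, -1)
        xh = xhat.reshape(n, g, -1)
        dx = (dxhat - dxhat.mean(axis=2, keepdims=True)
              - xh * (dxhat * xh).mean(axis=2, keepdims=True)) / sigma
        return dx.reshape(xshape)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gy):
        return np.where(self._mask, gy, 0)


class MaxPool2x2(Layer):
    def forward(self, x):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pool requires even spatial dims, got {x.shape}")
        xw = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._argmax = xw.argmax(axis=4)
        self._xshape = x.shape
        return np.take_along_axis(xw, self._argmax[..., None], axis=4)[..., 0]

    def backward(self, gy):
        n, c, h, w = self._xshape
        gw = np.zeros((n, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(gw, self._argmax[..., None], gy[..., None], axis=4)
        return gw.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )


class ConvTranspose2x2(Layer):
    """2x2, stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, cin, cout, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = cin * 4
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(cin, cout, 2, 2)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.zero_grad()

    def forward(self, x):
        n, cin, h, w = x.shape
        W = self.params["W"]
        y = np.einsum("nchw,cokl->nohkwl", x, W, optimize=True)
        y = y.reshape(n, W.shape[1], 2 * h, 2 * w) + self.params["b"][:, None, None]
        self._x = x
        return y

    def backward(self, gy):
        x = self._x
        n, cin, h, w = x.shape
        cout = self.params["W"].shape[1]
        g6 = gy.reshape(n, cout, h, 2, w, 2)
        self.grads["W"] += np.einsum("nchw,nohkwl->cokl", x, g6, optimize=True)
        self.grads["b"] += gy.sum(axis=(0, 2, 3))
        return np.einsum("nohkwl,cokl->nchw", g6, self.params["W"], optimize=True)
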