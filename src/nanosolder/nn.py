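"""Minimal numpy building blocks for the upscaling network.

Implements exactly what the small fully convolutional upscaler needs —
3x3 'same' convolutions via im2col/BLAS, PReLU with one learnable slope per
layer, nearest-neighbor x2 upsampling, the Adam optimizer and a
differentiable structural-similarity (SSIM) loss — with analytic gradients
throughout. The SSIM computation matches ``skimage.metrics
.structural_similarity`` with a uniform 7x7 window and sample covariance,
evaluated on fully interior windows.

Feature maps are channels-last, (batch, height, width, channels), which
keeps the im2col gather contiguous per pixel; kernels are stored flattened
as (kh*kw*in_channels, out_channels). Layers run in float32 by default
(pass ``dtype=np.float64`` for e.g. finite-difference checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "PReLU",
    "UpsampleNearest2x",
    "Adam",
    "ssim_loss_and_grad",
]


class Conv2D:
    """3x3 (or any odd-size) convolution with 'same' zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        k = kernel_size
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init, suits the PReLU activations
        self.weight = rng.normal(0.0, scale, size=(k * k * in_channels, out_channels)).astype(dtype)
        self.bias = np.zeros(out_channels, dtype=dtype)
        self.kernel_size = k
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache = None

    @property
    def params(self):
        return [self.weight, self.bias]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        k = self.kernel_size
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (n, h, w, c, k, k) -> (n*h*w, k*k*c); per-pixel gather is c-contiguous
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
        return np.ascontiguousarray(cols)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        cols = self._im2col(x)
        y = cols @ self.weight + self.bias
        self._cache = (x.shape, cols)
        return y.reshape(n, h, w, self.out_channels)

    def backward(self, dy: np.ndarray):
        (n, h, w, c), cols = self._cache
        k = self.kernel_size
        dyf = dy.reshape(n * h * w, self.out_channels)
        self.dweight = cols.T @ dyf
        self.dbias = dyf.sum(axis=0)
        # input gradient = correlation of dy with spatially flipped kernels,
        # in/out channels swapped (transpose of the forward linear map)
        w4 = self.weight.reshape(k, k, self.in_channels, self.out_channels)
        wrot = np.ascontiguousarray(
            w4[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * self.out_channels, self.in_channels)
        )
        dycols = self._im2col(dy)
        return (dycols @ wrot).reshape(n, h, w, self.in_channels)

    @property
    def grads(self):
        return [self.dweight, self.dbias]


class PReLU:
    """Parametric ReLU with a single learnable negative slope (init 0.25)."""

    def __init__(self, init_slope: float = 0.25, dtype=np.float32):
        self.alpha = np.array(init_slope, dtype=dtype)
        self._cache = None

    @property
    def params(self):
        return [self.alpha]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x
        return np.where(x > 0, x, self.alpha * x)

    def backward(self, dy: np.ndarray):
        x = self._cache
        neg = x <= 0
        self.dalpha = np.asarray((dy * np.where(neg, x, 0)).sum(), dtype=self.alpha.dtype)
        return dy * np.where(neg, self.alpha, np.asarray(1.0, dtype=self.alpha.dtype))

    @property
    def grads(self):
        return [self.dalpha]


class UpsampleNearest2x:
    """Nearest-neighbor x2 spatial upsampling."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray):
        n, h2, w2, c = dy.shape
        return dy.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class Adam:
    """Standard Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= np.asarray(self.lr * mhat / (np.sqrt(vhat) + self.eps), dtype=p.dtype)


def _box_valid(x: np.ndarray, k: int) -> np.ndarray:
    """Sums over all fully interior k x k windows of the last two axes."""
    c = np.cumsum(np.cumsum(x, axis=-2), axis=-1)
    c = np.pad(c, [(0, 0)] * (x.ndim - 2) + [(1, 0), (1, 0)])
    return c[..., k:, k:] - c[..., :-k, k:] - c[..., k:, :-k] + c[..., :-k, :-k]


def _box_spread(g: np.ndarray, k: int) -> np.ndarray:
    """Adjoint of :func:`_box_valid`: scatter window values back onto pixels."""
    pad = [(0, 0)] * (g.ndim - 2) + [(k - 1, k - 1), (k - 1, k - 1)]
    return _box_valid(np.pad(g, pad), k)


def ssim_loss_and_grad(
    pred: np.ndarray,
    target: np.ndarray,
    win_size: int = 7,
    data_range: float = 1.0,
    k1: float = 0.01,
    k2: float = 0.03,
) -> tuple[float, np.ndarray]:
    """Mean SSIM over interior windows and its gradient w.r.t. ``pred``.

    Returns ``(loss, dloss/dpred)`` with ``loss = 1 - mean(SSIM)``; inputs
    are (n, h, w) image batches on a common intensity scale. Computed in
    float64 internally for a well-conditioned gradient.
    """
    x = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    k = win_size
    nw = k * k
    cov_norm = nw / (nw - 1)  # sample covariance, as skimage uses
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2

    ux = _box_valid(x, k) / nw
    uy = _box_valid(y, k) / nw
    uxx = _box_valid(x * x, k) / nw
    uyy = _box_valid(y * y, k) / nw
    uxy = _box_valid(x * y, k) / nw
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)

    a1 = 2.0 * ux * uy + c1
    a2 = 2.0 * vxy + c2
    b1 = ux * ux + uy * uy + c1
    b2 = vx + vy + c2
    d = b1 * b2
    s = (a1 * a2) / d
    n_windows = s.size
    loss = 1.0 - float(s.mean())

    # dS/d(ux, uxx, uxy), treating the uy-side statistics as constants
    g_ux = (2.0 * uy * a2) / d - s * (2.0 * ux) / b1 \
        + (2.0 * a1 / d) * (-cov_norm * uy) + (s / b2) * (2.0 * cov_norm * ux)
    g_uxx = -(s / b2) * cov_norm
    g_uxy = (2.0 * a1 / d) * cov_norm

    scale = -1.0 / (n_windows * nw)  # mean over windows, box filter 1/nw, loss = 1 - mean
    dx = scale * (
        _box_spread(g_ux, k)
        + 2.0 * x * _box_spread(g_uxx, k)
        + y * _box_spread(g_uxy, k)
    )
    return loss, dx.astype(np.asarray(pred).dtype, copy=False)
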