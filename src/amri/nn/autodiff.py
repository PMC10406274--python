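"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the residual denoising CNN and
its composite loss on a CPU: elementwise arithmetic, reductions, stride-1 2D
convolution (im2col + matmul), 2x2 max/average pooling, nearest-neighbour
upsampling, and a fused Fourier-crop RMS node for the k-space
data-consistency loss term.  Tensors keep whatever float dtype they are
given (float32 for training speed; float64 in gradient-check tests).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "relu",
    "absolute",
    "mean",
    "tsum",
    "power",
    "conv2d",
    "maxpool2",
    "avgpool2",
    "upsample2",
    "fourier_crop_rms",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, lambda a, b: a + b,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, lambda a, b: a * b,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, lambda a, b: a - b,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _as_tensor(other, like=self) - self

    def __truediv__(self, other):
        return _binary(self, other, lambda a, b: a / b,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return _as_tensor(other, like=self) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p):
        return power(self, p)


def _as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    # python scalars adopt the partner tensor's dtype to avoid float64 creep
    if like is not None and np.isscalar(x):
        return Tensor(np.asarray(x, dtype=like.data.dtype))
    return Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _binary(a, b, fwd, bwd_a, bwd_b) -> Tensor:
    if isinstance(a, Tensor):
        a, b = a, _as_tensor(b, like=a)
    else:
        b = _as_tensor(b)
        a = _as_tensor(a, like=b)
    data = fwd(a.data, b.data)

    def backward(g):
        a._accumulate(_unbroadcast(bwd_a(g, a.data, b.data), a.data.shape))
        b._accumulate(_unbroadcast(bwd_b(g, a.data, b.data), b.data.shape))

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    pos = x.data > 0

    def backward(g):
        x._accumulate(g * pos)

    return _make(np.maximum(x.data, 0), (x,), backward)


def absolute(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    sign = np.sign(x.data)

    def backward(g):
        x._accumulate(g * sign)

    return _make(np.abs(x.data), (x,), backward)


def power(x: Tensor, p: float) -> Tensor:
    """Elementwise ``x**p`` for scalar ``p`` (positive base expected)."""
    x = _as_tensor(x)
    data = x.data**p

    def backward(g):
        x._accumulate(g * p * x.data ** (p - 1.0))

    return _make(data, (x,), backward)


def mean(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size

    def backward(g):
        x._accumulate(np.full_like(x.data, float(g) / n))

    return _make(np.asarray(x.data.mean()), (x,), backward)


def tsum(x: Tensor) -> Tensor:
    x = _as_tensor(x)

    def backward(g):
        x._accumulate(np.full_like(x.data, float(g)))

    return _make(np.asarray(x.data.sum()), (x,), backward)


# -- convolution ------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, ph: int, pw: int) -> np.ndarray:
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    n, c, ho, wo = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw), n, ho, wo


def _corr(x: np.ndarray, w: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Stride-1 cross-correlation of (N,C,H,W) with (F,C,kh,kw)."""
    cols, n, ho, wo = _im2col(x, w.shape[2], w.shape[3], ph, pw)
    out = cols @ w.reshape(w.shape[0], -1).T
    return np.ascontiguousarray(out.reshape(n, ho, wo, w.shape[0]).transpose(0, 3, 1, 2))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: str = "same") -> Tensor:
    """Stride-1 2D convolution (cross-correlation), 'same' or 'valid' padding.

    Kernels have odd height/width (rectangular allowed, e.g. separable 1 x k
    passes).  The im2col column matrix is cached for the weight-gradient
    pass when the kernel is trainable.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    kh, kw = w.data.shape[2], w.data.shape[3]
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel height/width must be odd")
    ph, pw = ((kh - 1) // 2, (kw - 1) // 2) if pad == "same" else (0, 0)
    cols, n, ho, wo = _im2col(x.data, kh, kw, ph, pw)
    out = cols @ w.data.reshape(w.data.shape[0], -1).T
    data = np.ascontiguousarray(
        out.reshape(n, ho, wo, w.data.shape[0]).transpose(0, 3, 1, 2)
    )
    if not w.requires_grad:
        cols = None  # free the column buffer when no weight gradient is needed
    if b is not None:
        b = _as_tensor(b)
        data = data + b.data.reshape(1, -1, 1, 1)

    def backward(g):
        g = np.ascontiguousarray(g)
        if x.requires_grad or x._parents:
            # dx: full correlation of g with channel-transposed, rotated kernels
            w_rot = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            x._accumulate(_corr(g, w_rot, kh - 1 - ph, kw - 1 - pw))
        if w.requires_grad:
            gw = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, -1)
            w._accumulate((gw.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2 (even spatial dims required); ties split."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    m = xr.max(axis=(3, 5), keepdims=True)
    hits = (xr == m)
    frac = (hits / hits.sum(axis=(3, 5), keepdims=True)).astype(x.data.dtype)

    def backward(g):
        gr = g.reshape(n, c, h // 2, 1, w // 2, 1)
        x._accumulate((gr * frac).reshape(n, c, h, w))

    return _make(m.reshape(n, c, h // 2, w // 2), (x,), backward)


def avgpool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2 (even spatial dims required)."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avgpool2 requires even spatial dimensions")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)

    def backward(g):
        gr = (g * 0.25).reshape(n, c, h // 2, 1, w // 2, 1)
        x._accumulate(np.broadcast_to(gr, (n, c, h // 2, 2, w // 2, 2))
                      .reshape(n, c, h, w).copy())

    return _make(xr.mean(axis=(3, 5)), (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(data, (x,), backward)


def fourier_crop_rms(pred: Tensor, true: Tensor, kmask: int) -> Tensor:
    """Batch mean of the RMS magnitude of the spectral residual inside the
    central ``kmask x kmask`` k-space crop.

    For each item: ``D = F(pred) - F(true)`` with the DFT normalised by the
    patch area (so spectral coefficients are on the image intensity scale
    and the term is stable across patch sizes), value
    ``sqrt(mean_{central crop} |D|^2)``; the batch mean is returned.
    Gradient is analytic (verified against finite differences in tests).
    """
    pred, true = _as_tensor(pred), _as_tensor(true)
    n, c, h, w = pred.data.shape
    if c != 1:
        raise ValueError("single-channel patches expected")
    if kmask > min(h, w):
        raise ValueError("kmask exceeds patch size")
    # centred mask, stored in unshifted DFT coordinates
    mask_s = np.zeros((h, w))
    r0, c0 = h // 2 - kmask // 2, w // 2 - kmask // 2
    mask_s[r0 : r0 + kmask, c0 : c0 + kmask] = 1.0
    mask = np.fft.ifftshift(mask_s)
    kcount = kmask * kmask

    area = h * w
    diff = pred.data[:, 0] - true.data[:, 0]
    D = np.fft.fft2(diff) * mask / area
    per_item = np.sqrt((np.abs(D) ** 2).sum(axis=(1, 2)) / kcount)
    value = per_item.mean()

    def backward(g):
        # d value / d pred = (1/n) * Re(F^H(M .* D)) / (area * kcount * L_i)
        safe = np.where(per_item > 0, per_item, 1.0)
        grad_items = np.real(np.fft.ifft2(D)) / (kcount * safe[:, None, None])
        grad_items = np.where(per_item[:, None, None] > 0, grad_items, 0.0)
        gp = (float(g) / n) * grad_items[:, None, :, :]
        pred._accumulate(gp.astype(pred.data.dtype))
        if true.requires_grad:
            true._accumulate(-gp.astype(true.data.dtype))

    return _make(np.asarray(value, dtype=pred.data.dtype), (pred, true), backward)
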