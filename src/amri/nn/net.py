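"""Residual denoising network and the Adam optimizer.

The network is single-channel in/out and fully convolutional: a chain of
ResBlocks (two ReLU-activated 3x3 convolutions plus a skip connection that
becomes a ReLU-activated 1x1 projection when the filter count changes), 2x2
max-pooling after one third and two thirds of the blocks with matching
nearest-neighbour upsamplings before the output stage, a global identity
skip adding the input to the pre-final feature map, and a final ReLU 3x3
single-filter convolution.  All spatial dims must be multiples of 4.
"""

from __future__ import annotations

import math

import numpy as np

from .autodiff import Tensor, conv2d, maxpool2, relu, upsample2

__all__ = ["Conv2D", "ResBlock", "DenoiserNet", "Adam"]


class Conv2D:
    """ReLU-activated stride-1 convolution layer with He-normal init."""

    def __init__(self, n_in: int, n_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = math.sqrt(2.0 / (n_in * kernel * kernel))
        self.w = Tensor(rng.normal(0.0, std, (n_out, n_in, kernel, kernel)).astype(dtype),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(conv2d(x, self.w, self.b, pad="same"))

    @property
    def params(self):
        return [self.w, self.b]


class ResBlock:
    """Two ReLU 3x3 convolutions with an (optionally projected) skip."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.conv1 = Conv2D(n_in, n_out, 3, rng)
        self.conv2 = Conv2D(n_out, n_out, 3, rng)
        self.proj = Conv2D(n_in, n_out, 1, rng) if n_in != n_out else None

    def __call__(self, x: Tensor, record=None) -> Tensor:
        h = self.conv1(x)
        if record is not None:
            record.append(h)
        h = self.conv2(h)
        if record is not None:
            record.append(h)
        skip = x if self.proj is None else self.proj(x)
        if self.proj is not None and record is not None:
            record.append(skip)
        return h + skip

    @property
    def params(self):
        p = self.conv1.params + self.conv2.params
        if self.proj is not None:
            p += self.proj.params
        return p


class DenoiserNet:
    """The residual patch denoiser.

    ``filters`` gives the output filter count of each ResBlock (length must
    equal ``n_resblocks``).  Pooling follows blocks ``ceil(n/3)`` and
    ``ceil(2n/3)``; two upsamplings precede the global skip and final layer.
    """

    def __init__(self, n_resblocks: int = 13, filters=None, seed: int = 0):
        if filters is None:
            filters = default_filter_schedule(n_resblocks)
        if len(filters) != n_resblocks:
            raise ValueError(
                f"filter schedule length {len(filters)} != n_resblocks {n_resblocks}"
            )
        self.n_resblocks = n_resblocks
        self.filters = list(filters)
        self.seed = seed
        self.pool_after = {math.ceil(n_resblocks / 3), math.ceil(2 * n_resblocks / 3)}
        rng = np.random.default_rng(seed)
        self.blocks = []
        n_in = 1
        for f in self.filters:
            self.blocks.append(ResBlock(n_in, f, rng))
            n_in = f
        self.final = Conv2D(n_in, 1, 3, rng)

    # -- forward -----------------------------------------------------------
    def forward(self, x: Tensor, record: list | None = None) -> Tensor:
        h = x
        for i, block in enumerate(self.blocks, start=1):
            h = block(h, record=record)
            if i in self.pool_after:
                h = maxpool2(h)
        h = upsample2(upsample2(h))
        h = h + x  # global identity skip (broadcast over channels)
        out = self.final(h)
        if record is not None:
            record.append(out)
        return out

    __call__ = forward

    def predict_patches(self, patches: np.ndarray) -> np.ndarray:
        """Forward pass on a (n, 64, 64)-style stack, no gradient bookkeeping."""
        x = Tensor(np.asarray(patches, dtype=np.float32)[:, None, :, :])
        return self.forward(x).data[:, 0]

    # -- bookkeeping -------------------------------------------------------
    @property
    def params(self):
        p = []
        for b in self.blocks:
            p += b.params
        return p + self.final.params

    def n_conv_layers(self) -> int:
        return sum(2 + (b.proj is not None) for b in self.blocks) + 1

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params)

    def state_dict(self) -> dict:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.params)}

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params):
            src = state[f"p{i}"]
            if src.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = src.astype(p.data.dtype).copy()


def default_filter_schedule(n_resblocks: int, base: int = 64, mid: int = 128) -> list[int]:
    """``base`` filters everywhere except ``mid`` between the two pooling stages."""
    lo, hi = math.ceil(n_resblocks / 3), math.ceil(2 * n_resblocks / 3)
    return [mid if lo < i <= hi else base for i in range(1, n_resblocks + 1)]


class Adam:
    """Adaptive-moment-estimation optimizer."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
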