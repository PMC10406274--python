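"""Contrast- and subject-specific residual CNN denoising.

Training minimises the composite loss

    Mix-L       = alpha * (1 - MS-SSIM) + (1 - alpha) * L1,   alpha = 0.84
    Mix-L+FTD   = Mix-L + beta * FTD

where FTD (Fourier-transform data consistency) is the RMS magnitude of the
spectral residual between prediction and target restricted to the central
16 x 16 k-space crop -- it anchors the low-frequency content that carries
most MR image energy while the image-domain terms clean up the rest.
MS-SSIM inside the loss uses 3 scales (the most that fit a 64 x 64 patch)
with renormalised canonical weights.

Subject-specific (SS) fine-tuning follows the noisy-as-clean idea: the
baseline model is briefly re-trained on pairs (subject's noisiest
acquisition + scaled native noise -> that same acquisition) at a reduced
learning rate, adapting the filters to the subject's own noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .metrics import MSSSIM_WEIGHTS
from .noise import NoiseModel, corrupt_volume
from .volume import Volume, central_slab

__all__ = [
    "BASELINE_LR",
    "SS_LR",
    "DenoiserConfig",
    "LossBreakdown",
    "build_model",
    "mix_l",
    "ftd_term",
    "mix_l_ftd",
    "sample_patches",
    "train",
    "finetune_subject",
    "denoise_volume",
]

#: Initial Adam learning rates per contrast (baseline training).
BASELINE_LR = {"T1": 2.5e-4, "T2": 1e-4, "T2FLAIR": 1e-4, "T2STAR": 2.5e-4, "DWI": 1e-4}

#: Reduced learning rates for subject-specific fine-tuning (``None``: the SS
#: stage is not applicable for that contrast).  T1 lists both documented
#: settings; the first is the default.
SS_LR = {"T1": (1e-5, 1e-6), "T2": (1e-5,), "T2FLAIR": (1e-4,), "T2STAR": None,
         "DWI": (1e-5,)}


@dataclass
class DenoiserConfig:
    """Architecture, loss, and training hyperparameters."""

    patch: int = 64
    n_resblocks: int = 13
    filters: list | None = None
    alpha: float = 0.84
    beta: float = 1.0
    kmask: int = 16
    epochs: int = 100
    batch: int = 256
    lr_baseline: dict = field(default_factory=lambda: dict(BASELINE_LR))
    lr_ss: dict = field(default_factory=lambda: dict(SS_LR))
    data_range: float = 1.0
    ft_epochs: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.patch < 16 or self.patch & (self.patch - 1):
            raise ValueError("patch must be a power of two >= 16")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.kmask > self.patch:
            raise ValueError("kmask must not exceed the patch size")
        if self.filters is not None and len(self.filters) != self.n_resblocks:
            raise ValueError("filter schedule length must equal n_resblocks")

    def loss_scales(self) -> int:
        """MS-SSIM scale count that fits the patch (11-pixel window)."""
        s = 1
        while s < 5 and self.patch // (2**s) >= 11:
            s += 1
        return min(s, 3)


@dataclass
class LossBreakdown:
    mix_l: float
    ftd: float
    alpha: float
    beta: float

    @property
    def total(self) -> float:
        return self.mix_l + self.beta * self.ftd


def build_model(cfg: DenoiserConfig) -> nn.DenoiserNet:
    """Instantiate the residual denoiser with seeded deterministic init."""
    return nn.DenoiserNet(n_resblocks=cfg.n_resblocks, filters=cfg.filters, seed=cfg.seed)


# ---------------------------------------------------------------------------
# differentiable loss graph

def _gauss_kernels_1d(dtype, size: int = 11, sigma: float = 1.5):
    """Separable row/column Gaussian kernels (two 1-D passes == 11x11 window)."""
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    g /= g.sum()
    return (nn.Tensor(g.reshape(1, 1, size, 1).astype(dtype)),
            nn.Tensor(g.reshape(1, 1, 1, size).astype(dtype)))


def _msssim_graph(pred: nn.Tensor, true: nn.Tensor, scales: int,
                  data_range: float) -> nn.Tensor:
    """Differentiable MS-SSIM of (N,1,H,W) tensors (same conventions as
    :func:`amri.metrics.ms_ssim`, valid Gaussian window)."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    krow, kcol = _gauss_kernels_1d(pred.data.dtype)

    def smooth(t):
        return nn.conv2d(nn.conv2d(t, krow, pad="valid"), kcol, pad="valid")

    weights = np.asarray(MSSSIM_WEIGHTS[:scales])
    weights = weights / weights.sum()
    eps = 1e-8
    value = None
    x, y = pred, true
    for s in range(scales):
        mu_x = smooth(x)
        mu_y = smooth(y)
        sxx = smooth(x * x) - mu_x * mu_x
        syy = smooth(y * y) - mu_y * mu_y
        sxy = smooth(x * y) - mu_x * mu_y
        cs = (2.0 * sxy + c2) / (sxx + syy + c2)
        if s == scales - 1:
            lum = (2.0 * mu_x * mu_y + c1) / (mu_x * mu_x + mu_y * mu_y + c1)
            comp = nn.mean(lum * cs)
        else:
            comp = nn.mean(cs)
            x, y = nn.avgpool2(x), nn.avgpool2(y)
        term = nn.power(nn.relu(comp) + eps, float(weights[s]))
        value = term if value is None else value * term
    return value


def _as_batch(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim == 2:
        a = a[None]
    if a.ndim == 3:
        a = a[:, None]
    return a


def _mix_l_graph(true_t: nn.Tensor, pred_t: nn.Tensor, alpha: float, scales: int,
                 data_range: float) -> nn.Tensor:
    msssim = _msssim_graph(pred_t, true_t, scales, data_range)
    l1 = nn.mean(nn.absolute(pred_t - true_t))
    return alpha * (1.0 - msssim) + (1.0 - alpha) * l1


def mix_l(y_true: np.ndarray, y_pred: np.ndarray, alpha: float = 0.84,
          scales: int = 3, data_range: float = 1.0) -> float:
    """``alpha * (1 - MS-SSIM) + (1 - alpha) * L1`` on a patch (or batch)."""
    t = nn.Tensor(_as_batch(np.asarray(y_true, dtype=np.float64)))
    p = nn.Tensor(_as_batch(np.asarray(y_pred, dtype=np.float64)))
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {p.shape}")
    return _mix_l_graph(t, p, alpha, scales, data_range).item()


def ftd_term(y_true: np.ndarray, y_pred: np.ndarray, kmask: int = 16) -> float:
    """RMS spectral residual magnitude over the central k-space crop."""
    t = nn.Tensor(_as_batch(np.asarray(y_true, dtype=np.float64)))
    p = nn.Tensor(_as_batch(np.asarray(y_pred, dtype=np.float64)))
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {p.shape}")
    return nn.fourier_crop_rms(p, t, kmask).item()


def mix_l_ftd(y_true: np.ndarray, y_pred: np.ndarray,
              cfg: DenoiserConfig) -> LossBreakdown:
    """Full composite loss with its breakdown."""
    scales = cfg.loss_scales()
    return LossBreakdown(
        mix_l=mix_l(y_true, y_pred, alpha=cfg.alpha, scales=scales,
                    data_range=cfg.data_range),
        ftd=ftd_term(y_true, y_pred, kmask=cfg.kmask),
        alpha=cfg.alpha,
        beta=cfg.beta,
    )


def _loss_graph(pred_t: nn.Tensor, true_t: nn.Tensor, cfg: DenoiserConfig) -> nn.Tensor:
    total = _mix_l_graph(true_t, pred_t, cfg.alpha, cfg.loss_scales(), cfg.data_range)
    if cfg.beta > 0:
        total = total + cfg.beta * nn.fourier_crop_rms(pred_t, true_t, cfg.kmask)
    return total


# ---------------------------------------------------------------------------
# patch sampling / training

def sample_patches(noisy_slices, clean_slices, n: int, seed: int, patch: int = 64,
                   bounds: tuple[int, int, int, int] | None = None):
    """``n`` paired (noisy, clean) square patches at identical coordinates.

    ``bounds = (r0, r1, c0, c1)`` restricts patches to lie inside the given
    half-open rectangle of every slice (the per-dataset crop bounds that keep
    random crops on anatomy); default is the full slice.
    """
    if len(noisy_slices) != len(clean_slices) or not noisy_slices:
        raise ValueError("need equal, non-empty noisy/clean slice lists")
    rng = np.random.default_rng(seed)
    noisy_out = np.empty((n, patch, patch), dtype=np.float32)
    clean_out = np.empty((n, patch, patch), dtype=np.float32)
    for i in range(n):
        j = int(rng.integers(len(noisy_slices)))
        ns, cs = np.asarray(noisy_slices[j]), np.asarray(clean_slices[j])
        if ns.shape != cs.shape:
            raise ValueError(f"slice {j}: noisy/clean shape mismatch")
        h, w = ns.shape
        r0, r1, c0, c1 = bounds if bounds is not None else (0, h, 0, w)
        if min(h, w) < patch or r1 - r0 < patch or c1 - c0 < patch:
            raise ValueError(f"slice {j} ({h}x{w}) cannot fit a {patch}-pixel patch")
        r = int(rng.integers(r0, r1 - patch + 1))
        c = int(rng.integers(c0, c1 - patch + 1))
        noisy_out[i] = ns[r : r + patch, c : c + patch]
        clean_out[i] = cs[r : r + patch, c : c + patch]
    return noisy_out, clean_out


def _eval_loss(model: nn.DenoiserNet, noisy: np.ndarray, clean: np.ndarray,
               cfg: DenoiserConfig, chunk: int = 128) -> float:
    losses, weights = [], []
    for k in range(0, len(noisy), chunk):
        p = nn.Tensor(noisy[k : k + chunk, None])
        t = nn.Tensor(clean[k : k + chunk, None])
        losses.append(_loss_graph(model(p), t, cfg).item())
        weights.append(len(noisy[k : k + chunk]))
    return float(np.average(losses, weights=weights))


def train(model: nn.DenoiserNet, train_pairs, val_pairs, cfg: DenoiserConfig,
          lr: float | None = None, verbose: bool = False):
    """Adam training with per-epoch validation; returns the best snapshot.

    ``train_pairs``/``val_pairs`` are ``(noisy, clean)`` stacks of shape
    (n, patch, patch).  The model state with the lowest validation
    Mix-L+FTD is restored before returning; ``history`` records per-epoch
    train and validation losses.  Data order and everything else stochastic
    derive from ``cfg.seed``.
    """
    noisy_tr, clean_tr = (np.asarray(a, dtype=np.float32) for a in train_pairs)
    noisy_va, clean_va = (np.asarray(a, dtype=np.float32) for a in val_pairs)
    if not len(noisy_tr) or not len(noisy_va):
        raise ValueError("empty train or validation set")
    history = {"train": [], "val": []}
    if cfg.epochs == 0:
        return model, history
    if lr is None:
        lr = 1e-4
    opt = nn.Adam(model.params, lr=lr)
    rng = np.random.default_rng(cfg.seed + 1)
    best_state, best_val = None, np.inf
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(noisy_tr))
        epoch_losses = []
        for k in range(0, len(order), cfg.batch):
            idx = order[k : k + cfg.batch]
            pred = model(nn.Tensor(noisy_tr[idx][:, None]))
            loss = _loss_graph(pred, nn.Tensor(clean_tr[idx][:, None]), cfg)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        val_loss = _eval_loss(model, noisy_va, clean_va, cfg)
        history["train"].append(float(np.mean(epoch_losses)))
        history["val"].append(val_loss)
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: "
                  f"train {history['train'][-1]:.4f} val {val_loss:.4f}")
        if val_loss < best_val:
            best_val, best_state = val_loss, model.state_dict()
    model.load_state_dict(best_state)
    return model, history


def finetune_subject(base: nn.DenoiserNet, subject_noisiest: Volume,
                     model: NoiseModel, lr: float, cfg: DenoiserConfig,
                     n_patches: int = 512, slab_fraction: float = 0.5):
    """Noisy-as-clean subject-specific fine-tuning.

    The subject's noisiest acquisition, further corrupted with its own
    scaled native noise, is the input; the acquisition itself is the target.
    A short re-training (``cfg.ft_epochs``) at the reduced rate ``lr``
    returns the SS model (the base model is not modified).
    """
    target = central_slab(subject_noisiest, slab_fraction)
    noisy = central_slab(corrupt_volume(subject_noisiest, model, seed=cfg.seed + 7),
                        slab_fraction)
    noisy_slices = [noisy.data[:, :, k] for k in range(noisy.n_slices)]
    clean_slices = [target.data[:, :, k] for k in range(target.n_slices)]
    pn, pc = sample_patches(noisy_slices, clean_slices, n_patches, seed=cfg.seed + 11,
                            patch=cfg.patch)
    n_val = max(1, n_patches // 10)
    ss = nn.DenoiserNet(n_resblocks=base.n_resblocks, filters=base.filters,
                        seed=base.seed)
    ss.load_state_dict(base.state_dict())
    ft_cfg = DenoiserConfig(**{**cfg.__dict__, "epochs": cfg.ft_epochs})
    ss, history = train(ss, (pn[n_val:], pc[n_val:]), (pn[:n_val], pc[:n_val]),
                        ft_cfg, lr=lr)
    return ss, history


def beta_sweep(train_pairs, val_pairs, cfg: DenoiserConfig,
               betas=(0.0, 0.01, 0.1, 1.0), lr: float | None = None) -> dict:
    """Train one model per data-consistency weight beta.

    Returns ``{beta: (model, history)}``; downstream selection (e.g. by
    volumetric error on denoised outputs) is left to the caller.
    """
    out = {}
    for beta in betas:
        sweep_cfg = DenoiserConfig(**{**cfg.__dict__, "beta": float(beta)})
        model = build_model(sweep_cfg)
        out[float(beta)] = train(model, train_pairs, val_pairs, sweep_cfg, lr=lr)
    return out


def denoise_volume(model, v: Volume, stride: int = 32, patch: int = 64) -> Volume:
    """Sliding-window per-slice inference with uniform overlap averaging.

    Edge positions are clamped to the border; ``model`` needs only a
    ``predict_patches`` method mapping (n, patch, patch) to (n, patch, patch).
    """
    h, w, _ = v.shape
    if h < patch or w < patch:
        raise ValueError(f"in-plane dims {h}x{w} smaller than patch {patch}")
    if not (1 <= stride <= patch):
        raise ValueError("stride must lie in [1, patch]")

    def starts(dim):
        s = list(range(0, dim - patch + 1, stride))
        if s[-1] != dim - patch:
            s.append(dim - patch)
        return s

    rows, cols = starts(h), starts(w)
    out = np.zeros(v.shape, dtype=np.float64)
    weight = np.zeros((h, w), dtype=np.float64)
    for r in rows:
        for c in cols:
            weight[r : r + patch, c : c + patch] += 1.0
    positions = [(r, c) for r in rows for c in cols]
    for k in range(v.n_slices):
        sl = v.data[:, :, k]
        batch = np.stack([sl[r : r + patch, c : c + patch] for r, c in positions])
        preds = np.asarray(model.predict_patches(batch))
        acc = np.zeros((h, w), dtype=np.float64)
        for (r, c), p in zip(positions, preds):
            acc[r : r + patch, c : c + patch] += p
        out[:, :, k] = acc / weight
    return v.with_data(out.astype(np.float32), denoised="true")
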