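"""Image-quality metrics: object masking, local SNR, PSNR, MS-SSIM, var-Lap,
and the MR Value.

The MR Value summarises a whole protocol's worth per unit time: the sum over
contrasts of the median object-masked local SNR, divided by the protocol's
acquisition duration in seconds (units 1/s).  Local SNR maps are the local
in-plane mean divided by a robust global estimate of the background noise
scale; "object-masked" restricts the median to the imaged anatomy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import Mask, Volume, central_slab

__all__ = [
    "SNRMap",
    "ProtocolQuality",
    "object_mask",
    "background_sigma",
    "local_snr_map",
    "median_masked_snr",
    "psnr",
    "ssim",
    "ms_ssim",
    "var_laplacian",
    "mr_value",
    "compare_protocols",
]

# Canonical 5-scale MS-SSIM weights (Wang et al. convention).
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)
_Q75_TO_SIGMA = 0.6744897501960817  # Phi^-1(0.75)


@dataclass
class SNRMap:
    """Local SNR map restricted to a central slab, with its object mask."""

    data: np.ndarray
    mask: Mask
    sigma: float

    @property
    def median_masked(self) -> float:
        return float(np.median(self.data[self.mask.data]))


@dataclass
class ProtocolQuality:
    """Per-contrast median local SNR of a protocol plus its duration."""

    per_contrast_median_snr: dict
    t_acq_s: float
    mr_value: float = field(init=False)

    def __post_init__(self):
        self.mr_value = mr_value(self.per_contrast_median_snr, self.t_acq_s)


def object_mask(v: Volume) -> Mask:
    """Mask of the imaged object.

    Threshold at ``p2 + 0.1 * (p98 - p2)`` of the intensity histogram, keep
    the largest 3D connected component, fill internal holes.
    """
    data = v.data
    p2, p98 = np.percentile(data, [2, 98])
    if p98 <= p2:
        raise ValueError("degenerate (near-constant) volume: cannot build object mask")
    thresholded = data > p2 + 0.1 * (p98 - p2)
    if not thresholded.any():
        raise ValueError("object masking failed: empty mask after thresholding")
    labels, n = ndimage.label(thresholded)
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return Mask(mask, source="object")


def background_sigma(v: Volume, mask: Mask) -> float:
    """Robust noise scale of the non-object (background) intensities.

    Uses the upper half-spread ``(Q75 - median) / Phi^-1(0.75)``, which
    matches the MAD-implied sigma for symmetric noise and remains exact when
    magnitude clipping has floored half the background at zero.
    """
    bg = v.data[~mask.data]
    if bg.size == 0:
        raise ValueError("no background voxels outside the object mask")
    med, q75 = np.percentile(bg, [50, 75])
    sigma = float(q75 - med) / _Q75_TO_SIGMA
    if sigma <= 0:
        raise ValueError("zero background noise scale: SNR undefined")
    return sigma


def local_snr_map(v: Volume, window: int = 5, slab_fraction: float = 0.5) -> SNRMap:
    """Local SNR map on the central slab of ``v``.

    Local signal is the in-plane ``window x window`` mean; the noise scale is
    the global robust background sigma from :func:`background_sigma`.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    slab = central_slab(v, slab_fraction)
    mask = object_mask(slab)
    sigma = background_sigma(slab, mask)
    local_mean = ndimage.uniform_filter(
        slab.data.astype(np.float64), size=(window, window, 1), mode="nearest"
    )
    return SNRMap(data=local_mean / sigma, mask=mask, sigma=sigma)


def median_masked_snr(v: Volume, window: int = 5, slab_fraction: float = 0.5) -> float:
    """Median object-masked local SNR (convenience wrapper)."""
    return local_snr_map(v, window=window, slab_fraction=slab_fraction).median_masked


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float | None = None) -> float:
    """Peak SNR in dB: ``20 log10(data_range) - 10 log10(MSE)``."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {test.shape}")
    if data_range is None:
        data_range = float(ref.max())
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0:
        raise ValueError("identical inputs: PSNR is unbounded")
    return 20.0 * np.log10(data_range) - 10.0 * np.log10(mse)


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _filter_valid(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """2D correlation keeping only fully-supported (valid) positions."""
    out = ndimage.correlate(img, kernel, mode="constant")
    m = kernel.shape[0] // 2
    return out[m:-m, m:-m]


def ssim(ref: np.ndarray, test: np.ndarray, data_range: float | None = None,
         k1: float = 0.01, k2: float = 0.03) -> tuple[float, float]:
    """Single-scale SSIM and its contrast-structure component (Gaussian 11x11,
    sigma 1.5, means over the valid region)."""
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {test.shape}")
    if data_range is None:
        data_range = float(ref.max() - ref.min()) or 1.0
    c1, c2 = (k1 * data_range) ** 2, (k2 * data_range) ** 2
    kern = _gaussian_kernel()
    mu_x = _filter_valid(ref, kern)
    mu_y = _filter_valid(test, kern)
    sxx = _filter_valid(ref * ref, kern) - mu_x**2
    syy = _filter_valid(test * test, kern) - mu_y**2
    sxy = _filter_valid(ref * test, kern) - mu_x * mu_y
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    cs = (2 * sxy + c2) / (sxx + syy + c2)
    return float(np.mean(lum * cs)), float(np.mean(cs))


def _downsample2(img: np.ndarray) -> np.ndarray:
    h, w = (img.shape[0] // 2) * 2, (img.shape[1] // 2) * 2
    img = img[:h, :w]
    return 0.25 * (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2])


def n_msssim_scales(shape: tuple[int, int], window: int = 11, max_scales: int = 5) -> int:
    """Largest scale count such that the coarsest image still fits the window."""
    s = 1
    while s < max_scales and min(shape) // (2**s) >= window:
        s += 1
    return s


def ms_ssim(ref: np.ndarray, test: np.ndarray, data_range: float | None = None,
            scales: int | None = None) -> float:
    """Multi-scale SSIM.

    5 scales with the canonical weights when the images are large enough;
    otherwise the scale count is reduced and the weights renormalised (with a
    warning).  2D inputs only; volumes are averaged per slice by callers.
    """
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch {ref.shape} vs {test.shape}")
    if data_range is None:
        data_range = float(ref.max() - ref.min()) or 1.0
    fit = n_msssim_scales(ref.shape)
    if scales is None:
        scales = fit
        if scales < 5:
            warnings.warn(
                f"image {ref.shape} too small for 5 MS-SSIM scales; using {scales}",
                stacklevel=2,
            )
    elif scales > fit:
        raise ValueError(f"image {ref.shape} too small for {scales} scales")
    weights = np.array(MSSSIM_WEIGHTS[:scales])
    weights = weights / weights.sum()
    value = 1.0
    for s in range(scales):
        sim, cs = ssim(ref, test, data_range=data_range)
        comp = sim if s == scales - 1 else cs
        value *= max(comp, 0.0) ** weights[s]
        if s < scales - 1:
            ref, test = _downsample2(ref), _downsample2(test)
    return float(value)


def ms_ssim_volume(ref: Volume, test: Volume, data_range: float | None = None) -> float:
    """Per-slice MS-SSIM averaged over the slice axis."""
    if ref.shape != test.shape:
        raise ValueError("volume shapes differ")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vals = [
            ms_ssim(ref.data[:, :, k], test.data[:, :, k], data_range=data_range)
            for k in range(ref.n_slices)
        ]
    return float(np.mean(vals))


_LAPLACIAN = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


def var_laplacian(img) -> float:
    """Variance of the 3x3 Laplacian response over interior pixels.

    A referenceless sharpness measure: blurring suppresses high-frequency
    structure and drives it toward zero.  Accepts a 2D slice, a 3D array, or
    a :class:`Volume`; slices of a volume are pooled.
    """
    data = img.data if isinstance(img, Volume) else np.asarray(img, dtype=np.float64)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.shape[0] < 3 or data.shape[1] < 3:
        raise ValueError("need at least 3x3 in-plane extent")
    responses = []
    for k in range(data.shape[2]):
        out = ndimage.correlate(data[:, :, k], _LAPLACIAN, mode="constant")
        responses.append(out[1:-1, 1:-1].ravel())
    return float(np.var(np.concatenate(responses)))


def mr_value(per_contrast_median_snr: dict, t_acq_s: float) -> float:
    """Sum of per-contrast median object-masked local SNR over the duration (1/s)."""
    if t_acq_s <= 0:
        raise ValueError("t_acq_s must be > 0")
    if not per_contrast_median_snr:
        raise ValueError("need at least one contrast")
    return float(sum(per_contrast_median_snr.values())) / float(t_acq_s)


def compare_protocols(a: ProtocolQuality, b: ProtocolQuality) -> dict:
    """Head-to-head summary with ``a`` as the reference protocol.

    Returns throughput gain (a.t / b.t), percentage time reduction, and
    percentage MR Value increase of ``b`` over ``a``.
    """
    return {
        "throughput_gain": a.t_acq_s / b.t_acq_s,
        "time_reduction_pct": 100.0 * (1.0 - b.t_acq_s / a.t_acq_s),
        "mr_value_increase_pct": 100.0 * (b.mr_value - a.mr_value) / a.mr_value,
    }
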