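"""Native-noise forward simulation.

Instead of assuming a noise distribution, the forward model harvests the
empirical ("native") noise of the noisiest real acquisition -- every voxel
outside the object mask -- collages those values into a reusable block, and
corrupts clean volumes by adding randomly resampled, scaled draws from the
block.  The scaling factor is calibrated on a grid (start, start+step, ...)
until the corrupted volume's median object-masked local SNR drops strictly
below that of the noisiest acquisition, so the simulated data is at least as
noisy as the worst real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import median_masked_snr, object_mask
from .volume import Volume

__all__ = [
    "NoiseBlock",
    "NoiseModel",
    "find_noisiest_acquisition",
    "extract_native_noise",
    "sample_noise",
    "corrupt_volume",
    "calibrate_scaling_factor",
    "split_subjects",
]

MIN_NOISE_SAMPLES = 10_000


def is_clean_pool_eligible(v: Volume) -> bool:
    """Whether a volume may serve as clean training data.

    Diffusion acquisitions qualify only as b0 (non-diffusion-weighted)
    images, marked by a ``b0 = "true"`` metadata flag; diffusion schemes are
    never parsed.  All other contrasts qualify unconditionally.
    """
    if v.contrast == "DWI":
        return v.meta.get("b0", "").lower() == "true"
    return True


@dataclass
class NoiseBlock:
    """Collaged native-noise values plus their 3D layout."""

    samples: np.ndarray  # flat
    source_id: str
    layout: tuple[int, int, int]

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float32).ravel()
        if not np.isfinite(self.samples).all():
            raise ValueError("noise samples must be finite")

    @property
    def block(self) -> np.ndarray:
        return self.samples[: int(np.prod(self.layout))].reshape(self.layout)


@dataclass
class NoiseModel:
    """A noise block plus its calibrated scaling factor and the SNR it targets."""

    block: NoiseBlock
    scale: float
    target_snr: float

    def __post_init__(self):
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


def find_noisiest_acquisition(
    volumes: list[Volume], window: int = 5, slab_fraction: float = 0.5
) -> tuple[Volume, float]:
    """Volume minimising median object-masked local SNR (ties: first in order)."""
    if not volumes:
        raise ValueError("need at least one volume")
    best, best_snr = None, None
    for i, v in enumerate(volumes):
        try:
            snr = median_masked_snr(v, window=window, slab_fraction=slab_fraction)
        except ValueError as exc:
            raise ValueError(
                f"cannot compute local SNR for volume {i} "
                f"(subject {v.subject_id!r}, contrast {v.contrast!r}): {exc}"
            ) from exc
        if best_snr is None or snr < best_snr:
            best, best_snr = v, snr
    return best, float(best_snr)


def extract_native_noise(v: Volume, layout: tuple[int, int, int] | None = None,
                         seed: int = 0) -> NoiseBlock:
    """Collect all non-object voxel intensities of ``v`` into a noise block.

    The block layout defaults to the source volume's shape; surplus values
    are discarded and any deficit is filled by seeded shuffled repetition.
    """
    mask = object_mask(v)
    values = v.data[~mask.data]
    if values.size < MIN_NOISE_SAMPLES:
        raise ValueError(
            f"insufficient background voxels for noise extraction: "
            f"{values.size} < {MIN_NOISE_SAMPLES}"
        )
    layout = tuple(int(n) for n in (layout or v.shape))
    need = int(np.prod(layout))
    rng = np.random.default_rng(seed)
    if values.size < need:
        reps = int(np.ceil(need / values.size))
        values = np.concatenate([rng.permutation(values) for _ in range(reps)])
    return NoiseBlock(samples=values[:need], source_id=f"{v.subject_id}/{v.contrast}",
                      layout=layout)


def sample_noise(block: NoiseBlock, shape, seed: int) -> np.ndarray:
    """I.i.d. draws with replacement from the block, arranged into ``shape``."""
    if block.samples.size == 0:
        raise ValueError("empty noise block")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, block.samples.size, size=int(np.prod(shape)))
    return block.samples[idx].reshape(tuple(shape)).astype(np.float32)


def corrupt_volume(clean: Volume, model: NoiseModel, seed: int = 0) -> Volume:
    """``clean + scale * sampled noise``, clipped at zero (magnitude data)."""
    noise = sample_noise(model.block, clean.shape, seed)
    data = np.clip(clean.data + model.scale * noise, 0.0, None)
    return clean.with_data(data, corrupted="true", noise_scale=model.scale)


def calibrate_scaling_factor(
    block: NoiseBlock,
    clean: Volume,
    target_snr: float,
    start: float = 1.0,
    step: float = 0.5,
    max_iter: int = 50,
    seed: int = 0,
    window: int = 5,
    slab_fraction: float = 0.5,
) -> NoiseModel:
    """Smallest grid scale driving the corrupted volume's median local SNR
    strictly below ``target_snr``.

    The grid is ``{start, start+step, start+2*step, ...}``; each candidate is
    evaluated at one fixed seed so the returned scale is reproducible.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    if float(np.std(block.samples)) == 0.0:
        raise ValueError("degenerate noise block with zero spread")
    last_snr = None
    for k in range(max_iter):
        scale = start + k * step
        model = NoiseModel(block=block, scale=scale, target_snr=target_snr)
        corrupted = corrupt_volume(clean, model, seed=seed)
        last_snr = median_masked_snr(corrupted, window=window, slab_fraction=slab_fraction)
        if last_snr < target_snr:
            return model
    raise RuntimeError(
        f"calibration did not reach target SNR {target_snr:.3f} within "
        f"{max_iter} iterations (last median SNR {last_snr:.3f})"
    )


def split_subjects(subject_ids: list[str], ratios=(85.0, 10.0, 5.0), seed: int = 0):
    """Subject-wise train/val/test partition with largest-remainder rounding.

    Ratios are percentages summing to 100; each partition receives
    ``round(ratio * n / 100)`` subjects, adjusted by largest remainder so the
    counts sum to ``n``.  Deterministic given ``seed``.
    """
    subject_ids = list(subject_ids)
    n = len(subject_ids)
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 100.0) > 0.01:
        raise ValueError("ratios must be positive and sum to 100")
    exact = [r * n / 100.0 for r in ratios]
    counts = [int(np.floor(x + 0.5)) for x in exact]
    # largest-remainder adjustment toward sum == n
    while sum(counts) != n:
        residue = [x - c for x, c in zip(exact, counts)]
        if sum(counts) < n:
            i = int(np.argmax(residue))
            counts[i] += 1
        else:
            i = int(np.argmin(residue))
            counts[i] = max(counts[i] - 1, 0)
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [subject_ids[i] for i in order]
    train = shuffled[: counts[0]]
    val = shuffled[counts[0] : counts[0] + counts[1]]
    test = shuffled[counts[0] + counts[1] :]
    return train, val, test
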