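"""Synthetic multi-contrast phantoms and LUT fixtures.

The phantom emulates what the downstream pipeline actually consumes from a
brain acquisition: a compact bright object (three nested ellipsoidal tissue
shells standing in for CSF/GM/WM contrast) on a dark noise background, with
subject-to-subject variation of object size (hence SNR -- larger objects
yield more high-signal voxels per local window) and of noise level.  No MR
physics is simulated; the object is purely geometric.

LUT fixtures provide look-up tables with rSNR positively correlated with
acquisition time and a designated default (gold-standard) entry, so the
protocol search can be validated against brute force on known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocolling import LUT, LUTEntry
from .volume import CONTRASTS, Volume

__all__ = ["PhantomSpec", "make_phantom", "make_subject", "make_lut_fixture",
           "DEFAULT_TISSUE_LEVELS"]

#: Default shell intensities (outer, middle, inner) per contrast, chosen so
#: relative tissue brightness orders the way the named weighting orders them.
DEFAULT_TISSUE_LEVELS = {
    "T1": (0.35, 0.65, 0.95),
    "T2": (0.95, 0.55, 0.35),
    "T2FLAIR": (0.30, 0.75, 0.55),
    "T2STAR": (0.45, 0.70, 0.60),
    "DWI": (0.40, 0.80, 0.65),
}

#: Shell boundaries as fractions of the object semi-axes: outer shell spans
#: (0.75, 1.0], middle (0.5, 0.75], inner [0, 0.5].
_SHELL_FRACTIONS = (1.0, 0.75, 0.5)


@dataclass
class PhantomSpec:
    """Geometry, contrast, and noise of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (96, 96, 32)
    object_radius_frac: float = 0.3
    tissue_levels: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_LEVELS))
    background_sigma: float = 0.05
    rician: bool = False
    seed: int = 0
    subject_id: str = "synth-000"

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3 or any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 components, each >= 16")
        if not (0.2 < self.object_radius_frac < 0.45):
            raise ValueError("object_radius_frac must lie in (0.2, 0.45)")
        if self.background_sigma < 0:
            raise ValueError("background_sigma must be >= 0")
        for c, levels in self.tissue_levels.items():
            if c not in CONTRASTS:
                raise ValueError(f"unknown contrast {c!r}")
            if len(levels) != 3 or len(set(levels)) != 3:
                raise ValueError(f"{c}: need 3 distinct tissue levels")
            if any(not (0 < v <= 1) for v in levels):
                raise ValueError(f"{c}: tissue levels must lie in (0, 1]")


def _ellipsoid_radius2(shape, radius_frac):
    """Squared normalised ellipsoid coordinate r^2 for every voxel."""
    grids = np.ogrid[tuple(slice(n) for n in shape)]
    r2 = np.zeros(shape, dtype=np.float64)
    for ax, n in enumerate(shape):
        c = (n - 1) / 2.0
        semi = radius_frac * n
        r2 = r2 + ((grids[ax] - c) / semi) ** 2
    return r2


def object_support(spec: PhantomSpec) -> np.ndarray:
    """Boolean ground-truth support of the phantom object."""
    return _ellipsoid_radius2(spec.grid_shape, spec.object_radius_frac) <= 1.0


def _contrast_rng(spec: PhantomSpec, contrast: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, CONTRASTS.index(contrast)])


def make_phantom(spec: PhantomSpec, contrast: str) -> Volume:
    """One contrast of the phantom subject.

    Three nested tissue shells at the configured intensities on a zero
    background, i.i.d. zero-mean Gaussian noise of std ``background_sigma``
    added everywhere, magnitudes clipped at zero.  Deterministic given
    ``spec.seed`` and the contrast.
    """
    if contrast not in spec.tissue_levels:
        raise ValueError(f"contrast {contrast!r} not configured in spec.tissue_levels")
    levels = spec.tissue_levels[contrast]
    r2 = _ellipsoid_radius2(spec.grid_shape, spec.object_radius_frac)
    clean = np.zeros(spec.grid_shape, dtype=np.float64)
    for frac, level in zip(_SHELL_FRACTIONS, levels):
        clean[r2 <= frac**2] = level
    if spec.background_sigma > 0:
        rng = _contrast_rng(spec, contrast)
        if spec.rician:
            # magnitude of a complex signal with Gaussian channel noise
            re = clean + rng.normal(0.0, spec.background_sigma, spec.grid_shape)
            im = rng.normal(0.0, spec.background_sigma, spec.grid_shape)
            data = np.sqrt(re**2 + im**2)
        else:
            data = clean + rng.normal(0.0, spec.background_sigma, spec.grid_shape)
    else:
        data = clean
    return Volume(
        data=np.clip(data, 0.0, None).astype(np.float32),
        contrast=contrast,
        subject_id=spec.subject_id,
        meta={"synthetic": "true", "background_sigma": str(spec.background_sigma)},
    )


def make_subject(spec: PhantomSpec) -> dict[str, Volume]:
    """All configured contrasts of one subject (shared geometry and identity)."""
    if not spec.tissue_levels:
        raise ValueError("spec configures no contrasts")
    return {c: make_phantom(spec, c) for c in spec.tissue_levels}


def make_lut_fixture(
    n_entries: int,
    dof_names: list[str],
    t_range: tuple[float, float] = (30.0, 300.0),
    seed: int = 0,
    sequence_id: str = "synthseq",
) -> LUT:
    """Random LUT with rSNR positively correlated with acquisition time.

    DOF values are uniform on [1, 10); ``t_acq`` uniform on ``t_range``; rSNR
    rises linearly with ``t_acq`` plus Gaussian jitter.  The slowest entry is
    designated the default (gold-standard) combination.  Deterministic given
    ``seed``.
    """
    if n_entries < 1:
        raise ValueError("n_entries must be >= 1")
    if not dof_names:
        raise ValueError("dof_names must be non-empty")
    t_lo, t_hi = t_range
    if not (0 < t_lo <= t_hi):
        raise ValueError(f"invalid t_range {t_range}")
    rng = np.random.default_rng(seed)
    entries = []
    for _ in range(n_entries):
        t = float(rng.uniform(t_lo, t_hi)) if t_hi > t_lo else t_lo
        frac = (t - t_lo) / (t_hi - t_lo) if t_hi > t_lo else 1.0
        rsnr = 0.2 + 0.8 * frac + float(rng.normal(0.0, 0.05))
        entries.append(
            LUTEntry(
                p_acq={d: round(float(rng.uniform(1.0, 10.0)), 4) for d in dof_names},
                t_acq_s=round(t, 3),
                rsnr=round(max(rsnr, 0.05), 4),
            )
        )
    default = max(entries, key=lambda e: e.t_acq_s)
    return LUT(sequence_id=sequence_id, entries=entries, default=default)
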