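"""Volume data model and NIfTI I/O.

A :class:`Volume` is the package's universal image currency: a 3D magnitude
image with voxel spacing and acquisition metadata.  The through-plane (slice)
direction is by convention the *last* array axis; all in-plane operations
elsewhere in the package act on the first two axes.

Metadata that NIfTI-1 has no native slots for (contrast, subject identity,
repeat index, acquisition duration) travels in a JSON sidecar named
``<stem>.json`` next to the image file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CONTRASTS",
    "Volume",
    "Mask",
    "read_volume",
    "write_volume",
    "central_slab",
]

#: Recognised contrast tags (MRI sequence families).
CONTRASTS = ("T1", "T2", "T2FLAIR", "T2STAR", "DWI")


@dataclass
class Volume:
    """A 3D magnitude MR volume.

    Parameters
    ----------
    data : ndarray
        3D floating-point intensity grid (arbitrary units).
    spacing : tuple of float
        Per-axis voxel size in mm; all components positive.
    contrast : str
        One of :data:`CONTRASTS`, or ``""`` when unknown.
    subject_id : str
        Free-form subject identifier.
    repeat_id : int
        Repeat (re-scan) index, >= 0.
    meta : dict
        Free-form string map (sequence name, ``t_acq_s`` when known, flags
        such as ``corrupted`` / ``denoised``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    contrast: str = ""
    subject_id: str = ""
    repeat_id: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume data must have exactly 3 axes, got {self.data.ndim}"
            )
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise ValueError(f"Volume contains {n_bad} non-finite voxel(s)")
        if self.contrast and self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}; expected one of {CONTRASTS}")
        if self.repeat_id < 0:
            raise ValueError("repeat_id must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_slices(self) -> int:
        return self.data.shape[-1]

    def with_data(self, data: np.ndarray, **meta_updates) -> "Volume":
        """Copy of this volume carrying new voxel data (same geometry/identity)."""
        v = replace(self, data=np.asarray(data), meta=dict(self.meta))
        v.meta.update({k: str(val) for k, val in meta_updates.items()})
        return v


@dataclass
class Mask:
    """Boolean companion grid of a :class:`Volume` (``object`` or ``background``)."""

    data: np.ndarray
    source: str = "object"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("Mask must be 3D")
        if self.source not in ("object", "background"):
            raise ValueError(f"invalid mask source {self.source!r}")

    @property
    def n_true(self) -> int:
        return int(self.data.sum())

    def inverted(self) -> "Mask":
        other = "background" if self.source == "object" else "object"
        return Mask(~self.data, source=other)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def read_volume(path, contrast: str | None = None, subject_id: str | None = None) -> Volume:
    """Load a NIfTI-1 volume (``.nii``/``.nii.gz``) plus its optional JSON sidecar.

    Singleton trailing axes are squeezed; a 4th non-singleton axis is an error.
    Explicit ``contrast``/``subject_id`` arguments override sidecar values.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several I/O flavours
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float32)
    while data.ndim > 3 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3 spatial dimensions, got shape {data.shape}")
    n_bad = int(data.size - np.isfinite(data).sum())
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel(s)")
    if data.min() < 0:
        # Magnitude convention: negative values only arise from storage
        # round-off; anything structurally negative is rejected.
        if data.min() < -1e-3 * max(abs(float(data.max())), 1.0):
            raise ValueError(f"{path}: negative intensities violate magnitude convention")
        data = np.clip(data, 0.0, None)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Volume(
        data=data,
        spacing=spacing,
        contrast=contrast if contrast is not None else meta.pop("contrast", ""),
        subject_id=subject_id if subject_id is not None else meta.pop("subject_id", ""),
        repeat_id=int(meta.pop("repeat_id", 0)),
        meta={k: str(v) for k, v in meta.items()},
    )


def write_volume(v: Volume, path) -> None:
    """Write ``v`` as NIfTI-1 with spacing on the affine diagonal, plus sidecar."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"directory {path.parent} does not exist")
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(v.data.astype(np.float32), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    sidecar = {"contrast": v.contrast, "subject_id": v.subject_id, "repeat_id": v.repeat_id}
    sidecar.update(v.meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def central_slab(v: Volume, fraction: float) -> Volume:
    """Centered contiguous block of ``round(fraction * n_slices)`` slices.

    Rounding is half-up, the count floor is 1, and when the discarded margin
    is odd the extra slice is dropped from the start.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n = v.n_slices
    if n < 2 and fraction < 1:
        raise ValueError("need >= 2 slices to take a partial slab")
    k = max(1, int(math.floor(fraction * n + 0.5)))
    start = (n - k + 1) // 2  # drop the extra slice from the start on ties
    return v.with_data(v.data[:, :, start : start + k])
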