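"""Filter-response explainability for the denoising network.

A DC-biased probe -- a 2x2 collage of constant-intensity panels -- is
corrupted with native noise and pushed through the network.  Every 2D
convolution layer's filter stack is collapsed to a single map by per-pixel
maximum-intensity projection, min-max normalised to [0, 1], and hard
thresholded, exposing whether a layer behaves as a low-pass (smooth panels
survive) or high-pass (panel edges survive) stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from . import nn
from .noise import NoiseBlock, sample_noise

__all__ = ["PROBE_PANEL_VALUES", "ProbeCollage", "LayerResponse", "make_probe",
           "layer_responses", "collage_responses"]

#: Default panel intensities of the DC-biased probe.
PROBE_PANEL_VALUES = (0.125, 0.375, 0.625, 0.875)


@dataclass
class ProbeCollage:
    """2x2 tiling of constant panels (row-major ascending by default)."""

    data: np.ndarray
    panel_values: tuple
    panel_size: int

    @property
    def side(self) -> int:
        return 2 * self.panel_size


@dataclass
class LayerResponse:
    """One convolution layer's collapsed, normalised, thresholded response."""

    layer_index: int
    map: np.ndarray          # in [0, 1]
    thresholded: np.ndarray  # zero where map <= threshold
    threshold: float


def make_probe(panel_values=PROBE_PANEL_VALUES, panel_size: int = 64) -> ProbeCollage:
    """Assemble the probe: four constant panels tiled row-major."""
    values = tuple(float(v) for v in panel_values)
    if len(values) != 4 or any(not np.isfinite(v) for v in values):
        raise ValueError("need 4 finite panel values")
    p = panel_size
    data = np.empty((2 * p, 2 * p), dtype=np.float32)
    data[:p, :p] = values[0]
    data[:p, p:] = values[1]
    data[p:, :p] = values[2]
    data[p:, p:] = values[3]
    return ProbeCollage(data=data, panel_values=values, panel_size=p)


def _normalize01(m: np.ndarray) -> np.ndarray:
    lo, hi = float(m.min()), float(m.max())
    if hi <= lo:
        return np.zeros_like(m)
    return (m - lo) / (hi - lo)


def layer_responses(model: nn.DenoiserNet, probe: ProbeCollage,
                    noise: NoiseBlock | None = None, threshold: float = 0.75,
                    noise_scale: float = 1.0, seed: int = 0) -> list[LayerResponse]:
    """Per-convolution-layer responses to the noise-corrupted probe.

    For each 2D convolution layer, in network order: maximum-intensity
    projection over filters, min-max normalisation to [0, 1] (constant maps
    become all-zero), then values <= ``threshold`` are zeroed.
    """
    img = probe.data.astype(np.float32)
    if noise is not None:
        img = np.clip(img + noise_scale * sample_noise(noise, img.shape, seed), 0, None)
    record: list = []
    model.forward(nn.Tensor(img[None, None]), record=record)
    if not record:
        raise ValueError("model exposes no convolution layers")
    out = []
    for i, t in enumerate(record):
        mip = t.data[0].max(axis=0)
        norm = _normalize01(mip)
        out.append(LayerResponse(
            layer_index=i,
            map=norm,
            thresholded=np.where(norm > threshold, norm, 0.0),
            threshold=threshold,
        ))
    return out


def collage_responses(responses: list[LayerResponse], out_path,
                      use_threshold: bool = True) -> None:
    """Write a row-major grid montage of the responses as a PNG.

    Tile edge lengths follow the deepest (smallest) maps upsampled to the
    first map's size; each tile is labelled with its layer index.  The
    layout and encoder settings are deterministic, so identical inputs give
    byte-identical files.
    """
    if not responses:
        raise ValueError("need at least one response")
    n = len(responses)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    tile = max(r.map.shape[0] for r in responses)
    pad = 2
    canvas = Image.new("L", (cols * (tile + pad) + pad, rows * (tile + pad) + pad), 32)
    draw = ImageDraw.Draw(canvas)
    for i, r in enumerate(responses):
        m = r.thresholded if use_threshold else r.map
        img = Image.fromarray((np.clip(m, 0, 1) * 255).astype(np.uint8), mode="L")
        if img.size != (tile, tile):
            img = img.resize((tile, tile), Image.NEAREST)
        x = pad + (i % cols) * (tile + pad)
        y = pad + (i // cols) * (tile + pad)
        canvas.paste(img, (x, y))
        draw.text((x + 2, y + 1), str(r.layer_index), fill=255)
    canvas.save(out_path, format="PNG")
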