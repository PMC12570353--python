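"""Sliding-window prediction heatmaps and best-case IHC label maps.

A tile classifier emits one probability per 256 px field of view; sliding
that field across a section with a small stride and averaging every
prediction that covers a pixel produces a per-pixel melanocyte confidence
map.  The same overlap-averaging applied to the binary IHC-derived labels
of the hidden paired section gives the "label map" — the ceiling any
classifier could reach at this tile size.  Windows are centered on every
stride-th pixel and zero-padded past the section edge, so a section of
height h yields ceil(h/stride) window rows (stride 1 on a 10,000 px square
section means 10^8 forward passes, which is why maps use stride 6 while
dataset metrics use stride 256).

Overlap averaging is computed with sum and count accumulation arrays, so
memory stays linear in the section size regardless of stride.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
from matplotlib import colormaps

from .labeling import DabMaskConfig, LabelThresholds, label_tile

TILE = 256

__all__ = [
    "ScalarMap",
    "count_positions",
    "position_anchors",
    "padded_window",
    "prediction_heatmap",
    "label_map",
    "position_labels_from_dab",
    "overlap_average",
    "render_overlay",
    "save_map",
]


@dataclass
class ScalarMap:
    """A float image in [0, 1] registered to a section frame."""

    values: np.ndarray
    stride_used: int
    kind: str  # "prediction" | "label"
    provenance: str = ""

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("scalar map must be finite")


def count_positions(section_h: int, section_w: int, stride: int) -> int:
    """Number of sliding-window positions: ceil(h/s) * ceil(w/s)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    return ceil(section_h / stride) * ceil(section_w / stride)


def position_anchors(section_h: int, section_w: int, stride: int) -> tuple[np.ndarray, np.ndarray]:
    """Window-center coordinates per axis (multiples of the stride)."""
    rows = np.arange(ceil(section_h / stride)) * stride
    cols = np.arange(ceil(section_w / stride)) * stride
    return rows, cols


def padded_window(image: np.ndarray, center_r: int, center_c: int, size: int = TILE) -> np.ndarray:
    """Extract a size x size window centered at (center_r, center_c),
    zero-padded where it extends past the image."""
    h, w = image.shape[:2]
    half = size // 2
    r0, c0 = center_r - half, center_c - half
    out_shape = (size, size) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + size, h), min(c0 + size, w)
    if re > rs and ce > cs:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = image[rs:re, cs:ce]
    return out


def overlap_average(position_values: np.ndarray, shape: tuple[int, int], stride: int, size: int = TILE) -> np.ndarray:
    """Per-pixel mean of all window values covering each pixel.

    ``position_values[i, j]`` belongs to the window centered at
    ``(i * stride, j * stride)``.
    """
    h, w = shape
    half = size // 2
    acc = np.zeros((h, w), dtype=np.float64)
    cnt = np.zeros((h, w), dtype=np.float64)
    nr, nc = position_values.shape
    for i in range(nr):
        r0 = max(i * stride - half, 0)
        r1 = min(i * stride - half + size, h)
        if r1 <= r0:
            continue
        row = position_values[i]
        for j in range(nc):
            c0 = max(j * stride - half, 0)
            c1 = min(j * stride - half + size, w)
            if c1 <= c0:
                continue
            acc[r0:r1, c0:c1] += row[j]
            cnt[r0:r1, c0:c1] += 1.0
    cnt[cnt == 0] = 1.0
    return acc / cnt


def prediction_heatmap(model, he_section: np.ndarray, stride: int = 6, batch_size: int = 240) -> ScalarMap:
    """Overlap-averaged per-pixel melanocyte probability over a section."""
    h, w = he_section.shape[:2]
    if h < 1 or w < 1:
        raise ValueError("section must be at least 1x1")
    rows, cols = position_anchors(h, w, stride)
    probs = np.empty((len(rows), len(cols)), dtype=np.float64)
    centers = [(r, c) for r in rows for c in cols]
    buf = np.empty((min(batch_size, len(centers)), TILE, TILE, 3), dtype=he_section.dtype)
    k = 0
    filled = 0
    flat = probs.reshape(-1)
    for (r, c) in centers:
        buf[filled] = padded_window(he_section, int(r), int(c), TILE)
        filled += 1
        if filled == len(buf):
            flat[k : k + filled] = model.probability(buf[:filled])
            k += filled
            filled = 0
    if filled:
        flat[k : k + filled] = model.probability(buf[:filled])
    values = overlap_average(probs, (h, w), stride, TILE)
    return ScalarMap(values, stride, "prediction", provenance=type(model).__name__)


def position_labels_from_dab(
    dab_mask: np.ndarray,
    stride: int,
    stain: str,
    thresholds: LabelThresholds | None = None,
    dab_cfg: DabMaskConfig | None = None,
) -> np.ndarray:
    """Binary tile label at every sliding-window position of a DAB mask."""
    h, w = dab_mask.shape
    rows, cols = position_anchors(h, w, stride)
    out = np.empty((len(rows), len(cols)), dtype=np.float64)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            win = padded_window(dab_mask.astype(np.uint8), int(r), int(c), TILE).astype(bool)
            out[i, j] = label_tile(stain, win, thresholds, dab_cfg, tile_shape=(TILE, TILE))
    return out


def label_map(position_labels: np.ndarray, shape: tuple[int, int], stride: int, provenance: str = "") -> ScalarMap:
    """Best-case map: overlap-average the per-position binary labels."""
    values = overlap_average(np.asarray(position_labels, dtype=np.float64), shape, stride, TILE)
    return ScalarMap(values, stride, "label", provenance=provenance)


def render_overlay(
    smap: ScalarMap,
    background: np.ndarray,
    colormap: str = "viridis",
    confidence_threshold: float | None = None,
    alpha: float = 0.5,
) -> np.ndarray:
    """Colormapped map alpha-blended over the section image.

    Below ``confidence_threshold`` the output is desaturated grayscale —
    tissue without a strong melanocyte prediction.
    """
    vals = smap.values
    if vals.shape != background.shape[:2]:
        raise ValueError("map and background dims differ")
    cmap = colormaps[colormap]
    colored = cmap(np.clip(vals, 0, 1))[..., :3] * 255.0
    bg = background.astype(np.float64)
    out = (1 - alpha) * bg + alpha * colored
    if confidence_threshold is not None:
        gray = bg.mean(axis=-1, keepdims=True) * np.ones(3)
        low = vals < confidence_threshold
        out[low] = gray[low]
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def save_map(smap: ScalarMap, path) -> None:
    """Persist as a 32-bit float single-channel TIFF."""
    import tifffile

    tifffile.imwrite(path, smap.values.astype(np.float32))
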