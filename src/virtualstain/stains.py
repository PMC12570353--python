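"""Color deconvolution between RGB and H/E/DAB optical density.

Brightfield stains obey Beer-Lambert absorption: a pixel's optical density
``OD = -log10(I / I0)`` is (approximately) a non-negative linear combination
of per-chromophore unit absorption vectors.  Unmixing RGB into hematoxylin,
eosin and DAB (3,3'-diaminobenzidine) channels therefore reduces to one 3x3
matrix inverse.  This module is the single source of truth for that matrix:
the synthetic renderer composes images with the forward matrix and the IHC
labeler unmixes with its inverse, so round trips are exact by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "RGB_FROM_HED",
    "HED_FROM_RGB",
    "I0",
    "OD_EPS",
    "rgb_to_od",
    "od_to_rgb",
    "rgb_to_hed",
    "hed_to_rgb",
    "render_from_od",
]

I0 = 255.0
#: floor on transmitted intensity, guards log of zero (one quantization step)
OD_EPS = 1.0 / 255.0


def _unit_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    return m / norms


# Ruifrok-Johnston absorption vectors, rows = (hematoxylin, eosin, DAB),
# columns = (R, G, B), each row normalized to unit length.
RGB_FROM_HED = _unit_rows(
    np.array(
        [
            [0.65, 0.70, 0.29],
            [0.07, 0.99, 0.11],
            [0.27, 0.57, 0.78],
        ]
    )
)

HED_FROM_RGB = np.linalg.inv(RGB_FROM_HED)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density ``-log10(I / I0)`` of an RGB image.

    Accepts uint8 or float arrays on the 0..255 scale; intensities below
    one quantization step are clamped so the log never diverges.
    """
    img = np.asarray(rgb, dtype=np.float64)
    return -np.log10(np.maximum(img, OD_EPS) / I0)


_LN10 = np.log(10.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; returns float RGB clipped to [0, 255]."""
    od = np.asarray(od, dtype=np.float64)
    return np.clip(I0 * np.exp(-_LN10 * od), 0.0, 255.0)


def rgb_to_hed(rgb: np.ndarray) -> np.ndarray:
    """Unmix an RGB image into stacked (H, E, DAB) optical-density channels.

    Parameters
    ----------
    rgb : array, shape (..., 3)
        8-bit or float RGB on the 0..255 scale.

    Returns
    -------
    array, shape (..., 3)
        Optical density per stain.  Values are non-negative up to small
        numerical noise (slightly negative entries can occur for colors
        outside the stain gamut).
    """
    od = rgb_to_od(rgb)
    return od @ HED_FROM_RGB


def hed_to_rgb(hed: np.ndarray) -> np.ndarray:
    """Recompose (H, E, DAB) optical densities into float RGB."""
    return render_from_od(hed, RGB_FROM_HED)


def render_from_od(od_maps: np.ndarray, stain_matrix: np.ndarray | None = None) -> np.ndarray:
    """Render per-chromophore OD maps to an RGB image.

    ``RGB = I0 * 10**(-OD @ M)`` with ``M`` a matrix of unit absorption row
    vectors; zero OD everywhere renders pure white.  Output is float64 in
    [0, 255]; quantize with ``np.rint(...).astype(np.uint8)`` when writing
    8-bit images.

    Raises
    ------
    ValueError
        If ``od_maps`` contains negative densities or ``stain_matrix`` is
        singular (cannot be unmixed again).
    """
    od = np.asarray(od_maps, dtype=np.float64)
    if od.shape[-1] != 3:
        raise ValueError("od_maps must have 3 chromophore channels last")
    if np.any(od < -1e-9):
        raise ValueError("optical densities must be non-negative")
    m = RGB_FROM_HED if stain_matrix is None else _unit_rows(np.asarray(stain_matrix, dtype=np.float64))
    if abs(np.linalg.det(m)) < 1e-8:
        raise ValueError("stain matrix is not invertible")
    return od_to_rgb(od @ m)
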