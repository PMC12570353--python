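"""IHC-derived tile labels: DAB isolation, artifact exclusion, stain rules.

The brown DAB chromogen marks antibody binding, so melanocyte presence in an
IHC section reduces to finding DAB-positive pixels.  RGB is unmixed into
hematoxylin / eosin / DAB optical densities (:mod:`virtualstain.stains`);
pixels are DAB-positive when their DAB density clears ``max(Otsu, floor)``
on tissue, excluding artifact pixels (marker ink by HSV range, hemorrhage
by an Otsu cascade, plus manual correction masks).

Tile labels follow the stain's biology:

* SOX10 (nuclear): positive iff the tile holds at least ``sox10_min_nuclei``
  discrete DAB-positive nuclei (connected components in a plausible
  nucleus-area band), default 2.
* MelanA / MelPro (cytoplasmic): positive iff the DAB-positive fraction of
  the tile area reaches ``melana_min_fraction``, default 3%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .stains import rgb_to_hed

__all__ = [
    "DabMaskConfig",
    "LabelThresholds",
    "ArtifactConfig",
    "artifact_mask",
    "dab_mask",
    "count_dab_nuclei",
    "dab_fraction",
    "label_tile",
    "rgb_to_hed",
]

TILE = 256

NUCLEAR_STAINS = ("SOX10",)
CYTOPLASMIC_STAINS = ("MelanA", "MelPro")


@dataclass(frozen=True)
class DabMaskConfig:
    """DAB positivity thresholding.

    ``od_floor`` is the minimum DAB optical density ever counted positive;
    with ``use_otsu`` the per-section Otsu threshold on tissue DAB density
    is combined as ``max(otsu, od_floor)``, which survives faded archival
    chromogen (Otsu alone would chase noise on DAB-free sections).
    ``nucleus_area_px`` brackets a plausible nucleus footprint at 0.25 MPP
    (~5-18 um equivalent diameter).
    """

    od_floor: float = 0.15
    use_otsu: bool = True
    nucleus_area_px: tuple[int, int] = (80, 5000)
    connectivity: int = 8

    def __post_init__(self):
        if not (0 < self.od_floor < 2):
            raise ValueError("od_floor must be in (0, 2)")
        if self.nucleus_area_px[0] >= self.nucleus_area_px[1]:
            raise ValueError("nucleus area min must be < max")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class LabelThresholds:
    """Positive-label cutoffs per stain rule.

    ``inclusive=True`` reads the cutoffs as "at least" (>=); setting it
    False gives the strict ">" reading.
    """

    sox10_min_nuclei: int = 2
    melana_min_fraction: float = 0.03
    inclusive: bool = True

    def __post_init__(self):
        if self.sox10_min_nuclei < 1:
            raise ValueError("sox10_min_nuclei must be >= 1")
        if not (0 < self.melana_min_fraction < 1):
            raise ValueError("melana_min_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ArtifactConfig:
    """Artifact exclusion: ink HSV ranges, Otsu cascade, manual corrections.

    Each ink range is ((h_lo, h_hi) degrees, (s_lo, s_hi), (v_lo, v_hi)).
    Defaults cover blue and green marker ink at saturation >= 0.5.
    """

    ink_hsv_ranges: tuple = (
        ((200.0, 260.0), (0.5, 1.0), (0.0, 1.0)),  # blue ink
        ((90.0, 150.0), (0.5, 1.0), (0.0, 1.0)),  # green ink
    )
    otsu_steps: int = 2
    min_artifact_area_px: int = 1500
    #: Otsu-cascade components must exceed this mean saturation to be
    #: flagged; keeps the hemorrhage proxy from swallowing DAB, whose
    #: counterstain-mixed saturation stays below fresh-blood levels
    min_artifact_saturation: float = 0.65
    correction_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.otsu_steps < 1:
            raise ValueError("otsu_steps must be >= 1")
        for (h, s, v) in self.ink_hsv_ranges:
            if h[0] > h[1] or s[0] > s[1] or v[0] > v[1]:
                raise ValueError("malformed HSV interval")


def _structure(connectivity: int) -> np.ndarray:
    return np.ones((3, 3), dtype=int) if connectivity == 8 else ndi.generate_binary_structure(2, 1)


def artifact_mask(rgb: np.ndarray, cfg: ArtifactConfig | None = None, tissue_mask: np.ndarray | None = None) -> np.ndarray:
    """Binary exclusion mask over an IHC section image.

    Union of (a) ink hits inside the configured HSV ranges, (b) an Otsu
    cascade flagging dark *and* saturated outlier regions (hemorrhage
    proxy) of sufficient size, and (c) the manual correction mask, which is
    honored regardless of color.  Excluded pixels never count as
    DAB-positive downstream.
    """
    cfg = cfg or ArtifactConfig()
    h, w = rgb.shape[:2]
    if cfg.correction_mask is not None and cfg.correction_mask.shape != (h, w):
        raise ValueError("correction mask dims do not match image")
    hsv = rgb2hsv(rgb)
    hue_deg = hsv[..., 0] * 360.0
    sat, val = hsv[..., 1], hsv[..., 2]

    mask = np.zeros((h, w), dtype=bool)
    for (hr, sr, vr) in cfg.ink_hsv_ranges:
        mask |= (
            (hue_deg >= hr[0]) & (hue_deg <= hr[1]) & (sat >= sr[0]) & (sat <= sr[1]) & (val >= vr[0]) & (val <= vr[1])
        )

    # Otsu cascade: split off the dark cluster on V, then the saturated
    # cluster within it; keep only large components so nuclei (small, dark)
    # are not swept up
    tissue = tissue_mask if tissue_mask is not None else np.ones((h, w), dtype=bool)
    cand = tissue.copy()
    for step in range(cfg.otsu_steps):
        chan = val if step % 2 == 0 else -sat  # dark first, then high-saturation
        pix = chan[cand]
        if pix.size < 2 or np.ptp(pix) < 1e-6:
            cand &= False
            break
        thr = threshold_otsu(pix)
        cand &= chan < thr
    if cand.any():
        labels, n = ndi.label(cand, structure=_structure(8))
        if n:
            sizes = np.bincount(labels.ravel())
            mean_sat = ndi.mean(sat, labels=labels, index=np.arange(1, n + 1))
            keep = [
                lab
                for lab in range(1, n + 1)
                if sizes[lab] >= cfg.min_artifact_area_px and mean_sat[lab - 1] >= cfg.min_artifact_saturation
            ]
            mask |= np.isin(labels, keep)

    if cfg.correction_mask is not None:
        mask |= cfg.correction_mask.astype(bool)
    return mask


def dab_mask(
    hed_dab: np.ndarray,
    tissue_mask: np.ndarray | None = None,
    artifact: np.ndarray | None = None,
    cfg: DabMaskConfig | None = None,
) -> np.ndarray:
    """DAB-positive pixels: in tissue, not artifact, density >= max(Otsu, floor)."""
    cfg = cfg or DabMaskConfig()
    od = np.asarray(hed_dab, dtype=np.float64)
    tissue = tissue_mask if tissue_mask is not None else np.ones(od.shape, dtype=bool)
    if artifact is not None:
        tissue = tissue & ~artifact.astype(bool)
    if not tissue.any():
        return np.zeros(od.shape, dtype=bool)
    thr = cfg.od_floor
    if cfg.use_otsu:
        pix = od[tissue]
        if np.ptp(pix) > 1e-6:
            thr = max(float(threshold_otsu(pix)), cfg.od_floor)
    return tissue & (od >= thr)


def count_dab_nuclei(mask: np.ndarray, cfg: DabMaskConfig | None = None) -> int:
    """Number of discrete DAB-positive nuclei: connected components whose
    area falls inside the configured nucleus-area band.  Touching nuclei
    merge into one component and under-count, by design."""
    cfg = cfg or DabMaskConfig()
    labels, n = ndi.label(np.asarray(mask, dtype=bool), structure=_structure(cfg.connectivity))
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    lo, hi = cfg.nucleus_area_px
    return int(np.count_nonzero((sizes >= lo) & (sizes <= hi)))


def dab_fraction(mask: np.ndarray, tile_shape: tuple[int, int] = (TILE, TILE)) -> float:
    """Fraction of the tile frame that is DAB-positive."""
    denom = tile_shape[0] * tile_shape[1]
    return float(np.count_nonzero(mask) / denom)


def label_tile(
    stain: str,
    mask: np.ndarray,
    thresholds: LabelThresholds | None = None,
    cfg: DabMaskConfig | None = None,
    tile_shape: tuple[int, int] | None = None,
) -> int:
    """Binary melanocyte label for one tile from its DAB-positive mask."""
    thresholds = thresholds or LabelThresholds()
    if stain in NUCLEAR_STAINS:
        n = count_dab_nuclei(mask, cfg)
        hit = n >= thresholds.sox10_min_nuclei if thresholds.inclusive else n > thresholds.sox10_min_nuclei
    elif stain in CYTOPLASMIC_STAINS:
        frac = dab_fraction(mask, tile_shape or mask.shape)
        hit = (
            frac >= thresholds.melana_min_fraction
            if thresholds.inclusive
            else frac > thresholds.melana_min_fraction
        )
    else:
        raise ValueError(f"unknown stain {stain!r}")
    return int(hit)
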