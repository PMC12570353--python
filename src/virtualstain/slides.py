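"""Whole-slide preparation: background detection, section extraction, pairing.

A scanned slide holds one or more tissue sections on a near-white glass
background.  Background is modeled in HSV: its center is learned from the
slide's outer border ring (or given explicitly) and pixels within the
tolerance envelope — or simply unsaturated and bright — count as glass.
Connected foreground components above a size threshold become `Section`
crops; H&E and IHC sections from the two slides of one case are paired
greedily by centroid position in normalized slide coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.color import rgb2hsv

__all__ = [
    "TissueMaskConfig",
    "Section",
    "SectionPairCandidate",
    "detect_background",
    "extract_sections",
    "match_sections",
    "read_slide",
    "write_sections",
]

STAINS = ("HE", "SOX10", "MelanA", "MelPro")


@dataclass(frozen=True)
class TissueMaskConfig:
    """Thresholds for chroma, size, and region-enclosure; all adjustable."""

    #: background saturation ceiling (HSV S in [0, 1])
    max_background_saturation: float = 0.08
    #: background value floor (HSV V in [0, 1])
    min_background_value: float = 0.90
    #: optional learned HSV center + per-channel tolerance, overrides the
    #: S/V envelope when given: (h, s, v), (th, ts, tv)
    background_hsv: tuple[float, float, float] | None = None
    background_tolerance: tuple[float, float, float] = (0.05, 0.08, 0.08)
    min_section_area_px: int = 50_000
    enclosure_fill: bool = True
    #: fraction of the slide edge used to learn the background color
    border_frac: float = 0.02

    def __post_init__(self):
        if self.min_section_area_px <= 0:
            raise ValueError("min_section_area_px must be > 0")
        if any(t < 0 for t in self.background_tolerance):
            raise ValueError("tolerances must be >= 0")


@dataclass
class Section:
    source_slide_id: str
    stain: str
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    mask: np.ndarray  # bool, crop frame
    image: np.ndarray  # uint8 RGB crop, background zeroed
    mpp: float = 0.25

    @property
    def centroid_slide(self) -> tuple[float, float]:
        r = np.argwhere(self.mask).mean(axis=0)
        return (self.bbox[0] + float(r[0]), self.bbox[1] + float(r[1]))


@dataclass
class SectionPairCandidate:
    he: Section | None
    ihc: Section | None
    match_method: str = "auto_position"
    status: str = "kept"
    discard_reason: str = ""


def learn_background_hsv(slide_image: np.ndarray, border_frac: float = 0.02) -> tuple[float, float, float]:
    """Median HSV of the slide's outer border ring."""
    h, w = slide_image.shape[:2]
    b = max(1, int(round(border_frac * min(h, w))))
    hsv = rgb2hsv(slide_image)
    ring = np.ones((h, w), dtype=bool)
    ring[b:-b, b:-b] = False
    vals = hsv[ring]
    med = np.median(vals, axis=0)
    return (float(med[0]), float(med[1]), float(med[2]))


def detect_background(slide_image: np.ndarray, cfg: TissueMaskConfig | None = None) -> np.ndarray:
    """Binary tissue mask: 1 on tissue, 0 on glass background.

    With ``cfg.background_hsv`` unset, the background envelope is the default
    low-saturation/high-value box, widened around the border-learned center.
    Enclosed holes inside tissue are filled when ``cfg.enclosure_fill``.
    """
    if slide_image.size == 0:
        raise ValueError("empty slide image")
    cfg = cfg or TissueMaskConfig()
    hsv = rgb2hsv(slide_image)
    s, v = hsv[..., 1], hsv[..., 2]
    if cfg.background_hsv is not None:
        c = np.asarray(cfg.background_hsv)
        t = np.asarray(cfg.background_tolerance)
        dh = np.minimum(np.abs(hsv[..., 0] - c[0]), 1.0 - np.abs(hsv[..., 0] - c[0]))
        bg = (dh <= t[0]) & (np.abs(s - c[1]) <= t[1]) & (np.abs(v - c[2]) <= t[2])
    else:
        bg = (s <= cfg.max_background_saturation) & (v >= cfg.min_background_value)
    tissue = ~bg
    if cfg.enclosure_fill:
        tissue = ndi.binary_fill_holes(tissue)
    return tissue


def extract_sections(
    slide_image: np.ndarray,
    mask: np.ndarray,
    cfg: TissueMaskConfig | None = None,
    slide_id: str = "slide",
    stain: str = "HE",
    mpp: float = 0.25,
) -> list[Section]:
    """Connected tissue components meeting the size requirement, each cropped
    to its bounding box with background pixels zeroed; ordered by (row0, col0)."""
    cfg = cfg or TissueMaskConfig()
    if stain not in STAINS:
        raise ValueError(f"unknown stain {stain!r}")
    labels, _ = ndi.label(mask, structure=np.ones((3, 3), dtype=int))
    sections: list[Section] = []
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        if comp.sum() < cfg.min_section_area_px:
            continue
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        crop = slide_image[r0:r1, c0:c1].copy()
        crop[~comp] = 0
        sections.append(Section(slide_id, stain, (r0, c0, r1, c1), comp, crop, mpp))
    sections.sort(key=lambda s: (s.bbox[0], s.bbox[1]))
    return sections


def match_sections(
    he_sections: list[Section],
    ihc_sections: list[Section],
    slide_shapes: tuple[tuple[int, int], tuple[int, int]] | None = None,
    manual_overrides: dict[int, int] | None = None,
) -> list[SectionPairCandidate]:
    """Pair H&E with IHC sections by greedy nearest-centroid matching.

    Centroids are normalized by each slide's extent so slides scanned at
    different canvas sizes still match by layout.  ``manual_overrides`` maps
    H&E section index to IHC section index and takes precedence; duplicate
    manual targets are an error.  Unmatched sections on either side become
    discarded candidates with reason "unmatched".
    """
    manual_overrides = manual_overrides or {}
    if len(set(manual_overrides.values())) != len(manual_overrides):
        raise ValueError("duplicate manual assignment")

    def norm_centroids(secs: list[Section], shape_hint) -> np.ndarray:
        if not secs:
            return np.zeros((0, 2))
        cents = np.array([s.centroid_slide for s in secs], dtype=np.float64)
        if shape_hint is not None:
            extent = np.asarray(shape_hint, dtype=np.float64)
        else:
            extent = np.array([max(s.bbox[2] for s in secs), max(s.bbox[3] for s in secs)], dtype=np.float64)
        return cents / extent

    he_c = norm_centroids(he_sections, slide_shapes[0] if slide_shapes else None)
    ihc_c = norm_centroids(ihc_sections, slide_shapes[1] if slide_shapes else None)

    pairs: list[SectionPairCandidate] = []
    used_he: set[int] = set()
    used_ihc: set[int] = set()
    for i, j in manual_overrides.items():
        pairs.append(SectionPairCandidate(he_sections[i], ihc_sections[j], match_method="manual"))
        used_he.add(i)
        used_ihc.add(j)

    # greedy globally-closest pairing over remaining sections
    cand = [
        (float(np.hypot(*(he_c[i] - ihc_c[j]))), i, j)
        for i in range(len(he_sections))
        if i not in used_he
        for j in range(len(ihc_sections))
        if j not in used_ihc
    ]
    for d, i, j in sorted(cand):
        if i in used_he or j in used_ihc:
            continue
        pairs.append(SectionPairCandidate(he_sections[i], ihc_sections[j]))
        used_he.add(i)
        used_ihc.add(j)
    for i, s in enumerate(he_sections):
        if i not in used_he:
            pairs.append(SectionPairCandidate(s, None, status="discarded", discard_reason="unmatched"))
    for j, s in enumerate(ihc_sections):
        if j not in used_ihc:
            pairs.append(SectionPairCandidate(None, s, status="discarded", discard_reason="unmatched"))
    return pairs


def read_slide(path: str | Path) -> np.ndarray:
    """Read a slide image (plain TIFF/PNG, or the highest-resolution level of
    a pyramidal TIFF) as an RGB uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff", ".svs"):
        import tifffile

        arr = tifffile.imread(path, level=0) if _is_pyramidal(path) else tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr[..., :3].astype(np.uint8)


def _is_pyramidal(path: Path) -> bool:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            return len(tf.series) > 0 and len(tf.series[0].levels) > 1
    except Exception:
        return False


def write_sections(
    out_dir: str | Path,
    pairs: list[SectionPairCandidate],
    case_id: str,
    patient_id: str,
) -> pd.DataFrame:
    """Persist per-section crops + masks and return the manifest table."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, p in enumerate(pairs):
        for role, sec in (("he", p.he), ("ihc", p.ihc)):
            if sec is None:
                continue
            stem = f"{case_id}_pair{k}_{role}"
            if p.status == "kept":
                Image.fromarray(sec.image).save(out / f"{stem}.png")
                Image.fromarray((sec.mask * 255).astype(np.uint8)).save(out / f"{stem}_mask.png")
            rows.append(
                {
                    "case_id": case_id,
                    "patient_id": patient_id,
                    "pair_index": k,
                    "role": role,
                    "stain": sec.stain,
                    "bbox_row0": sec.bbox[0],
                    "bbox_col0": sec.bbox[1],
                    "bbox_row1": sec.bbox[2],
                    "bbox_col1": sec.bbox[3],
                    "status": p.status,
                    "discard_reason": p.discard_reason,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / f"{case_id}_manifest.csv", index=False)
    return df
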