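"""Synthetic paired H&E / IHC sections with known melanocyte ground truth.

Archival melanoma-in-situ slide pairs cannot be redistributed, so every
stage of the pipeline is exercised on rendered stand-ins instead: a tissue
ellipse populated with keratinocytes everywhere and a clustered "lesion" of
melanocytes, composed in optical-density space with the shared
Ruifrok-Johnston stain vectors (:mod:`virtualstain.stains`) and rendered to
RGB.  The H&E rendition shows all nuclei in hematoxylin plus an eosin
background, with melanocytes distinguished by larger nuclei and a
perinuclear clearing halo; the IHC rendition adds DAB chromogen on
melanocyte nuclei (nuclear mode, SOX10-like) or cytoplasm (cytoplasmic
mode, MelanA-like) over a hematoxylin counterstain, and is displaced by a
known affine (plus optional smooth) warp to emulate serial-section
misalignment.  Ink and hemorrhage patches can be planted as artifacts.

Everything is deterministic per seed and the ground truth records planted
cell coordinates, masks and the exact warp, so downstream modules can be
scored against it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .stains import render_from_od

__all__ = [
    "Misalignment",
    "ArtifactSpec",
    "FixtureSpec",
    "GroundTruth",
    "AffineWarp",
    "generate_section_pair",
    "make_negative_tiles",
    "make_study",
    "compose_slide",
    "write_fixture",
]

TILE = 256

# optical densities of the rendered chromophores; melanocytes get markedly
# hyperchromatic nuclei (the atypia cue a dermatopathologist keys on)
_OD_NUCLEUS_KERA = 0.55
_OD_NUCLEUS_MEL = 1.1
_OD_EOSIN_BASE = 0.35
_OD_EOSIN_HALO = 0.08
_OD_COUNTERSTAIN = 0.50
_OD_DAB_NUCLEAR = 1.0
_OD_DAB_CYTO = 0.8


@dataclass(frozen=True)
class Misalignment:
    """Rigid/similarity displacement of the IHC frame plus optional smooth warp.

    Defaults are large enough that naive (unaligned) tiling mislabels tiles,
    yet recoverable by the default registrar.
    """

    tx: float = 15.0
    ty: float = -7.0
    rotation_deg: float = 3.0
    scale: float = 1.0
    warp_amplitude_px: float = 0.0

    def validate(self) -> None:
        if self.scale <= 0:
            raise ValueError("misalignment scale must be > 0 (invertible)")
        if self.warp_amplitude_px < 0:
            raise ValueError("warp amplitude must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """Counts and HSV ranges for planted slide artifacts.

    Ink hue defaults cover marker-pen blue; hue is in degrees.
    """

    n_ink: int = 0
    n_hemorrhage: int = 0
    ink_hue_deg: tuple[float, float] = (200.0, 260.0)
    ink_sat: tuple[float, float] = (0.55, 0.95)
    ink_val: tuple[float, float] = (0.35, 0.8)
    hemorrhage_hue_deg: tuple[float, float] = (0.0, 12.0)
    patch_radius_px: tuple[int, int] = (18, 36)
    hemorrhage_radius_px: tuple[int, int] = (26, 42)


@dataclass(frozen=True)
class FixtureSpec:
    """Full parameterization of one rendered section pair."""

    section_height_px: int = 640
    section_width_px: int = 640
    mpp: float = 0.25
    n_melanocytes: int = 25
    melanocyte_nucleus_radius_px: int = 9
    cytoplasm_radius_px: int = 16
    n_keratinocytes: int = 160
    keratinocyte_nucleus_radius_px: int = 6
    ihc_mode: str = "cytoplasmic"  # or "nuclear"
    misalignment: Misalignment = field(default_factory=Misalignment)
    artifact_spec: ArtifactSpec = field(default_factory=ArtifactSpec)
    background_value: tuple[int, int, int] = (247, 246, 248)
    lesion_radius_frac: float = 0.32
    #: melanocytes grow in junctional nests of this size range; nests are
    #: scattered within the lesion, so different positive tiles carry
    #: salient cell clusters at different positions
    nest_size: tuple[int, int] = (3, 6)
    nest_radius_px: int = 40
    noise_sigma_od: float = 0.02
    tissue: str = "ellipse"  # or "full" (tissue fills the frame, for tiles)
    seed: int = 0

    def validate(self) -> None:
        if self.ihc_mode not in ("nuclear", "cytoplasmic"):
            raise ValueError(f"unknown ihc_mode {self.ihc_mode!r}")
        if self.melanocyte_nucleus_radius_px <= 0 or self.cytoplasm_radius_px <= 0:
            raise ValueError("radii must be > 0")
        if self.cytoplasm_radius_px <= self.melanocyte_nucleus_radius_px:
            raise ValueError("cytoplasm radius must exceed nucleus radius")
        if self.n_melanocytes < 0 or self.n_keratinocytes < 0:
            raise ValueError("cell counts must be >= 0")
        if self.tissue not in ("ellipse", "full"):
            raise ValueError(f"unknown tissue mode {self.tissue!r}")
        self.misalignment.validate()


class AffineWarp:
    """Similarity transform (optionally plus a smooth residual field) mapping
    IHC pixel coordinates to H&E pixel coordinates, row/col convention."""

    def __init__(
        self,
        tx: float,
        ty: float,
        rotation_deg: float,
        scale: float,
        center: tuple[float, float],
        displacement: np.ndarray | None = None,
    ):
        self.tx = tx
        self.ty = ty
        self.rotation_deg = rotation_deg
        self.scale = scale
        self.center = center
        self.displacement = displacement  # (2, H, W) residual added to the affine map

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (row, col, 1) IHC coordinates."""
        th = np.deg2rad(self.rotation_deg)
        rot = self.scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cr, cc = self.center
        c = np.array([cr, cc])
        t = np.array([self.ty, self.tx])
        offset = c + t - rot @ c
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = offset
        return m

    def map_points(self, points_ihc: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of IHC (row, col) points into the H&E frame."""
        pts = np.asarray(points_ihc, dtype=np.float64)
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        if self.displacement is not None:
            h, w = self.displacement.shape[1:]
            r = np.clip(pts[:, 0], 0, h - 1)
            c = np.clip(pts[:, 1], 0, w - 1)
            dr = ndi.map_coordinates(self.displacement[0], [r, c], order=1)
            dc = ndi.map_coordinates(self.displacement[1], [r, c], order=1)
            out = out + np.stack([dr, dc], axis=1)
        return out

    def coordinate_grid(self, shape: tuple[int, int]) -> np.ndarray:
        """H&E-frame sample coordinates for every IHC pixel; shape (2, H, W)."""
        h, w = shape
        rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
        m = self.matrix
        out_r = m[0, 0] * rr + m[0, 1] * cc + m[0, 2]
        out_c = m[1, 0] * rr + m[1, 1] * cc + m[1, 2]
        grid = np.stack([out_r, out_c])
        if self.displacement is not None:
            grid = grid + self.displacement
        return grid

    def params(self) -> dict:
        return {
            "tx": self.tx,
            "ty": self.ty,
            "rotation_deg": self.rotation_deg,
            "scale": self.scale,
            "center": list(self.center),
        }


@dataclass
class GroundTruth:
    """Everything the generator knows about what it planted."""

    melanocyte_centers: np.ndarray  # (n, 2) row/col in the H&E frame
    nucleus_labels: np.ndarray  # int32, H&E frame; label i+1 = melanocyte i's nucleus
    cytoplasm_labels: np.ndarray  # int32, H&E frame; annular cytoplasm per melanocyte
    dab_mask_he: np.ndarray  # bool, planted DAB in the H&E (scene) frame
    dab_mask_ihc: np.ndarray  # bool, planted DAB as it appears in the IHC frame
    tissue_mask_he: np.ndarray
    tissue_mask_ihc: np.ndarray
    ink_mask_ihc: np.ndarray
    hemorrhage_mask_ihc: np.ndarray
    true_warp: AffineWarp  # maps IHC frame -> H&E frame


def _place_cells(
    rng: np.random.Generator,
    region_mask: np.ndarray,
    n: int,
    min_dist: float,
    taken: list[np.ndarray],
    taken_min_dist: float | None = None,
) -> np.ndarray:
    """Rejection-sample ``n`` centers inside ``region_mask`` keeping ``min_dist``
    from each other and ``taken_min_dist`` from previously placed centers."""
    valid = np.argwhere(region_mask)
    if len(valid) == 0 and n > 0:
        raise ValueError("overcrowded fixture")
    if taken_min_dist is None:
        taken_min_dist = min_dist
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * max(n, 1)
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("overcrowded fixture")
        cand = valid[rng.integers(len(valid))].astype(np.float64)
        ok = all(np.hypot(*(cand - c)) >= min_dist for c in centers) and all(
            np.hypot(*(cand - c)) >= taken_min_dist for c in taken
        )
        if ok:
            centers.append(cand)
    return np.array(centers, dtype=np.float64).reshape(len(centers), 2)


def _place_nested_cells(
    rng: np.random.Generator, lesion_mask: np.ndarray, spec: "FixtureSpec", min_dist: float
) -> np.ndarray:
    """Place melanocytes as tight nests scattered within the lesion."""
    n = spec.n_melanocytes
    if n == 0:
        return np.zeros((0, 2))
    if not lesion_mask.any():
        raise ValueError("overcrowded fixture")
    h, w = lesion_mask.shape
    centers: list[np.ndarray] = []
    nest_centers: list[np.ndarray] = []
    valid = np.argwhere(lesion_mask)
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("overcrowded fixture")
        nest_c = valid[rng.integers(len(valid))].astype(np.float64)
        # nests keep their distance so tiles see discrete clusters; on tiny
        # sections where separated nests no longer fit, relax the spacing
        # rather than fail (cell-level min distance still holds)
        relaxed = attempts > 100 * n
        if not relaxed and any(np.hypot(*(nest_c - c)) < 2.2 * spec.nest_radius_px for c in nest_centers):
            continue
        nest_centers.append(nest_c)
        size = int(rng.integers(spec.nest_size[0], spec.nest_size[1] + 1))
        placed = 0
        cell_tries = 0
        while placed < size and len(centers) < n and cell_tries < 200:
            cell_tries += 1
            offset = rng.uniform(-spec.nest_radius_px, spec.nest_radius_px, size=2)
            cand = nest_c + offset
            r, c = int(round(cand[0])), int(round(cand[1]))
            if not (0 <= r < h and 0 <= c < w) or not lesion_mask[r, c]:
                continue
            if np.hypot(*offset) > spec.nest_radius_px:
                continue
            if any(np.hypot(*(cand - cc)) < min_dist for cc in centers):
                continue
            centers.append(cand)
            placed += 1
    return np.array(centers, dtype=np.float64).reshape(len(centers), 2)


def _paint_disk(arr: np.ndarray, center: np.ndarray, radius: float, value: float) -> None:
    rr, cc = draw_disk(tuple(center), radius, shape=arr.shape)
    arr[rr, cc] = np.maximum(arr[rr, cc], value)


def _quantize(rgb_float: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(rgb_float, 0, 255)).astype(np.uint8)


def generate_section_pair(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render one matched H&E / IHC section pair plus its ground truth.

    Returns ``(he_image, ihc_image, truth)`` with uint8 RGB images.  The IHC
    image lives in its own frame, displaced from the H&E frame by
    ``spec.misalignment``; ``truth.true_warp`` maps IHC coordinates back to
    H&E coordinates.
    """
    spec.validate()
    h, w = spec.section_height_px, spec.section_width_px
    rng = np.random.default_rng(spec.seed)

    # --- tissue support -------------------------------------------------
    tissue = np.zeros((h, w), dtype=bool)
    if spec.tissue == "ellipse":
        margin = max(6, min(h, w) // 32)
        rr, cc = draw_ellipse(h / 2, w / 2, h / 2 - margin, w / 2 - margin, shape=(h, w))
        tissue[rr, cc] = True
    else:
        tissue[:] = True

    # feasibility: planted disks must not dominate the tissue
    cell_area = (
        spec.n_melanocytes * np.pi * spec.cytoplasm_radius_px**2
        + spec.n_keratinocytes * np.pi * spec.keratinocyte_nucleus_radius_px**2
    )
    if cell_area > 0.55 * tissue.sum():
        raise ValueError("overcrowded fixture")

    # --- cell placement -------------------------------------------------
    interior = ndi.binary_erosion(tissue, iterations=spec.cytoplasm_radius_px + 2)
    lesion_mask = np.zeros_like(tissue)
    if spec.n_melanocytes > 0:
        lesion_r = spec.lesion_radius_frac * min(h, w)
        cand = np.argwhere(interior)
        lc = cand[rng.integers(len(cand))].astype(np.float64)
        rr, cc = draw_disk(tuple(lc), lesion_r, shape=(h, w))
        lesion_mask[rr, cc] = True
        lesion_mask &= interior
    mel_min_dist = 2.0 * spec.melanocyte_nucleus_radius_px + 4
    mel_centers = _place_nested_cells(rng, lesion_mask, spec, mel_min_dist)
    ker_min_dist = 2.0 * spec.keratinocyte_nucleus_radius_px + 2
    ker_centers = _place_cells(
        rng,
        interior,
        spec.n_keratinocytes,
        ker_min_dist,
        list(mel_centers),
        taken_min_dist=spec.cytoplasm_radius_px + spec.keratinocyte_nucleus_radius_px + 2,
    )

    # --- compose the H&E-frame scene in OD space ------------------------
    hema = np.zeros((h, w))
    eosin = np.zeros((h, w))
    dab = np.zeros((h, w))

    eosin[tissue] = _OD_EOSIN_BASE
    # low-frequency eosin texture
    tex = ndi.gaussian_filter(rng.standard_normal((h, w)), 25)
    tex /= max(np.abs(tex).max(), 1e-9)
    eosin[tissue] *= 1.0 + 0.15 * tex[tissue]
    hema[tissue] = 0.04

    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    cytoplasm_labels = np.zeros((h, w), dtype=np.int32)
    for c in ker_centers:
        _paint_disk(hema, c, spec.keratinocyte_nucleus_radius_px, _OD_NUCLEUS_KERA)
    for i, c in enumerate(mel_centers):
        rr, cc = draw_disk(tuple(c), spec.cytoplasm_radius_px, shape=(h, w))
        cyto = np.zeros((h, w), dtype=bool)
        cyto[rr, cc] = True
        rr, cc = draw_disk(tuple(c), spec.melanocyte_nucleus_radius_px, shape=(h, w))
        nuc = np.zeros((h, w), dtype=bool)
        nuc[rr, cc] = True
        cyto &= ~nuc
        nucleus_labels[nuc] = i + 1
        cytoplasm_labels[cyto] = i + 1
        hema[nuc] = np.maximum(hema[nuc], _OD_NUCLEUS_MEL)
        eosin[cyto] = _OD_EOSIN_HALO  # perinuclear clearing, the H&E cue

    # IHC-frame chromogens (composed in the H&E frame, then warped)
    counter = np.zeros((h, w))
    counter[tissue] = 0.04
    counter[nucleus_labels > 0] = _OD_COUNTERSTAIN
    for c in ker_centers:
        _paint_disk(counter, c, spec.keratinocyte_nucleus_radius_px, _OD_COUNTERSTAIN)
    if spec.ihc_mode == "nuclear":
        dab[nucleus_labels > 0] = _OD_DAB_NUCLEAR
    else:
        dab[cytoplasm_labels > 0] = _OD_DAB_CYTO
        dab[nucleus_labels > 0] = 0.3 * _OD_DAB_CYTO  # faint nuclear bleed-through
    dab_mask_he = dab > 0.05

    noise = lambda: spec.noise_sigma_od * rng.standard_normal((h, w))  # noqa: E731

    he_od = np.stack(
        [
            np.maximum(hema + noise(), 0),
            np.maximum(eosin + noise(), 0),
            np.zeros((h, w)),
        ],
        axis=-1,
    )
    # near-white background tint is applied multiplicatively in RGB, i.e. a
    # small constant absorption not aligned to any stain vector
    he_rgb = render_from_od(he_od)
    he_rgb *= np.asarray(spec.background_value, dtype=np.float64) / 255.0
    he_image = _quantize(he_rgb)

    # hematoxylin counterstain wash tints all tissue on a real IHC slide
    counter[tissue] = np.maximum(counter[tissue], 0.10)
    ihc_od_scene = np.stack(
        [
            np.maximum(counter + noise(), 0),
            np.maximum(0.15 * tissue * (1.0 + 0.15 * tex) + noise(), 0),
            np.maximum(dab + noise(), 0),
        ],
        axis=-1,
    )

    # --- displace into the IHC frame ------------------------------------
    mis = spec.misalignment
    displacement = None
    if mis.warp_amplitude_px > 0:
        dr = ndi.gaussian_filter(rng.standard_normal((h, w)), 40)
        dc = ndi.gaussian_filter(rng.standard_normal((h, w)), 40)
        for d in (dr, dc):
            d /= max(np.abs(d).max(), 1e-9)
            d *= mis.warp_amplitude_px
        displacement = np.stack([dr, dc])
    warp = AffineWarp(mis.tx, mis.ty, mis.rotation_deg, mis.scale, ((h - 1) / 2.0, (w - 1) / 2.0), displacement)
    grid = warp.coordinate_grid((h, w))

    ihc_od = np.stack(
        [ndi.map_coordinates(ihc_od_scene[..., k], grid, order=1, mode="constant", cval=0.0) for k in range(3)],
        axis=-1,
    )
    tissue_ihc = ndi.map_coordinates(tissue.astype(np.float64), grid, order=0, mode="constant", cval=0.0) > 0.5
    dab_mask_ihc = ndi.map_coordinates(dab_mask_he.astype(np.float64), grid, order=0, mode="constant", cval=0.0) > 0.5

    ihc_rgb = render_from_od(ihc_od)
    ihc_rgb *= np.asarray(spec.background_value, dtype=np.float64) / 255.0

    # --- artifacts (painted in RGB on the IHC rendition) ----------------
    ink_mask = np.zeros((h, w), dtype=bool)
    hem_mask = np.zeros((h, w), dtype=bool)
    art = spec.artifact_spec
    for _ in range(art.n_ink):
        ink_mask |= _paint_hsv_patch(ihc_rgb, rng, art.ink_hue_deg, art.ink_sat, art.ink_val, art.patch_radius_px, None)
    for _ in range(art.n_hemorrhage):
        hem_mask |= _paint_hsv_patch(
            ihc_rgb, rng, art.hemorrhage_hue_deg, (0.72, 0.95), (0.25, 0.45), art.hemorrhage_radius_px, tissue_ihc
        )
    ihc_image = _quantize(ihc_rgb)

    truth = GroundTruth(
        melanocyte_centers=mel_centers,
        nucleus_labels=nucleus_labels,
        cytoplasm_labels=cytoplasm_labels,
        dab_mask_he=dab_mask_he,
        dab_mask_ihc=dab_mask_ihc,
        tissue_mask_he=tissue,
        tissue_mask_ihc=tissue_ihc,
        ink_mask_ihc=ink_mask,
        hemorrhage_mask_ihc=hem_mask,
        true_warp=warp,
    )
    return he_image, ihc_image, truth


def _paint_hsv_patch(
    rgb: np.ndarray,
    rng: np.random.Generator,
    hue_deg: tuple[float, float],
    sat: tuple[float, float],
    val: tuple[float, float],
    radius_range: tuple[int, int],
    within: np.ndarray | None,
) -> np.ndarray:
    """Paint one rough disk-shaped patch of an HSV-range color; returns its mask."""
    h, w = rgb.shape[:2]
    radius = rng.integers(radius_range[0], radius_range[1] + 1)
    if within is not None and within.any():
        cand = np.argwhere(within)
        center = cand[rng.integers(len(cand))]
    else:
        center = np.array([rng.integers(radius, h - radius), rng.integers(radius, w - radius)])
    hsv = np.array(
        [
            rng.uniform(*hue_deg) / 360.0,
            rng.uniform(*sat),
            rng.uniform(*val),
        ]
    )
    color = hsv_to_rgb(hsv) * 255.0
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_disk(tuple(center.astype(float)), radius, shape=(h, w))
    mask[rr, cc] = True
    # opaque pigment with slight per-pixel brightness texture
    jitter = 1.0 + 0.04 * rng.standard_normal((int(mask.sum()), 1))
    rgb[mask] = np.clip(color * jitter, 0, 255)
    return mask


def make_negative_tiles(n: int, seed: int = 0) -> list[np.ndarray]:
    """Melanocyte-free H&E-like 256x256 tiles, a stand-in for non-cutaneous
    negative tissue.  Both tile labelers score them 0 (no DAB is rendered)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    tiles = []
    for i in range(n):
        spec = FixtureSpec(
            section_height_px=TILE,
            section_width_px=TILE,
            n_melanocytes=0,
            n_keratinocytes=24,
            tissue="full",
            misalignment=Misalignment(0, 0, 0, 1.0),
            seed=(seed * 1_000_003 + 7919 * i) % (2**31),
        )
        he, _, _ = generate_section_pair(spec)
        tiles.append(he)
    return tiles


def make_fraction_tile(fraction: float, seed: int = 0) -> tuple[np.ndarray, int]:
    """Render a 256x256 cytoplasmic-mode IHC tile whose planted DAB-positive
    area is the smallest pixel count with ``count / 256**2 >= fraction``.

    Returns ``(tile_rgb_uint8, planted_pixel_count)``.  Used to sweep the
    area-fraction labeling rule against known ground truth.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    h = w = TILE
    n_target = int(np.ceil(fraction * h * w))
    # quasi-disk of exactly n_target pixels: order pixels by distance to a
    # random interior center and take the nearest n_target
    center = rng.uniform(0.3, 0.7, size=2) * (h, w)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    dab_mask = np.zeros(h * w, dtype=bool)
    dab_mask[order[:n_target]] = True
    dab_mask = dab_mask.reshape(h, w)

    hema = np.full((h, w), 0.08)
    for _ in range(20):
        c = rng.uniform(8, h - 8, size=2)
        rr2, cc2 = draw_disk(tuple(c), 6, shape=(h, w))
        hema[rr2, cc2] = _OD_COUNTERSTAIN
    dab = np.where(dab_mask, _OD_DAB_CYTO, 0.0)
    noise = 0.02 * rng.standard_normal((h, w, 3))
    od = np.stack([hema, np.full((h, w), 0.15), dab], axis=-1)
    od = np.maximum(od + noise, 0)
    return _quantize(render_from_od(od)), int(n_target)


def make_nuclei_tile(n_nuclei: int, seed: int = 0, nucleus_radius_px: int = 9) -> np.ndarray:
    """Render a 256x256 nuclear-mode IHC tile with exactly ``n_nuclei``
    well-separated DAB-positive nuclei over a hematoxylin counterstain.

    Used to sweep the nucleus-count labeling rule against known ground
    truth.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    h = w = TILE
    margin = nucleus_radius_px + 4
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_nuclei:
        tries += 1
        if tries > 500 * max(n_nuclei, 1):
            raise ValueError("overcrowded fixture")
        cand = rng.uniform(margin, h - margin, size=2)
        if all(np.hypot(*(cand - c)) >= 3 * nucleus_radius_px for c in centers):
            centers.append(cand)
    hema = np.full((h, w), 0.08)
    dab = np.zeros((h, w))
    for c in centers:
        rr, cc = draw_disk(tuple(c), nucleus_radius_px, shape=(h, w))
        dab[rr, cc] = _OD_DAB_NUCLEAR
        hema[rr, cc] = _OD_COUNTERSTAIN
    # DAB-negative bystander nuclei
    for _ in range(15):
        c = rng.uniform(margin, h - margin, size=2)
        if any(np.hypot(*(c - cc)) < 3 * nucleus_radius_px for cc in centers):
            continue
        rr, cc = draw_disk(tuple(c), 6, shape=(h, w))
        hema[rr, cc] = _OD_COUNTERSTAIN
    od = np.stack([hema, np.full((h, w), 0.15), dab], axis=-1)
    od = np.maximum(od + 0.02 * rng.standard_normal((h, w, 3)), 0)
    return _quantize(render_from_od(od))


@dataclass
class PairFixture:
    """One patient's matched section pair plus ground truth."""

    patient_id: str
    pair_id: str
    stain: str  # HE partner stain: "SOX10" or "MelanA"
    spec: FixtureSpec
    he_image: np.ndarray
    ihc_image: np.ndarray
    truth: GroundTruth


def make_study(
    n_patients: int = 10,
    ihc_mode: str = "cytoplasmic",
    seed: int = 0,
    section_px: int = 768,
    n_melanocytes: int = 35,
    n_keratinocytes: int = 230,
) -> list[PairFixture]:
    """Generate the default synthetic study: one section pair per patient.

    The per-patient layouts differ (seeded) but share the study-level
    conditions: section size, cell counts, default misalignment.
    """
    stain = "SOX10" if ihc_mode == "nuclear" else "MelanA"
    out = []
    for i in range(n_patients):
        spec = FixtureSpec(
            section_height_px=section_px,
            section_width_px=section_px,
            n_melanocytes=n_melanocytes,
            n_keratinocytes=n_keratinocytes,
            ihc_mode=ihc_mode,
            seed=(seed * 1_000_003 + 104729 * (i + 1)) % (2**31),
        )
        he, ihc, truth = generate_section_pair(spec)
        out.append(PairFixture(f"P{i:02d}", f"P{i:02d}-pair0", stain, spec, he, ihc, truth))
    return out


def compose_slide(
    section_images: list[np.ndarray],
    offsets: list[tuple[int, int]],
    slide_shape: tuple[int, int],
    background_value: tuple[int, int, int] = (250, 249, 251),
) -> np.ndarray:
    """Paste rendered sections onto a near-white slide canvas (for testing
    whole-slide background detection and section extraction)."""
    h, w = slide_shape
    slide = np.ones((h, w, 3), dtype=np.uint8) * np.asarray(background_value, dtype=np.uint8)
    for img, (r0, c0) in zip(section_images, offsets):
        sh, sw = img.shape[:2]
        if r0 < 0 or c0 < 0 or r0 + sh > h or c0 + sw > w:
            raise ValueError("section does not fit on the slide")
        slide[r0 : r0 + sh, c0 : c0 + sw] = img
    return slide


def write_fixture(out_dir: str | Path, pair: PairFixture) -> None:
    """Persist one fixture pair: PNG images, PNG masks, JSON ground truth."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    Image.fromarray(pair.he_image).save(out / f"{pair.pair_id}_he.png")
    Image.fromarray(pair.ihc_image).save(out / f"{pair.pair_id}_ihc.png")
    Image.fromarray((pair.truth.dab_mask_ihc * 255).astype(np.uint8)).save(out / f"{pair.pair_id}_dab_ihc.png")
    Image.fromarray((pair.truth.tissue_mask_he * 255).astype(np.uint8)).save(out / f"{pair.pair_id}_tissue_he.png")
    meta = {
        "patient_id": pair.patient_id,
        "pair_id": pair.pair_id,
        "stain": pair.stain,
        "spec": _spec_dict(pair.spec),
        "melanocyte_centers": pair.truth.melanocyte_centers.tolist(),
        "true_warp": pair.truth.true_warp.params(),
    }
    (out / f"{pair.pair_id}_truth.json").write_text(json.dumps(meta, indent=1))


def _spec_dict(spec: FixtureSpec) -> dict:
    d = dataclasses.asdict(spec)
    return d
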