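"""Section-pair registration: align IHC onto H&E and gate by alignment score.

Serial sections differ by a global placement (translation, rotation, slight
scale) plus smooth elastic distortion from cutting and mounting.  The
built-in registrar recovers the similarity part by an exhaustive rotation /
scale grid with per-candidate translation from phase correlation, selected
by masked normalized cross-correlation (NCC) of inverted luminance, then
refines with a coarse B-spline control grid fit by gradient-free coordinate
descent on masked squared differences.  Alternative engines (e.g. wrappers
around external elastic-registration tools) can be plugged in behind the
same :class:`Registrar` protocol.

Alignment quality is the masked NCC in [-1, 1]; pairs below the acceptance
threshold are gated out of training, mirroring how poorly matched archival
slide pairs must be discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.measure import block_reduce
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

__all__ = [
    "RegistrationConfig",
    "Deformation",
    "AlignmentResult",
    "BuiltinRegistrar",
    "align_pair",
    "gate_pairs",
    "gating_report",
    "split_oversize",
    "foreground_mask",
]


@dataclass(frozen=True)
class RegistrationConfig:
    rotation_range_deg: float = 8.0
    rotation_coarse_step_deg: float = 1.0
    rotation_fine_step_deg: float = 0.1
    scales: tuple[float, ...] = (1.0,)
    search_max_dim: int = 320
    use_bspline: bool = True
    bspline_grid: tuple[int, int] = (8, 8)
    bspline_max_evals: int = 200
    bspline_step_px: float = 3.0
    accept_threshold: float = 0.5
    min_overlap_px: int = 500


class Deformation:
    """Total recovered transform: H&E coordinates -> IHC coordinates.

    ``x_ihc = A @ (x_he, 1) + D(x_he)`` with ``A`` an affine (row/col
    homogeneous) matrix and ``D`` an optional dense residual displacement.
    """

    def __init__(self, matrix: np.ndarray, displacement: np.ndarray | None = None):
        self.matrix = np.asarray(matrix, dtype=np.float64)
        self.displacement = displacement

    def coordinate_grid(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        rr, cc = np.meshgrid(np.arange(h, dtype=np.float64), np.arange(w, dtype=np.float64), indexing="ij")
        m = self.matrix
        grid = np.stack([m[0, 0] * rr + m[0, 1] * cc + m[0, 2], m[1, 0] * rr + m[1, 1] * cc + m[1, 2]])
        if self.displacement is not None:
            d = self.displacement
            if d.shape[1:] != shape:
                d = np.stack([resize(d[k], shape, order=1, mode="edge", anti_aliasing=False) for k in range(2)])
            grid = grid + d
        return grid

    def map_points(self, points_he: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_he, dtype=np.float64)
        out = pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]
        if self.displacement is not None:
            h, w = self.displacement.shape[1:]
            r = np.clip(pts[:, 0], 0, h - 1)
            c = np.clip(pts[:, 1], 0, w - 1)
            out[:, 0] += ndi.map_coordinates(self.displacement[0], [r, c], order=1)
            out[:, 1] += ndi.map_coordinates(self.displacement[1], [r, c], order=1)
        return out

    def warp_image(self, ihc_image: np.ndarray, output_shape: tuple[int, int], order: int = 1) -> np.ndarray:
        """Resample an IHC-frame image into the H&E frame."""
        grid = self.coordinate_grid(output_shape)
        if ihc_image.ndim == 2:
            return ndi.map_coordinates(ihc_image.astype(np.float64), grid, order=order, mode="constant", cval=0.0)
        chans = [
            ndi.map_coordinates(ihc_image[..., k].astype(np.float64), grid, order=order, mode="constant", cval=0.0)
            for k in range(ihc_image.shape[-1])
        ]
        out = np.stack(chans, axis=-1)
        if ihc_image.dtype == np.uint8:
            out = np.rint(np.clip(out, 0, 255)).astype(np.uint8)
        return out

    def params(self) -> dict:
        """Similarity decomposition of the affine part (rotation in degrees,
        scale, and the translation of the frame center)."""
        m = self.matrix
        rot = float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0])))
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        return {"rotation_deg": rot, "scale": scale, "matrix": m.tolist()}


@dataclass
class AlignmentResult:
    warped_ihc: np.ndarray
    deformation: Deformation
    score: float
    engine: str = "builtin"
    accepted: bool = False
    pair_id: str = ""


class Registrar(Protocol):
    name: str

    def register(
        self,
        fixed: np.ndarray,
        moving: np.ndarray,
        fixed_mask: np.ndarray,
        moving_mask: np.ndarray,
        cfg: RegistrationConfig,
    ) -> Deformation: ...


def foreground_mask(image: np.ndarray) -> np.ndarray:
    """Tissue pixels: neither zero padding nor near-white glass."""
    lum = rgb2gray(image) if image.ndim == 3 else image.astype(np.float64) / 255.0
    return (lum > 0.02) & (lum < 0.93)


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray, min_px: int) -> float:
    if mask.sum() < min_px:
        return -1.0
    x = a[mask]
    y = b[mask]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom < 1e-12:
        return -1.0
    return float(np.clip((x * y).sum() / denom, -1.0, 1.0))


def _rot_scale_matrix(theta_deg: float, scale: float, center: tuple[float, float]) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    rot = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = np.asarray(center)
    m = np.eye(3)
    m[:2, :2] = rot
    m[:2, 2] = c - rot @ c
    return m


def _translate(shift_rc: np.ndarray) -> np.ndarray:
    m = np.eye(3)
    m[:2, 2] = shift_rc
    return m


def _warp2d(img: np.ndarray, matrix: np.ndarray, displacement: np.ndarray | None = None) -> np.ndarray:
    return Deformation(matrix, displacement).warp_image(img, img.shape[:2], order=1)


class BuiltinRegistrar:
    """Similarity grid search + coarse B-spline coordinate-descent refinement."""

    name = "builtin"

    def register(self, fixed, moving, fixed_mask, moving_mask, cfg: RegistrationConfig) -> Deformation:
        h, w = fixed.shape
        f = max(1, int(np.ceil(max(h, w) / cfg.search_max_dim)))
        gf = block_reduce(fixed * fixed_mask, (f, f), np.mean)
        gm = block_reduce(moving * moving_mask, (f, f), np.mean)
        mf = block_reduce(fixed_mask.astype(np.float64), (f, f), np.mean) > 0.3
        mm = block_reduce(moving_mask.astype(np.float64), (f, f), np.mean) > 0.3
        center_s = ((gf.shape[0] - 1) / 2.0, (gf.shape[1] - 1) / 2.0)

        def eval_candidate(theta, scale):
            rot_m = _rot_scale_matrix(theta, scale, center_s)
            rotated = _warp2d(gm, rot_m)
            shift, _, _ = phase_cross_correlation(gf, rotated, upsample_factor=4, normalization=None)
            mat = rot_m @ _translate(-shift)
            warped = _warp2d(gm, mat)
            wmask = _warp2d(mm.astype(np.float64), mat) > 0.5
            score = _masked_ncc(gf, warped, mf & wmask, max(16, cfg.min_overlap_px // (f * f)))
            return score, mat, shift

        best = (-np.inf, None, None, 0.0, 1.0)
        thetas = np.arange(
            -cfg.rotation_range_deg, cfg.rotation_range_deg + 1e-9, cfg.rotation_coarse_step_deg
        )
        for s in cfg.scales:
            for th in thetas:
                score, mat, shift = eval_candidate(th, s)
                if score > best[0]:
                    best = (score, mat, shift, th, s)
        th0, s0 = best[3], best[4]
        fine = np.arange(
            th0 - cfg.rotation_coarse_step_deg,
            th0 + cfg.rotation_coarse_step_deg + 1e-9,
            cfg.rotation_fine_step_deg,
        )
        for th in fine:
            score, mat, shift = eval_candidate(th, s0)
            if score > best[0]:
                best = (score, mat, shift, th, s0)
        theta, scale = best[3], best[4]

        # refine translation at full resolution with the chosen rotation/scale
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
        rot_full = _rot_scale_matrix(theta, scale, center)
        rotated_full = _warp2d(moving * moving_mask, rot_full)
        shift, _, _ = phase_cross_correlation(
            fixed * fixed_mask, rotated_full, upsample_factor=10, normalization=None
        )
        affine = rot_full @ _translate(-shift)

        displacement = None
        if cfg.use_bspline:
            affine_s = _scale_matrix(affine, f)
            control = self._fit_bspline(gf, gm, mf, mm, affine_s, cfg)
            if control is not None:
                # control displacements were estimated at the search scale
                displacement = np.stack(
                    [resize(control[k] * f, (h, w), order=3, mode="edge", anti_aliasing=False) for k in range(2)]
                ).astype(np.float32)
        return Deformation(affine, displacement)

    @staticmethod
    def _fit_bspline(gf, gm, mf, mm, affine_s, cfg: RegistrationConfig) -> np.ndarray | None:
        gr, gc = cfg.bspline_grid
        control = np.zeros((2, gr, gc))
        shape = gf.shape

        def cost(ctrl):
            disp = np.stack(
                [resize(ctrl[k], shape, order=3, mode="edge", anti_aliasing=False) for k in range(2)]
            )
            warped = _warp2d(gm, affine_s, disp)
            wmask = _warp2d(mm.astype(np.float64), affine_s, disp) > 0.5
            m = mf & wmask
            if m.sum() < 16:
                return np.inf
            d = (gf - warped)[m]
            return float((d * d).mean())

        best_cost = cost(control)
        step = cfg.bspline_step_px
        evals = 0
        improved_any = False
        while evals < cfg.bspline_max_evals and step >= 0.5:
            improved = False
            for k in range(2):
                for i in range(gr):
                    for j in range(gc):
                        if evals >= cfg.bspline_max_evals:
                            break
                        for sgn in (1.0, -1.0):
                            trial = control.copy()
                            trial[k, i, j] += sgn * step
                            c = cost(trial)
                            evals += 1
                            if c < best_cost - 1e-12:
                                control, best_cost, improved = trial, c, True
                                break
            if improved:
                improved_any = True
            else:
                step /= 2.0
        return control if improved_any else None


def _scale_matrix(m: np.ndarray, f: float) -> np.ndarray:
    """Conjugate an affine (full-res coords) down to coords divided by f."""
    s = np.diag([1.0 / f, 1.0 / f, 1.0])
    si = np.diag([f, f, 1.0])
    return s @ m @ si


def _pad_to(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad an image (bottom/right) to the target shape."""
    out_shape = (shape[0], shape[1]) + img.shape[2:]
    out = np.zeros(out_shape, dtype=img.dtype)
    out[: img.shape[0], : img.shape[1]] = img
    return out


def align_pair(
    he,
    ihc,
    cfg: RegistrationConfig | None = None,
    registrar: Registrar | None = None,
    he_mask: np.ndarray | None = None,
    ihc_mask: np.ndarray | None = None,
    pair_id: str = "",
) -> AlignmentResult:
    """Align an IHC section onto its matched H&E section.

    ``he``/``ihc`` may be RGB arrays or :class:`virtualstain.slides.Section`
    objects.  The smaller image is zero-padded to the size of the larger
    before alignment.  Degenerate optimization (no tissue overlap) yields
    ``score = -1`` and ``accepted = False`` rather than an exception.
    """
    cfg = cfg or RegistrationConfig()
    he_img = he.image if hasattr(he, "image") else np.asarray(he)
    ihc_img = ihc.image if hasattr(ihc, "image") else np.asarray(ihc)
    if he_img.size == 0 or ihc_img.size == 0:
        raise ValueError("empty section image")
    if he_mask is None:
        he_mask = he.mask if hasattr(he, "mask") else foreground_mask(he_img)
    if ihc_mask is None:
        ihc_mask = ihc.mask if hasattr(ihc, "mask") else foreground_mask(ihc_img)

    shape = (max(he_img.shape[0], ihc_img.shape[0]), max(he_img.shape[1], ihc_img.shape[1]))
    he_img = _pad_to(he_img, shape)
    ihc_img = _pad_to(ihc_img, shape)
    he_mask = _pad_to(he_mask.astype(np.uint8), shape).astype(bool)
    ihc_mask = _pad_to(ihc_mask.astype(np.uint8), shape).astype(bool)

    # register on the hematoxylin-deconvolved channel: the nuclear
    # counterstain is the content both stain modalities share, so it is a
    # far better multimodal registration feature than raw luminance
    from .stains import rgb_to_hed

    hf = np.clip(rgb_to_hed(he_img)[..., 0], 0, 1.5) * he_mask
    hm_ = np.clip(rgb_to_hed(ihc_img)[..., 0], 0, 1.5) * ihc_mask

    engine = registrar or BuiltinRegistrar()
    deformation = engine.register(hf, hm_, he_mask, ihc_mask, cfg)

    lf = (1.0 - rgb2gray(he_img)) * he_mask

    warped = deformation.warp_image(ihc_img, shape, order=1)
    wmask = deformation.warp_image(ihc_mask.astype(np.float64), shape, order=1) > 0.5
    score = _masked_ncc(1.0 - rgb2gray(warped), lf, he_mask & wmask, cfg.min_overlap_px)
    return AlignmentResult(
        warped_ihc=warped,
        deformation=deformation,
        score=score,
        engine=getattr(engine, "name", "external"),
        accepted=bool(score >= cfg.accept_threshold),
        pair_id=pair_id,
    )


def gate_pairs(results: list[AlignmentResult], accept_threshold: float | None = None):
    """Partition alignment results into kept/discarded by score threshold."""
    kept, discarded = [], []
    for r in results:
        thr = accept_threshold if accept_threshold is not None else None
        ok = (r.score >= thr) if thr is not None else r.accepted
        (kept if ok else discarded).append(r)
    return kept, discarded


def gating_report(n_candidates: int, n_discarded: int) -> dict:
    """Counts plus the retained percentage, reported to one decimal."""
    if n_candidates <= 0:
        raise ValueError("n_candidates must be > 0")
    n_kept = n_candidates - n_discarded
    return {
        "n_candidates": n_candidates,
        "n_discarded": n_discarded,
        "n_kept": n_kept,
        "retained_pct": round(100.0 * n_kept / n_candidates, 1),
    }


def split_oversize(
    he_img: np.ndarray, ihc_img: np.ndarray, byte_budget: int = 5 * 2**30
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Split a pair whose combined uncompressed size exceeds the budget into
    two vertical halves; otherwise return the pair unchanged."""
    if he_img.nbytes + ihc_img.nbytes <= byte_budget:
        return [(he_img, ihc_img)]
    hh = he_img.shape[0] // 2
    hi = ihc_img.shape[0] // 2
    return [(he_img[:hh], ihc_img[:hi]), (he_img[hh:], ihc_img[hi:])]
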