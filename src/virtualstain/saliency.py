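"""Attribution maps and cross-stain blob agreement statistics.

Two classifiers trained from biologically different weak labels (nuclear
vs. cytoplasmic IHC) can be compared by *where* they look: per-tile
attribution maps are binarized into salient blobs and overlapping blobs
from the two models are scored with IoU and Dice.  A mismatched-pair null
baseline — attributions from two *different* melanocyte-positive tiles —
calibrates the statistic: genuine convergence must beat the (near-zero)
chance overlap of unrelated tiles.

Attribution methods:

* ``guided_gradcam`` — per conv block, the class-activation map (spatial
  ReLU of activation maps weighted by their pooled gradients) is upsampled
  to tile size, averaged across blocks, and gated by the rectified guided-
  backpropagation input gradient.
* ``integrated_gradients`` — Riemann-sum path integral of input gradients
  from a black baseline, channel-summed and rectified.

Both are stabilized with a noise tunnel (averaging over Gaussian-perturbed
copies of the input) and normalized to [0, 1] by their maximum, making the
result invariant to positive rescaling of the raw attribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .training import TileClassifier

__all__ = [
    "AttributionMap",
    "Blob",
    "BlobSet",
    "BlobMatchSet",
    "attribution",
    "normalize_attribution",
    "detect_blobs",
    "blob_agreement",
    "agreement_dataset",
    "null_baseline",
    "agreement_map_render",
    "stitch_maps",
]

TILE = 256


@dataclass
class AttributionMap:
    values: np.ndarray  # (H, W) in [0, 1]
    method: str
    noise_samples: int = 5
    layers_averaged: int = 1

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution must be finite")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("attribution must be normalized to [0, 1]")


def normalize_attribution(values: np.ndarray) -> np.ndarray:
    """Rectify and scale to [0, 1] by the maximum (idempotent; invariant to
    multiplication by any positive constant)."""
    v = np.maximum(np.asarray(values, dtype=np.float64), 0.0)
    m = v.max()
    return v / m if m > 0 else v


def _gradcam_layers(net) -> list[np.ndarray]:
    """Per-conv-block CAMs for the cached forward/backward, upsampled to tile size."""
    cams = []
    for act, grad in zip(net.conv_activations(), net.conv_gradients()):
        alpha = grad.mean(axis=(2, 3))  # (1, C)
        cam = np.maximum((alpha[:, :, None, None] * act).sum(axis=1), 0.0)[0]
        cams.append(resize(cam, (TILE, TILE), order=1, mode="edge", anti_aliasing=False))
    return cams


def attribution(
    model: TileClassifier,
    tile: np.ndarray,
    method: str = "guided_gradcam",
    noise_samples: int = 5,
    seed: int = 0,
    noise_sigma: float = 0.1,
    ig_steps: int = 16,
    smooth_sigma: float = 2.0,
) -> AttributionMap:
    """Attribution of the melanocyte logit over one uint8 RGB tile.

    ``noise_sigma`` scales Gaussian input noise by the normalized input's
    value range (the noise-tunnel stabilization); attribution maps from the
    perturbed copies are averaged.  ``smooth_sigma`` Gaussian-smooths the
    averaged map before normalization — the same stabilization spirit,
    turning pixel-sparse gradients into contiguous salient regions.
    Deterministic per seed.
    """
    if method not in ("guided_gradcam", "integrated_gradients"):
        raise ValueError(f"unknown attribution method {method!r}")
    net = model.net
    if method == "guided_gradcam" and net.n_conv_blocks == 0:
        raise ValueError("guided_gradcam requires a model with conv layers")
    rng = np.random.default_rng(seed)
    x = model.normalize_tiles(tile[None] if tile.ndim == 3 else tile)
    span = float(x.max() - x.min())
    total = np.zeros((TILE, TILE), dtype=np.float64)
    layers_avg = net.n_conv_blocks if method == "guided_gradcam" else 1
    for _ in range(max(noise_samples, 1)):
        if noise_samples > 1:
            xs = x + (noise_sigma * span * rng.standard_normal(x.shape)).astype(np.float32)
        else:
            xs = x
        if method == "guided_gradcam":
            net.forward(xs)
            net.zero_grad()
            net.backward(np.ones(1), guided=False, need_input_grad=False)
            cam = np.mean(_gradcam_layers(net), axis=0)
            net.zero_grad()
            g = net.backward(np.ones(1), guided=True, need_input_grad=True)
            gate = np.maximum(g[0].sum(axis=0), 0.0)
            total += cam * gate
        else:
            x0 = model.normalize_tiles(np.zeros_like(tile)[None] if tile.ndim == 3 else np.zeros_like(tile))
            alphas = (np.arange(1, ig_steps + 1) / ig_steps)[:, None, None, None].astype(np.float32)
            path = x0 + alphas * (xs - x0)
            net.forward(path)
            net.zero_grad()
            g = net.backward(np.ones(len(path)), need_input_grad=True)
            avg_grad = g.mean(axis=0)
            ig = ((xs - x0)[0] * avg_grad).sum(axis=0)
            total += np.maximum(ig, 0.0)
    net.zero_grad()
    if smooth_sigma > 0:
        total = ndi.gaussian_filter(total, smooth_sigma)
    return AttributionMap(
        normalize_attribution(total), method, noise_samples=noise_samples, layers_averaged=layers_avg
    )


@dataclass
class Blob:
    mask: np.ndarray  # bool, tile frame

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class BlobSet:
    blobs: list[Blob]
    threshold: float = 0.2
    min_area: int = 100
    frame_shape: tuple[int, int] = (TILE, TILE)


def detect_blobs(attr, threshold: float = 0.2, min_area: int = 100) -> BlobSet:
    """Salient blobs: binarize above threshold, morphological open then
    close (3x3), 8-connected components, drop those under ``min_area``."""
    values = attr.values if isinstance(attr, AttributionMap) else np.asarray(attr)
    binary = values > threshold
    se = np.ones((3, 3), dtype=bool)
    cleaned = ndi.binary_closing(ndi.binary_opening(binary, structure=se), structure=se)
    labels, n = ndi.label(cleaned, structure=np.ones((3, 3), dtype=int))
    blobs = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() >= min_area:
            blobs.append(Blob(mask))
    return BlobSet(blobs, threshold, min_area, values.shape)


@dataclass
class BlobMatchSet:
    """Cross-stain matched blobs for one tile."""

    pairs: list[tuple[int, int, float, float]]  # (index_a, index_b, iou, dice)
    mean_iou: float
    mean_dice: float
    qualifying: bool = True


def blob_agreement(blobs_a: BlobSet, blobs_b: BlobSet) -> BlobMatchSet:
    """Match blobs across the two sets by nonempty pixel intersection and
    score each matched pair with IoU and Dice; the tile score is the mean
    over matched pairs (0 when nothing matches)."""
    if blobs_a.frame_shape != blobs_b.frame_shape:
        raise ValueError("blob sets come from different frames")
    pairs = []
    for i, a in enumerate(blobs_a.blobs):
        for j, b in enumerate(blobs_b.blobs):
            inter = int((a.mask & b.mask).sum())
            if inter == 0:
                continue
            union = int((a.mask | b.mask).sum())
            iou = inter / union
            dice = 2.0 * inter / (a.area + b.area)
            pairs.append((i, j, iou, dice))
    if pairs:
        mean_iou = float(np.mean([p[2] for p in pairs]))
        mean_dice = float(np.mean([p[3] for p in pairs]))
    else:
        mean_iou = mean_dice = 0.0
    return BlobMatchSet(pairs, mean_iou, mean_dice)


def _tile_agreement(
    model_a: TileClassifier,
    model_b: TileClassifier,
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    method: str,
    seed: int,
    threshold: float,
    min_area: int,
    cache: dict | None = None,
    keys: tuple | None = None,
) -> BlobMatchSet:
    def attr_for(model, tile, key):
        if cache is not None and key in cache:
            return cache[key]
        a = detect_blobs(attribution(model, tile, method=method, seed=seed), threshold, min_area)
        if cache is not None:
            cache[key] = a
        return a

    ka, kb = keys if keys else (None, None)
    ba = attr_for(model_a, tile_a, ("a", ka))
    bb = attr_for(model_b, tile_b, ("b", kb))
    return blob_agreement(ba, bb)


def agreement_dataset(
    model_a: TileClassifier,
    model_b: TileClassifier,
    tiles: np.ndarray,
    confidence: float = 0.9,
    method: str = "guided_gradcam",
    seed: int = 0,
    threshold: float = 0.2,
    min_area: int = 100,
) -> dict:
    """Cross-stain agreement over qualifying tiles.

    A tile qualifies when either model predicts it with confidence above
    the cutoff.  Returns mean +/- sd IoU and Dice over qualifying tiles,
    plus per-tile scores.
    """
    pa = model_a.probability(tiles)
    pb = model_b.probability(tiles)
    qualifying = np.flatnonzero(np.maximum(pa, pb) > confidence)
    if len(qualifying) == 0:
        warnings.warn("no qualifying tiles above the confidence cutoff")
        return {"n_qualifying": 0, "mean_iou": np.nan, "sd_iou": np.nan, "mean_dice": np.nan, "sd_dice": np.nan, "per_tile": []}
    per = []
    for idx in qualifying:
        m = _tile_agreement(model_a, model_b, tiles[idx], tiles[idx], method, seed, threshold, min_area)
        per.append({"tile": int(idx), "iou": m.mean_iou, "dice": m.mean_dice, "n_pairs": len(m.pairs)})
    ious = np.array([p["iou"] for p in per])
    dices = np.array([p["dice"] for p in per])
    return {
        "n_qualifying": int(len(qualifying)),
        "mean_iou": float(ious.mean()),
        "sd_iou": float(ious.std()),
        "mean_dice": float(dices.mean()),
        "sd_dice": float(dices.std()),
        "per_tile": per,
    }


def null_baseline(
    model_a: TileClassifier,
    model_b: TileClassifier,
    positive_tiles: np.ndarray,
    n_pairs: int = 100,
    seed: int = 0,
    method: str = "guided_gradcam",
    threshold: float = 0.2,
    min_area: int = 100,
    pairs: list[tuple[int, int]] | None = None,
) -> dict:
    """Mismatched-pair null: agreement between model A's attribution on tile
    i and model B's attribution on a *different* tile j, over ``n_pairs``
    random ordered pairs.  Calibrates the matched-tile statistic; unrelated
    tiles should share (essentially) no salient blobs.

    ``pairs`` overrides the random sampling with an explicit pair list
    (e.g. degenerate (i, i) pairs as a control, which reduce exactly to the
    matched-tile computation).
    """
    n = len(positive_tiles)
    if n < 2:
        raise ValueError("need at least 2 distinct positive tiles")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    cache: dict = {}
    ious, dices = [], []
    if pairs is None:
        sampled = []
        for _ in range(n_pairs):
            i = int(rng.integers(n))
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
            sampled.append((i, j))
    else:
        sampled = list(pairs)
    for (i, j) in sampled:
        m = _tile_agreement(
            model_a, model_b, positive_tiles[i], positive_tiles[j], method, seed, threshold, min_area,
            cache=cache, keys=(i, j),
        )
        ious.append(m.mean_iou)
        dices.append(m.mean_dice)
    ious = np.asarray(ious)
    dices = np.asarray(dices)
    return {
        "n_pairs": len(sampled),
        "pairs": sampled,
        "mean_iou": float(ious.mean()),
        "sd_iou": float(ious.std()),
        "mean_dice": float(dices.mean()),
        "sd_dice": float(dices.std()),
    }


def stitch_maps(grid: list[list[np.ndarray]], smooth_sigma: float = 2.0) -> np.ndarray:
    """Stitch a grid of per-tile maps into one view, Gaussian-smoothed to
    remove edge effects between tiles."""
    stitched = np.block(grid)
    if smooth_sigma > 0:
        stitched = ndi.gaussian_filter(stitched, smooth_sigma)
    return stitched


def agreement_map_render(
    attr_a: np.ndarray,
    attr_b: np.ndarray,
    background: np.ndarray,
    confidence_mask: np.ndarray | None = None,
    threshold: float = 0.2,
    alpha: float = 0.65,
) -> np.ndarray:
    """Categorical agreement view: both-salient pixels blue, A-only green,
    B-only red; pixels outside the confidence mask are desaturated."""
    va = attr_a.values if isinstance(attr_a, AttributionMap) else np.asarray(attr_a)
    vb = attr_b.values if isinstance(attr_b, AttributionMap) else np.asarray(attr_b)
    if va.shape != vb.shape or va.shape != background.shape[:2]:
        raise ValueError("frame dims differ")
    sal_a = va > threshold
    sal_b = vb > threshold
    out = background.astype(np.float64).copy()
    colors = {"both": (40, 70, 220), "a": (40, 180, 60), "b": (220, 50, 40)}
    for mask, col in (
        (sal_a & sal_b, colors["both"]),
        (sal_a & ~sal_b, colors["a"]),
        (sal_b & ~sal_a, colors["b"]),
    ):
        out[mask] = (1 - alpha) * out[mask] + alpha * np.asarray(col, dtype=np.float64)
    if confidence_mask is not None:
        gray = background.astype(np.float64).mean(axis=-1, keepdims=True) * np.ones(3)
        out[~confidence_mask] = gray[~confidence_mask]
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)
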