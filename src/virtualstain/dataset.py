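"""Tile datasets: grids, IHC-derived labels, folds, negative injection.

Aligned section pairs are cut into 256x256 tiles on the H&E frame — stride
128 (overlapping) for training, stride 256 for validation/test — and each
tile inherits a binary melanocyte label computed from the warped IHC DAB
mask at the same coordinates.  Cross-validation folds are stratified by
patient: every patient is in the test partition of exactly one fold and no
patient ever straddles the train/val/test boundary within a fold.
Melanocyte-free "injected" tiles (the stand-in for non-cutaneous negative
tissue) are pooled into training (70%) and validation (30%) only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labeling import DabMaskConfig, LabelThresholds, count_dab_nuclei, dab_fraction, label_tile

__all__ = [
    "TILE_SIZE",
    "NormStats",
    "LabeledPair",
    "DatasetManifest",
    "tile_grid",
    "tile_physical_size",
    "make_folds",
    "build_manifest",
    "compute_norm_stats",
    "normalize",
    "denormalize",
    "gather_tiles",
    "labeled_pair_from_alignment",
]

TILE_SIZE = 256


@dataclass(frozen=True)
class NormStats:
    """Per-channel mean/sd on the 0..255 scale, from the training split only."""

    mean: tuple[float, float, float]
    sd: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.sd):
            raise ValueError("sd must be > 0 per channel")


@dataclass
class LabeledPair:
    """An aligned pair reduced to what tiling needs: the H&E image plus the
    IHC-derived DAB and tissue masks warped into the H&E frame."""

    pair_id: str
    patient_id: str
    stain: str
    he_image: np.ndarray
    tissue_mask: np.ndarray
    dab_mask: np.ndarray


@dataclass
class DatasetManifest:
    records: pd.DataFrame
    thresholds: LabelThresholds
    dab_cfg: DabMaskConfig
    tcga_condition: str
    seed: int
    n_folds: int

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)
        side = {
            "thresholds": {
                "sox10_min_nuclei": self.thresholds.sox10_min_nuclei,
                "melana_min_fraction": self.thresholds.melana_min_fraction,
                "inclusive": self.thresholds.inclusive,
            },
            "dab_cfg": {
                "od_floor": self.dab_cfg.od_floor,
                "use_otsu": self.dab_cfg.use_otsu,
                "nucleus_area_px": list(self.dab_cfg.nucleus_area_px),
                "connectivity": self.dab_cfg.connectivity,
            },
            "tcga_condition": self.tcga_condition,
            "seed": self.seed,
            "n_folds": self.n_folds,
        }
        Path(str(path) + ".json").write_text(json.dumps(side, indent=1, sort_keys=True))


def tile_grid(section_h: int, section_w: int, size: int = TILE_SIZE, stride: int = TILE_SIZE) -> list[tuple[int, int]]:
    """Row-major top-left anchors of fully contained tiles.

    Anchors sit at multiples of the stride; tiles that would cross the
    section boundary are omitted (dataset tiles are never padded).
    """
    if size <= 0 or stride <= 0:
        raise ValueError("size and stride must be > 0")
    rows = range(0, section_h - size + 1, stride)
    cols = range(0, section_w - size + 1, stride)
    return [(r, c) for r in rows for c in cols]


def tile_physical_size(size_px: int, mpp: float) -> float:
    """Physical tile edge in microns (e.g. 256 px at 0.25 MPP = 64 um)."""
    if mpp <= 0:
        raise ValueError("mpp must be > 0")
    return size_px * mpp


def _largest_remainder_split(n: int, k: int) -> list[int]:
    """Group sizes summing to n, as equal as possible, deterministic."""
    base = n // k
    sizes = [base] * k
    for i in range(n - base * k):
        sizes[i] += 1
    return sizes


def make_folds(
    patients: list[str], k: int = 5, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2), seed: int = 0
) -> list[dict[str, list[str]]]:
    """Patient-stratified k-fold assignment with train/val/test partitions.

    Patients are shuffled (seeded) and divided into k groups; fold i takes
    group i as test, the next ``round(fractions[1] * k)`` groups as val and
    the remainder as train.  Every patient is in the test partition of
    exactly one fold.
    """
    patients = list(patients)
    if len(patients) < k:
        raise ValueError(f"need at least {k} patients, got {len(patients)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(patients)))
    shuffled = [patients[i] for i in order]
    sizes = _largest_remainder_split(len(patients), k)
    groups: list[list[str]] = []
    pos = 0
    for s in sizes:
        groups.append(shuffled[pos : pos + s])
        pos += s
    n_val_groups = max(1, round(fractions[1] * k))
    folds = []
    for i in range(k):
        test = groups[i]
        val: list[str] = []
        for j in range(1, n_val_groups + 1):
            val.extend(groups[(i + j) % k])
        used = set(test) | set(val)
        train = [p for p in shuffled if p not in used]
        folds.append({"train": train, "val": val, "test": test})
    return folds


def build_manifest(
    pairs: list[LabeledPair],
    negatives: list[np.ndarray] | None = None,
    tcga_condition: str = "zero",
    seed: int = 0,
    n_folds: int = 5,
    thresholds: LabelThresholds | None = None,
    dab_cfg: DabMaskConfig | None = None,
    train_stride: int = 128,
    eval_stride: int = TILE_SIZE,
    min_tissue_frac: float = 0.25,
) -> DatasetManifest:
    """Assemble the tile manifest over all folds.

    Cutaneous tiles are cut at ``train_stride`` for the training partition
    and ``eval_stride`` for validation/test; tiles with less than
    ``min_tissue_frac`` tissue are dropped.  Injected negatives (condition
    "full" uses all provided tiles, "half" half as many) are pooled 70/30
    into train/val with per-tile pseudo patients, never into test.
    """
    thresholds = thresholds or LabelThresholds()
    dab_cfg = dab_cfg or DabMaskConfig()
    if tcga_condition not in ("zero", "half", "full"):
        raise ValueError(f"unknown tcga_condition {tcga_condition!r}")
    if tcga_condition != "zero" and not negatives:
        raise ValueError("negatives required for condition != zero")

    patients = sorted({p.patient_id for p in pairs})
    folds = make_folds(patients, k=n_folds, seed=seed)

    # per-pair tile labels are identical across folds at a given stride;
    # compute once per stride
    def tiles_for(pair: LabeledPair, stride: int):
        h, w = pair.he_image.shape[:2]
        out = []
        for (r, c) in tile_grid(h, w, TILE_SIZE, stride):
            tis = pair.tissue_mask[r : r + TILE_SIZE, c : c + TILE_SIZE]
            if tis.mean() < min_tissue_frac:
                continue
            sub = pair.dab_mask[r : r + TILE_SIZE, c : c + TILE_SIZE]
            out.append(
                {
                    "tile_row": r,
                    "tile_col": c,
                    "label": label_tile(pair.stain, sub, thresholds, dab_cfg),
                    "nuclei_count": count_dab_nuclei(sub, dab_cfg),
                    "dab_fraction": round(dab_fraction(sub, (TILE_SIZE, TILE_SIZE)), 6),
                }
            )
        return out

    cache: dict[tuple[str, int], list[dict]] = {}
    rows = []
    for fold_idx, fold in enumerate(folds):
        split_of = {p: s for s in ("train", "val", "test") for p in fold[s]}
        for pair in pairs:
            split = split_of[pair.patient_id]
            stride = train_stride if split == "train" else eval_stride
            key = (pair.pair_id, stride)
            if key not in cache:
                cache[key] = tiles_for(pair, stride)
            for t in cache[key]:
                rows.append(
                    {
                        "pair_id": pair.pair_id,
                        "patient_id": pair.patient_id,
                        "stain": pair.stain,
                        "origin": "cutaneous",
                        "fold": fold_idx,
                        "split": split,
                        "size_px": TILE_SIZE,
                        **t,
                    }
                )

    if tcga_condition != "zero":
        n_avail = len(negatives)
        n_used = n_avail if tcga_condition == "full" else n_avail // 2
        rng = np.random.default_rng(seed)
        order = rng.permutation(n_avail)[:n_used]
        n_train = round(0.7 * n_used)
        for fold_idx in range(n_folds):
            for k, idx in enumerate(order):
                rows.append(
                    {
                        "pair_id": f"injected{idx}",
                        "patient_id": f"NEG{idx}",
                        "stain": "none",
                        "origin": "injected_negative",
                        "fold": fold_idx,
                        "split": "train" if k < n_train else "val",
                        "size_px": TILE_SIZE,
                        "tile_row": 0,
                        "tile_col": 0,
                        "label": 0,
                        "nuclei_count": 0,
                        "dab_fraction": 0.0,
                    }
                )

    records = pd.DataFrame(rows)
    records = records[
        [
            "fold",
            "split",
            "origin",
            "pair_id",
            "patient_id",
            "stain",
            "tile_row",
            "tile_col",
            "size_px",
            "label",
            "nuclei_count",
            "dab_fraction",
        ]
    ]
    records = records.sort_values(
        ["fold", "split", "origin", "pair_id", "tile_row", "tile_col"], kind="stable"
    ).reset_index(drop=True)
    return DatasetManifest(records, thresholds, dab_cfg, tcga_condition, seed, n_folds)


def compute_norm_stats(tiles: np.ndarray) -> NormStats:
    """Per-channel mean and sd of a stack of uint8 tiles (N, H, W, 3)."""
    x = np.asarray(tiles, dtype=np.float64)
    mean = x.mean(axis=(0, 1, 2))
    sd = x.std(axis=(0, 1, 2))
    if np.any(sd <= 0):
        raise ValueError("constant-valued channel: sd = 0")
    return NormStats(tuple(float(m) for m in mean), tuple(float(s) for s in sd))


def normalize(tiles: np.ndarray, stats: NormStats) -> np.ndarray:
    """(x - mean) / sd per channel; always with training-split statistics."""
    x = np.asarray(tiles, dtype=np.float32)
    return (x - np.asarray(stats.mean, dtype=np.float32)) / np.asarray(stats.sd, dtype=np.float32)


def denormalize(z: np.ndarray, stats: NormStats) -> np.ndarray:
    return np.asarray(z, dtype=np.float32) * np.asarray(stats.sd, dtype=np.float32) + np.asarray(
        stats.mean, dtype=np.float32
    )


def gather_tiles(
    manifest: DatasetManifest,
    pairs: list[LabeledPair],
    negatives: list[np.ndarray] | None,
    fold: int,
    split: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Materialize (tiles, labels) for one fold/split as uint8 / int arrays."""
    by_id = {p.pair_id: p for p in pairs}
    sel = manifest.records
    sel = sel[(sel["fold"] == fold) & (sel["split"] == split)]
    tiles = np.empty((len(sel), TILE_SIZE, TILE_SIZE, 3), dtype=np.uint8)
    labels = np.empty(len(sel), dtype=np.int64)
    for i, row in enumerate(sel.itertuples(index=False)):
        if row.origin == "injected_negative":
            idx = int(row.pair_id.removeprefix("injected"))
            tiles[i] = negatives[idx]
        else:
            p = by_id[row.pair_id]
            tiles[i] = p.he_image[row.tile_row : row.tile_row + TILE_SIZE, row.tile_col : row.tile_col + TILE_SIZE]
        labels[i] = row.label
    return tiles, labels.astype(np.int64)


def labeled_pair_from_alignment(
    pair_id: str,
    patient_id: str,
    stain: str,
    he_image: np.ndarray,
    ihc_image: np.ndarray,
    deformation,
    he_tissue_mask: np.ndarray | None = None,
    dab_cfg: DabMaskConfig | None = None,
    artifact_cfg=None,
) -> LabeledPair:
    """Run IHC labeling on a registered pair and warp the result into the
    H&E frame, producing the tiling-ready :class:`LabeledPair`."""
    from .labeling import ArtifactConfig, artifact_mask, dab_mask, rgb_to_hed
    from .register import foreground_mask

    ihc_tissue = foreground_mask(ihc_image)
    art = artifact_mask(ihc_image, artifact_cfg or ArtifactConfig(), tissue_mask=ihc_tissue)
    dab_ihc = dab_mask(rgb_to_hed(ihc_image)[..., 2], ihc_tissue, art, dab_cfg)
    shape = he_image.shape[:2]
    dab_he = deformation.warp_image(dab_ihc.astype(np.float64), shape, order=0) > 0.5
    tissue = he_tissue_mask if he_tissue_mask is not None else foreground_mask(he_image)
    return LabeledPair(pair_id, patient_id, stain, he_image, tissue, dab_he)
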