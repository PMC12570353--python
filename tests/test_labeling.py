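"""DAB isolation, artifact exclusion and the stain-specific tile label rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from virtualstain.fixtures import ArtifactSpec, FixtureSpec, generate_section_pair, make_fraction_tile
from virtualstain.labeling import (
    ArtifactConfig,
    DabMaskConfig,
    LabelThresholds,
    artifact_mask,
    count_dab_nuclei,
    dab_fraction,
    dab_mask,
    label_tile,
    rgb_to_hed,
)
from virtualstain.stains import RGB_FROM_HED, render_from_od


# ---------------------------------------------------------------- rgb_to_hed
def test_white_pixel_unmixes_to_zero_density():
    assert np.all(np.abs(rgb_to_hed(np.full((1, 1, 3), 255, np.uint8))) < 1e-3)


def test_rendered_dab_density_recovered():
    od = np.zeros((1, 1, 3))
    od[0, 0, 2] = 1.0
    assert abs(rgb_to_hed(render_from_od(od))[0, 0, 2] - 1.0) < 1e-3


def test_hematoxylin_only_pixel_has_negligible_dab():
    od = np.zeros((1, 1, 3))
    od[0, 0, 0] = 1.0
    assert rgb_to_hed(render_from_od(od))[0, 0, 2] < 0.05


# ------------------------------------------------------------- artifact_mask
@pytest.fixture(scope="module")
def inked_section():
    spec = FixtureSpec(
        section_height_px=448,
        section_width_px=448,
        n_melanocytes=10,
        n_keratinocytes=60,
        seed=5,
        artifact_spec=ArtifactSpec(n_ink=2, n_hemorrhage=1),
    )
    _, ihc, truth = generate_section_pair(spec)
    return ihc, truth


def test_planted_ink_excluded_but_tissue_kept(inked_section):
    ihc, truth = inked_section
    mask = artifact_mask(ihc, tissue_mask=truth.tissue_mask_ihc)
    ink = truth.ink_mask_ihc
    clean = truth.tissue_mask_ihc & ~ink & ~truth.hemorrhage_mask_ihc
    assert mask[ink].mean() >= 0.99
    assert mask[clean].mean() < 0.01


def test_clean_section_barely_excluded():
    spec = FixtureSpec(section_height_px=448, section_width_px=448, n_melanocytes=10, n_keratinocytes=60, seed=6)
    _, ihc, truth = generate_section_pair(spec)
    mask = artifact_mask(ihc, tissue_mask=truth.tissue_mask_ihc)
    assert mask[truth.tissue_mask_ihc].mean() < 0.02


def test_correction_mask_excludes_regardless_of_color(inked_section):
    ihc, truth = inked_section
    corr = np.zeros(ihc.shape[:2], dtype=bool)
    corr[10:50, 10:50] = True
    mask = artifact_mask(ihc, ArtifactConfig(correction_mask=corr), tissue_mask=truth.tissue_mask_ihc)
    assert mask[corr].all()


def test_malformed_correction_mask_rejected(inked_section):
    ihc, _ = inked_section
    with pytest.raises(ValueError, match="dims"):
        artifact_mask(ihc, ArtifactConfig(correction_mask=np.zeros((8, 8), dtype=bool)))


# ----------------------------------------------------------------- dab_mask
def test_all_white_tile_has_empty_dab_mask():
    tile = np.full((256, 256, 3), 255, np.uint8)
    assert not dab_mask(rgb_to_hed(tile)[..., 2]).any()


def test_empty_tissue_mask_gives_empty_dab_mask():
    od = np.ones((16, 16))
    assert not dab_mask(od, tissue_mask=np.zeros((16, 16), dtype=bool)).any()


def test_raising_od_floor_never_grows_the_mask():
    tile, _ = make_fraction_tile(0.04, seed=3)
    od = rgb_to_hed(tile)[..., 2]
    prev = None
    for floor in (0.1, 0.3, 0.5, 0.7):
        m = dab_mask(od, cfg=DabMaskConfig(od_floor=floor, use_otsu=False))
        if prev is not None:
            assert m.sum() <= prev
        prev = m.sum()


# ------------------------------------------------------- counting / fraction
def _disk_mask(centers, radius, shape=(256, 256)):
    m = np.zeros(shape, dtype=bool)
    for c in centers:
        rr, cc = draw_disk(c, radius, shape=shape)
        m[rr, cc] = True
    return m


def test_empty_mask_counts_zero():
    assert count_dab_nuclei(np.zeros((256, 256), dtype=bool)) == 0


def test_three_disjoint_disks_count_three():
    m = _disk_mask([(50, 50), (50, 150), (150, 100)], 10)
    assert count_dab_nuclei(m) == 3


def test_overlapping_disks_merge_and_undercount():
    m = _disk_mask([(100, 100), (100, 112)], 10)  # overlapping -> one component
    assert count_dab_nuclei(m) == 1


def test_nucleus_area_band_filters_components():
    m = _disk_mask([(100, 100)], 3)  # area ~29 < default min of 80
    assert count_dab_nuclei(m) == 0
    assert count_dab_nuclei(m, DabMaskConfig(nucleus_area_px=(10, 5000))) == 1


def test_dab_fraction_exact_arithmetic():
    full = np.ones((256, 256), dtype=bool)
    assert dab_fraction(full) == 1.0
    assert dab_fraction(np.zeros((256, 256), dtype=bool)) == 0.0
    m = np.zeros((256, 256), dtype=bool)
    m.reshape(-1)[:1966] = True
    assert dab_fraction(m) == pytest.approx(1966 / 65536)
    assert dab_fraction(m) < 0.03  # 1966 px sits just under the 3% rule
    m.reshape(-1)[1966] = True
    assert dab_fraction(m) >= 0.03


# ----------------------------------------------------------------- label_tile
def test_sox10_rule_boundary_at_two_nuclei():
    one = _disk_mask([(100, 100)], 10)
    two = _disk_mask([(100, 100), (100, 200)], 10)
    assert label_tile("SOX10", one) == 0
    assert label_tile("SOX10", two) == 1


def test_melana_rule_boundary_at_three_percent():
    below = np.zeros((256, 256), dtype=bool)
    below.reshape(-1)[: int(0.029 * 65536)] = True
    above = np.zeros((256, 256), dtype=bool)
    above.reshape(-1)[: int(0.031 * 65536)] = True
    assert label_tile("MelanA", below) == 0
    assert label_tile("MelanA", above) == 1
    assert label_tile("MelPro", above) == 1  # MelPro shares the MelanA rule


def test_empty_mask_is_negative_for_both_stains():
    empty = np.zeros((256, 256), dtype=bool)
    assert label_tile("SOX10", empty) == 0
    assert label_tile("MelanA", empty) == 0


def test_unknown_stain_rejected():
    with pytest.raises(ValueError, match="stain"):
        label_tile("KI67", np.zeros((256, 256), dtype=bool))


def test_strict_threshold_reading_via_inclusive_flag():
    two = _disk_mask([(100, 100), (100, 200)], 10)
    assert label_tile("SOX10", two, LabelThresholds(inclusive=False)) == 0
    three = _disk_mask([(50, 50), (100, 200), (200, 60)], 10)
    assert label_tile("SOX10", three, LabelThresholds(inclusive=False)) == 1


def test_label_monotone_in_thresholds():
    """Raising either cutoff never flips a negative tile positive, and the
    positive count over a tile set is non-increasing."""
    rng = np.random.default_rng(0)
    masks = []
    for _ in range(12):
        centers = [(int(r), int(c)) for r, c in rng.integers(20, 236, size=(rng.integers(0, 6), 2))]
        masks.append(_disk_mask(centers, 11))
    for stain, grid in (("SOX10", range(1, 6)), ("MelanA", [0.01, 0.02, 0.03, 0.04, 0.05])):
        counts = []
        for thr in grid:
            th = (
                LabelThresholds(sox10_min_nuclei=thr)
                if stain == "SOX10"
                else LabelThresholds(melana_min_fraction=thr)
            )
            labels = [label_tile(stain, m, th) for m in masks]
            counts.append(sum(labels))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# -------------------------------------------------- exhaustive 16x16 oracle
def _brute_force_components(mask, connectivity=8):
    """Flood-fill component sizes, independent of scipy labeling."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    sizes = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                size = 0
                while stack:
                    y, x = stack.pop()
                    size += 1
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                sizes.append(size)
    return sizes


@settings(max_examples=40, deadline=None, derandomize=True)
@given(bits=st.lists(st.booleans(), min_size=256, max_size=256), conn=st.sampled_from([4, 8]))
def test_count_and_fraction_match_enumeration_oracle(bits, conn):
    mask = np.array(bits, dtype=bool).reshape(16, 16)
    cfg = DabMaskConfig(nucleus_area_px=(2, 50), connectivity=conn)
    expected = sum(1 for s in _brute_force_components(mask, conn) if 2 <= s <= 50)
    assert count_dab_nuclei(mask, cfg) == expected
    assert dab_fraction(mask, (16, 16)) == mask.sum() / 256
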