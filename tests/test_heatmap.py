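"""Sliding-window position counts, overlap averaging, overlays."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from virtualstain.heatmap import (
    ScalarMap,
    count_positions,
    overlap_average,
    padded_window,
    position_anchors,
    prediction_heatmap,
    render_overlay,
)


class ConstantModel:
    def __init__(self, p):
        self.p = p

    def probability(self, tiles, batch_size=240):
        return np.full(len(tiles), self.p)


class MeanIntensityModel:
    """Probability = mean pixel intensity of the tile, scaled to [0, 1]."""

    def probability(self, tiles, batch_size=240):
        return tiles.reshape(len(tiles), -1).mean(axis=1) / 255.0


# ---------------------------------------------------------- count_positions
@pytest.mark.parametrize(
    "h, w, stride, expected",
    [
        (10_000, 10_000, 1, 100_000_000),
        (10_000, 10_000, 6, 1667**2),
        (100, 50, 200, 1),
        (7, 7, 7, 1),
    ],
)
def test_count_positions_closed_form(h, w, stride, expected):
    assert count_positions(h, w, stride) == expected


def test_count_positions_matches_enumeration():
    for h in range(1, 51, 7):
        for w in range(1, 51, 5):
            for stride in range(1, 8):
                n_rows = len(range(0, h, stride))
                n_cols = len(range(0, w, stride))
                assert count_positions(h, w, stride) == n_rows * n_cols
                rows, cols = position_anchors(h, w, stride)
                assert len(rows) == n_rows and len(cols) == n_cols


def test_count_positions_rejects_zero_stride():
    with pytest.raises(ValueError):
        count_positions(10, 10, 0)


# ----------------------------------------------------------- windows & maps
def test_padded_window_zero_fills_out_of_bounds():
    img = np.arange(16, dtype=np.uint8).reshape(4, 4)
    win = padded_window(img, 0, 0, size=4)
    assert win.shape == (4, 4)
    assert win[0, 0] == 0  # padding above-left
    assert win[2, 2] == img[0, 0]


def test_overlap_average_matches_bruteforce_window_enumeration():
    """64x64 toy section: accumulated overlap averaging equals explicit
    per-pixel enumeration of all covering windows."""
    rng = np.random.default_rng(5)
    h = w = 64
    stride, size = 5, 16
    rows, cols = position_anchors(h, w, stride)
    vals = rng.uniform(size=(len(rows), len(cols)))
    fast = overlap_average(vals, (h, w), stride, size)
    half = size // 2
    brute = np.zeros((h, w))
    for pr in range(h):
        for pc in range(w):
            cover = []
            for i, r in enumerate(rows):
                for j, c in enumerate(cols):
                    if r - half <= pr < r - half + size and c - half <= pc < c - half + size:
                        cover.append(vals[i, j])
            brute[pr, pc] = np.mean(cover)
    assert np.allclose(fast, brute)


def test_constant_model_gives_uniform_map():
    section = np.zeros((64, 64, 3), dtype=np.uint8)
    smap = prediction_heatmap(ConstantModel(0.7), section, stride=16)
    assert np.allclose(smap.values, 0.7)
    assert smap.stride_used == 16


def test_heatmap_bounded_by_tile_probabilities():
    rng = np.random.default_rng(1)
    section = rng.integers(0, 255, (128, 128, 3), dtype=np.uint8)
    model = MeanIntensityModel()
    smap = prediction_heatmap(model, section, stride=32)
    rows, cols = position_anchors(128, 128, 32)
    probs = [
        model.probability(padded_window(section, int(r), int(c))[None])[0] for r in rows for c in cols
    ]
    assert smap.values.min() >= min(probs) - 1e-12
    assert smap.values.max() <= max(probs) + 1e-12


def test_stride_equal_to_tile_size_reproduces_tile_probabilities():
    rng = np.random.default_rng(2)
    section = rng.integers(0, 255, (512, 512, 3), dtype=np.uint8)
    model = MeanIntensityModel()
    smap = prediction_heatmap(model, section, stride=256)
    rows, cols = position_anchors(512, 512, 256)
    for r in rows:
        for c in cols:
            p = model.probability(padded_window(section, int(r), int(c))[None])[0]
            assert smap.values[r, c] == pytest.approx(p)


def test_nonfinite_map_rejected():
    with pytest.raises(ValueError):
        ScalarMap(np.array([[np.nan]]), 1, "prediction")


# ------------------------------------------------------------------ label maps
def test_label_map_of_empty_dab_mask_is_zero():
    from virtualstain.heatmap import label_map, position_labels_from_dab

    dab = np.zeros((300, 300), dtype=bool)
    labels = position_labels_from_dab(dab, stride=100, stain="MelanA")
    smap = label_map(labels, (300, 300), stride=100)
    assert smap.kind == "label"
    assert not smap.values.any()


def test_label_map_single_positive_region_at_tile_stride():
    from virtualstain.heatmap import label_map, position_labels_from_dab

    dab = np.zeros((512, 512), dtype=bool)
    # saturate the window centered at (256, 256) with DAB
    dab[128:384, 128:384] = True
    labels = position_labels_from_dab(dab, stride=256, stain="MelanA")
    assert labels[1, 1] == 1
    smap = label_map(labels, (512, 512), stride=256)
    assert smap.values[256, 256] == 1.0
    assert smap.values[0, 0] == labels[0, 0]


# ----------------------------------------------------------------- overlays
def test_overlay_below_threshold_is_desaturated():
    bg = np.random.default_rng(0).integers(0, 255, (32, 32, 3), dtype=np.uint8)
    smap = ScalarMap(np.zeros((32, 32)), 6, "prediction")
    out = render_overlay(smap, bg, confidence_threshold=0.9)
    assert out.dtype == np.uint8 and out.shape == bg.shape
    assert np.all(out[..., 0] == out[..., 1]) and np.all(out[..., 1] == out[..., 2])


def test_overlay_top_value_uses_colormap_top_color():
    from matplotlib import colormaps

    bg = np.zeros((8, 8, 3), dtype=np.uint8)
    smap = ScalarMap(np.ones((8, 8)), 6, "prediction")
    out = render_overlay(smap, bg, alpha=1.0)
    top = np.rint(np.array(colormaps["viridis"](1.0)[:3]) * 255)
    assert np.allclose(out[0, 0], top)


def test_overlay_dim_mismatch_rejected():
    smap = ScalarMap(np.zeros((8, 8)), 6, "prediction")
    with pytest.raises(ValueError, match="dims"):
        render_overlay(smap, np.zeros((9, 9, 3), dtype=np.uint8))


# ------------------------------------------------------ stride comparability
def test_fine_and_coarse_stride_summaries_correlate():
    """Section-level read-outs from stride-6 and stride-256 maps agree for a
    spatially stable scorer: the overlap-averaging machinery itself does not
    distort the section ranking across strides."""
    from virtualstain.fixtures import FixtureSpec, generate_section_pair

    model = MeanIntensityModel()
    fine, coarse = [], []
    for k, n_kera in enumerate([20, 70, 140, 220, 320]):
        spec = FixtureSpec(
            section_height_px=512, section_width_px=512, n_melanocytes=8, n_keratinocytes=n_kera, seed=40 + k
        )
        he, _, _ = generate_section_pair(spec)
        # denser sections are darker -> lower mean intensity, at both strides
        fine.append(prediction_heatmap(model, he, stride=6).values.mean())
        coarse.append(prediction_heatmap(model, he, stride=256).values.mean())
    rho = spearmanr(fine, coarse).statistic
    assert rho >= 0.9
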