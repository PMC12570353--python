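"""Attribution maps, blob detection, and cross-stain agreement statistics."""

import numpy as np
import pytest

from virtualstain.dataset import compute_norm_stats
from virtualstain.nn import SmallConvNet
from virtualstain.saliency import (
    AttributionMap,
    Blob,
    BlobSet,
    agreement_dataset,
    agreement_map_render,
    attribution,
    blob_agreement,
    detect_blobs,
    normalize_attribution,
    null_baseline,
    stitch_maps,
)
from virtualstain.training import TileClassifier, TrainConfig


def _blobset(masks, shape=(256, 256)):
    return BlobSet([Blob(m) for m in masks], frame_shape=shape)


def _rect(shape, r0, c0, h, w):
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


# ------------------------------------------------------------ normalization
def test_normalization_idempotent_and_scale_invariant():
    rng = np.random.default_rng(0)
    raw = rng.uniform(0, 7, size=(32, 32))
    n1 = normalize_attribution(raw)
    assert np.allclose(normalize_attribution(n1), n1)
    assert np.allclose(normalize_attribution(3.7 * raw), n1)
    assert n1.max() == pytest.approx(1.0)


def test_all_zero_attribution_stays_zero():
    assert normalize_attribution(np.zeros((8, 8))).sum() == 0.0


# ------------------------------------------------------------ blob detection
def test_zero_map_has_no_blobs():
    assert detect_blobs(np.zeros((256, 256))) .blobs == []


def test_area_filter_keeps_only_blobs_of_at_least_min_area():
    attr = np.zeros((256, 256))
    attr[_rect((256, 256), 10, 10, 5, 10)] = 1.0  # 50 px
    attr[_rect((256, 256), 60, 10, 9, 11)] = 1.0  # 99 px
    attr[_rect((256, 256), 120, 10, 10, 10)] = 1.0  # 100 px
    attr[_rect((256, 256), 180, 10, 10, 15)] = 1.0  # 150 px
    bs = detect_blobs(attr, threshold=0.2, min_area=100)
    assert len(bs.blobs) == 2
    assert sorted(b.area for b in bs.blobs) == [100, 150]


def test_min_area_sweep_recovers_cutoff_at_hundred_pixels():
    attr = np.zeros((256, 256))
    attr[_rect((256, 256), 50, 50, 10, 10)] = 1.0  # exactly 100 px
    retained = [ma for ma in range(80, 121, 5) if len(detect_blobs(attr, min_area=ma).blobs) > 0]
    assert max(retained) == 100


def test_binarization_respects_threshold():
    attr = np.full((256, 256), 0.19)
    assert detect_blobs(attr).blobs == []
    attr[:64] = 0.21
    assert len(detect_blobs(attr).blobs) == 1


# ---------------------------------------------------------- blob agreement
def test_identical_blob_sets_score_one():
    masks = [_rect((256, 256), 10, 10, 12, 12), _rect((256, 256), 100, 100, 20, 10)]
    m = blob_agreement(_blobset(masks), _blobset([x.copy() for x in masks]))
    assert m.mean_iou == 1.0 and m.mean_dice == 1.0
    assert all(p[2] == p[3] == 1.0 for p in m.pairs)


def test_disjoint_blob_sets_score_zero():
    a = _blobset([_rect((256, 256), 10, 10, 10, 10)])
    b = _blobset([_rect((256, 256), 200, 200, 10, 10)])
    m = blob_agreement(a, b)
    assert m.pairs == [] and m.mean_iou == 0.0 and m.mean_dice == 0.0


def test_half_overlap_pixel_count_oracle():
    a = _blobset([_rect((256, 256), 0, 0, 10, 10)])  # 100 px
    b = _blobset([_rect((256, 256), 0, 5, 10, 10)])  # 100 px, 50 shared
    m = blob_agreement(a, b)
    assert m.mean_iou == pytest.approx(1 / 3)
    assert m.mean_dice == pytest.approx(1 / 2)


def test_mismatched_frames_rejected():
    with pytest.raises(ValueError, match="frames"):
        blob_agreement(_blobset([], shape=(256, 256)), _blobset([], shape=(128, 128)))


def test_dice_dominates_iou_with_equality_iff_identical():
    rng = np.random.default_rng(3)
    for _ in range(200):
        a = rng.random((32, 32)) < 0.3
        b = rng.random((32, 32)) < 0.3
        if not a.any() or not b.any():
            continue
        m = blob_agreement(_blobset([a], (32, 32)), _blobset([b], (32, 32)))
        if not m.pairs:
            continue
        _, _, iou, dice = m.pairs[0]
        # brute-force pixel-set oracle
        sa = set(map(tuple, np.argwhere(a)))
        sb = set(map(tuple, np.argwhere(b)))
        inter, union = len(sa & sb), len(sa | sb)
        assert iou == pytest.approx(inter / union)
        assert dice == pytest.approx(2 * inter / (len(sa) + len(sb)))
        assert dice >= iou
        assert (dice == iou) == (sa == sb)


# -------------------------------------------------------------- attribution
def _zeroed_classifier():
    """A classifier whose output is constant (all weights zero)."""
    net = SmallConvNet(channels=(4, 8), seed=0)
    net.set_state([np.zeros_like(p) for p in net.get_state()])
    rng = np.random.default_rng(0)
    tiles = rng.integers(0, 255, (4, 256, 256, 3), dtype=np.uint8)
    return TileClassifier(net, compute_norm_stats(tiles), TrainConfig(channels=(4, 8)))


def test_constant_model_yields_zero_attribution():
    clf = _zeroed_classifier()
    tile = np.random.default_rng(1).integers(0, 255, (256, 256, 3), dtype=np.uint8)
    for method in ("guided_gradcam", "integrated_gradients"):
        am = attribution(clf, tile, method=method, seed=2)
        assert am.values.shape == (256, 256)
        assert am.values.sum() == 0.0


def test_attribution_matches_tile_shape_and_method_metadata(mel_model):
    tile = np.random.default_rng(2).integers(0, 255, (256, 256, 3), dtype=np.uint8)
    am = attribution(mel_model, tile, method="integrated_gradients", noise_samples=2, seed=3)
    assert am.values.shape == (256, 256)
    assert am.method == "integrated_gradients"
    assert 0.0 <= am.values.min() and am.values.max() <= 1.0


def test_unknown_method_rejected(mel_model):
    with pytest.raises(ValueError, match="method"):
        attribution(mel_model, np.zeros((256, 256, 3), dtype=np.uint8), method="lime")


def test_guided_gradcam_requires_conv_layers():
    net = SmallConvNet(channels=(), seed=0)
    rng = np.random.default_rng(0)
    tiles = rng.integers(0, 255, (4, 256, 256, 3), dtype=np.uint8)
    clf = TileClassifier(net, compute_norm_stats(tiles), TrainConfig())
    with pytest.raises(ValueError, match="conv"):
        attribution(clf, tiles[0], method="guided_gradcam")


def test_attribution_localizes_on_planted_melanocytes(mel_model, mel_study):
    """Most top-decile attribution mass falls on the planted cell regions."""
    from scipy import ndimage as ndi

    rec = mel_study.manifest.records
    sel = rec[(rec.fold == 0) & (rec.split == "train") & (rec.origin == "cutaneous") & (rec.label == 1)]
    fracs = []
    for row in sel.head(8).itertuples(index=False):
        fx = next(f for f in mel_study.fixtures if f.pair_id == row.pair_id)
        cells = (fx.truth.nucleus_labels > 0) | (fx.truth.cytoplasm_labels > 0)
        cells = ndi.binary_dilation(
            cells[row.tile_row : row.tile_row + 256, row.tile_col : row.tile_col + 256], iterations=8
        )
        tile = fx.he_image[row.tile_row : row.tile_row + 256, row.tile_col : row.tile_col + 256]
        v = attribution(mel_model, tile, seed=5).values
        top = v >= np.quantile(v, 0.9)
        fracs.append((top & cells).sum() / max(top.sum(), 1))
    assert np.mean(fracs) >= 0.6


# ----------------------------------------------------- dataset-level scores
def test_self_agreement_is_perfect_where_blobs_exist(mel_model, positive_tiles):
    rep = agreement_dataset(mel_model, mel_model, positive_tiles[:12], seed=4)
    assert rep["n_qualifying"] >= 1
    scored = [t for t in rep["per_tile"] if t["n_pairs"] > 0]
    assert scored, "no qualifying tile produced salient blobs"
    assert all(t["iou"] == 1.0 and t["dice"] == 1.0 for t in scored)


def test_cross_stain_models_converge_above_zero(mel_model, sox_model, positive_tiles):
    rep = agreement_dataset(mel_model, sox_model, positive_tiles[:20], seed=4)
    assert rep["n_qualifying"] >= 3
    assert rep["mean_dice"] >= rep["mean_iou"] >= 0.0
    assert rep["mean_iou"] > 0.0 and rep["mean_dice"] > 0.0


def test_unreachable_confidence_leaves_no_qualifying_tiles(mel_model, sox_model, positive_tiles):
    with pytest.warns(UserWarning, match="qualifying"):
        rep = agreement_dataset(mel_model, sox_model, positive_tiles[:6], confidence=1.0)
    assert rep["n_qualifying"] == 0


# ------------------------------------------------------------ null baseline
def test_null_baseline_deterministic_per_seed(mel_model, sox_model, positive_tiles):
    a = null_baseline(mel_model, sox_model, positive_tiles[:10], n_pairs=8, seed=6)
    b = null_baseline(mel_model, sox_model, positive_tiles[:10], n_pairs=8, seed=6)
    assert a["pairs"] == b["pairs"]
    assert a["mean_iou"] == b["mean_iou"] and a["mean_dice"] == b["mean_dice"]
    assert all(i != j for i, j in a["pairs"])


def test_degenerate_identical_pairs_reduce_to_matched_agreement(mel_model, sox_model, positive_tiles):
    idx = [0, 1, 2]
    control = null_baseline(mel_model, sox_model, positive_tiles[:6], seed=1, pairs=[(i, i) for i in idx])
    matched = []
    from virtualstain.saliency import _tile_agreement

    for i in idx:
        m = _tile_agreement(mel_model, sox_model, positive_tiles[i], positive_tiles[i], "guided_gradcam", 1, 0.2, 100)
        matched.append((m.mean_iou, m.mean_dice))
    assert control["mean_iou"] == pytest.approx(np.mean([m[0] for m in matched]))
    assert control["mean_dice"] == pytest.approx(np.mean([m[1] for m in matched]))


def test_null_baseline_needs_two_tiles(mel_model, sox_model, positive_tiles):
    with pytest.raises(ValueError, match="2 distinct"):
        null_baseline(mel_model, sox_model, positive_tiles[:1], n_pairs=5)


# -------------------------------------------------------------- renderings
def test_agreement_render_identical_attrs_have_no_exclusive_colors():
    rng = np.random.default_rng(0)
    attr = normalize_attribution(rng.uniform(size=(64, 64)))
    bg = np.full((64, 64, 3), 200, dtype=np.uint8)
    out = agreement_map_render(attr, attr, bg)
    both = attr > 0.2
    # exclusive colors are green- or red-dominant; none should appear
    greenish = (out[..., 1].astype(int) - out[..., 0] > 40) & (out[..., 1].astype(int) - out[..., 2] > 40)
    reddish = (out[..., 0].astype(int) - out[..., 1] > 40) & (out[..., 0].astype(int) - out[..., 2] > 40)
    assert not greenish.any() and not reddish.any()
    if both.any():
        blueish = out[..., 2].astype(int) - out[..., 0] > 20
        assert blueish[both].all()


def test_agreement_render_disjoint_attrs_have_no_blue():
    a = np.zeros((64, 64))
    b = np.zeros((64, 64))
    a[:16] = 1.0
    b[-16:] = 1.0
    bg = np.full((64, 64, 3), 200, dtype=np.uint8)
    out = agreement_map_render(a, b, bg)
    blueish = (out[..., 2].astype(int) - out[..., 0] > 40) & (out[..., 2].astype(int) - out[..., 1] > 40)
    assert not blueish.any()


def test_agreement_render_dim_mismatch_rejected():
    with pytest.raises(ValueError, match="dims"):
        agreement_map_render(np.zeros((8, 8)), np.zeros((9, 9)), np.zeros((8, 8, 3), dtype=np.uint8))


def test_stitched_view_has_no_hard_seams_after_smoothing():
    tiles = [[np.full((64, 64), float((i + j) % 2)) for j in range(4)] for i in range(4)]
    raw = stitch_maps(tiles, smooth_sigma=0)
    smoothed = stitch_maps(tiles, smooth_sigma=2.0)
    raw_jump = max(np.abs(np.diff(raw, axis=0)).max(), np.abs(np.diff(raw, axis=1)).max())
    smooth_jump = max(np.abs(np.diff(smoothed, axis=0)).max(), np.abs(np.diff(smoothed, axis=1)).max())
    assert raw_jump == 1.0
    assert smooth_jump < 0.3
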