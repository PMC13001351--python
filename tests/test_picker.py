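"""Tiling, stitching, skeletonization, NMS, and end-to-end picking."""

import numpy as np
import pytest
from skimage.morphology import medial_axis

from actinpick import (
    Micrograph,
    ParameterError,
    PickerParams,
    Pose,
    SegmentationMap,
    TargetParams,
    downsample,
    make_semantic_target,
    nms_picks,
    pick_from_truth,
    pick_micrograph,
    render_scene,
    skeletonize,
    stitch_max,
    tile_raster,
)
from actinpick.picker import binarize_channel
from actinpick.simulate import FilamentInstance, SceneSpec

VOX = 4.36


# ---------------------------------------------------------------- downsample

def test_downsample_identity_and_dc(rng):
    img = rng.standard_normal((64, 64)).astype(np.float32)
    m = Micrograph(img, 1.09)
    assert downsample(m, 1) is m
    const = Micrograph(np.full((64, 64), 3.5, np.float32), 1.09)
    out = downsample(const, 4)
    assert out.pixel_size == pytest.approx(4.36)
    np.testing.assert_allclose(out.image, 3.5, atol=1e-5)


def test_fourier_crop_passes_low_and_kills_high_frequencies():
    n, factor = 128, 4
    x = np.arange(n)
    xx, yy = np.meshgrid(x, x)
    low = np.cos(2 * np.pi * 3 * xx / n)  # 3 cycles, survives /4
    high = np.cos(2 * np.pi * 30 * xx / n)  # above the new Nyquist (16)
    out_low = downsample(Micrograph(low.astype(np.float32), 1.0), factor).image
    out_high = downsample(Micrograph(high.astype(np.float32), 1.0), factor).image
    expected = np.cos(2 * np.pi * 3 * np.arange(n // factor) * factor / n)
    np.testing.assert_allclose(out_low, np.broadcast_to(expected, out_low.shape), atol=1e-5)
    assert np.abs(out_high).max() < 1e-5


# ---------------------------------------------------------------- tiling

def test_single_tile_when_image_equals_tile():
    tiles, origins = tile_raster(np.zeros((128, 128)), 128, 32)
    assert origins == [(0, 0)] and len(tiles) == 1


def test_stride_arithmetic_224():
    _, origins = tile_raster(np.zeros((224, 224)), 128, 32)
    xs = sorted({ox for _, ox in origins})
    assert xs == [0, 96]


@pytest.mark.parametrize("shape", [(128, 160), (200, 333), (517, 129)])
def test_tile_coverage_is_exhaustive(shape):
    image = np.zeros(shape)
    tiles, origins = tile_raster(image, 128, 32)
    covered = np.zeros(shape, bool)
    for (oy, ox), t in zip(origins, tiles):
        assert t.shape == (128, 128)
        covered[oy : oy + 128, ox : ox + 128] = True
    assert covered.all()


def test_tile_rejects_small_image():
    with pytest.raises(ParameterError):
        tile_raster(np.zeros((64, 64)), 128, 32)


# ---------------------------------------------------------------- stitching

def test_stitch_single_tile_identity():
    tile = np.random.default_rng(0).dirichlet(np.ones(3), size=(16, 16)).transpose(2, 0, 1)
    seg = stitch_max([tile.astype(np.float32)], [(0, 0)], (16, 16), VOX)
    np.testing.assert_allclose(seg.channels, tile, rtol=1e-5)


def test_stitch_takes_maximum_in_overlap():
    a = np.full((1, 8, 8), 0.3, np.float32)
    b = np.full((1, 8, 8), 0.7, np.float32)
    seg = stitch_max([a, b], [(0, 0), (0, 4)], (8, 12), VOX, renormalize=False)
    np.testing.assert_allclose(seg.channels[0, :, 4:8], 0.7)
    np.testing.assert_allclose(seg.channels[0, :, :4], 0.3)


def test_stitch_order_invariant(rng):
    tiles = [rng.random((3, 16, 16)).astype(np.float32) for _ in range(4)]
    origins = [(0, 0), (0, 8), (8, 0), (8, 8)]
    a = stitch_max(tiles, origins, (24, 24), VOX)
    b = stitch_max(tiles[::-1], origins[::-1], (24, 24), VOX)
    np.testing.assert_array_equal(a.channels, b.channels)


def test_stitch_matches_brute_force(rng):
    tiles = [rng.random((2, 16, 16)).astype(np.float32) for _ in range(4)]
    origins = [(0, 0), (0, 10), (4, 0), (4, 10)]
    seg = stitch_max(tiles, origins, (20, 26), VOX, renormalize=False)
    brute = np.full((2, 20, 26), -np.inf)
    for t, (oy, ox) in zip(tiles, origins):
        for c in range(2):
            for y in range(16):
                for x in range(16):
                    brute[c, oy + y, ox + x] = max(brute[c, oy + y, ox + x], t[c, y, x])
    covered = ~np.isneginf(brute)
    np.testing.assert_array_equal(seg.channels[covered], brute[covered].astype(np.float32))


def test_stitch_rejects_out_of_bounds():
    with pytest.raises(ParameterError):
        stitch_max([np.ones((3, 8, 8), np.float32)], [(4, 0)], (8, 8), VOX)


# ---------------------------------------------------------------- binarize / skeleton

def test_binarize_channel_behaviour():
    ch = np.zeros((3, 8, 8), np.float32)
    ch[0] = 1.0
    seg = SegmentationMap(ch, VOX)
    mask, _ = binarize_channel(seg, "decorated", 0.8)
    assert not mask.any()
    ch2 = np.zeros((3, 8, 8), np.float32)
    ch2[2] = 0.9
    ch2[0] = 0.1
    mask2, score = binarize_channel(SegmentationMap(ch2, VOX), "decorated", 0.8)
    assert mask2.all()
    np.testing.assert_allclose(score, 0.9)
    with pytest.raises(ParameterError):
        binarize_channel(seg, "ribosome", 0.8)
    # monotone nonincreasing in threshold
    rng = np.random.default_rng(1)
    ch3 = np.zeros((3, 32, 32), np.float32)
    ch3[2] = rng.random((32, 32))
    seg3 = SegmentationMap(ch3, VOX)
    lo, _ = binarize_channel(seg3, 2, 0.3)
    hi, _ = binarize_channel(seg3, 2, 0.7)
    assert np.all(lo[hi])


def test_skeletonize_empty_and_thin_line():
    assert not skeletonize(np.zeros((16, 16), bool)).any()
    line = np.zeros((16, 16), bool)
    line[8, 2:14] = True
    np.testing.assert_array_equal(skeletonize(line), line)


def test_skeleton_of_bar_tracks_centerline():
    """5-px-wide bar thins to within 1 px of its centre row, matching an
    independent medial-axis reference."""
    bar = np.zeros((11, 60), bool)
    bar[3:8, 5:55] = True
    skel = skeletonize(bar)
    ys, xs = np.nonzero(skel)
    interior = (xs > 8) & (xs < 51)
    assert np.all(np.abs(ys[interior] - 5) <= 1)
    ref = medial_axis(bar)
    ry, rx = np.nonzero(ref)
    assert np.all(np.abs(ry[(rx > 8) & (rx < 51)] - 5) <= 1)
    # topology preserved: one 8-connected component in, one out
    from scipy import ndimage

    assert ndimage.label(skel, structure=np.ones((3, 3)))[1] == 1


# ---------------------------------------------------------------- NMS

def test_single_candidate_kept():
    skel = np.zeros((8, 8), bool)
    skel[3, 4] = True
    picks = nms_picks(skel, np.full((8, 8), 0.9), 44.0, VOX)
    assert len(picks) == 1
    assert tuple(picks.coords[0]) == (4.0, 3.0)


def test_hand_traced_three_candidate_nms():
    """Collinear candidates at 0/30/60 A with scores .90/.95/.85: the middle
    one wins and suppresses both neighbours."""
    px = 10.0  # Å per pixel; candidates 3 px apart = 30 Å
    skel = np.zeros((8, 16), bool)
    score = np.zeros((8, 16))
    for x, s in ((2, 0.90), (5, 0.95), (8, 0.85)):
        skel[4, x] = True
        score[4, x] = s
    picks = nms_picks(skel, score, 44.0, px)
    assert len(picks) == 1
    assert tuple(picks.coords[0]) == (5.0, 4.0)
    assert picks.scores[0] == pytest.approx(0.95)


def test_nms_spacing_and_greedy_optimality(rng):
    skel = rng.random((256, 256)) < 0.05
    score = rng.random((256, 256))
    picks = nms_picks(skel, score, 44.0, VOX)
    assert picks.min_pairwise_spacing_A() >= 44.0
    # every suppressed candidate is within the radius of a kept pick with
    # greater-or-equal score
    ys, xs = np.nonzero(skel)
    kept = {tuple(c) for c in picks.coords}
    kept_arr = picks.coords
    kept_scores = picks.scores
    r_px = 44.0 / VOX
    for y, x in zip(ys, xs):
        if (float(x), float(y)) in kept:
            continue
        d = np.hypot(kept_arr[:, 0] - x, kept_arr[:, 1] - y)
        near = d <= r_px + 1e-9
        assert near.any()
        assert kept_scores[near].max() >= score[y, x]


def test_nms_determinism_with_tied_scores():
    skel = np.zeros((32, 32), bool)
    skel[10:20, 10:20] = True
    a = nms_picks(skel, np.ones((32, 32)), 44.0, VOX)
    b = nms_picks(skel, np.ones((32, 32)), 44.0, VOX)
    np.testing.assert_array_equal(a.coords, b.coords)
    # row-major tie-break: first candidate in reading order wins first
    assert tuple(a.coords[0]) == (10.0, 10.0)


# ---------------------------------------------------------------- end-to-end

class _BackgroundModel:
    """Stub segmenter: everything is background."""

    def predict_proba(self, X):
        out = np.zeros((len(X), 3) + X.shape[1:], np.float32)
        out[:, 0] = 1.0
        return out


def test_blank_micrograph_gives_empty_picklist():
    m = Micrograph(np.zeros((512, 512), np.float32), 1.09)
    picks = pick_micrograph(m, _BackgroundModel())
    assert len(picks) == 0


def _planted_scene(small_library, box=64):
    dec = FilamentInstance(5, Pose(psi=20.0, rot=30.0, tilt=90.0, shift_xy=(40.0, 40.0)))
    bare = FilamentInstance(None, Pose(psi=0.0, rot=120.0, tilt=90.0, shift_xy=(-60.0, -60.0)))
    scene = SceneSpec([dec, bare], box_px_out=box)
    composite, per = render_scene(scene, small_library)
    target = make_semantic_target(
        per, [True, False], TargetParams(pixel_size_A=VOX), shape=(box, box)
    )
    return scene, composite, per, target


def test_planted_truth_pick_hits_decorated_axis(small_library):
    """With the ground-truth map standing in for the model, picks land within
    20 A of the planted decorated filament axis and avoid the bare one."""
    scene, composite, per, target = _planted_scene(small_library)
    m = Micrograph(composite, VOX)
    seg = SegmentationMap(target.channels.astype(np.float32), VOX)
    picks = pick_micrograph(m, None, PickerParams(downsample_factor=1), segmentation=seg)
    assert len(picks) >= 1

    def axis_distance(fil, x_px, y_px):
        # projected axis: direction of the rotated z axis, through centre+shift
        from actinpick.simulate import rotation_matrix

        R = rotation_matrix(fil.pose.rot, fil.pose.tilt, fil.pose.psi)
        d = R @ np.array([0.0, 0.0, 1.0])
        d2 = np.array([d[0], d[1]])
        d2 /= np.linalg.norm(d2)
        c = (64 - 1) / 2.0
        p0 = np.array([c + fil.pose.shift_xy[0] / VOX, c + fil.pose.shift_xy[1] / VOX])
        v = np.array([x_px, y_px]) - p0
        return abs(v[0] * d2[1] - v[1] * d2[0]) * VOX

    dec, bare = scene.filaments
    dists_dec = [axis_distance(dec, x, y) for x, y in picks.coords]
    assert min(dists_dec) <= 20.0
    bare_mask = target.channels[1].astype(bool)
    for x, y in picks.coords:
        assert not bare_mask[int(round(y)), int(round(x))]


def test_pick_count_bounded_by_packing(small_library):
    """A single filament of projected length L yields at most L/44 + 1 picks."""
    scene = SceneSpec(
        [FilamentInstance(3, Pose(0.0, 45.0, 90.0))], box_px_out=64
    )
    _, per = render_scene(scene, small_library)
    target = make_semantic_target(per, [True], TargetParams(pixel_size_A=VOX))
    picks = pick_from_truth(target, PickerParams(), VOX)
    length_A = 64 * np.sqrt(2) * VOX  # diagonal upper bound on projected length
    assert 1 <= len(picks) <= int(length_A / 44.0) + 1


def test_truth_path_trivial_cases(fixture50):
    t_empty = np.zeros((3, 64, 64), np.uint8)
    t_empty[0] = 1
    from actinpick import SemanticTarget

    empty = pick_from_truth(SemanticTarget(t_empty), PickerParams(), VOX)
    assert len(empty) == 0
    tgt = SemanticTarget(fixture50.targets[2])
    a = pick_from_truth(tgt, PickerParams(), VOX)
    b = pick_from_truth(tgt, PickerParams(), VOX)
    np.testing.assert_array_equal(a.coords, b.coords)


def test_end_to_end_determinism(small_library):
    _, composite, _, target = _planted_scene(small_library)
    m = Micrograph(composite, VOX)
    seg = SegmentationMap(target.channels.astype(np.float32), VOX)
    p1 = pick_micrograph(m, None, PickerParams(downsample_factor=1), segmentation=seg)
    p2 = pick_micrograph(m, None, PickerParams(downsample_factor=1), segmentation=seg)
    np.testing.assert_array_equal(p1.coords, p2.coords)
    np.testing.assert_array_equal(p1.scores, p2.scores)


def test_picklist_star_roundtrip(tmp_path, rng):
    from actinpick.io import read_star_picks, write_star_picks
    from actinpick.picker import PickList

    coords = rng.uniform(0, 4000, size=(100, 2))
    scores = rng.uniform(0.5, 1.0, size=100)
    picks = PickList(coords, scores, 1.09)
    path = tmp_path / "picks.star"
    write_star_picks(picks, path)
    coords2, scores2 = read_star_picks(path)
    np.testing.assert_array_equal(coords, coords2)
    np.testing.assert_array_equal(scores, scores2)

    empty = PickList(np.empty((0, 2)), np.empty(0), 1.09)
    write_star_picks(empty, tmp_path / "empty.star")
    c3, s3 = read_star_picks(tmp_path / "empty.star")
    assert len(c3) == 0 and len(s3) == 0
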