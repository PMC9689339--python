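"""Slice segmentation stages: stretch, binarize, morphology, growing."""

from collections import deque
from dataclasses import replace

import numpy as np
import pytest

from gliopipe.fcm import FCMParams, FCMState, neighboring_fcm
from gliopipe.metrics import dice
from gliopipe.phantom import PhantomConfig, generate_volume, region_masks
from gliopipe.segmentation import (
    MorphParams,
    RegionGrowParams,
    binarize_from_fcm,
    enhance_contrast,
    enhance_stack,
    fill_gaps,
    region_grow,
    remove_small_regions,
    score_objects,
    segment_slice,
    select_tumor_object,
)


def interp_percentile(values, q):
    """Independent linear-interpolation percentile (sorted-order definition)."""
    v = np.sort(np.ravel(values))
    pos = q * (len(v) - 1)
    lo, frac = int(np.floor(pos)), pos - int(np.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] * (1 - frac) + v[hi] * frac


class TestEnhanceContrast:
    def test_constant_slice_returned_unchanged(self):
        sl = np.full((10, 10), 0.4)
        assert np.array_equal(enhance_contrast(sl), sl)

    def test_full_range_linear_stretch_hits_endpoints(self):
        sl = np.linspace(0.2, 0.6, 100).reshape(10, 10)
        out = enhance_contrast(sl, low_frac=0.0, high_frac=0.0)
        assert out.min() == 0.0 and out.max() == 1.0
        assert np.allclose(out, (sl - 0.2) / 0.4)

    def test_percentile_saturation_matches_independent_oracle(self):
        sl = (np.arange(1, 101) / 100.0).reshape(10, 10)
        out = enhance_contrast(sl, 0.01, 0.01)
        lo = interp_percentile(sl, 0.01)
        hi = interp_percentile(sl, 0.99)
        assert np.all(out[sl <= lo] == 0.0)
        assert np.all(out[sl >= hi] == 1.0)
        mid = (sl > lo) & (sl < hi)
        assert np.allclose(out[mid], (sl[mid] - lo) / (hi - lo))


def one_hot_state(labels, centroids):
    labels = np.asarray(labels)
    c = len(centroids)
    u = np.eye(c)[labels.ravel()]
    return FCMState(u, np.asarray(centroids, float), 1, True, labels.shape, np.array([]))


class TestBinarize:
    def test_bright_cluster_pixels_selected(self):
        labels = np.array([[0, 2], [1, 2]])
        mask = binarize_from_fcm(one_hot_state(labels, [0.1, 0.5, 0.9]))
        assert np.array_equal(mask, labels == 2)

    def test_unsorted_centroids_still_pick_brightest(self):
        labels = np.array([[0, 1], [1, 0]])
        mask = binarize_from_fcm(one_hot_state(labels, [0.9, 0.1]))
        assert np.array_equal(mask, labels == 0)

    def test_all_dark_gives_empty_mask(self):
        labels = np.zeros((3, 3), dtype=int)
        assert not binarize_from_fcm(one_hot_state(labels, [0.2, 0.8])).any()

    def test_phantom_tumor_recovered_before_refinement(self, suite_volume):
        # bright-cluster mask alone should already overlap the tumor well
        state = neighboring_fcm(enhance_stack(suite_volume.slices), 10, FCMParams(c=4))
        mask = binarize_from_fcm(state)
        truth = region_masks(suite_volume.multiclass_masks[10])["region1"]
        assert dice(mask, truth) > 0.8


def flood_components(mask, connectivity=8):
    """BFS connected components, an oracle for the labelling-based path."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    offs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offs += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    comps = []
    for r, c in zip(*np.nonzero(mask)):
        if seen[r, c]:
            continue
        comp = []
        queue = deque([(r, c)])
        seen[r, c] = True
        while queue:
            i, j = queue.popleft()
            comp.append((i, j))
            for di, dj in offs:
                ni, nj = i + di, j + dj
                if 0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]:
                    if mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        queue.append((ni, nj))
        comps.append(comp)
    return comps


class TestRemoveSmallRegions:
    def test_threshold_semantics_at_256(self):
        mask = np.zeros((40, 40), bool)
        mask[:16, :16] = True  # 256 px
        assert remove_small_regions(mask, 256).sum() == 256
        mask2 = np.zeros((40, 40), bool)
        mask2[:16, :16] = True
        mask2[0, 0] = False  # 255 px
        assert not remove_small_regions(mask2, 256).any()

    def test_empty_mask_passes_through(self):
        assert not remove_small_regions(np.zeros((5, 5), bool), 10).any()

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(5):
            mask = rng.random((24, 24)) > 0.6
            got = remove_small_regions(mask, 10)
            expected = np.zeros_like(mask)
            for comp in flood_components(mask):
                if len(comp) >= 10:
                    for i, j in comp:
                        expected[i, j] = True
            assert np.array_equal(got, expected)

    def test_idempotent(self, rng):
        mask = rng.random((30, 30)) > 0.55
        once = remove_small_regions(mask, 12)
        assert np.array_equal(once, remove_small_regions(once, 12))


def closing_oracle(mask, k=2):
    """Set-morphology closing with a k x k structuring element.

    Works on an enlarged domain so the background outside the array is
    honoured exactly (infinite-domain semantics); closing is invariant to
    the structuring-element origin, so offsets (0..k-1) are used for both
    passes.
    """
    mask = np.asarray(mask, bool)
    offs = [(i, j) for i in range(k) for j in range(k)]
    h, w = mask.shape
    big = np.zeros((h + 2 * k, w + 2 * k), bool)
    big[k : k + h, k : k + w] = mask
    dil = np.zeros_like(big)
    for r, c in zip(*np.nonzero(big)):
        for di, dj in offs:
            dil[r + di, c + dj] = True
    out = np.zeros_like(big)
    for r in range(big.shape[0] - k):
        for c in range(big.shape[1] - k):
            if all(dil[r + di, c + dj] for di, dj in offs):
                out[r, c] = True
    return out[k : k + h, k : k + w]


class TestFillGaps:
    def test_solid_rectangle_unchanged_by_closing(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 2:10] = True
        assert np.array_equal(fill_gaps(mask), mask)

    def test_interior_single_pixel_hole_filled(self):
        mask = np.zeros((12, 12), bool)
        mask[3:9, 3:9] = True
        mask[5, 5] = False
        assert fill_gaps(mask)[5, 5]

    def test_empty_mask_stays_empty(self):
        assert not fill_gaps(np.zeros((6, 6), bool)).any()

    def test_matches_set_morphology_oracle(self, rng):
        for _ in range(3):
            mask = rng.random((14, 14)) > 0.45
            assert np.array_equal(fill_gaps(mask, 2, "close"), closing_oracle(mask, 2))

    def test_closing_idempotent_on_own_output(self, rng):
        mask = rng.random((20, 20)) > 0.5
        once = fill_gaps(mask)
        assert np.array_equal(fill_gaps(once), once)

    def test_open_order_erodes_first(self):
        mask = np.zeros((8, 8), bool)
        mask[4, 4] = True  # single pixel: opening removes it, closing keeps it
        assert not fill_gaps(mask, 2, "open").any()
        assert fill_gaps(mask, 2, "close")[4, 4]


class TestScoreAndSelect:
    def test_disk_roundness_near_one(self):
        rr, cc = np.meshgrid(np.arange(50), np.arange(50), indexing="ij")
        disk = (rr - 25) ** 2 + (cc - 25) ** 2 <= 20**2
        objs = score_objects(disk)
        assert len(objs) == 1
        assert 0.85 <= objs[0].roundness <= 1.15

    def test_thin_line_has_low_roundness(self):
        mask = np.zeros((5, 60), bool)
        mask[2, 5:55] = True
        objs = score_objects(mask)
        assert objs[0].area == 50
        assert objs[0].roundness < 0.3

    def test_empty_mask_yields_no_objects(self):
        assert score_objects(np.zeros((4, 4), bool)) == []

    def test_best_roundness_wins(self):
        rr, cc = np.meshgrid(np.arange(40), np.arange(80), indexing="ij")
        disk = (rr - 20) ** 2 + (cc - 60) ** 2 <= 10**2
        line = np.zeros_like(disk)
        line[5, 2:30] = True
        objs = score_objects(disk | line)
        chosen = select_tumor_object(objs)
        assert chosen is not None and chosen.mask[20, 60]

    def test_empty_list_selects_nothing(self):
        assert select_tumor_object([]) is None

    def test_ties_broken_by_area_then_centroid(self):
        from gliopipe.segmentation import RegionObject

        small = RegionObject(np.ones((1, 1), bool), 100, 10.0, 0.5, (8.0, 8.0))
        large = RegionObject(np.ones((1, 1), bool), 400, 20.0, 0.5, (30.0, 30.0))
        assert select_tumor_object([small, large]) is large
        twin = RegionObject(np.ones((1, 1), bool), 100, 10.0, 0.5, (2.0, 2.0))
        assert select_tumor_object([small, twin]) is twin


def grow_oracle(img, seed_mask, tau):
    """Exhaustive sweep-based region growing (pure python)."""
    region = {tuple(p) for p in np.argwhere(seed_mask)}
    h, w = img.shape
    while True:
        mean = np.mean([img[p] for p in region])
        frontier = set()
        for i, j in region:
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni, nj = i + di, j + dj
                    if 0 <= ni < h and 0 <= nj < w and (ni, nj) not in region:
                        frontier.add((ni, nj))
        added = {p for p in frontier if abs(img[p] - mean) <= tau}
        if not added:
            break
        region |= added
    out = np.zeros_like(seed_mask)
    for p in region:
        out[p] = True
    return out


class TestRegionGrow:
    def test_flat_blob_grows_to_exactly_the_blob(self):
        img = np.full((10, 10), 0.2)
        img[3:7, 3:7] = 0.9
        seed = np.zeros((10, 10), bool)
        seed[5, 5] = True
        out = region_grow(img, seed, tau=0.1)
        assert np.array_equal(out, img == 0.9)

    def test_zero_tolerance_takes_equal_valued_closure_only(self, rng):
        img = rng.permutation(100).reshape(10, 10).astype(float)
        seed = np.zeros((10, 10), bool)
        seed[4, 4] = True
        out = region_grow(img, seed, tau=0.0)
        assert np.array_equal(out, seed)

    def test_two_intensity_image_matches_bfs_oracle(self):
        img = np.full((12, 12), 0.3)
        img[2:8, 3:9] = 0.9
        seed = np.zeros((12, 12), bool)
        seed[4, 5] = True
        got = region_grow(img, seed, tau=0.2)
        assert np.array_equal(got, grow_oracle(img, seed, 0.2))
        assert not got[(img == 0.3)].any()

    def test_oracle_agreement_on_noisy_image(self, rng):
        img = rng.random((10, 10))
        seed = np.zeros((10, 10), bool)
        seed[5, 5] = True
        tau = 0.25
        assert np.array_equal(region_grow(img, seed, tau), grow_oracle(img, seed, tau))

    def test_output_superset_of_seed(self, rng):
        img = rng.random((9, 9))
        seed = rng.random((9, 9)) > 0.8
        seed[0, 0] = True
        out = region_grow(img, seed, tau=0.1)
        assert np.all(out[seed])

    def test_empty_seed_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            region_grow(np.zeros((4, 4)), np.zeros((4, 4), bool), 0.1)


class TestSegmentSlice:
    def test_noiseless_single_disk_recovered_exactly(self):
        base = PhantomConfig().scaled(96, 96, slice_count=11, tumorous_slice_range=(3, 7), seed=0)
        tumor = replace(
            base.tumor,
            subregion_fractions={1: 0.0, 2: 0.0, 3: 0.0, 4: 1.0},
            modulation=0.0,
        )
        cfg = replace(base, tumor=tumor, noise_sigma=0.0, bias_field_amplitude=0.0)
        vol = generate_volume(cfg)
        res = segment_slice(vol.slices, 5, FCMParams(), MorphParams(min_px=41))
        truth = region_masks(vol.multiclass_masks[5])["region1"]
        assert dice(res.final_tumor_mask, truth) == 1.0

    def test_stage_masks_nest_correctly(self, suite_volume):
        res = segment_slice(suite_volume.slices, 10, FCMParams(), MorphParams(min_px=41))
        assert res.selected_object is not None
        assert np.all(res.initial_tumor_mask <= res.cleaned_mask)
        assert np.all(res.initial_tumor_mask <= res.final_tumor_mask)

    def test_no_surviving_object_yields_empty_result_not_error(self):
        # a featureless noisy stack: nothing passes the area filter
        rng = np.random.default_rng(0)
        stack = 0.02 * rng.random((5, 32, 32))
        res = segment_slice(stack, 2, FCMParams(c=2), MorphParams(min_px=2000))
        assert not res.final_tumor_mask.any()
        assert res.selected_object is None

    def test_neighboring_beats_standard_on_phantom_volume(self, suite_volume):
        # paired run over every tumorous slice of one seeded phantom; the
        # window-averaged variant avoids the single-slice failure modes
        from gliopipe.segmentation import enhance_stack

        enhanced = enhance_stack(suite_volume.slices)
        near, std = [], []
        for s in suite_volume.tumorous_indices():
            truth = region_masks(suite_volume.multiclass_masks[s])["region1"]
            rn = segment_slice(
                suite_volume.slices, int(s), FCMParams(), MorphParams(min_px=41),
                enhanced_stack=enhanced,
            )
            rs = segment_slice(
                suite_volume.slices, int(s), FCMParams(window_halfwidth=0),
                MorphParams(min_px=41), enhanced_stack=enhanced,
            )
            near.append(dice(rn.final_tumor_mask, truth))
            std.append(dice(rs.final_tumor_mask, truth))
        assert np.mean(near) >= np.mean(std)
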