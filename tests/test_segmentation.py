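import numpy as np
import pytest
from skimage import morphology

from imfishctc.io import ChannelImage, ChannelRole, FormatError
from imfishctc.segmentation import (
    QcFlag,
    SegmentationParams,
    binarize,
    gradient_magnitude,
    label_nuclei,
    morph_clean,
    otsu_threshold,
    segment_dapi,
    segment_watershed,
    to_gray,
)
from imfishctc.synthetic import SimulationParams, match_regions, simulate_field

from conftest import make_stack


def brute_force_otsu(values: np.ndarray) -> int:
    """Independent oracle: exhaustive between-class-variance maximization."""
    flat = values.ravel().astype(np.int64)
    n = flat.size
    best_t, best_v = int(flat.max()), -1.0
    for t in range(int(flat.max())):
        bg = flat[flat <= t]
        fg = flat[flat > t]
        if bg.size == 0 or fg.size == 0:
            continue
        w0, w1 = bg.size / n, fg.size / n
        v = w0 * w1 * (bg.mean() - fg.mean()) ** 2
        if v > best_v + 1e-12:  # strict: ties keep the lower threshold
            best_t, best_v = t, v
    return best_t


class TestToGray:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((0, 0, 0), 0), ((255, 255, 255), 255), ((100, 0, 0), 30)],
    )
    def test_luminance_formula(self, rgb, expected):
        arr = np.tile(np.array(rgb, np.uint8), (4, 4, 1))
        assert np.all(to_gray(arr).pixels == expected)

    def test_single_plane_rejected(self):
        with pytest.raises(FormatError):
            to_gray(np.zeros((4, 4), np.uint8))


class TestGradientMagnitude:
    def test_constant_image_zero_gradient(self):
        img = ChannelImage(np.full((8, 8), 77, np.uint8), 8, ChannelRole.DAPI)
        assert not gradient_magnitude(img).pixels.any()

    def test_vertical_step_responds_4h_on_edge_columns(self):
        h = 50
        arr = np.zeros((8, 8), np.uint8)
        arr[:, 4:] = h
        mag = gradient_magnitude(ChannelImage(arr, 8, ChannelRole.DAPI)).pixels
        assert mag.max() == 4 * h
        assert np.all(mag[:, [3, 4]] == 4 * h)
        assert not mag[:, :3].any() and not mag[:, 6:].any()

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(0)
        arr = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        a = gradient_magnitude(ChannelImage(arr, 8, ChannelRole.DAPI)).pixels
        b = gradient_magnitude(ChannelImage(arr.T.copy(), 8, ChannelRole.DAPI)).pixels
        assert np.array_equal(a.T, b)


class TestOtsu:
    def test_bimodal_threshold_separates_modes(self):
        arr = np.concatenate([np.full(50, 10), np.full(50, 200)]).astype(np.uint8)
        t = otsu_threshold(arr)
        assert 10 <= t < 200
        img = ChannelImage(arr.reshape(10, 10), 8, ChannelRole.DAPI)
        assert binarize(img).sum() == 50

    def test_constant_image_has_empty_foreground(self):
        img = ChannelImage(np.full((5, 5), 42, np.uint8), 8, ChannelRole.DAPI)
        assert not binarize(img).any()

    def test_three_level_histogram_matches_brute_force(self):
        arr = np.concatenate(
            [np.zeros(30), np.full(50, 100), np.full(20, 200)]
        ).astype(np.uint8)
        assert otsu_threshold(arr) == brute_force_otsu(arr)

    def test_random_histograms_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n_levels = rng.integers(2, 8)
            levels = rng.choice(256, size=n_levels, replace=False)
            counts = rng.integers(1, 50, size=n_levels)
            arr = np.repeat(levels, counts).astype(np.uint8)
            assert otsu_threshold(arr) == brute_force_otsu(arr)


class TestMorphClean:
    PARAMS = SegmentationParams(min_area_px=5, max_area_px=10_000, morphology_radius_px=2)

    def test_isolated_pixel_removed(self):
        m = np.zeros((20, 20), bool)
        m[10, 10] = True
        assert not morph_clean(m, self.PARAMS).any()

    def test_hole_filled_outline_kept(self):
        m = np.zeros((60, 60), bool)
        rr, cc = np.ogrid[:60, :60]
        disk = (rr - 30) ** 2 + (cc - 30) ** 2 <= 20**2
        m[disk] = True
        m[29:32, 29:32] = False  # 3-px hole
        out = morph_clean(m, self.PARAMS)
        assert out[30, 30]  # hole filled
        assert abs(out.sum() - disk.sum()) < 60  # outline preserved up to radius effects

    def test_idempotent_on_random_disk_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            m = np.zeros((80, 80), bool)
            for _ in range(rng.integers(1, 6)):
                r, c = rng.integers(10, 70, 2)
                rad = rng.integers(3, 12)
                rr, cc = np.ogrid[:80, :80]
                m |= (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
            once = morph_clean(m, self.PARAMS)
            assert np.array_equal(morph_clean(once, self.PARAMS), once)


class TestLabelNuclei:
    PARAMS = SegmentationParams(
        min_area_px=10, max_area_px=10_000, min_solidity=0.85, exclude_border=True
    )

    @staticmethod
    def _disk(center, radius, shape=(100, 100)):
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2

    def test_two_disks_labeled_in_raster_order(self):
        m = self._disk((70, 20), 8) | self._disk((20, 70), 8)
        regions = label_nuclei(m, self.PARAMS)
        assert [r.label for r in regions] == [1, 2]
        assert regions[0].centroid[0] < regions[1].centroid[0]

    def test_dumbbell_flagged_aggregated(self):
        m = self._disk((50, 40), 12) | self._disk((50, 68), 12)
        m |= self._disk((50, 54), 3)  # thin bridge
        regions = label_nuclei(m, self.PARAMS)
        assert len(regions) == 1
        assert QcFlag.AGGREGATED in regions[0].qc_flags
        assert regions[0].excluded

    def test_empty_mask_gives_empty_list(self):
        assert label_nuclei(np.zeros((10, 10), bool), self.PARAMS) == []

    def test_border_touching_region_flagged(self):
        m = self._disk((0, 50), 10)
        regions = label_nuclei(m, self.PARAMS)
        assert QcFlag.TOUCHES_BORDER in regions[0].qc_flags

    def test_area_gates_flag_small_and_large(self):
        params = SegmentationParams(min_area_px=50, max_area_px=400)
        m = self._disk((20, 20), 3) | self._disk((60, 60), 13)
        regions = label_nuclei(m, params)
        assert QcFlag.TOO_SMALL in regions[0].qc_flags
        assert QcFlag.TOO_LARGE in regions[1].qc_flags

    def test_masks_disjoint_and_area_consistent(self):
        m = self._disk((30, 30), 10) | self._disk((70, 70), 12)
        regions = label_nuclei(m, self.PARAMS)
        full = np.zeros((100, 100), int)
        for r in regions:
            assert r.area == int(r.mask.sum())
            full += r.full_mask((100, 100)).astype(int)
        assert full.max() == 1  # pairwise disjoint


class TestSegmentDapi:
    def test_recovers_all_nuclei_with_good_iou(self, easy_field):
        stack, truth = easy_field
        regions = segment_dapi(stack)
        clean = [r for r in regions if not r.excluded]
        assert len(clean) == len(truth)
        matches = match_regions(truth, regions, (stack.height, stack.width), min_iou=0.7)
        assert all(lab is not None for lab in matches.values())

    def test_blank_field_yields_no_regions(self):
        stack = make_stack(DAPI=np.zeros((64, 64)))
        assert segment_dapi(stack) == []

    def test_missing_dapi_rejected(self):
        from imfishctc.io import ChannelStack

        with pytest.raises(ValueError):
            ChannelStack(field_id="x", channels={})

    def test_deterministic(self, easy_field):
        stack, _ = easy_field
        a = segment_dapi(stack)
        b = segment_dapi(stack)
        assert [(r.label, r.bbox, r.area) for r in a] == [
            (r.label, r.bbox, r.area) for r in b
        ]
        assert all(np.array_equal(x.mask, y.mask) for x, y in zip(a, b))


class TestWatershed:
    def test_splits_overlapping_pair_plain_pipeline_merges(self):
        stack, truth = simulate_field(
            SimulationParams(seed=201, overlap_fraction=0.34, n_cells=12)
        )
        plain = segment_dapi(stack)
        ws = segment_watershed(stack)
        assert len(plain) < len(truth)  # overlapped pairs fuse
        assert len(ws) == len(truth)  # watershed recovers them

    def test_agrees_with_plain_pipeline_on_separated_nuclei(self, easy_field):
        stack, _ = easy_field
        assert len(segment_watershed(stack)) == len(segment_dapi(stack))

    def test_blank_field(self):
        stack = make_stack(DAPI=np.zeros((64, 64)))
        assert segment_watershed(stack) == []

    def test_region_masks_disjoint(self):
        stack, _ = simulate_field(
            SimulationParams(seed=202, overlap_fraction=0.34, n_cells=12)
        )
        regions = segment_watershed(stack)
        total = np.zeros((stack.height, stack.width), int)
        for r in regions:
            total += r.full_mask(total.shape).astype(int)
        assert total.max() == 1
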