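"""Thresholding, MSER and ROI-extraction oracles and algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planktosort.segmentation import (
    MserParams,
    SauvolaParams,
    calibrate_k,
    combine_masks,
    deduplicate_rois,
    extract_rois,
    mser_large,
    otsu_global,
    sauvola_mask,
    sauvola_threshold,
)
from planktosort.synthscene import SceneConfig, generate_scene
from oracles import otsu_exhaustive, sauvola_naive


# ---------------------------------------------------------------------------
# Otsu



class TestOtsu:
    def test_constant_image_degenerate(self):
        res = otsu_global(np.full((8, 8), 128, np.uint8))
        assert res.degenerate
        assert res.t_star == 128
        assert res.sigma_b2 == 0.0

    def test_bimodal_half_half(self):
        img = np.concatenate(
            [np.full(50, 50, np.uint8), np.full(50, 200, np.uint8)]
        ).reshape(10, 10)
        res = otsu_global(img, smooth_window=1)
        assert res.sigma_b2 == pytest.approx(0.25 * 150**2)  # w0*w1*(mu0-mu1)^2
        assert 50 <= res.t_star < 200

    def test_quarter_three_quarter_split(self):
        img = np.concatenate(
            [np.zeros(25, np.uint8), np.full(75, 255, np.uint8)]
        ).reshape(10, 10)
        res = otsu_global(img, smooth_window=1)
        assert res.sigma_b2 == pytest.approx(0.1875 * 255**2)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        res = otsu_global(img, smooth_window=1)
        t_ref, s_ref = otsu_exhaustive(img)
        assert res.t_star == t_ref
        assert res.sigma_b2 == pytest.approx(s_ref, rel=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_class_fractions_and_mixture_identity(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        res = otsu_global(img, smooth_window=5)
        assert res.w0 + res.w1 == pytest.approx(1.0, abs=1e-9)
        assert res.mu_t == pytest.approx(
            res.w0 * res.mu0 + res.w1 * res.mu1, abs=1e-6
        )
        assert res.sigma_b2 >= 0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_global(np.empty((0, 0), np.uint8))


# ---------------------------------------------------------------------------
# Sauvola



class TestSauvola:
    def test_constant_image_gives_empty_mask(self):
        # s = 0 everywhere, so T = 100 * (1 - k) = 40 and nothing is darker
        img = np.full((60, 60), 100, np.uint8)
        p = SauvolaParams(window=19, k=0.6, R=128)
        t = sauvola_threshold(img, p)
        assert np.allclose(t, 40.0)
        assert not sauvola_mask(img, p).any()

    def test_defaults_are_study_operating_point(self):
        p = SauvolaParams()
        assert (p.window, p.k, p.R) == (77, 0.6, 128.0)

    def test_matches_naive_oracle_on_disk_scene(self):
        img = np.full((200, 200), 200, np.uint8)
        yy, xx = np.mgrid[:200, :200]
        img[(yy - 100) ** 2 + (xx - 100) ** 2 <= 30**2] = 20
        p = SauvolaParams(window=31, k=0.6, R=128)
        assert np.array_equal(sauvola_mask(img, p), sauvola_naive(img, p))

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            sauvola_mask(np.zeros((10, 10), np.uint8), SauvolaParams(window=11))

    def test_catches_small_dark_organisms(self):
        cfg = SceneConfig(
            width=300, height=300, scale=0.25, n_particulates=0,
            n_copepod=2, n_bubble=0, noise_sigma=0.0, seed=9, target_cap=None,
        )
        scene = generate_scene(cfg)
        mask = sauvola_mask(scene.image, SauvolaParams(window=19))
        for t in scene.truth:
            sub = mask[t.top : t.top + t.height, t.left : t.left + t.width]
            assert sub.sum() >= 0.3 * t.area


# ---------------------------------------------------------------------------
# MSER


class TestMser:
    def test_constant_image_has_no_regions(self):
        assert mser_large(np.full((100, 100), 77, np.uint8)) == []

    def test_uniform_disk_recovered(self):
        img = np.full((512, 512), 200, np.uint8)
        yy, xx = np.mgrid[:512, :512]
        disk = (yy - 256) ** 2 + (xx - 256) ** 2 <= 56**2  # ~9850 px
        img[disk] = 20
        regions = mser_large(img, MserParams())
        assert len(regions) == 1
        inter = (regions[0] & disk).sum()
        union = (regions[0] | disk).sum()
        assert inter / union >= 0.9

    def test_area_gate_drops_small_disk(self):
        img = np.full((512, 512), 200, np.uint8)
        yy, xx = np.mgrid[:512, :512]
        img[(yy - 256) ** 2 + (xx - 256) ** 2 <= 30**2] = 20  # ~2800 px
        assert mser_large(img, MserParams(min_area=5000)) == []

    def test_no_region_at_or_below_gate(self, small_scene):
        params = MserParams(min_area=312)
        for m in mser_large(small_scene.image, params):
            assert m.sum() > params.min_area

    def test_component_tree_matches_skimage(self):
        """Cross-check the numba union-find flood against skimage's max_tree:
        identical (level, subtree-area) node sets."""
        from skimage.morphology import max_tree

        from planktosort.segmentation import _canonical_pointers, _max_tree_parent

        rng = np.random.default_rng(0)
        img = rng.integers(0, 40, (40, 40)).astype(np.int64)

        def node_set(parent, val):
            n = parent.size
            canon = _canonical_pointers(parent, val)
            area = np.bincount(canon, minlength=n).astype(np.int64)
            nodes = np.flatnonzero(
                (parent == np.arange(n)) | (val[parent] != val)
            )
            lv = val[nodes]
            for level in np.unique(lv)[::-1]:
                grp = nodes[lv == level]
                par = canon[parent[grp]]
                keep = par != grp
                np.add.at(area, par[keep], area[grp[keep]])
            return {(int(val[x]), int(area[x])) for x in nodes}

        flat = img.ravel()
        order = np.argsort(flat, kind="stable")
        ours = _max_tree_parent(flat, order, img.shape[1], img.shape[0])
        ref, _ = max_tree(img, connectivity=2)
        assert node_set(ours, flat) == node_set(ref.ravel(), flat)

    def test_translucent_body_kept_whole(self):
        """Two interior opacities must not split the region (the very reason
        MSER handles gelatinous bodies)."""
        img = np.full((512, 512), 200, np.uint8)
        yy, xx = np.mgrid[:512, :512]
        body = (yy - 256) ** 2 + (xx - 256) ** 2 <= 60**2
        organ = (yy - 256) ** 2 + (xx - 236) ** 2 <= 20**2
        img[body] = 160
        img[organ] = 120
        regions = mser_large(img, MserParams(min_area=5000))
        assert len(regions) == 1
        assert (regions[0] & body).sum() / body.sum() >= 0.95


# ---------------------------------------------------------------------------
# mask combination and ROI extraction


class TestCombineMasks:
    def test_union_with_empty_is_identity(self):
        a = np.zeros((10, 10), bool)
        a[2:4, 2:4] = True
        assert np.array_equal(combine_masks(a, []), a)

    def test_disjoint_areas_add(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        a[:4, :10] = True  # 40
        b[10:16, :10] = True  # 60
        assert combine_masks(a, [b]).sum() == 100

    def test_inclusion_exclusion(self):
        rng = np.random.default_rng(3)
        a = rng.random((30, 30)) < 0.3
        b = rng.random((30, 30)) < 0.3
        out = combine_masks(a, [b])
        assert out.sum() == a.sum() + b.sum() - (a & b).sum()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_masks(np.zeros((5, 5), bool), [np.zeros((6, 6), bool)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_commutative_idempotent_monotone(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((16, 16)) < 0.4
        b = rng.random((16, 16)) < 0.4
        ab = combine_masks(a, [b])
        assert np.array_equal(ab, combine_masks(b, [a]))
        assert np.array_equal(combine_masks(ab, [ab]), ab)
        assert (ab | a).sum() == ab.sum()  # adding regions never removes


class TestExtractRois:
    def test_empty_mask(self):
        img = np.zeros((10, 10), np.uint8)
        assert extract_rois(np.zeros((10, 10), bool), img) == []

    def test_two_squares_exact_geometry(self):
        mask = np.zeros((40, 40), bool)
        mask[2:12, 3:13] = True
        mask[25:35, 20:30] = True
        img = np.random.default_rng(0).integers(0, 255, (40, 40)).astype(np.uint8)
        rois = extract_rois(mask, img, min_roi_area=50)
        assert len(rois) == 2
        assert (rois[0].top, rois[0].left, rois[0].height, rois[0].width) == (2, 3, 10, 10)
        assert (rois[1].top, rois[1].left) == (25, 20)
        assert all(r.area == 100 for r in rois)
        assert np.array_equal(rois[0].crop, img[2:12, 3:13])

    def test_rectangle_axes_match_moment_oracle(self):
        mask = np.zeros((60, 60), bool)
        mask[10:20, 5:45] = True  # 10 x 40 solid rectangle
        rois = extract_rois(mask, np.zeros((60, 60), np.uint8), 50)
        assert len(rois) == 1
        # central second moments of a solid h x w box of unit pixels
        h, w = 10, 40
        var_r = (h**2 - 1) / 12 + 1 / 12
        var_c = (w**2 - 1) / 12 + 1 / 12
        assert rois[0].major_axis == pytest.approx(4 * np.sqrt(var_c), rel=0.01)
        assert rois[0].minor_axis == pytest.approx(4 * np.sqrt(var_r), rel=0.01)
        assert rois[0].major_axis >= rois[0].minor_axis > 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_component_conservation(self, seed):
        """Sum of ROI areas == foreground pixels minus sub-threshold specks."""
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        mask = rng.random((48, 48)) < 0.25
        img = np.zeros((48, 48), np.uint8)
        min_area = 5
        rois = extract_rois(mask, img, min_area)
        lbl, n = ndimage.label(mask, structure=np.ones((3, 3), int))
        counts = np.bincount(lbl.ravel())[1:]
        expected = counts[counts >= min_area].sum()
        assert sum(r.area for r in rois) == expected

    def test_scan_order(self):
        mask = np.zeros((30, 30), bool)
        mask[20:26, 1:7] = True
        mask[1:7, 20:26] = True
        rois = extract_rois(mask, np.zeros((30, 30), np.uint8), 10)
        assert (rois[0].top, rois[0].left) == (1, 20)
        assert (rois[1].top, rois[1].left) == (20, 1)


class TestDeduplicate:
    def _roi(self, top, left, h, w, area=None):
        from planktosort.segmentation import ROI

        return ROI(
            id=0, top=top, left=left, height=h, width=w,
            area=area if area is not None else h * w,
            major_axis=1.0, minor_axis=1.0,
            crop=np.zeros((h, w), np.uint8), mask=np.ones((h, w), bool),
        )

    def test_disjoint_unchanged(self):
        rois = [self._roi(0, 0, 5, 5), self._roi(20, 20, 5, 5)]
        assert len(deduplicate_rois(rois, 0.8)) == 2

    def test_contained_fragment_removed(self):
        big = self._roi(0, 0, 20, 20)
        small = self._roi(5, 5, 4, 4)
        kept = deduplicate_rois([small, big], 0.8)
        assert len(kept) == 1
        assert kept[0].area == 400

    def test_chain_keeps_non_duplicates(self):
        # A inside B; B overlaps C at 0.5 of min; threshold 0.8 -> {B, C}
        b = self._roi(0, 0, 10, 20)
        a = self._roi(2, 2, 4, 4)
        c = self._roi(0, 10, 10, 20)  # overlap with B = 10x10 = 0.5 of min(200,200)
        kept = deduplicate_rois([a, b, c], 0.8)
        assert len(kept) == 2
        assert {(r.top, r.left) for r in kept} == {(0, 0), (0, 10)}


# ---------------------------------------------------------------------------
# k calibration


class TestCalibrateK:
    def test_singleton_grid(self, sparse_scene):
        k, table = calibrate_k([sparse_scene], [0.55], SauvolaParams(window=19),
                               min_roi_area=3)
        assert k == 0.55
        assert len(table) == 1

    def test_empty_grid_rejected(self, sparse_scene):
        with pytest.raises(ValueError):
            calibrate_k([sparse_scene], [], SauvolaParams(window=19))

    def test_no_targets_rejected(self):
        cfg = SceneConfig(
            width=300, height=300, scale=0.25, n_particulates=10,
            n_copepod=0, n_bubble=0, seed=3,
        )
        scene = generate_scene(cfg)
        with pytest.raises(ValueError, match="target"):
            calibrate_k([scene], [0.5], SauvolaParams(window=19))

    def test_prefers_k_that_separates_organisms_from_texture(self):
        """On a frame with faint mottled texture, a tiny k floods the mask
        into one web that swallows the copepods, while a large k misses the
        bodies outright; an intermediate k recovers them."""
        rng = np.random.default_rng(17)
        from scipy import ndimage as ndi
        from planktosort.synthscene import ObjectTruth, Scene, render_object

        img = np.full((400, 400), 180.0)
        blotch = ndi.gaussian_filter(rng.normal(size=(400, 400)), 6)
        img[blotch > 0.0] = 150.0  # faint texture web covering half the frame
        truths = []
        for i, (top, left) in enumerate([(50, 60), (200, 250), (320, 100)]):
            stamp, support = render_object("copepod", 30, 0.4, rng)
            n = stamp.shape[0]
            img[top : top + n, left : left + n] *= stamp / 255.0
            rows, cols = np.nonzero(support)
            truths.append(ObjectTruth(
                object_id=i, cls="copepod",
                row=float(rows.mean() + top), col=float(cols.mean() + left),
                top=top + rows.min(), left=left + cols.min(),
                height=rows.max() - rows.min() + 1,
                width=cols.max() - cols.min() + 1,
                area=int(support.sum()), image_id="cal_0000",
            ))
        scene = Scene("cal_0000", np.clip(np.rint(img), 0, 255).astype(np.uint8), truths)
        params = SauvolaParams(window=25)
        k, table = calibrate_k([scene], [0.02, 0.6, 2.0], params, min_roi_area=10)
        misses = dict(table)
        assert k == 0.6
        assert misses[0.6] == 0
        assert misses[0.02] >= 1  # flooding buries copepods in texture webs
        assert misses[2.0] == 3  # threshold collapses: everything missed
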