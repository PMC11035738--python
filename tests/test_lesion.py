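"""Lesioning: exact-area regions, masks, random controls, Gaussian blur."""

import numpy as np
import pytest
from scipy import stats

from facelesion.lesion import (DEFAULT_AREAS, FeatureRegion, LesionSpec,
                               apply_lesion, apply_mask, blur_region,
                               blur_level_sigma, gaussian_kernel,
                               region_from_keypoints, regions_for_sample,
                               sample_random_regions)
from facelesion.synthetic import (FEATURES, GeneratorConfig, render_face,
                                  sample_identities)


@pytest.fixture(scope="module")
def face_sample():
    cfg = GeneratorConfig(n_identities=4, images_per_identity=2, seed=0)
    return render_face(sample_identities(cfg)[0], cfg, 0)


class TestRegionFromKeypoints:
    @pytest.mark.parametrize("feature", FEATURES)
    def test_exact_area_fully_interior(self, face_sample, feature):
        region = region_from_keypoints(face_sample.keypoints[feature],
                                       DEFAULT_AREAS[feature],
                                       face_sample.image.shape, feature)
        x0, y0, w, h = region.rect
        assert region.exact
        assert region.actual_area == w * h == DEFAULT_AREAS[feature]
        assert x0 >= 0 and y0 >= 0 and x0 + w <= 112 and y0 + h <= 112

    def test_exact_area_holds_across_renders(self):
        # the area contract must hold for any render, not just one fixture
        cfg = GeneratorConfig(n_identities=40, images_per_identity=2, seed=9)
        for ident in sample_identities(cfg):
            s = render_face(ident, cfg, 1)
            for f in FEATURES:
                r = region_from_keypoints(s.keypoints[f], DEFAULT_AREAS[f],
                                          s.image.shape, f)
                assert r.exact and r.actual_area == DEFAULT_AREAS[f], (f, r)

    def test_keypoints_always_covered(self, face_sample):
        for f in FEATURES:
            r = region_from_keypoints(face_sample.keypoints[f],
                                      DEFAULT_AREAS[f],
                                      face_sample.image.shape, f)
            x0, y0, w, h = r.rect
            for x, y in face_sample.keypoints[f]:
                assert x0 <= x < x0 + w and y0 <= y < y0 + h

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            region_from_keypoints([(10, 10), (10, 10)], 800, (112, 112))

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            region_from_keypoints([(10, 10)], 800, (112, 112))

    def test_target_smaller_than_bbox_flags_inexact(self):
        pts = [(10, 10), (60, 40)]  # bbox 51 x 31 = 1581 > 800
        r = region_from_keypoints(pts, 800, (112, 112))
        assert not r.exact
        assert r.rect == (10, 10, 51, 31)

    def test_random_point_sets_cover_and_meet_area(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 8)
            pts = rng.integers(5, 90, size=(n, 2))
            if np.all(pts == pts[0]):
                continue
            r = region_from_keypoints(pts, 400, (112, 112))
            x0, y0, w, h = r.rect
            for x, y in pts:
                assert x0 <= x < x0 + w and y0 <= y < y0 + h
            bw = pts[:, 0].max() - pts[:, 0].min() + 1
            bh = pts[:, 1].max() - pts[:, 1].min() + 1
            touches_border = (x0 == 0 or y0 == 0
                              or x0 + w == 112 or y0 + h == 112)
            if bw * bh <= 400 and not touches_border:
                assert w * h >= 400


class TestApplyMask:
    def test_interior_mask_zeroes_exact_area(self, face_sample):
        img = np.ones((112, 112), dtype=np.float32)
        r = region_from_keypoints(face_sample.keypoints["mouth"], 800,
                                  img.shape, "mouth")
        out = apply_mask(img, r)
        assert int((out == 0).sum()) == 800

    def test_idempotent_and_local(self, face_sample):
        r = region_from_keypoints(face_sample.keypoints["eyes"], 800,
                                  face_sample.image.shape, "eyes")
        once = apply_mask(face_sample.image, r)
        twice = apply_mask(once, r)
        assert np.array_equal(once, twice)
        outside = np.ones_like(face_sample.image, dtype=bool)
        sy, sx = r.slices
        outside[sy, sx] = False
        assert np.array_equal(once[outside], face_sample.image[outside])

    def test_border_clipping_records_actual_area(self):
        img = np.ones((112, 112), dtype=np.float32)
        # 40 x 20 rectangle placed half off the left edge
        r = region_from_keypoints([(0, 50), (10, 60)], 800, img.shape)
        out = apply_mask(img, r)
        assert int((out == 0).sum()) == r.actual_area
        assert r.actual_area < r.target_area


class TestRandomRegions:
    def _templates(self, face_sample):
        return regions_for_sample(face_sample, FEATURES)

    def test_deterministic(self, face_sample):
        t = self._templates(face_sample)
        a = sample_random_regions(t, (112, 112), seed=5)
        b = sample_random_regions(t, (112, 112), seed=5)
        assert [r.rect for r in a] == [r.rect for r in b]

    def test_interior_and_disjoint_across_seeds(self, face_sample):
        t = self._templates(face_sample)
        for seed in range(40):
            placed = sample_random_regions(t, (112, 112), seed=seed)
            for i, r in enumerate(placed):
                x0, y0, w, h = r.rect
                assert x0 >= 0 and y0 >= 0 and x0 + w <= 112 and y0 + h <= 112
                for other in placed[:i]:
                    ox, oy, ow, oh = other.rect
                    assert (x0 >= ox + ow or ox >= x0 + w
                            or y0 >= oy + oh or oy >= y0 + h)

    def test_anchor_distribution_uniform(self):
        # 10,000 placements of one 20x40 box: chi-square on a binned anchor
        # grid should not reject uniformity at alpha = 0.01
        template = FeatureRegion("mouth", (0, 0, 20, 40), 800, 800)
        nx, ny = 112 - 20 + 1, 112 - 40 + 1
        draws = np.array([sample_random_regions([template], (112, 112),
                                                seed=s)[0].rect[:2]
                          for s in range(10000)])
        nbin = 6
        xedges = np.linspace(0, nx, nbin + 1)
        yedges = np.linspace(0, ny, nbin + 1)
        obs, _, _ = np.histogram2d(draws[:, 0], draws[:, 1],
                                   bins=[xedges, yedges])
        xcnt = np.diff(np.ceil(xedges))
        ycnt = np.diff(np.ceil(yedges))
        expected = np.outer(xcnt, ycnt) / (nx * ny) * len(draws)
        _, p = stats.chisquare(obs.ravel(), expected.ravel())
        assert p > 0.01

    def test_oversized_template_rejected(self):
        t = FeatureRegion("eyes", (0, 0, 150, 10), 1500, 1500)
        with pytest.raises(ValueError, match="fit"):
            sample_random_regions([t], (112, 112), seed=0)


class TestGaussianKernel:
    @pytest.mark.parametrize("sigma", [2.0, 8.0, 10.0, 20.0])
    def test_normalized(self, sigma):
        k = gaussian_kernel(sigma)
        assert abs(k.weights.sum() - 1.0) <= 1e-9

    def test_size_rule(self):
        assert gaussian_kernel(2.0).size == 13  # 2*ceil(6)+1

    def test_matches_double_sum_oracle_sigma1(self):
        # independent oracle: evaluate G(i,j) = exp(-(i^2+j^2)/2s^2)/(2 pi s^2)
        # on the support grid and renormalize; center raw value is 1/(2 pi)
        k = gaussian_kernel(1.0)
        half = k.size // 2
        raw = np.empty((k.size, k.size))
        for i in range(-half, half + 1):
            for j in range(-half, half + 1):
                raw[i + half, j + half] = (
                    np.exp(-(i * i + j * j) / 2.0) / (2.0 * np.pi))
        assert raw[half, half] == pytest.approx(1.0 / (2.0 * np.pi), abs=1e-12)
        assert np.allclose(k.weights, raw / raw.sum(), atol=1e-12)

    def test_symmetry_and_center_max(self):
        k = gaussian_kernel(3.0)
        assert np.allclose(k.weights, k.weights[::-1, :])
        assert np.allclose(k.weights, k.weights[:, ::-1])
        assert k.weights.max() == k.weights[k.size // 2, k.size // 2]

    @pytest.mark.parametrize("sigma", [0.0, -1.0])
    def test_nonpositive_sigma_rejected(self, sigma):
        with pytest.raises(ValueError):
            gaussian_kernel(sigma)

    def test_level_mapping(self):
        assert [blur_level_sigma(i) for i in (1, 2, 3, 4)] == [2, 8, 10, 20]
        with pytest.raises(ValueError):
            blur_level_sigma(5)


class TestBlur:
    def test_constant_image_is_fixed_point(self):
        img = np.full((50, 50), 0.37, dtype=np.float64)
        r = FeatureRegion("eyes", (10, 10, 20, 10), 200, 200)
        for sigma in (2.0, 20.0):
            out = blur_region(img, r, sigma)
            assert np.allclose(out, img, atol=1e-9)

    def test_variance_shrinks_with_sigma(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (60, 60))
        r = FeatureRegion("nose", (15, 15, 30, 20), 600, 600)
        sy, sx = r.slices
        v2 = blur_region(img, r, 2.0)[sy, sx].var()
        v20 = blur_region(img, r, 20.0)[sy, sx].var()
        assert v20 < v2 < img[sy, sx].var()

    def test_matches_brute_force_double_sum(self):
        # direct evaluation of the convolution with symmetric padding
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (9, 9))
        sigma = 1.5
        kern = gaussian_kernel(sigma)
        half = kern.size // 2
        padded = np.pad(img, half, mode="symmetric")
        expected = np.zeros_like(img)
        for y in range(9):
            for x in range(9):
                acc = 0.0
                for i in range(-half, half + 1):
                    for j in range(-half, half + 1):
                        acc += kern.weights[i + half, j + half] * \
                            padded[y + i + half, x + j + half]
                expected[y, x] = acc
        r = FeatureRegion("mouth", (0, 0, 9, 9), 81, 81)
        out = blur_region(img, r, sigma)
        assert np.allclose(out, expected, atol=1e-6)

    def test_locality(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (40, 40))
        r = FeatureRegion("eyes", (5, 5, 10, 8), 80, 80)
        out = blur_region(img, r, 4.0)
        outside = np.ones_like(img, dtype=bool)
        sy, sx = r.slices
        outside[sy, sx] = False
        assert np.array_equal(out[outside], img[outside])


class TestApplyLesion:
    def test_none_is_identity(self, face_sample):
        out = apply_lesion(face_sample, LesionSpec(kind="none"))
        assert np.array_equal(out, face_sample.image)

    def test_mask_all_features_zeroes_region_union(self, face_sample):
        # adjacent inflated regions may overlap, so the zeroed count equals
        # the union of the rectangles (<= sum of areas), checked by an
        # independent boolean-canvas scan
        regions = regions_for_sample(face_sample, FEATURES)
        canvas = np.zeros((112, 112), dtype=bool)
        for r in regions:
            sy, sx = r.slices
            canvas[sy, sx] = True
        out = apply_lesion(face_sample, LesionSpec(kind="mask",
                                                   features=FEATURES))
        # a few rendered pixels may already be exactly 0 from noise clipping
        expected = canvas | (face_sample.image == 0)
        assert np.array_equal(out == 0, expected)
        assert int(canvas.sum()) <= sum(r.actual_area for r in regions)

    def test_single_mask_zeroes_exact_area(self, face_sample):
        out = apply_lesion(face_sample, LesionSpec(kind="mask",
                                                   features=("mouth",)))
        pre = int((face_sample.image == 0).sum())
        r = regions_for_sample(face_sample, ["mouth"])[0]
        in_region = int((face_sample.image[r.slices[0], r.slices[1]] == 0).sum())
        assert int((out == 0).sum()) == 800 + pre - in_region

    def test_blur_sigma_changes_only_inside_region(self, face_sample):
        a = apply_lesion(face_sample, LesionSpec(kind="blur",
                                                 features=("eyes",), sigma=2))
        b = apply_lesion(face_sample, LesionSpec(kind="blur",
                                                 features=("eyes",), sigma=20))
        diff = a != b
        r = regions_for_sample(face_sample, ["eyes"])[0]
        mask = np.zeros_like(diff)
        sy, sx = r.slices
        mask[sy, sx] = True
        assert diff.any()
        assert not diff[~mask].any()

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            LesionSpec(kind="mask", features=("ears",))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            LesionSpec(kind="erase", features=("eyes",))

    def test_random_mask_zero_count_matches_areas(self, face_sample):
        clean = GeneratorConfig(n_identities=2, images_per_identity=2,
                                seed=1, within_jitter=0.0, noise_sd=0.0)
        s = render_face(sample_identities(clean)[0], clean, 0)
        assert not (s.image == 0).any()
        out = apply_lesion(s, LesionSpec(kind="random_mask",
                                         features=FEATURES, seed=1))
        # random placements never overlap, so the count is the exact sum
        assert int((out == 0).sum()) == sum(DEFAULT_AREAS.values())
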