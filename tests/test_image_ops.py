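"""Pre-processing: filters, thresholds, shape selection, peak location."""

import numpy as np
import pytest
from skimage.filters import threshold_yen as sk_threshold_yen

from afmbend import SceneSpec, generate_scene
from afmbend.image_ops import (BinaryMask, HeightMap, gaussian_blur,
                               locate_protein_peaks, median_filter,
                               ridge_rethreshold, shape_filter,
                               threshold_intermodes, threshold_yen,
                               yen_criterion)

PX = 1.95


def hmap(values):
    return HeightMap(np.asarray(values, dtype=float), PX)


class TestMedianFilter:
    def test_constant_unchanged(self):
        out = median_filter(hmap(np.full((16, 16), 3.0)), 2)
        assert np.all(out.values == 3.0)

    def test_spike_removed(self):
        img = np.zeros((16, 16))
        img[8, 8] = 100.0
        out = median_filter(hmap(img), 2)
        assert out.values[8, 8] == 0.0

    def test_matches_bruteforce_disc_median(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(16, 16))
        out = median_filter(hmap(img), 2)
        r = 2
        for i in (3, 8, 12):
            for j in (2, 7, 13):
                vals = []
                for di in range(-r, r + 1):
                    for dj in range(-r, r + 1):
                        if di * di + dj * dj <= r * r:
                            ii = min(max(i + di, 0), 15)
                            jj = min(max(j + dj, 0), 15)
                            vals.append(img[ii, jj])
                assert out.values[i, j] == pytest.approx(np.median(vals))


class TestGaussianBlur:
    def test_constant_invariant(self):
        out = gaussian_blur(hmap(np.full((16, 16), 2.0)), 2.0)
        assert np.allclose(out.values, 2.0)

    def test_delta_gives_kernel(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        out = gaussian_blur(hmap(img), 2.0)
        yy, xx = np.mgrid[-16:17, -16:17]
        kernel = np.exp(-(xx ** 2 + yy ** 2) / (2 * 2.0 ** 2))
        kernel /= kernel.sum()
        # discrete (truncated, normalized) Gaussian: agree to ~1e-3
        assert np.allclose(out.values[8:25, 8:25], kernel[8:25, 8:25],
                           atol=2e-3)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_random_image_matches_direct_convolution(self):
        rng = np.random.default_rng(4)
        img = rng.normal(size=(16, 16))
        out = gaussian_blur(hmap(img), 2.0)
        # oracle: direct convolution with the filter impulse response
        delta = np.zeros((33, 33))
        delta[16, 16] = 1.0
        kernel = gaussian_blur(hmap(delta), 2.0).values
        from scipy.signal import convolve2d
        brute = convolve2d(np.pad(img, 8, mode="edge"), kernel,
                           mode="same")[8:-8, 8:-8]
        assert np.allclose(out.values[4:12, 4:12], brute[4:12, 4:12],
                           atol=1e-6)


class TestYen:
    def test_two_level_image_separated_exactly(self):
        img = np.full((20, 20), 10.0)
        img[5:10, 5:10] = 200.0
        level, mask = threshold_yen(hmap(img))
        assert 10.0 <= level < 200.0
        assert np.array_equal(mask.values, img == 200.0)

    def test_matches_exhaustive_search_oracle(self):
        rng = np.random.default_rng(1)
        img = np.concatenate([rng.normal(0.1, 0.05, 4000),
                              rng.normal(0.9, 0.1, 800)]).reshape(60, 80)
        level, _ = threshold_yen(hmap(img))
        # independent exhaustive evaluation of Yen's criterion
        vmin, vmax = img.min(), img.max()
        img8 = np.clip(np.round((img - vmin) / (vmax - vmin) * 255),
                       0, 255).astype(np.uint8)
        hist = np.bincount(img8.ravel(), minlength=256)
        p = hist / hist.sum()
        best, best_t = -np.inf, None
        for t in range(256):
            p1 = p[:t + 1].sum()
            g1 = (p[:t + 1] ** 2).sum()
            g2 = (p[t + 1:] ** 2).sum()
            if p1 in (0.0, 1.0) or g1 == 0 or g2 == 0:
                continue
            crit = -np.log(g1 * g2) + 2 * np.log(p1 * (1 - p1))
            if crit > best:
                best, best_t = crit, t
        expected = vmin + best_t * (vmax - vmin) / 255.0
        assert level == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_skimage(self):
        rng = np.random.default_rng(2)
        img = np.concatenate([rng.normal(0.1, 0.05, 5000),
                              rng.normal(0.8, 0.1, 800)]).reshape(58, 100)
        level, _ = threshold_yen(hmap(img))
        sk_level = sk_threshold_yen(img, nbins=256)
        bin_width = (img.max() - img.min()) / 255.0
        assert abs(level - sk_level) <= 4 * bin_width

    def test_shift_monotonicity(self):
        rng = np.random.default_rng(3)
        img = np.concatenate([rng.normal(0.1, 0.05, 4000),
                              rng.normal(0.9, 0.1, 800)]).reshape(60, 80)
        level1, _ = threshold_yen(hmap(img))
        level2, _ = threshold_yen(hmap(img + 5.0))
        bin_width = (img.max() - img.min()) / 255.0
        assert abs((level2 - 5.0) - level1) <= bin_width

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            threshold_yen(hmap(np.ones((8, 8))))

    def test_criterion_vector_shape(self):
        crit = yen_criterion(np.ones(256, dtype=int))
        assert crit.shape == (256,)

    def test_mask_covers_ground_truth_molecules(self):
        spec = SceneSpec(image_size_px=(256, 256), n_molecules=2,
                         contour_length_nm=120.0, rng_seed=4)
        hm, truth = generate_scene(spec)
        _, mask = threshold_yen(hm)
        covered = total = 0
        for m in truth.molecules:
            for x, y in m.path_nm:
                total += 1
                covered += bool(mask.values[int(round(y / PX)),
                                            int(round(x / PX))])
        assert covered / total >= 0.95


class TestIntermodes:
    def test_level_between_two_gaussian_modes(self):
        rng = np.random.default_rng(5)
        img = np.concatenate([rng.normal(0.2, 0.03, 3000),
                              rng.normal(0.8, 0.03, 3000)]).reshape(60, 100)
        level, _ = threshold_intermodes(hmap(img))
        assert 0.3 < level < 0.7

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        img = np.concatenate([rng.normal(0.2, 0.05, 2000),
                              rng.normal(0.9, 0.05, 2000)]).reshape(40, 100)
        l1, _ = threshold_intermodes(hmap(img))
        l2, _ = threshold_intermodes(hmap(img))
        assert l1 == l2

    def test_manual_offset_applied(self):
        rng = np.random.default_rng(7)
        img = np.concatenate([rng.normal(0.2, 0.03, 2000),
                              rng.normal(0.8, 0.03, 2000)]).reshape(40, 100)
        l0, _ = threshold_intermodes(hmap(img))
        l1, _ = threshold_intermodes(hmap(img), manual_offset=0.1)
        assert l1 == pytest.approx(l0 + 0.1)

    def test_unimodal_histogram_raises(self):
        # smooth unimodal histogram built deterministically: no amount of
        # smoothing produces two modes
        from scipy.stats import norm
        q = (np.arange(1, 120 * 120 + 1)) / (120 * 120 + 1)
        img = (0.5 + 0.08 * norm.ppf(q)).reshape(120, 120)
        with pytest.raises(ValueError):
            threshold_intermodes(hmap(img))


class TestShapeFilter:
    def _mask(self, arr):
        return BinaryMask(arr, PX)

    def test_disc_removed_line_kept(self):
        arr = np.zeros((260, 260), dtype=bool)
        yy, xx = np.mgrid[:260, :260]
        arr[(yy - 40) ** 2 + (xx - 40) ** 2 <= 15 ** 2] = True   # disc
        arr[130:133, 20:240] = True                              # 220-px line
        out = shape_filter(self._mask(arr))
        assert not out.values[40, 40]
        assert out.values[131, 120]

    def test_short_line_removed_by_perimeter(self):
        arr = np.zeros((64, 64), dtype=bool)
        arr[30:33, 20:45] = True     # perimeter ~ 50 px < 90
        out = shape_filter(self._mask(arr))
        assert not out.values.any()

    def test_border_touching_discarded(self):
        arr = np.zeros((64, 300), dtype=bool)
        arr[0:3, 50:250] = True
        out = shape_filter(self._mask(arr))
        assert not out.values.any()

    def test_idempotent(self):
        spec = SceneSpec(image_size_px=(256, 256), n_molecules=2,
                         contour_length_nm=120.0, rng_seed=9)
        hm, _ = generate_scene(spec)
        _, mask = threshold_yen(hm)
        once = shape_filter(mask, (0.0, 1.0), 90)
        twice = shape_filter(once, (0.0, 1.0), 90)
        assert np.array_equal(once.values, twice.values)

    def test_separates_dna_from_free_proteins(self):
        spec = SceneSpec(image_size_px=(512, 512), n_molecules=3,
                         n_free_proteins=3, rng_seed=10)
        hm, truth = generate_scene(spec)
        _, mask = threshold_yen(hm)
        out = shape_filter(mask, (0.0, 1.0), 90)
        # free protein blobs removed
        for (x, y) in truth.free_protein_xy_nm:
            assert not out.values[int(round(y / PX)), int(round(x / PX))]
        # DNA backbones kept
        kept = sum(out.values[int(round(y / PX)), int(round(x / PX))]
                   for m in truth.molecules for x, y in m.path_nm[10:-10])
        total = sum(len(m.path_nm) - 20 for m in truth.molecules)
        assert kept / total > 0.9


class TestRidgeRethreshold:
    def test_narrows_mask_without_breaking_it(self):
        spec = SceneSpec(image_size_px=(256, 256), n_molecules=1,
                         contour_length_nm=120.0, rng_seed=11)
        hm, _ = generate_scene(spec)
        _, mask = threshold_yen(hm)
        out = ridge_rethreshold(mask, hm, 0.5)
        assert 0 < out.values.sum() < mask.values.sum()


class TestLocateProteinPeaks:
    def _disc_mask(self, radius_px, center=(32, 32), shape=(64, 64)):
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        arr = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2
               <= radius_px ** 2)
        return BinaryMask(arr, PX)

    def test_centroid_within_one_pixel(self):
        kept, rejected = locate_protein_peaks(self._disc_mask(2.6))
        assert len(kept) == 1 and not rejected
        cx, cy = kept[0].centroid_nm
        assert abs(cx - 32 * PX) < PX and abs(cy - 32 * PX) < PX

    def test_large_aggregate_discarded(self):
        # 2e-4 um^2 = 2e5 nm^2 -> radius ~ 130 px at 1.95 nm/px
        mask = self._disc_mask(135, center=(150, 150), shape=(300, 300))
        kept, rejected = locate_protein_peaks(mask)
        assert not kept
        assert len(rejected) == 1
        assert rejected[0].area_um2 > 1e-4

    def test_empty_mask_gives_empty_lists(self):
        mask = BinaryMask(np.zeros((32, 32), dtype=bool), PX)
        kept, rejected = locate_protein_peaks(mask)
        assert kept == [] and rejected == []
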