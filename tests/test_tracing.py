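"""Tracing: skeleton ordering, resampling, refinement, reconnection."""

import numpy as np
import pytest

from afmbend.image_ops import BinaryMask, HeightMap
from afmbend.tracing import (FilamentTrace, connect_fragments, contour_length,
                             end_to_end, refine_subpixel, resample,
                             skeletonize_and_order, spline_resample)

PX = 1.95


class TestSkeletonizeAndOrder:
    def test_straight_line_recovered_on_axis(self):
        arr = np.zeros((40, 120), dtype=bool)
        arr[19:22, 10:110] = True
        polylines, rejects = skeletonize_and_order(BinaryMask(arr, PX))
        assert len(polylines) == 1 and not rejects
        poly = polylines[0]
        assert np.all(np.abs(poly[:, 1] - 20.0) <= 1.0)
        assert np.mean(np.abs(poly[:, 1] - 20.0) <= 0.5) >= 0.8
        assert poly.shape[0] > 90

    def test_crossing_rejected_as_branch(self):
        arr = np.zeros((80, 80), dtype=bool)
        for i in range(10, 70):
            arr[i - 1:i + 2, i - 1:i + 2] = True
            arr[i - 1:i + 2, 79 - i - 1:79 - i + 2] = True
        polylines, rejects = skeletonize_and_order(BinaryMask(arr, PX))
        assert not polylines
        assert any(r.reason == "branch" for r in rejects)

    def test_ring_rejected_as_loop(self):
        yy, xx = np.mgrid[:80, :80]
        r = np.hypot(yy - 40, xx - 40)
        arr = (r > 25) & (r < 30)
        polylines, rejects = skeletonize_and_order(BinaryMask(arr, PX))
        assert not polylines
        assert [r_.reason for r_ in rejects] == ["loop"]

    def test_tiny_fragment_rejected_as_too_short(self):
        arr = np.zeros((32, 32), dtype=bool)
        arr[15:17, 10:15] = True
        polylines, rejects = skeletonize_and_order(BinaryMask(arr, PX))
        assert not polylines
        assert [r.reason for r in rejects] == ["too_short"]

    def test_rejection_reasons_partition_everything(self):
        # nothing silently dropped: every skeleton is traced or has a reason
        arr = np.zeros((120, 120), dtype=bool)
        arr[10:13, 10:110] = True                       # good line
        yy, xx = np.mgrid[:120, :120]
        r = np.hypot(yy - 70, xx - 60)
        arr[(r > 20) & (r < 24)] = True                 # loop
        arr[100:102, 5:9] = True                        # tiny
        polylines, rejects = skeletonize_and_order(BinaryMask(arr, PX))
        assert len(polylines) + len(rejects) == 3


class TestResample:
    def test_straight_ten_nm_gives_six_nodes(self):
        pts = np.column_stack((np.linspace(0, 10, 50), np.zeros(50)))
        t = resample(pts, 2.0)
        assert t.points.shape[0] == 6
        assert np.allclose(t.points[0], (0, 0))
        assert np.allclose(t.points[-1], (10, 0))

    def test_uniform_spacing_on_curve(self):
        s = np.linspace(0, np.pi, 300)
        pts = 30.0 * np.column_stack((np.cos(s), np.sin(s)))
        t = resample(pts, 2.0)
        seg = np.linalg.norm(np.diff(t.points, axis=0), axis=1)
        assert np.allclose(seg, seg[0], atol=1e-6)

    def test_quarter_circle_arc_length(self):
        s = np.linspace(0, np.pi / 2, 2000)
        pts = 20.0 * np.column_stack((np.cos(s), np.sin(s)))
        t = resample(pts, 2.0)
        assert t.contour_length_nm == pytest.approx(np.pi * 10.0, rel=0.01)

    def test_too_short_raises(self):
        pts = np.column_stack(([0, 1.0], [0, 0]))
        with pytest.raises(ValueError):
            resample(pts, 2.0)


class TestRefineSubpixel:
    def _ridge_image(self, y0_nm, sigma=2.74, noise=0.0, seed=0):
        ny, nx = 64, 200
        yy = np.arange(ny)[:, None] * PX
        img = np.exp(-(yy - y0_nm) ** 2 / (2 * sigma ** 2)) * np.ones((1, nx))
        if noise:
            img = img + np.random.default_rng(seed).normal(0, noise,
                                                           img.shape)
        return HeightMap(img, PX)

    def _initial_trace(self, row):
        x = np.arange(10, 190) * PX
        return resample(np.column_stack((x, np.full_like(x, row * PX))), 2.0)

    def test_noiseless_half_pixel_offset_recovered(self):
        y0 = (30 + 0.5) * PX
        refined, failures = refine_subpixel(self._initial_trace(30),
                                            self._ridge_image(y0), 6.45)
        assert failures == 0
        assert np.abs(refined.points[2:-2, 1] - y0).max() < 0.1

    def test_on_axis_trace_stays_put(self):
        y0 = 30 * PX
        refined, _ = refine_subpixel(self._initial_trace(30),
                                     self._ridge_image(y0), 6.45)
        assert np.abs(refined.points[2:-2, 1] - y0).max() < 1e-6

    def test_noisy_ridge_rms_below_half_nm(self):
        y0 = (30 + 0.5) * PX
        img = self._ridge_image(y0, noise=0.1, seed=5)   # SNR 10
        refined, _ = refine_subpixel(self._initial_trace(30), img, 6.45)
        dev = refined.points[2:-2, 1] - y0
        assert np.sqrt(np.mean(dev ** 2)) < 0.5

    def test_fwhm_must_exceed_pixel(self):
        with pytest.raises(ValueError):
            refine_subpixel(self._initial_trace(30),
                            self._ridge_image(30 * PX), 1.0)


class TestConnectFragments:
    def test_collinear_halves_with_gap(self):
        a = resample(np.column_stack((np.linspace(0, 40, 50),
                                      np.zeros(50))), 2.0)
        b = resample(np.column_stack((np.linspace(44, 84, 50),
                                      np.zeros(50))), 2.0)
        merged = connect_fragments(a, b, gap_tolerance_nm=6.0)
        assert merged.contour_length_nm == pytest.approx(84.0, abs=0.1)

    def test_bent_halves_measure_seventy_degrees(self):
        from afmbend import AngleQuery, bend_angle_at
        phi = np.deg2rad(70.0)
        a = resample(np.column_stack((np.linspace(-60, -2, 60),
                                      np.zeros(60))), 2.0)
        s = np.linspace(2, 60, 60)
        b = resample(np.column_stack((s * np.cos(phi), s * np.sin(phi))), 2.0)
        merged = connect_fragments(a, b, gap_tolerance_nm=6.0)
        fine = spline_resample(merged, 0.1)
        theta = bend_angle_at(fine, fine.contour_length_nm / 2.0,
                              AngleQuery(8.0))
        assert theta == pytest.approx(70.0, abs=2.0)

    def test_gap_beyond_tolerance_raises(self):
        a = resample(np.column_stack((np.linspace(0, 40, 50),
                                      np.zeros(50))), 2.0)
        b = resample(np.column_stack((np.linspace(60, 100, 50),
                                      np.zeros(50))), 2.0)
        with pytest.raises(ValueError):
            connect_fragments(a, b)   # default tolerance 3 x 2 nm


class TestSplineResample:
    def test_straight_stays_straight(self):
        t = resample(np.column_stack((np.linspace(0, 60, 61),
                                      np.zeros(61))), 2.0)
        fine = spline_resample(t, 0.1)
        assert np.abs(fine.points[:, 1]).max() < 1e-9
        assert fine.node_spacing_nm == pytest.approx(0.1, abs=1e-4)

    def test_circle_radius_recovered(self):
        s = np.linspace(0, 1.5 * np.pi, 400)
        t = resample(20.0 * np.column_stack((np.cos(s), np.sin(s))), 2.0)
        fine = spline_resample(t, 0.1)
        radii = np.linalg.norm(fine.points, axis=1)
        assert np.abs(radii - 20.0).max() < 0.02   # 0.1%

    def test_passes_through_original_nodes(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(1.0, 0.2, (40, 2)), axis=0) * 2.0
        t = resample(pts, 2.0)
        fine = spline_resample(t, 0.1)
        from scipy.spatial import cKDTree
        d, _ = cKDTree(fine.points).query(t.points)
        # nearest fine sample is within one 0.1 nm sampling step of a node
        assert d.max() < 0.06

    def test_node_count_matches_contour(self):
        t = resample(np.column_stack((np.linspace(0, 100, 101),
                                      np.zeros(101))), 2.0)
        fine = spline_resample(t, 0.1)
        assert fine.points.shape[0] == pytest.approx(
            fine.contour_length_nm / 0.1 + 1, abs=1.5)

    def test_idempotent_under_re_resampling(self):
        s = np.linspace(0, np.pi, 200)
        t = resample(40.0 * np.column_stack((np.cos(s), np.sin(s))), 2.0)
        fine = spline_resample(t, 0.1)
        back = resample(fine.points, 2.0)
        fine2 = spline_resample(back, 0.1)
        n = min(fine.points.shape[0], fine2.points.shape[0])
        assert np.abs(fine.points[:n] - fine2.points[:n]).max() < 0.01


class TestDistances:
    def test_straight_trace_end_to_end(self):
        t = resample(np.column_stack((np.linspace(0, 172, 200),
                                      np.zeros(200))), 2.0)
        assert end_to_end(t) == pytest.approx(172.0)
        assert contour_length(t) == pytest.approx(172.0)

    def test_semicircle_end_to_end(self):
        s = np.linspace(0, np.pi, 1000)
        R = 30.0
        t = resample(R * np.column_stack((np.cos(s), np.sin(s))), 1.0)
        L = contour_length(t)
        assert end_to_end(t) == pytest.approx(2 * L / np.pi, rel=1e-3)

    def test_wlc_ensemble_mean_end_to_end(self):
        # traced chains at Lp 45, Lc 172 average R ~ 131 nm
        from afmbend import sample_wlc_chain
        rng = np.random.default_rng(6)
        r2 = []
        for _ in range(3000):
            t = FilamentTrace(sample_wlc_chain(172.0, 45.0, 2.0, rng),
                              2.0, 172.0)
            r2.append(end_to_end(t) ** 2)
        assert np.sqrt(np.mean(r2)) == pytest.approx(131.0, abs=3.0)
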