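"""Otsu, morphology, spoke casting and ellipse fitting contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vascaccess as va
from vascaccess.detection import Detection
from vascaccess.phantom import ImagingConfig
from vascaccess.segmentation import (SegmentationError, clean_mask,
                                     fit_ellipse, otsu_threshold,
                                     segment_vessel, spoke_fit)


def brute_force_otsu(values: np.ndarray) -> int:
    """Independent oracle: scan all 256 thresholds for max between-class
    variance (classes <= t and > t); first maximum wins."""
    values = np.asarray(values).ravel()
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / values.size, hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


class TestOtsu:
    def test_two_point_histogram_separates_populations(self):
        img = np.array([0] * 50 + [255] * 50)
        t = otsu_threshold(img)
        assert (img <= t).sum() == 50 and (img > t).sum() == 50

    def test_matches_brute_force_on_bimodal_histogram(self):
        img = np.array([10] * 60 + [200] * 40)
        assert otsu_threshold(img) == brute_force_otsu(img)

    def test_matches_brute_force_on_200_random_histograms(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            levels = rng.choice(256, size=16, replace=False)
            counts = rng.integers(1, 50, size=16)
            values = np.repeat(levels, counts)
            assert otsu_threshold(values) == brute_force_otsu(values)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((10, 10), 7))


class TestCleanMask:
    def test_salt_noise_removed_disk_preserved(self):
        from skimage.morphology import disk as disk_fp
        mask = np.zeros((100, 100), bool)
        mask[30:71, 30:71] = disk_fp(20).astype(bool)
        rng = np.random.default_rng(1)
        noisy = mask.copy()
        salt = rng.random(mask.shape) < 0.01
        noisy |= salt
        cleaned = clean_mask(noisy)
        # isolated salt gone, disk preserved within a 1 px band
        assert not (cleaned & ~np.pad(mask, 0)).any() or \
            (cleaned & ~mask).sum() < 0.01 * mask.sum()
        assert (mask & ~cleaned).sum() < 0.05 * mask.sum()

    def test_small_components_removed(self):
        mask = np.zeros((50, 50), bool)
        mask[5:10, 5:10] = True  # 25 px < default min area 30
        assert not clean_mask(mask).any()

    def test_empty_mask_stays_empty(self):
        mask = np.zeros((20, 20), bool)
        out = clean_mask(mask)
        assert not out.any() and out.shape == mask.shape


def _disk_mask(shape, center_rc, radius_px):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2 \
        <= radius_px ** 2


class TestSpokeFit:
    def test_disk_boundary_at_uniform_radius(self):
        sp = 0.1
        mask = _disk_mask((200, 200), (99.5, 99.5), 50)  # radius 5 mm
        seed = (100.0 * sp, 100.0 * sp)
        points = spoke_fit(mask, seed, sp, n_spokes=32)
        assert len(points) == 32
        dists = np.hypot(points[:, 0] - seed[0], points[:, 1] - seed[1])
        assert np.all(np.abs(dists - 5.0) <= sp + 1e-9)

    def test_axis_aligned_ellipse_axes(self):
        sp = 0.1
        rr, cc = np.mgrid[0:300, 0:300]
        mask = ((cc - 149.5) / 60.0) ** 2 + ((rr - 149.5) / 30.0) ** 2 <= 1.0
        seed = (150.0 * sp, 150.0 * sp)
        points = spoke_fit(mask, seed, sp, n_spokes=32)
        d = np.hypot(points[:, 0] - seed[0], points[:, 1] - seed[1])
        ang = np.arctan2(points[:, 1] - seed[1], points[:, 0] - seed[0])
        along_x = d[np.isclose(np.abs(np.cos(ang)), 1.0, atol=1e-6)]
        along_y = d[np.isclose(np.abs(np.sin(ang)), 1.0, atol=1e-6)]
        assert np.allclose(along_x, 6.0, atol=2 * sp)
        assert np.allclose(along_y, 3.0, atol=2 * sp)

    def test_seed_in_background_rejected(self):
        mask = _disk_mask((100, 100), (50, 50), 10)
        with pytest.raises(SegmentationError):
            spoke_fit(mask, (0.2, 0.2), 0.1)

    def test_quorum_failure_when_mask_unbounded(self):
        mask = np.ones((50, 50), bool)  # no spoke ever leaves the mask
        with pytest.raises(SegmentationError):
            spoke_fit(mask, (2.5, 2.5), 0.1, max_radius_mm=2.0)


def _ellipse_points(cx, cy, a, b, rot_deg, n=32):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(t), b * np.sin(t)
    r = math.radians(rot_deg)
    return np.column_stack([cx + x * math.cos(r) - y * math.sin(r),
                            cy + x * math.sin(r) + y * math.cos(r)])


class TestFitEllipse:
    def test_exact_circle_recovery(self):
        fit = fit_ellipse(_ellipse_points(0.0, 25.0, 5.0, 5.0, 0.0))
        assert fit.center_mm == pytest.approx((0.0, 25.0), abs=1e-6)
        assert fit.semi_axes_mm == pytest.approx((5.0, 5.0), abs=1e-6)

    def test_exact_rotated_ellipse_recovery(self):
        fit = fit_ellipse(_ellipse_points(2.0, 20.0, 6.0, 3.0, 30.0))
        assert fit.center_mm == pytest.approx((2.0, 20.0), abs=1e-6)
        assert fit.semi_axes_mm == pytest.approx((6.0, 3.0), abs=1e-6)
        assert fit.rotation_deg == pytest.approx(30.0, abs=1e-4)
        assert fit.effective_diameter_mm == pytest.approx(
            2 * math.sqrt(18.0), abs=1e-6)

    def test_noisy_center_recovery_median_below_tenth_mm(self):
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = _ellipse_points(1.0, 22.0, 4.5, 3.5, 10.0) \
                + rng.normal(0.0, 0.1, size=(32, 2))
            fit = fit_ellipse(pts)
            errors.append(math.hypot(fit.center_mm[0] - 1.0,
                                     fit.center_mm[1] - 22.0))
        assert np.median(errors) < 0.1

    def test_too_few_points_rejected(self):
        with pytest.raises(SegmentationError):
            fit_ellipse(_ellipse_points(0, 0, 5, 5, 0)[:4])

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 8), np.linspace(0, 2, 8)])
        with pytest.raises(SegmentationError):
            fit_ellipse(pts)


def _noiseless_frame(depth=20.0, diameter=10.0):
    vein = va.VesselGeometry(0.0, depth, diameter, 0.6, 1.0)
    artery = va.VesselGeometry(-14.0, 12.0, 6.0, 1.2, 1.0)
    inst = va.AnatomyInstance(artery=artery, vein=vein,
                              bifurcation_cc_mm=-40.0, state=va.NORMOTENSIVE,
                              tenting_capacity_mm=2.0, rng_seed=0)
    config = ImagingConfig(speckle_sigma=0.0)
    return va.render_frame(inst, (0.0, 0.0), config, seed=0)


class TestSegmentVessel:
    def test_noiseless_centroid_within_pixel_spacing(self):
        frame, gt = _noiseless_frame()
        vein = next(g for g in gt if g.cls == va.VEIN)
        det = Detection(cls=va.VEIN, bbox=vein.bbox, score=1.0)
        fit = segment_vessel(frame, det)
        assert abs(fit.center_mm[0] - vein.centroid_mm[0]) < 0.1
        assert abs(fit.center_mm[1] - vein.centroid_mm[1]) < 0.1

    def test_noiseless_diameter_within_one_pixel(self):
        frame, gt = _noiseless_frame(diameter=10.0)
        vein = next(g for g in gt if g.cls == va.VEIN)
        det = Detection(cls=va.VEIN, bbox=vein.bbox, score=1.0)
        fit = segment_vessel(frame, det)
        assert abs(fit.effective_diameter_mm - 10.0) < 2 * 0.1

    def test_background_bbox_raises_failure_signal(self):
        frame, _ = _noiseless_frame()
        det = Detection(cls=va.VEIN, bbox=(10, 280, 70, 360), score=1.0)
        with pytest.raises(SegmentationError):
            segment_vessel(frame, det)

    def test_translation_equivariance(self):
        """Shifting content by whole pixels shifts the fitted centre equally."""
        frame, gt = _noiseless_frame()
        vein = next(g for g in gt if g.cls == va.VEIN)
        det = Detection(cls=va.VEIN, bbox=vein.bbox, score=1.0)
        fit0 = segment_vessel(frame, det)

        dr, dc = 13, -9
        shifted = np.roll(np.roll(frame.pixels, dr, axis=0), dc, axis=1)
        frame2 = va.BModeFrame(pixels=shifted,
                               pixel_spacing_mm=frame.pixel_spacing_mm,
                               probe_lateral_mm=0.0, probe_cc_mm=0.0)
        r0, c0, r1, c1 = vein.bbox
        det2 = Detection(cls=va.VEIN,
                         bbox=(r0 + dr, c0 + dc, r1 + dr, c1 + dc), score=1.0)
        fit2 = segment_vessel(frame2, det2)
        assert fit2.center_mm[0] - fit0.center_mm[0] == pytest.approx(
            dc * 0.1, abs=1e-6)
        assert fit2.center_mm[1] - fit0.center_mm[1] == pytest.approx(
            dr * 0.1, abs=1e-6)


class TestAccuracyOnRenderedSet:
    def test_median_abs_error_within_printed_bound(self, centroid_eval_set):
        """Median |centroid error| <= 0.3 mm per axis per class."""
        errors = {(cls, axis): [] for cls in (va.ARTERY, va.VEIN)
                  for axis in (0, 1)}
        for state, frame, gt, fits in centroid_eval_set:
            for g, fit in fits:
                for axis in (0, 1):
                    errors[(g.cls, axis)].append(
                        abs(fit.center_mm[axis] - g.centroid_mm[axis]))
        for (cls, axis), errs in errors.items():
            assert len(errs) > 50
            assert np.median(errs) <= 0.3, (cls, axis, np.median(errs))

    def test_vein_error_dispersion_at_least_artery(self, centroid_eval_set):
        """Vein localisation spreads wider than artery (more variable shape)."""
        spread = {}
        for cls in (va.ARTERY, va.VEIN):
            errs = [math.hypot(fit.center_mm[0] - g.centroid_mm[0],
                               fit.center_mm[1] - g.centroid_mm[1])
                    for _, _, _, fits in centroid_eval_set
                    for g, fit in fits if g.cls == cls]
            spread[cls] = np.quantile(errs, 0.75) - np.quantile(errs, 0.25)
        assert spread[va.VEIN] >= spread[va.ARTERY]
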