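"""Gaussian-model spot detection, counting, and threshold calibration."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial import cKDTree

from conecensus.detection import (
    CalibrationGrid,
    DetectionParams,
    calibrate_params,
    count_in_half_radius,
    detect_cones,
)
from conecensus.geometry import manual_geometry
from conecensus.synthetic import FlatMountSpec, generate_flatmount

from ._oracles import match_spots, oracle_detect
from .conftest import gaussian_field


def scatter_spots(rng, n, shape, min_dist, margin=12):
    pts = []
    while len(pts) < n:
        p = rng.uniform(margin, shape[0] - margin, 2)
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= min_dist for q in pts):
            pts.append(p)
    return np.array(pts)


class TestDetectCones:
    def test_well_separated_noiseless_spots(self):
        """25 sigma=2 Gaussians >= 12 px apart, amplitude 200: all found
        with centers within 0.5 px."""
        rng = np.random.default_rng(42)
        pts = scatter_spots(rng, 25, (256, 256), 12.0)
        img = gaussian_field((256, 256), [(x, y, 200.0, 2.0) for x, y in pts])
        census = detect_cones(img, DetectionParams(peak_threshold=50.0, sigma_expected=2.0))
        assert census.n_total == 25
        d, _ = cKDTree(pts).query(np.column_stack([census.x, census.y]), k=1)
        assert d.max() < 0.5

    def test_background_only_image_empty_census(self):
        img = np.full((128, 128), 120.0)
        census = detect_cones(img, DetectionParams(peak_threshold=50.0, sigma_expected=2.0))
        assert census.n_total == 0

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            detect_cones(np.empty((0, 0)), DetectionParams())

    def test_merged_pair_single_detection(self):
        """Two sigma=2 Gaussians 3 px apart sum to a field with a single
        local maximum (brute-force check), hence one detection."""
        spots = [(30.0, 32.0, 200.0, 2.0), (33.0, 32.0, 200.0, 2.0)]
        img = gaussian_field((64, 64), spots)
        # brute-force oracle: evaluate the noiseless field on a fine grid
        # and confirm a single interior local maximum
        xs = np.linspace(25, 38, 261)
        ys = np.linspace(27, 37, 201)
        XX, YY = np.meshgrid(xs, ys)
        field = sum(
            a * np.exp(-((XX - x) ** 2 + (YY - y) ** 2) / (2 * s * s)) for x, y, a, s in spots
        )
        n_max = 0
        for i in range(1, field.shape[0] - 1):
            for j in range(1, field.shape[1] - 1):
                patch = field[i - 1 : i + 2, j - 1 : j + 2]
                if field[i, j] == patch.max() and (patch < field[i, j]).sum() == 8:
                    n_max += 1
        assert n_max == 1
        census = detect_cones(img, DetectionParams(peak_threshold=50.0, sigma_expected=2.0))
        assert census.n_total == 1

    def test_threshold_monotonicity(self):
        """Raising the peak threshold never increases the spot count."""
        spec = FlatMountSpec(
            image_size=(256, 256), retina_radius=110.0, n_cones_total=500, seed=17,
        )
        img, _ = generate_flatmount(spec)
        counts = [
            detect_cones(img, DetectionParams(peak_threshold=tau)).n_total
            for tau in [100, 200, 400, 800, 1400, 2000, 3000]
        ]
        assert counts == sorted(counts, reverse=True)

    def test_translation_equivariance(self):
        spec = FlatMountSpec(
            image_size=(192, 192), retina_radius=80.0, n_cones_total=150, seed=23,
        )
        img, _ = generate_flatmount(spec)
        shifted = np.roll(img, (7, 11), axis=(0, 1))
        params = DetectionParams()
        a = detect_cones(img, params)
        b = detect_cones(shifted, params)
        # ignore spots that wrapped around or sit near the roll seam
        core = (a.x > 2) & (a.x < 192 - 13) & (a.y > 2) & (a.y < 192 - 9)
        xa = np.column_stack([a.x[core] + 11, a.y[core] + 7])
        xb = np.column_stack([b.x, b.y])
        d, _ = cKDTree(xb).query(xa, k=1)
        assert d.max() < 1e-6

    def test_oracle_equivalence_random_images(self):
        """Detections equal the exhaustive pixel-scan oracle spot-for-spot
        on random small synthetic images."""
        params = DetectionParams(peak_threshold=400.0)
        for seed in range(8):
            spec = FlatMountSpec(
                image_size=(64, 64), retina_radius=26.0, n_cones_total=20,
                labeling_efficiency=0.7, seed=seed,
            )
            img, _ = generate_flatmount(spec)
            fast = detect_cones(img, params)
            slow = oracle_detect(img, params)
            assert fast.n_total == slow.n_total
            if fast.n_total:
                fa = np.lexsort((fast.x, fast.y))
                sl = np.lexsort((slow.x, slow.y))
                assert np.allclose(fast.x[fa], slow.x[sl], atol=1e-9)
                assert np.allclose(fast.y[fa], slow.y[sl], atol=1e-9)
                assert np.allclose(fast.amplitude[fa], slow.amplitude[sl], atol=1e-6)

    def test_recovery_on_default_preset(self):
        """Precision and recall vs ground truth >= 0.99 at default noise
        and 20% labeling (spots matched within one psf sigma)."""
        spec = FlatMountSpec(
            image_size=(512, 512), retina_radius=230.0, n_cones_total=5000, seed=31,
        )
        img, truth = generate_flatmount(spec)
        census = detect_cones(img, DetectionParams())
        det = np.column_stack([census.x, census.y])
        tp = match_spots(det, truth.labeled_centers, spec.psf_sigma)
        assert tp / len(det) >= 0.99
        assert tp / truth.n_labeled >= 0.99


class TestCountInHalfRadius:
    def test_all_spots_at_center(self):
        census = detect_cones(
            gaussian_field((64, 64), [(32, 32, 300.0, 1.3)]), DetectionParams()
        )
        geom = manual_geometry((32, 32), 40.0)
        assert count_in_half_radius(census, geom) == census.n_total == 1
        assert census.in_half_radius.all()

    def test_uniform_truth_quarter_fraction(self):
        """Uniformly placed spots fall in the half-radius ROI about a
        quarter of the time (exact binomial 99% interval)."""
        from conecensus.detection import CellCensus

        from ._oracles import binomial_ci_99

        rng = np.random.default_rng(5)
        n = 10_000
        r = np.sqrt(rng.uniform(size=n)) * 200.0
        th = rng.uniform(0, 2 * np.pi, n)
        census = CellCensus(
            x=256 + r * np.cos(th), y=256 + r * np.sin(th),
            amplitude=np.ones(n), variance=np.ones(n),
        )
        geom = manual_geometry((256, 256), 200.0)
        count = count_in_half_radius(census, geom)
        lo, hi = binomial_ci_99(n, 0.25)
        assert lo <= count / n <= hi

    def test_spot_exactly_at_half_radius_excluded(self):
        from conecensus.detection import CellCensus

        census = CellCensus(
            x=np.array([130.0, 129.999]), y=np.array([100.0, 100.0]),
            amplitude=np.ones(2), variance=np.ones(2),
        )
        geom = manual_geometry((100.0, 100.0), 60.0)
        assert count_in_half_radius(census, geom) == 1
        assert list(census.in_half_radius) == [False, True]


class TestCalibrateParams:
    def _calibration_set(self, n_images=3, tau_star=2000.0):
        """Synthetic 'manually counted' retinas: wide amplitude spread;
        the reference count is the number of nuclei truly brighter than
        the generating visibility threshold tau*."""
        out = []
        for s in range(n_images):
            spec = FlatMountSpec(
                image_size=(256, 256), retina_radius=110.0, n_cones_total=500,
                labeling_efficiency=1.0, amplitude_cv=0.5, seed=40 + s,
            )
            img, truth = generate_flatmount(spec)
            ref = int((truth.amplitudes >= tau_star).sum())
            out.append((img, ref))
        return out

    def test_recovers_generating_threshold(self):
        tau_star = 2000.0
        grid = CalibrationGrid(peak_thresholds=list(np.arange(1000.0, 3001.0, 200.0)))
        params = calibrate_params(self._calibration_set(tau_star=tau_star), grid)
        assert abs(params.peak_threshold - tau_star) <= 200.0

    def test_zero_loss_point_selected(self):
        """If some grid point reproduces every reference count exactly,
        the search lands on a zero-loss point."""
        cal = self._calibration_set()
        grid = CalibrationGrid(peak_thresholds=[1800.0, 2000.0, 2200.0])
        params = calibrate_params(cal, grid)
        # recompute the loss at the returned point
        loss = 0
        for img, ref in cal:
            census = detect_cones(img, params)
            loss += abs(census.n_total - ref)
        best = min(
            sum(
                abs(detect_cones(img, dataclasses.replace(params, peak_threshold=tau)).n_total - ref)
                for img, ref in cal
            )
            for tau in grid.peak_thresholds
        )
        assert loss == best

    def test_tie_breaks_to_higher_threshold(self):
        img = gaussian_field((96, 96), [(30, 30, 3000.0, 1.3), (64, 60, 3000.0, 1.3)])
        grid = CalibrationGrid(peak_thresholds=[500.0, 1000.0, 1500.0])
        params = calibrate_params([(img, 2)], grid)
        assert params.peak_threshold == 1500.0

    def test_empty_calibration_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_params([], CalibrationGrid(peak_thresholds=[100.0]))
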