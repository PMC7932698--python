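"""Condensate segmentation, radius CCD statistics, and power-law fits."""

import numpy as np
import pytest

from condensate_quant import droplets, synthetic
from condensate_quant.droplets import (
    DropletRegion,
    ccd_at,
    filter_regions,
    fit_power_law,
    highpass_fourier,
    match_detections,
    multiscale_canny,
    radius_ccd,
    regions_from_mask,
    segment_droplets,
)


def region(area, ecc, centroid=(10.0, 10.0)):
    r = float(np.sqrt(area / np.pi))
    return DropletRegion(centroid, area, r, r, ecc, perimeter_px=2 * np.pi * r)


class TestHighpass:
    def test_constant_image_zeroed(self):
        out = highpass_fourier(np.full((32, 32), 7.0), 0.05)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_checkerboard_passband_identity(self):
        yy, xx = np.mgrid[0:64, 0:64]
        board = ((yy + xx) % 2).astype(float)
        out = highpass_fourier(board, 0.05)
        rms = np.sqrt(np.mean((out - (board - board.mean())) ** 2))
        assert rms < 1e-6

    def test_removes_illumination_gradient_keeps_rims(self):
        spec = synthetic.SyntheticDropletSpec(
            image_shape=(128, 128), radii=[10], centers=[(64, 64)], noise_sigma=0.0
        )
        img, _ = synthetic.gen_droplet_image(spec)
        yy, xx = np.mgrid[0:128, 0:128]
        tilted = img + 0.5 * xx / 128 + 0.3 * yy / 128
        out = highpass_fourier(tilted, 0.05)
        # residual plane is a small fraction of the rim amplitude
        A = np.column_stack([np.ones(out.size), xx.ravel(), yy.ravel()])
        coef, *_ = np.linalg.lstsq(A, out.ravel(), rcond=None)
        plane = (A @ coef).reshape(out.shape)
        assert np.sqrt(np.mean(plane**2)) < 0.05 * spec.edge_ring_contrast
        assert out.max() > 0.5 * spec.edge_ring_contrast  # rim survives

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            highpass_fourier(np.zeros((8, 8)), 0.0)
        with pytest.raises(ValueError):
            highpass_fourier(np.zeros((8, 8)), 1.5)


class TestMultiscaleCanny:
    def test_blank_image_empty_mask(self):
        assert not multiscale_canny(np.zeros((64, 64)), [1.0, 2.0]).any()

    def test_empty_sigma_list_rejected(self):
        with pytest.raises(ValueError):
            multiscale_canny(np.zeros((64, 64)), [])

    def test_duplicate_sigmas_idempotent(self):
        spec = synthetic.SyntheticDropletSpec(
            image_shape=(96, 96), radii=[8], centers=[(48, 48)],
            noise_sigma=0.05, seed=2,
        )
        img, _ = synthetic.gen_droplet_image(spec)
        once = multiscale_canny(img, [2.0])
        twice = multiscale_canny(img, [2.0, 2.0])
        assert np.array_equal(once, twice)

    def test_sigma_ladder_covers_both_scales(self):
        # sharp-rimmed 3 px droplet + soft-rimmed 15 px droplet: the small
        # sigma misses the soft rim, the large sigma smooths away the small
        # droplet; only the ladder finds both
        spec = synthetic.SyntheticDropletSpec(
            image_shape=(128, 128), radii=[3, 15],
            centers=[(30, 30), (80, 80)], ring_width=[0.8, 6.0],
            noise_sigma=0.1, seed=1,
        )
        img, truth = synthetic.gen_droplet_image(spec)
        hp = highpass_fourier(img)

        def detect(sigmas):
            ds = filter_regions(regions_from_mask(multiscale_canny(hp, sigmas)))
            return match_detections(truth["centers"], truth["radii"], ds)

        assert detect([1.0])[0] == 1
        assert detect([4.0])[0] == 1
        assert detect([1.0, 4.0])[0] == 2


class TestFilterRegions:
    def test_area_boundary_strictly_greater(self):
        assert len(filter_regions([region(3.0, 0.5)])) == 0
        assert len(filter_regions([region(3.5, 0.5)])) == 1

    def test_eccentricity_boundary_inclusive(self):
        assert len(filter_regions([region(10.0, 0.94)])) == 1
        assert len(filter_regions([region(10.0, 0.95)])) == 0

    def test_pure_filter_subset_and_idempotent(self):
        regions = [region(2.0, 0.1), region(9.0, 0.5), region(30.0, 0.99)]
        once = filter_regions(regions)
        twice = filter_regions(once.regions)
        assert all(r in regions for r in once.regions)
        assert twice.regions == once.regions
        assert len(filter_regions([])) == 0


class TestSegmentationRecovery:
    def test_precision_and_recall_on_clean_fields(self):
        tp = fp = fn = 0
        layouts = [
            ([4, 8, 15], [(40, 40), (120, 180), (190, 70)]),
            ([3.5, 6, 10, 20], [(30, 200), (80, 60), (150, 150), (210, 50)]),
        ]
        for radii, centers in layouts:
            spec = synthetic.SyntheticDropletSpec(
                image_shape=(256, 256), radii=radii, centers=centers,
                noise_sigma=0.0,
            )
            img, truth = synthetic.gen_droplet_image(spec)
            ds = segment_droplets(img)
            t, f, n = match_detections(truth["centers"], truth["radii"], ds)
            tp, fp, fn = tp + t, fp + f, fn + n
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.95
        assert recall >= 0.95

    def test_recall_degrades_monotonically_with_noise(self):
        recalls = []
        for sigma in (0.0, 0.5, 1.5):
            tp = fn = 0
            for seed in range(3):
                spec = synthetic.SyntheticDropletSpec(
                    image_shape=(160, 160), radii=[4, 9],
                    centers=[(40, 40), (110, 110)],
                    noise_sigma=sigma, seed=seed,
                )
                img, truth = synthetic.gen_droplet_image(spec)
                ds = segment_droplets(img)
                t, _, n = match_detections(truth["centers"], truth["radii"], ds)
                tp, fn = tp + t, fn + n
            recalls.append(tp / (tp + fn))
        assert recalls[0] >= recalls[1] >= recalls[2]


class TestRadiusCCD:
    def test_enumeration_identities(self):
        dist = radius_ccd(np.array([1.0, 2.0, 3.0]), n_boot=50)
        assert ccd_at(dist, 2.0) == pytest.approx(2.0 / 3.0)
        assert dist.expected_radius == pytest.approx(2.0, abs=1e-9)
        assert ccd_at(dist, 0.0) == 1.0

    def test_ccd_monotone_and_one_at_minimum(self):
        rng = np.random.default_rng(0)
        dist = radius_ccd(rng.exponential(5.0, 200), n_boot=50)
        assert np.all(np.diff(dist.ccd) <= 0)
        assert dist.ccd[0] == 1.0

    def test_expected_radius_equals_mean(self):
        rng = np.random.default_rng(1)
        radii = rng.lognormal(0.5, 0.4, 300)
        dist = radius_ccd(radii, n_boot=50)
        assert dist.expected_radius == pytest.approx(radii.mean(), abs=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            radius_ccd(np.array([]))

    def test_bootstrap_ci_covers_true_mean(self):
        # Exp(mean 5), n = 500: the 95% CI should contain 5 in >= 90% of trials
        hits = 0
        trials = 50
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            radii = rng.exponential(5.0, 500)
            dist = radius_ccd(radii, n_boot=500, seed=seed)
            lo, hi = dist.expected_radius_ci
            hits += lo <= 5.0 <= hi
        assert hits / trials >= 0.90


class TestPowerLaw:
    def test_exact_recovery(self):
        c = np.array([1.0, 4.0, 16.0])
        fit = fit_power_law(c, 2.0 * c**0.5)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.exponent == pytest.approx(0.5, abs=1e-9)

    def test_insufficient_conditions_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([1.0], [2.0])
        with pytest.raises(ValueError):
            fit_power_law([1.0, 2.0, 3.0], [1.0, -2.0, 3.0])

    def test_exponent_recovery_under_lognormal_noise(self):
        errors = []
        c = np.array([0.5, 1, 2, 4, 8, 16, 32, 64])
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r = 1.5 * c**0.33 * np.exp(rng.normal(0, 0.05, c.size))
            errors.append(abs(fit_power_law(c, r).exponent - 0.33))
        assert np.median(errors) <= 0.05
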