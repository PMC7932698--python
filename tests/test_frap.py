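"""FRAP normalization, biexponential fitting, spatial photobleach correction."""

import numpy as np
import pytest
from scipy.stats import linregress

from condensate_quant import frap, synthetic
from condensate_quant.frap import (
    FrapTrace,
    correct_whole_drop_frap,
    fit_biexp_decay,
    fit_biexponential,
    fit_spatial_decay,
    measure_frap_traces,
    normalize_line_frap,
)
from condensate_quant.synthetic import SpatialDecayTruth, SyntheticFrapSpec


def unbleached_traces(movie, truth, background):
    return [movie[:, m].mean(axis=1) - background for m in truth["masks"]]


class TestNormalizeLineFrap:
    def test_identical_traces_give_unity(self):
        t = np.arange(30.0)
        y = 100 * np.exp(-0.02 * t)
        trace = FrapTrace(time=t, I_frap=y.copy(), I_unbleached=[y.copy(), y.copy()],
                          I_background=np.zeros(30), bleach_frame=5)
        assert np.allclose(normalize_line_frap(trace), 1.0)

    def test_degenerate_background_rejected(self):
        t = np.arange(30.0)
        y = np.full(30, 50.0)
        trace = FrapTrace(time=t, I_frap=y.copy(), I_unbleached=[y.copy()],
                          I_background=y.copy(), bleach_frame=5)
        with pytest.raises(ValueError):
            normalize_line_frap(trace)

    def test_recovers_ground_truth_curve_within_2pct_rms(self):
        spec = SyntheticFrapSpec(
            n_frames=80, image_shape=(96, 96), radii=[8, 8, 8],
            centers=[(20, 48), (48, 20), (70, 70)],
            decay=SpatialDecayTruth(a_mean=0.2, b_mean=0.8, k1_0=0.05, k2_0=0.01),
            bleach_frame=10, bleach_roi=(44, 0, 52, 96),
            recovery_a=0.8, recovery_b=0.0, recovery_k1=0.3466,
            noise_sigma=0.5, seed=5,
        )
        movie, truth = synthetic.gen_frap_movie(spec)
        trace = measure_frap_traces(movie, 10, (44, 0, 52, 96),
                                    exclusion_factor=0.0)
        norm = normalize_line_frap(trace)
        rms = np.sqrt(np.mean((norm[10:] - truth["recovery"][10:]) ** 2))
        assert rms < 0.02


class TestBiexponentialFit:
    def test_single_exponential_half_time_closed_form(self):
        t = np.arange(0, 30, 0.25)
        k = np.log(2) / 2.0
        fit = fit_biexponential(1 - 0.8 * np.exp(-k * t), t)
        assert fit.t_half == pytest.approx(2.0, rel=1e-6)

    def test_flat_series_flagged_degenerate(self):
        t = np.arange(20.0)
        fit = fit_biexponential(np.full(20, 0.4), t)
        assert not fit.converged
        assert fit.t_half is None

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_biexponential(np.ones(5), np.arange(5.0))

    def test_parameter_recovery_at_1pct_noise(self):
        t = np.arange(0, 60, 0.5)
        rels = {k: [] for k in ("a", "b", "k1", "k2")}
        t_half_err = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            clean = 1 - 0.6 * np.exp(-1.0 * t) - 0.3 * np.exp(-0.1 * t)
            fit = fit_biexponential(clean + rng.normal(0, 0.01, t.size), t)
            rels["a"].append(abs(fit.a - 0.6) / 0.6)
            rels["b"].append(abs(fit.b - 0.3) / 0.3)
            rels["k1"].append(abs(fit.k1 - 1.0) / 1.0)
            rels["k2"].append(abs(fit.k2 - 0.1) / 0.1)
            clean_fit = fit_biexponential(clean, t)
            t_half_err.append(abs(fit.t_half - clean_fit.t_half) / clean_fit.t_half)
        for key, errs in rels.items():
            assert np.median(errs) <= 0.10, key
        assert np.median(t_half_err) <= 0.05


class TestSpatialDecay:
    def make_field(self, decay, seed=3, noise=1.0, n_frames=100):
        centers = [(20, 20), (20, 100), (60, 40), (60, 110),
                   (100, 20), (100, 90), (40, 70), (90, 60)]
        spec = SyntheticFrapSpec(
            n_frames=n_frames, image_shape=(128, 128), radii=[8] * 8,
            centers=centers, decay=decay, noise_sigma=noise, seed=seed,
        )
        movie, truth = synthetic.gen_frap_movie(spec)
        traces = unbleached_traces(movie, truth, spec.background)
        xy = np.array([(c[1], c[0]) for c in centers], dtype=float)
        return traces, xy, truth["time"]

    def test_uniform_field_recovers_zero_gradients(self):
        decay = SpatialDecayTruth(k1_0=0.08, k2_0=0.008)
        traces, xy, t = self.make_field(decay, noise=0.2)
        model = fit_spatial_decay(traces, xy, t)
        assert abs(model.alpha1) < 1e-4
        assert abs(model.beta1) < 1e-4
        assert model.k1_0 == pytest.approx(0.08, rel=0.05)

    def test_gradient_recovery_within_10pct(self):
        decay = SpatialDecayTruth(
            k1_0=0.10, alpha1=1e-3, beta1=2e-3, k2_0=0.01,
            alpha2=1e-4, beta2=5e-5,
        )
        rels = {k: [] for k in ("alpha1", "beta1", "alpha2", "beta2")}
        for seed in range(10):
            traces, xy, t = self.make_field(decay, seed=seed)
            model = fit_spatial_decay(traces, xy, t)
            for key in rels:
                truth_v = getattr(decay, key)
                rels[key].append(abs(getattr(model, key) - truth_v) / truth_v)
        for key, errs in rels.items():
            assert np.median(errs) <= 0.10, key

    def test_gradient_estimates_unbiased(self):
        # signed error averages out over seeds at 1% relative noise
        decay = SpatialDecayTruth(k1_0=0.10, alpha1=1e-3, beta1=2e-3)
        signed = {"alpha1": [], "beta1": []}
        for seed in range(20):
            traces, xy, t = self.make_field(decay, seed=seed, noise=1.0)
            model = fit_spatial_decay(traces, xy, t)
            signed["alpha1"].append((model.alpha1 - decay.alpha1) / decay.alpha1)
            signed["beta1"].append((model.beta1 - decay.beta1) / decay.beta1)
        for key, errs in signed.items():
            assert abs(np.mean(errs)) < 0.02, key

    def test_too_few_droplets_rejected(self):
        t = np.arange(50.0)
        traces = [np.exp(-0.1 * t)] * 2
        with pytest.raises(ValueError, match="unbleached"):
            fit_spatial_decay(traces, np.array([[0, 0], [1, 1]]), t)

    def test_collinear_centroids_rejected(self):
        t = np.arange(50.0)
        traces = [np.exp(-0.1 * t)] * 6
        xy = np.array([[i, 2.0 * i] for i in range(6)])
        with pytest.raises(ValueError, match="collinear"):
            fit_spatial_decay(traces, xy, t)


class TestWholeDropCorrection:
    def test_self_consistency_on_unbleached_droplet(self):
        decay = SpatialDecayTruth(k1_0=0.05, alpha1=5e-4, beta1=2e-4, k2_0=0.005)
        centers = [(20, 20), (20, 100), (60, 40), (60, 110),
                   (100, 20), (100, 90), (40, 70), (90, 60)]
        spec = SyntheticFrapSpec(
            n_frames=100, image_shape=(128, 128), radii=[8] * 8,
            centers=centers, decay=decay, noise_sigma=0.5, seed=3,
        )
        movie, truth = synthetic.gen_frap_movie(spec)
        traces = unbleached_traces(movie, truth, spec.background)
        xy = np.array([(c[1], c[0]) for c in centers], dtype=float)
        model = fit_spatial_decay(traces, xy, truth["time"])
        corr, _ = correct_whole_drop_frap(traces[0], tuple(xy[0]), model,
                                          truth["time"], bleach_frame=5)
        assert np.max(np.abs(corr - 1.0)) < 0.05

    def test_full_recovery_plateaus_at_unity(self):
        decay = SpatialDecayTruth(k1_0=0.05, alpha1=5e-4, beta1=2e-4, k2_0=0.005)
        centers = [(20, 20), (20, 100), (60, 40), (60, 110),
                   (100, 20), (100, 90), (40, 70), (90, 60), (64, 64)]
        spec = SyntheticFrapSpec(
            n_frames=120, image_shape=(128, 128), radii=[8] * 9,
            centers=centers, decay=decay,
            bleach_frame=10, bleach_roi=(54, 54, 75, 75),
            recovery_a=0.8, recovery_b=0.1, recovery_k1=0.4, recovery_k2=0.05,
            noise_sigma=0.5, seed=7,
        )
        movie, truth = synthetic.gen_frap_movie(spec)
        bleached = movie[:, truth["masks"][8]].mean(axis=1) - spec.background
        traces = [movie[:, m].mean(axis=1) - spec.background
                  for m in truth["masks"][:8]]
        xy = np.array([(c[1], c[0]) for c in centers[:8]], dtype=float)
        model = fit_spatial_decay(traces, xy, truth["time"])
        corr, spread = correct_whole_drop_frap(
            bleached, (64.0, 64.0), model, truth["time"], bleach_frame=10,
            unbleached=traces, unbleached_centroids=xy,
        )
        assert corr[-20:].mean() == pytest.approx(1.0, abs=0.05)
        assert len(spread) == 8
        for s in spread:
            assert np.max(np.abs(s - 1.0)) < 0.1

    def test_zero_gradient_model_reduces_to_global_normalization(self):
        t = np.arange(60.0)
        model = frap.SpatialDecayModel(
            a_mean=0.7, b_mean=0.3, k1_0=0.05, k2_0=0.005,
            alpha1=0.0, beta1=0.0, alpha2=0.0, beta2=0.0,
        )
        y = 80.0 * (0.7 * np.exp(-0.05 * t) + 0.3 * np.exp(-0.005 * t))
        a, _ = correct_whole_drop_frap(y, (10.0, 10.0), model, t, 5)
        b, _ = correct_whole_drop_frap(y, (100.0, 100.0), model, t, 5)
        assert np.allclose(a, b, atol=1e-9)

    def test_no_recovery_stays_flat_after_correction(self):
        # pure photobleach, no true recovery: corrected slope ~ 0
        decay = SpatialDecayTruth(k1_0=0.05, alpha1=3e-4, beta1=1e-4, k2_0=0.005)
        slopes_sig = 0
        n_seeds = 10
        for seed in range(n_seeds):
            centers = [(20, 20), (20, 100), (60, 40), (60, 110),
                       (100, 20), (100, 90), (40, 70), (90, 60)]
            spec = SyntheticFrapSpec(
                n_frames=80, image_shape=(128, 128), radii=[8] * 8,
                centers=centers, decay=decay, noise_sigma=0.5, seed=seed,
            )
            movie, truth = synthetic.gen_frap_movie(spec)
            traces = unbleached_traces(movie, truth, spec.background)
            xy = np.array([(c[1], c[0]) for c in centers], dtype=float)
            model = fit_spatial_decay(traces, xy, truth["time"])
            corr, _ = correct_whole_drop_frap(traces[3], tuple(xy[3]), model,
                                              truth["time"], bleach_frame=5)
            res = linregress(truth["time"], corr)
            slopes_sig += res.pvalue < 0.05
        assert slopes_sig <= n_seeds // 2


class TestDecayFit:
    def test_amplitude_fractions_and_rates(self):
        t = np.arange(0, 100, 1.0)
        y = 200.0 * (0.7 * np.exp(-0.1 * t) + 0.3 * np.exp(-0.01 * t))
        fit = fit_biexp_decay(y, t)
        assert fit.a == pytest.approx(0.7, rel=0.02)
        assert fit.b == pytest.approx(0.3, rel=0.02)
        assert fit.k1 == pytest.approx(0.1, rel=0.02)
        assert fit.k2 == pytest.approx(0.01, rel=0.02)
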