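import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gazecond.equalize import histogram_equalize
from gazecond.geometry import ViewingGeometry
from gazecond.synth import (
    ObserverModel,
    PinkNoiseSpec,
    amplitude_spectrum,
    central_bias_density,
    make_pink_noise,
    make_test_pattern,
    pink_noise_field,
    sample_clicks,
    sample_fixations,
)

GEOM = ViewingGeometry(16.0, (96, 96))


class TestPinkNoise:
    def test_output_amplitude_matches_target_exactly(self):
        amp = amplitude_spectrum((128, 128), 1.0)
        field = pink_noise_field(amp, np.random.default_rng(0))
        out = np.abs(np.fft.fft2(field))
        mask = amp > 0
        rel = np.abs(out[mask] - amp[mask]) / amp[mask]
        assert rel.max() < 1e-6

    def test_field_is_real_by_conjugate_symmetry(self):
        amp = amplitude_spectrum((64, 64), 1.0)
        white = np.random.default_rng(1).standard_normal((64, 64))
        spectrum = np.fft.fft2(white)
        phase = spectrum / np.abs(spectrum)
        complex_field = np.fft.ifft2(amp * phase)
        assert np.abs(complex_field.imag).max() < 1e-9

    def test_gamma_one_spectral_slope_recovered(self):
        field = pink_noise_field(amplitude_spectrum((256, 256), 1.0), np.random.default_rng(2))
        out = np.abs(np.fft.fft2(field))
        fy = np.fft.fftfreq(256)[:, None]
        fx = np.fft.fftfreq(256)[None, :]
        fr = np.sqrt(fy**2 + fx**2)
        m = (fr > 0.01) & (fr < 0.4)
        slope = np.polyfit(np.log(fr[m]), np.log(out[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_image_channels_rescaled_and_deterministic(self):
        a = make_pink_noise(PinkNoiseSpec(shape=(64, 64), seed=5))
        b = make_pink_noise(PinkNoiseSpec(shape=(64, 64), seed=5))
        c = make_pink_noise(PinkNoiseSpec(shape=(64, 64), seed=6))
        assert a.shape == (64, 64, 3)
        assert a.min() >= 0.0 and a.max() <= 1.0
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_different_seeds_have_uncorrelated_phases(self):
        amp = amplitude_spectrum((256, 256), 1.0)
        f1 = pink_noise_field(amp, np.random.default_rng(7))
        f2 = pink_noise_field(amp, np.random.default_rng(8))
        p1 = np.angle(np.fft.fft2(f1)).ravel()
        p2 = np.angle(np.fft.fft2(f2)).ravel()
        corr = np.corrcoef(np.cos(p1), np.cos(p2))[0, 1]
        assert abs(corr) < 0.02

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_pink_noise(
                PinkNoiseSpec(shape=(64, 64), target_amplitude=np.ones((32, 32)))
            )


class TestTestPatterns:
    def test_uniform_constant(self):
        assert np.unique(make_test_pattern("uniform", (32, 32))).size == 1

    def test_step_edge_two_values_at_stated_column(self):
        img = make_test_pattern("step_edge", (64, 64))
        assert np.unique(img).size == 2
        assert np.all(img[:, :32] == img[0, 0])
        assert np.all(img[:, 32:] == img[0, 63])

    def test_rings_invariant_under_quarter_rotation(self):
        img = make_test_pattern("concentric_rings", (65, 65))
        assert np.abs(img - np.rot90(img)).max() < 1e-9

    def test_mirrored_noise_is_mirror_symmetric(self):
        img = make_test_pattern("mirrored_noise", (64, 64), seed=4)
        assert np.array_equal(img[:, :32], img[:, 32:][:, ::-1])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_test_pattern("spiral", (32, 32))


class TestSampleFixations:
    def test_uniform_sampling_passes_chi_square_gof(self):
        r = np.random.default_rng(0)
        pm = histogram_equalize(r.random((96, 96))).values
        obs = ObserverModel(saliency=None, bias_sigma_deg=None, fixations_per_trial=10_001)
        fix = sample_fixations(pm, obs, GEOM, 10_001, r)
        fix = fix[fix["rank"] > 1]  # rank 1 is the planted central artifact
        counts, _, _ = np.histogram2d(fix["y"], fix["x"], bins=(8, 8), range=[[0, 96], [0, 96]])
        _, p = stats.chisquare(counts.ravel())
        assert p > 0.01

    def test_linear_saliency_gives_three_quarters_above_median(self):
        r = np.random.default_rng(1)
        pm = histogram_equalize(r.random((96, 96))).values
        obs = ObserverModel(saliency=lambda x: x, bias_sigma_deg=None, fixations_per_trial=10_001)
        fix = sample_fixations(pm, obs, GEOM, 10_001, r)
        fix = fix[fix["rank"] > 1]
        frac = (fix["feature_pct"] > 50).mean()
        assert frac == pytest.approx(0.75, abs=0.02)

    def test_seed_determinism(self):
        pm = histogram_equalize(np.random.default_rng(2).random((96, 96))).values
        obs = ObserverModel()
        a = sample_fixations(pm, obs, GEOM, 200, np.random.default_rng(3))
        b = sample_fixations(pm, obs, GEOM, 200, np.random.default_rng(3))
        c = sample_fixations(pm, obs, GEOM, 200, np.random.default_rng(4))
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_spatial_marginal_converges_to_product_density(self):
        r = np.random.default_rng(5)
        pm = histogram_equalize(r.random((96, 96))).values
        obs = ObserverModel(saliency=lambda x: 10 + x, bias_sigma_deg=3.0,
                            fixations_per_trial=100_001)
        fix = sample_fixations(pm, obs, GEOM, 100_001, r)
        fix = fix[fix["rank"] > 1]
        target = (10 + pm) * central_bias_density(GEOM, 3.0)
        target = target / target.sum()
        counts = np.zeros((96, 96))
        np.add.at(counts, (fix["y"].astype(int), fix["x"].astype(int)), 1.0)
        emp_cdf = np.cumsum(counts.ravel() / counts.sum())
        target_cdf = np.cumsum(target.ravel())
        assert np.abs(emp_cdf - target_cdf).max() < 0.02

    def test_zero_saliency_rejected(self):
        pm = histogram_equalize(np.random.default_rng(6).random((32, 32))).values
        g = ViewingGeometry(16.0, (32, 32))
        obs = ObserverModel(saliency=lambda x: np.zeros_like(x))
        with pytest.raises(ValueError):
            sample_fixations(pm, obs, g, 10, np.random.default_rng(0))


class TestSampleClicks:
    def test_exact_click_counts(self):
        r = np.random.default_rng(0)
        clicks = sample_clicks([(48.0, 48.0)], 1.0, GEOM, n_subjects=35, rng=r)
        assert len(clicks) == 35 * 5
        assert clicks.groupby("subject").size().eq(5).all()

    def test_tiny_spread_stays_near_center(self):
        r = np.random.default_rng(1)
        clicks = sample_clicks([(48.0, 48.0)], 0.05, GEOM, n_subjects=10, rng=r)
        d = np.hypot(clicks["y"] - 48, clicks["x"] - 48)
        assert d.max() < GEOM.deg_to_px(1.0)

    def test_two_centers_split_within_binomial_band(self):
        r = np.random.default_rng(2)
        clicks = sample_clicks([(20.0, 20.0), (70.0, 70.0)], 0.5, GEOM, n_subjects=35, rng=r)
        near_first = (np.hypot(clicks["y"] - 20, clicks["x"] - 20) < 20).sum()
        n = len(clicks)
        band = stats.binom.interval(0.99, n, 0.5)
        assert band[0] <= near_first <= band[1]

    def test_no_centers_rejected(self):
        with pytest.raises(ValueError):
            sample_clicks([], 1.0, GEOM, n_subjects=2, rng=np.random.default_rng(0))
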