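import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gazecond.equalize import histogram_equalize
from gazecond.saliency import (
    bootstrap_ci,
    feature_dkl,
    saliency_1d,
    saliency_2d,
    symmetric_dkl,
)


def direct_symmetric_dkl(p, q):
    p = p / p.sum()
    q = q / q.sum()
    fwd = sum(pi * np.log2(pi / qi) for pi, qi in zip(p, q) if pi > 0)
    bwd = sum(qi * np.log2(qi / pi) for pi, qi in zip(p, q) if qi > 0)
    return 0.5 * (fwd + bwd)


class TestSymmetricDkl:
    def test_identical_distributions_give_exactly_zero(self, rng):
        p = rng.random(64)
        assert symmetric_dkl(p, p.copy()) == 0.0

    def test_two_bin_hand_oracle(self):
        got = symmetric_dkl(np.array([0.5, 0.5]), np.array([0.25, 0.75]))
        ref = 0.5 * (
            0.5 * np.log2(0.5 / 0.25)
            + 0.5 * np.log2(0.5 / 0.75)
            + 0.25 * np.log2(0.25 / 0.5)
            + 0.75 * np.log2(0.75 / 0.5)
        )
        assert abs(got - ref) < 1e-12

    def test_matches_direct_summation_on_1000_random_histogram_pairs(self):
        r = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            p = r.random(64) + 1e-3
            q = r.random(64) + 1e-3
            worst = max(worst, abs(symmetric_dkl(p, q) - direct_symmetric_dkl(p, q)))
        assert worst < 1e-12

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_nonnegative(self, seed):
        r = np.random.default_rng(seed)
        p, q = r.random(16), r.random(16)
        d = symmetric_dkl(p, q)
        assert d >= 0
        assert d == symmetric_dkl(q, p)

    def test_one_sided_zero_bins_stay_finite(self):
        p = np.array([1.0, 0.0, 0.0])
        q = np.array([0.2, 0.5, 0.3])
        assert np.isfinite(symmetric_dkl(p, q))

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            symmetric_dkl(np.ones(4), np.ones(5))


class TestBootstrapCI:
    def test_constant_values_give_degenerate_interval(self):
        assert bootstrap_ci([3.0] * 8, seed=0) == (3.0, 3.0)

    def test_binary_pool_interval_matches_monte_carlo_oracle(self):
        values = [0.0] * 20 + [1.0] * 20
        lo, hi = bootstrap_ci(values, level=0.99, seed=2)
        assert lo < 0.5 < hi
        r = np.random.default_rng(99)
        means = [r.choice(values, size=40, replace=True).mean() for _ in range(1000)]
        ref_lo, ref_hi = np.quantile(means, [0.005, 0.995])
        assert (hi - lo) == pytest.approx(ref_hi - ref_lo, rel=0.10)

    def test_same_seed_reproduces_interval(self, rng):
        v = rng.random(10)
        assert bootstrap_ci(v, seed=7) == bootstrap_ci(v, seed=7)


def _fix_df(pcts, pct_map):
    """Place one fixation on a pixel holding each requested percentile."""
    flat = pct_map.ravel()
    idx = [np.argmin(np.abs(flat - p)) for p in pcts]
    ys, xs = np.unravel_index(idx, pct_map.shape)
    return pd.DataFrame({"x": xs.astype(float), "y": ys.astype(float)})


class TestSaliencyFunctions:
    def test_uniform_fixations_give_flat_function(self):
        r = np.random.default_rng(0)
        pm = histogram_equalize(r.random((96, 96))).values
        n = 10_000
        fix = pd.DataFrame(
            {"x": r.integers(0, 96, n).astype(float), "y": r.integers(0, 96, n).astype(float)}
        )
        fn = saliency_1d(pm, fix)
        se = 64 * np.sqrt((1 / 64) * (1 - 1 / 64) / n)
        assert np.abs(fn.values - 1.0).max() < 4 * se

    def test_top_decile_fixations_concentrate_saliency(self):
        r = np.random.default_rng(1)
        pm = histogram_equalize(r.random((64, 64))).values
        fix = _fix_df(r.uniform(90.5, 99.5, 500), pm)
        fn = saliency_1d(pm, fix, pseudo=0.0)
        top_mass = fn.actual[-7:].sum()
        assert top_mass == pytest.approx(1.0)

    def test_2d_duplicated_feature_defined_only_on_diagonal(self):
        r = np.random.default_rng(2)
        pm = histogram_equalize(r.random((64, 64))).values
        fix = _fix_df(r.uniform(0, 100, 400), pm)
        fn = saliency_2d(pm, pm, fix, np.ones_like(pm))
        off_diag = ~np.eye(8, dtype=bool)
        assert np.isnan(fn.values[off_diag]).all()
        assert np.isfinite(np.diag(fn.values)).all()


def _planted_category(seed, g=None, n_per_image=2500, n_images=4, n_subjects=3):
    """Small planted-study helper: returns feature maps and fixations."""
    from gazecond.geometry import ViewingGeometry
    from gazecond.synth import ObserverModel, sample_fixations
    from gazecond.synth import amplitude_spectrum, pink_noise_field

    r = np.random.default_rng(seed)
    geom = ViewingGeometry(16.0, (128, 128))
    maps = {
        f"img{i}": pink_noise_field(amplitude_spectrum((128, 128), 1.0), r)
        for i in range(n_images)
    }
    pcts = {k: histogram_equalize(v).values for k, v in maps.items()}
    obs = ObserverModel(saliency=g, bias_sigma_deg=None)
    frames = [
        sample_fixations(
            pcts[img], obs, geom, n_per_image, r, subject=f"s{s}", image=img,
            category="Synthetic",
        )
        for s in range(n_subjects)
        for img in maps
    ]
    return geom, maps, pd.concat(frames, ignore_index=True)


class TestFeatureDkl:
    def test_stronger_planted_slope_gives_larger_dkl(self):
        geom, maps, fix_weak = _planted_category(3, g=lambda x: 100 + x)
        _, _, fix_strong = _planted_category(3, g=lambda x: 100 + 2 * x)
        weak = feature_dkl(maps, fix_weak, geom, seed=0).dkl.value_bits
        strong = feature_dkl(maps, fix_strong, geom, seed=0).dkl.value_bits
        assert strong > weak > 0

    def test_null_dkl_shrinks_with_sample_size(self):
        values = []
        for n in (500, 5000):
            geom, maps, fix = _planted_category(4, g=None, n_per_image=n, n_images=2)
            values.append(feature_dkl(maps, fix, geom, seed=0).dkl.value_bits)
        assert values[1] < values[0]

    def test_joint_dkl_dominates_marginals(self):
        # information cannot decrease when a second feature is added
        geom, maps, fix = _planted_category(5, g=lambda x: 20 + x)
        r = np.random.default_rng(11)
        from gazecond.synth import amplitude_spectrum, pink_noise_field

        maps2 = {
            k: pink_noise_field(amplitude_spectrum((128, 128), 1.0), r) for k in maps
        }
        joint = feature_dkl(maps, fix, geom, maps2=maps2, seed=0).dkl.value_bits
        m1 = feature_dkl(maps, fix, geom, n_bins=8, seed=0).dkl.value_bits
        m2 = feature_dkl(maps2, fix, geom, n_bins=8, seed=0).dkl.value_bits
        assert joint >= max(m1, m2) - 1e-9

    def test_requires_fixations(self):
        geom, maps, fix = _planted_category(6, n_per_image=50, n_images=2, n_subjects=1)
        with pytest.raises(ValueError):
            feature_dkl(maps, fix.iloc[0:0], geom)
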