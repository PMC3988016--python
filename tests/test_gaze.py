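import numpy as np
import pandas as pd
import pytest

from gazecond.gaze import (
    SaccadeThresholds,
    build_density_map,
    drop_out_of_bounds,
    exploration_summary,
    map_entropy,
    parse_fixations,
)
from gazecond.geometry import ViewingGeometry

GEOM = ViewingGeometry(16.0, (96, 96))


class TestParseFixations:
    def test_constant_trace_is_single_fixation(self):
        t = np.arange(0, 1000, 2.0)
        fx = parse_fixations(t, np.zeros(t.size), np.zeros(t.size))
        assert len(fx) == 1
        assert fx["duration_ms"].iloc[0] == pytest.approx(1000.0)

    def test_two_epochs_joined_by_fast_saccade(self):
        # 400 ms at x=0, 20 ms traversal of 10 deg (500 deg/s), 400 ms at x=10
        t = np.arange(0, 820, 2.0)
        x = np.concatenate([np.zeros(200), np.linspace(0, 10, 10), np.full(200, 10.0)])
        fx = parse_fixations(t, x, np.zeros(t.size))
        assert len(fx) == 2
        assert fx["x"].round(1).tolist() == [0.0, 10.0]
        assert (fx["duration_ms"] > 390).all()

    def test_subthreshold_jitter_keeps_one_fixation(self):
        r = np.random.default_rng(0)
        t = np.arange(0, 1000, 2.0)
        fx = parse_fixations(
            t, 0.02 * r.standard_normal(t.size), 0.02 * r.standard_normal(t.size)
        )
        assert len(fx) == 1

    def test_infinite_thresholds_yield_one_spanning_fixation(self):
        r = np.random.default_rng(1)
        t = np.arange(0, 500, 2.0)
        th = SaccadeThresholds(np.inf, np.inf, np.inf, np.inf)
        fx = parse_fixations(t, 20 * r.standard_normal(t.size), 20 * r.standard_normal(t.size), th)
        assert len(fx) == 1
        assert fx["duration_ms"].iloc[0] == pytest.approx(500.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            parse_fixations(np.array([0.0]), np.array([0.0]), np.array([0.0]))


class TestDensityMaps:
    def test_unit_integral_and_argmax_at_event(self):
        ev = pd.DataFrame({"x": [48.0], "y": [40.0]})
        m = build_density_map(ev, GEOM, 1.0)
        assert m.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(m.values >= 0)
        iy, ix = np.unravel_index(np.argmax(m.values), m.values.shape)
        assert (iy, ix) == (40, 48)

    def test_mirror_symmetric_events_give_mirror_symmetric_map(self):
        ev = pd.DataFrame({"x": [20.0, 75.0], "y": [48.0, 48.0]})
        m = build_density_map(ev, GEOM, 1.0).values
        assert np.abs(m - m[:, ::-1]).max() < 1e-9

    def test_linearity_in_events(self, rng):
        ev = pd.DataFrame({"x": rng.uniform(0, 95, 40), "y": rng.uniform(0, 95, 40)})
        full = build_density_map(ev, GEOM, 1.0).values
        a = build_density_map(ev.iloc[:15], GEOM, 1.0).values
        b = build_density_map(ev.iloc[15:], GEOM, 1.0).values
        assert np.abs(40 * full - (15 * a + 25 * b)).max() < 1e-9

    def test_moment_recovery_from_gaussian_events(self):
        r = np.random.default_rng(5)
        n = 10_000
        ev = pd.DataFrame(
            {
                "x": np.clip(r.normal(50, 8, n), 0, 95),
                "y": np.clip(r.normal(45, 6, n), 0, 95),
            }
        )
        m = build_density_map(ev, GEOM, 1.0).values
        yy, xx = np.mgrid[0:96, 0:96]
        mx, my = (m * xx).sum(), (m * yy).sum()
        sx = np.sqrt((m * (xx - mx) ** 2).sum())
        sy = np.sqrt((m * (yy - my) ** 2).sum())
        assert mx == pytest.approx(50, rel=0.05)
        assert my == pytest.approx(45, rel=0.05)
        # smoothing kernel (sigma ~2.9 px) adds variance in quadrature
        assert sx == pytest.approx(np.hypot(8, GEOM.fwhm_sigma_px(1.0)), rel=0.05)
        assert sy == pytest.approx(np.hypot(6, GEOM.fwhm_sigma_px(1.0)), rel=0.05)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            build_density_map(pd.DataFrame({"x": [], "y": []}), GEOM, 1.0)

    def test_out_of_bounds_dropped_not_clipped(self):
        ev = pd.DataFrame({"x": [10.0, -3.0, 200.0], "y": [10.0, 5.0, 5.0]})
        kept = drop_out_of_bounds(ev, GEOM)
        assert len(kept) == 1


class TestEntropy:
    def test_uniform_map_has_normalized_entropy_one(self):
        assert map_entropy(np.ones((32, 32)) / 1024, (4, 4)).normalized == pytest.approx(1.0)

    def test_single_cell_mass_has_zero_entropy(self):
        v = np.zeros((64, 64))
        v[3, 3] = 1.0
        r = map_entropy(v, (8, 8))
        assert r.raw_bits == 0.0
        assert r.normalized == 0.0

    def test_half_half_mass_is_one_bit(self):
        v = np.zeros((8, 8))
        v[0, 0] = 0.5
        v[7, 7] = 0.5
        r = map_entropy(v, (2, 2))
        assert r.raw_bits == pytest.approx(1.0, abs=1e-12)
        assert r.normalized == pytest.approx(0.5, abs=1e-12)

    def test_matches_direct_summation_on_random_histograms(self, rng):
        for _ in range(20):
            v = rng.random((16, 16))
            v /= v.sum()
            r = map_entropy(v, (4, 4))
            cells = v.reshape(4, 4, 4, 4).sum(axis=(1, 3)).ravel()
            ref = -(cells[cells > 0] * np.log2(cells[cells > 0])).sum()
            assert r.raw_bits == pytest.approx(ref, abs=1e-12)

    def test_degenerate_binning_rejected(self):
        with pytest.raises(ValueError):
            map_entropy(np.ones((8, 8)), (1, 1))


class TestExplorationSummary:
    def test_planted_image_specific_hotspots(self):
        # each image has its own hotspot: pooling across images spreads mass,
        # so category entropy exceeds the mean image-specific entropy
        r = np.random.default_rng(7)
        frames = []
        for i in range(6):
            cx, cy = r.uniform(15, 80, 2)
            n = 400
            frames.append(
                pd.DataFrame(
                    {
                        "subject": "s01",
                        "image": f"img{i}",
                        "category": "Synthetic",
                        "x": np.clip(r.normal(cx, 3, n), 0, 95),
                        "y": np.clip(r.normal(cy, 3, n), 0, 95),
                    }
                )
            )
        fix = pd.concat(frames, ignore_index=True)
        table = exploration_summary(fix, GEOM)
        row = table.iloc[0]
        assert row["category_entropy"] > row["mean_image_entropy"]

    def test_identical_fixations_give_matching_entropies(self):
        fix = pd.DataFrame(
            {
                "subject": ["s01"] * 40,
                "image": [f"img{i}" for i in range(4) for _ in range(10)],
                "category": "Synthetic",
                "x": 48.0,
                "y": 48.0,
            }
        )
        table = exploration_summary(fix, GEOM)
        row = table.iloc[0]
        assert row["category_entropy"] == pytest.approx(row["mean_image_entropy"], rel=1e-9)
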