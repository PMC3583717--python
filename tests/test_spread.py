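import numpy as np
import pytest

from gastroquant.spread import (
    CrossSection,
    DivisionEvent,
    compare_spread,
    fold_angle,
    g_factor,
    measured_spread,
    theoretical_spread,
)
from gastroquant.synth import SynthConfig, generate_lineage, render_cross_sections


def rasterized_extent(intervals, step=0.1):
    """Oracle: angular occupancy by rasterizing the circle at `step` degrees."""
    grid = np.zeros(int(round(360 / step)), dtype=bool)
    for a, b in intervals:
        i0, i1 = int(round(a / step)), int(round(b / step))
        grid[i0:i1] = True
    return grid.sum() * step


class TestMeasuredSpread:
    def test_two_lateral_halves_sum(self):
        sec = CrossSection(0.0, [("AB", 0.0, 90.0), ("AB", 270.0, 360.0)])
        series = measured_spread([sec], "AB")
        assert series.spread[0] == pytest.approx(50.0)

    def test_absent_tissue_warns_and_is_zero(self):
        sec = CrossSection(0.0, [("E", 10.0, 40.0)])
        with pytest.warns(UserWarning, match="absent"):
            series = measured_spread([sec], "AB")
        assert series.spread[0] == 0.0

    def test_overlapping_intervals_merged_with_warning(self):
        sec = CrossSection(0.0, [("AB", 0.0, 50.0), ("AB", 30.0, 80.0)])
        with pytest.warns(UserWarning, match="merged"):
            series = measured_spread([sec], "AB")
        assert series.spread[0] == pytest.approx(80.0 / 360.0 * 100.0)

    def test_matches_rasterization_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            edges = np.sort(rng.choice(np.arange(0, 3600), size=8, replace=False)) / 10.0
            intervals = [(edges[k], edges[k + 1]) for k in range(0, 8, 2)]
            sec = CrossSection(0.0, [("AB", a, b) for a, b in intervals])
            series = measured_spread([sec], "AB")
            oracle = rasterized_extent(intervals) / 360.0 * 100.0
            assert series.spread[0] == pytest.approx(oracle, abs=0.05)

    def test_rotation_of_angular_origin(self):
        base = [(10.0, 60.0), (200.0, 250.0)]
        for shift in (0.0, 37.0, 180.0):
            ivs = []
            for a, b in base:
                a2, b2 = (a + shift) % 360.0, (a + shift) % 360.0 + (b - a)
                if b2 <= 360:
                    ivs.append(("AB", a2, b2))
                else:
                    ivs.append(("AB", a2, 360.0))
                    ivs.append(("AB", 0.0, b2 - 360.0))
            series = measured_spread([CrossSection(0.0, ivs)], "AB")
            assert series.spread[0] == pytest.approx(100.0 / 360.0 * 100.0)

    def test_multi_embryo_mean_sd(self):
        secs = [
            CrossSection(0.0, [("AB", 0.0, 72.0)]),
            CrossSection(0.0, [("AB", 0.0, 108.0)]),
        ]
        series = measured_spread(secs, "AB")
        assert series.spread[0] == pytest.approx(25.0)
        assert series.sd[0] == pytest.approx(np.std([20.0, 30.0], ddof=1))


def stretch_oracle(theta_deg, n=2000):
    """Polygon oracle: stretch a unit-circle footprint x2 along the spindle and
    measure its circumferential (y) extent relative to the original."""
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, -s], [s, c]])
    A = R @ np.diag([2.0, 1.0]) @ R.T
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    circle = np.column_stack([np.cos(ang), np.sin(ang)])
    stretched = circle @ A.T
    return (stretched[:, 1].max() - stretched[:, 1].min()) / 2.0


class TestGFactor:
    def test_limits(self):
        assert g_factor(0.0) == pytest.approx(1.0)
        assert g_factor(90.0) == pytest.approx(2.0)

    def test_mean_angle_value(self):
        assert g_factor(36.0) == pytest.approx(1.427, abs=5e-4)

    @pytest.mark.parametrize("theta", [0.0, 10.0, 36.0, 55.0, 77.0, 90.0])
    def test_matches_polygon_stretch_oracle(self, theta):
        assert g_factor(theta) == pytest.approx(stretch_oracle(theta), rel=1e-5)

    def test_monotone_on_degree_grid(self):
        grid = np.arange(0.0, 91.0, 1.0)
        vals = np.array([g_factor(t) for t in grid])
        assert np.all(np.diff(vals) > 0)

    def test_angle_folding(self):
        assert fold_angle(-36.0) == pytest.approx(36.0)
        assert fold_angle(144.0) == pytest.approx(36.0)


class TestTheoreticalSpread:
    def test_no_divisions_constant(self):
        series = theoretical_spread(30.0, [], np.arange(5.0))
        np.testing.assert_allclose(series.spread, 30.0)

    def test_single_division_limits(self):
        times = np.array([0.0, 10.0])
        s90 = theoretical_spread(30.0, [DivisionEvent("AB", 5.0, 90.0)], times)
        assert s90.spread[-1] == pytest.approx(60.0)
        s0 = theoretical_spread(30.0, [DivisionEvent("AB", 5.0, 0.0)], times)
        assert s0.spread[-1] == pytest.approx(30.0)

    def test_capped_at_100(self):
        divs = [DivisionEvent("AB", float(t), 90.0) for t in (1, 2, 3)]
        series = theoretical_spread(40.0, divs, np.arange(5.0))
        assert series.spread[-1] == 100.0

    def test_round_uses_mean_g(self):
        divs = [DivisionEvent("a", 5.0, 0.0), DivisionEvent("b", 5.0, 90.0)]
        series = theoretical_spread(10.0, divs, np.array([0.0, 10.0]))
        assert series.spread[-1] == pytest.approx(10.0 * (1.0 + 2.0) / 2.0)

    def test_fixed_mean_angle_mode(self):
        divs = [DivisionEvent("a", 5.0, 10.0), DivisionEvent("b", 5.0, 80.0)]
        series = theoretical_spread(10.0, divs, np.array([10.0]), mean_angle=36.0)
        assert series.spread[0] == pytest.approx(10.0 * g_factor(36.0))


class TestCompareSpread:
    def test_identical_series_zero_rms(self):
        from gastroquant.spread import SpreadSeries

        t = np.arange(5.0)
        a = SpreadSeries(t, np.full(5, 40.0), np.zeros(5))
        _, resid, rms = compare_spread(a, a)
        assert rms == 0.0

    def test_constant_offset(self):
        from gastroquant.spread import SpreadSeries

        t = np.arange(5.0)
        a = SpreadSeries(t, np.full(5, 45.0), np.zeros(5))
        b = SpreadSeries(t, np.full(5, 40.0), np.zeros(5))
        _, resid, rms = compare_spread(a, b)
        assert rms == pytest.approx(5.0)
        np.testing.assert_allclose(resid, 5.0)

    def test_disjoint_ranges_rejected(self):
        from gastroquant.spread import SpreadSeries

        a = SpreadSeries(np.arange(5.0), np.full(5, 40.0), np.zeros(5))
        b = SpreadSeries(np.arange(10.0, 15.0), np.full(5, 40.0), np.zeros(5))
        with pytest.raises(ValueError, match="disjoint"):
            compare_spread(a, b)

    def test_generator_model_consistency(self):
        """Sections rendered from a generated lineage track the division model."""
        cfg = SynthConfig(seed=23)
        _, events = generate_lineage(cfg)
        times = np.arange(0.0, 721.0, 10.0)
        sections = render_cross_sections(events, cfg, times, initial_spread=30.0)
        meas = measured_spread(sections, "AB")
        theo = theoretical_spread(30.0, sorted(events, key=lambda e: e.time), times)
        _, _, rms = compare_spread(meas, theo)
        assert rms < 2.0
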