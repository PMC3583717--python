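import numpy as np
import pytest

from gastroquant.synth import SynthConfig, generate_lineage
from gastroquant.tracks import (
    CellTrack,
    combine_sisters,
    correlation_matrix,
    displacement_metrics,
    embryo_length,
    lr_correlation,
    midline_angle,
    smooth_path,
)


def track(name, z, x=None, parent=""):
    z = np.asarray(z, dtype=float)
    n = len(z)
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) if x is None else x
    pos[:, 2] = z
    return CellTrack(name, np.arange(n, dtype=float), pos, parent=parent)


class TestSmoothPath:
    def test_constant_path_unchanged(self):
        t = track("ABa", np.full(10, 2.0))
        sm = smooth_path(t, 5)
        np.testing.assert_allclose(sm.positions[:, 2], 2.0)
        np.testing.assert_array_equal(sm.times, t.times)

    def test_unit_impulse_spreads_to_fifths(self):
        z = np.zeros(11)
        z[5] = 1.0
        sm = smooth_path(track("ABa", z), 5)
        np.testing.assert_allclose(sm.positions[3:8, 2], 0.2)
        assert sm.positions[2, 2] == 0.0 and sm.positions[8, 2] == 0.0

    def test_matches_brute_force_windows(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=20)
        sm = smooth_path(track("ABa", z), 5)
        for i in range(20):
            lo, hi = max(0, i - 2), min(20, i + 3)
            assert sm.positions[i, 2] == pytest.approx(z[lo:hi].mean())

    def test_window_larger_than_track_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            smooth_path(track("ABa", np.zeros(3)), 5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_path(track("ABa", np.zeros(10)), 4)


class TestLrCorrelation:
    def test_self_correlation_is_one(self, rng):
        t = track("ABa", np.cumsum(rng.normal(size=30)))
        assert lr_correlation(t, t) == pytest.approx(1.0)

    def test_mirror_is_minus_one(self, rng):
        z = np.cumsum(rng.normal(size=30))
        assert lr_correlation(track("ABal", z), track("ABar", -z)) == pytest.approx(-1.0)

    def test_independent_walks_near_zero(self):
        rng = np.random.default_rng(9)
        a = track("ABa", np.cumsum(rng.normal(size=201)))
        b = track("ABp", np.cumsum(rng.normal(size=201)))
        assert abs(lr_correlation(a, b)) < 0.2

    def test_short_overlap_undefined(self):
        a = CellTrack("ABa", np.arange(2.0), np.zeros((2, 3)))
        b = CellTrack("ABp", np.arange(2.0), np.zeros((2, 3)))
        assert np.isnan(lr_correlation(a, b))

    def test_manual_increment_pearson_oracle(self, rng):
        za, zb = rng.normal(size=25), rng.normal(size=25)
        a, b = track("ABa", za), track("ABp", zb)
        da, db = np.diff(za), np.diff(zb)
        expected = np.corrcoef(da, db)[0, 1]
        assert lr_correlation(a, b) == pytest.approx(expected, rel=1e-12)

    def test_invariance_to_translation_and_positive_scaling(self, rng):
        za, zb = np.cumsum(rng.normal(size=30)), np.cumsum(rng.normal(size=30))
        r0 = lr_correlation(track("ABa", za), track("ABp", zb))
        r1 = lr_correlation(track("ABa", 3.0 * za + 10.0), track("ABp", 0.5 * zb - 4.0))
        assert r1 == pytest.approx(r0, rel=1e-12)


class TestCorrelationMatrix:
    def test_mirrored_and_duplicated_tracks(self, rng):
        z = np.cumsum(rng.normal(size=30))
        mat = correlation_matrix(
            [track("ABal", z), track("ABar", -z), track("ABpl", z)], clip=0.8
        )
        np.testing.assert_allclose(
            mat.values, [[1, -1, 1], [-1, 1, -1], [1, -1, 1]], atol=1e-12
        )

    def test_symmetric_unit_diagonal(self, rng):
        trks = [track(n, np.cumsum(rng.normal(size=20))) for n in ("ABal", "ABar", "ABpl", "ABpr")]
        mat = correlation_matrix(trks)
        np.testing.assert_allclose(np.diag(mat.values), 1.0)
        np.testing.assert_allclose(mat.values, mat.values.T)
        assert np.all(np.abs(mat.values) <= 1 + 1e-12)

    def test_clip_affects_display_only(self, rng):
        z = np.cumsum(rng.normal(size=30))
        mat = correlation_matrix([track("ABal", z), track("ABar", -z)], clip=0.8)
        assert mat.values[0, 1] == pytest.approx(-1.0)
        assert mat.clipped()[0, 1] == pytest.approx(-0.8)

    def test_bilateral_lineage_structure(self):
        """Within-side movements correlate; across sides they anti-correlate."""
        cfg = SynthConfig(seed=2, track_noise_sd=0.05)
        trks, _ = generate_lineage(cfg)
        terminal = [t for t in trks if len(t.name) == len("ABal") + 3]
        mat = correlation_matrix(terminal)
        left = [i for i, t in enumerate(terminal) if t.name.startswith(("ABal", "ABpl"))]
        right = [i for i, t in enumerate(terminal) if t.name.startswith(("ABar", "ABpr"))]
        within = [mat.values[i, j] for grp in (left, right) for i in grp for j in grp if i < j]
        across = [mat.values[i, j] for i in left for j in right]
        assert np.nanmean(within) > 0.3
        assert np.nanmean(across) < -0.3

    def test_combine_sisters_averages_paths(self, rng):
        z = np.cumsum(rng.normal(size=20))
        a, p = track("ABaa", z), track("ABap", z + 2.0)
        combined = combine_sisters([a, p])
        assert len(combined) == 1
        np.testing.assert_allclose(combined[0].positions[:, 2], z + 1.0)


class TestDisplacement:
    def test_static_track_zero(self):
        t = track("ABa", np.zeros(10), x=np.full(10, 3.0))
        assert displacement_metrics(t, (1, 0, 0), 50.0, 0.0, 9.0) == 0.0

    def test_five_micron_over_fifty(self):
        x = np.linspace(0.0, 5.0, 10)
        t = track("ABa", np.zeros(10), x=x)
        assert displacement_metrics(t, (1, 0, 0), 50.0, 0.0, 9.0) == pytest.approx(10.0)

    def test_scripted_anterior_move_recovered(self):
        cfg = SynthConfig(
            seed=4,
            track_noise_sd=0.0,
            u_step_sd=0.0,
            phi_step_sd=0.0,
            lr_coherence=0.0,
            scripted_anterior_move={"ABalaaa": 11.0},
        )
        trks, _ = generate_lineage(cfg)
        cell = next(t for t in trks if t.name == "ABalaaa")
        length = 2 * cfg.semi_axes[0]
        pct = displacement_metrics(cell, (1, 0, 0), length, cell.birth, cell.death)
        assert pct == pytest.approx(11.0, abs=0.1)

    def test_embryo_length_bounding_box(self):
        trks = [track("ABa", np.zeros(5), x=np.linspace(0, 30, 5)), track("ABp", np.zeros(5), x=np.linspace(-10, 5, 5))]
        assert embryo_length(trks) == pytest.approx(40.0)

    def test_zero_axis_rejected(self):
        t = track("ABa", np.zeros(10))
        with pytest.raises(ValueError, match="non-zero"):
            displacement_metrics(t, (0, 0, 0), 50.0, 0.0, 5.0)


class TestMidline:
    @staticmethod
    def pair_tracks(shear=0.0):
        left, right = [], []
        for name, x, z in (("ABal", 5.0, 8.0), ("ABpl", 15.0, 6.0), ("ABala", 25.0, 7.0)):
            n = name
            lt = CellTrack(n, np.arange(3.0), np.column_stack([np.full(3, x), np.zeros(3), np.full(3, z)]))
            rz = -z + shear * x
            rt = CellTrack(
                n.translate(str.maketrans("lr", "rl")),
                np.arange(3.0),
                np.column_stack([np.full(3, x), np.zeros(3), np.full(3, rz)]),
            )
            left.append(lt)
            right.append(rt)
        return left, right

    def test_perfect_mirror_gives_zero(self):
        left, right = self.pair_tracks()
        assert midline_angle(left, right, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_sheared_right_side_positive_angle(self):
        left, right = self.pair_tracks(shear=0.1)
        ang = midline_angle(left, right, 1.0)
        # midpoint z = shear*x/2 rises with anterior x: positive by convention
        assert ang == pytest.approx(np.degrees(np.arctan(0.05)), abs=1e-6)

    def test_unmatched_pair_listed(self):
        left, right = self.pair_tracks()
        right = right[:-1]
        with pytest.raises(ValueError, match="ABala"):
            midline_angle(left, right, 1.0)

    def test_scripted_symmetrisation_decreases_angle(self):
        cfg = SynthConfig(
            seed=6,
            track_noise_sd=0.0,
            u_step_sd=0.0,
            phi_step_sd=0.0,
            lr_coherence=0.0,
            midline_shear=6.0,
            division_times=(),
            track_duration=600.0,
        )
        trks, _ = generate_lineage(cfg)
        left = [t for t in trks if t.name in ("ABal", "ABpl")]
        right = [t for t in trks if t.name in ("ABar", "ABpr")]
        angles = [abs(midline_angle(left, right, t)) for t in np.arange(0.0, 601.0, 100.0)]
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(angles, angles[1:]))
        assert angles[-1] < 1.0


class TestSmoothingImprovesCoherence:
    def test_smoothing_raises_within_group_correlation(self):
        """Moving-average smoothing suppresses uncorrelated jitter, raising
        within-group correlation of coherently moving cells."""
        rng = np.random.default_rng(14)
        shared = np.cumsum(rng.normal(0, 1.0, 60))
        trks = [track(n, shared + rng.normal(0, 1.5, 60)) for n in ("ABal", "ABpl", "ABala")]
        raw = correlation_matrix(trks)
        smoothed = correlation_matrix([smooth_path(t, 5) for t in trks])
        iu = np.triu_indices(3, k=1)
        assert smoothed.values[iu].mean() > raw.values[iu].mean()
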