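import numpy as np
import pytest

from gastroquant.coupling import lag_scan, normalize_traces
from gastroquant.synth import (
    SynthConfig,
    generate_blebs,
    generate_cortex_movie,
    generate_coupled_traces,
    generate_lineage,
)


class TestConfig:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="foci_birth_rate"):
            SynthConfig(foci_birth_rate=-1.0)

    def test_bad_retraction_range_rejected(self):
        with pytest.raises(ValueError, match="low <= high"):
            SynthConfig(bleb_retraction_range=(60.0, 30.0))

    def test_small_image_rejected(self):
        with pytest.raises(ValueError, match=">= 16"):
            generate_cortex_movie(SynthConfig(image_shape=(8, 8)))


class TestCortexMovie:
    def test_no_sources_no_noise_gives_zero_movie(self):
        movie, truth = generate_cortex_movie(SynthConfig(foci_birth_rate=0.0, noise_sd=0.0))
        assert movie.data.max() == 0.0
        assert truth.empty

    def test_seeded_determinism_bit_exact(self):
        m1, t1 = generate_cortex_movie(SynthConfig(seed=9))
        m2, t2 = generate_cortex_movie(SynthConfig(seed=9))
        np.testing.assert_array_equal(m1.data, m2.data)
        assert t1.equals(t2)

    def test_focus_count_matches_poisson_stream_replay(self):
        cfg = SynthConfig(seed=1, foci_birth_rate=0.5, n_frames=100)
        _, truth = generate_cortex_movie(cfg)
        oracle = np.random.default_rng(1).poisson(0.5, 100).sum()
        assert truth.focus_id.nunique() == oracle

    def test_foci_flow_centripetally(self):
        cfg = SynthConfig(seed=4, noise_sd=0.0)
        _, truth = generate_cortex_movie(cfg)
        h, w = cfg.image_shape
        cy, cx = (h - 1) / 2, (w - 1) / 2
        for _, grp in truth.groupby("focus_id"):
            r = np.hypot(grp.x - cx, grp.y - cy).to_numpy()
            assert np.all(np.diff(r) <= 1e-9)


class TestCoupledTraces:
    def test_zero_delay_zero_noise_increments_proportional(self):
        cfg = SynthConfig(seed=2, noise_sd=0.0, coupling_delay=0.0, smoothing_sd=0.0)
        i, e = generate_coupled_traces(cfg)
        # position is an affine map of same-frame intensity, so increments align
        scale = np.ptp(e.tip_position) / np.ptp(i.values)
        np.testing.assert_allclose(np.diff(e.tip_position), scale * np.diff(i.values), atol=1e-9)

    def test_twenty_second_delay_is_ten_frame_shift(self):
        cfg = SynthConfig(seed=2, noise_sd=0.0, coupling_delay=20.0, smoothing_sd=0.0)
        i, e = generate_coupled_traces(cfg)
        scale = e.tip_position[-1] / i.values[-1]
        np.testing.assert_allclose(e.tip_position[10:], scale * i.values[:-10], rtol=1e-9)

    def test_extension_monotone_and_saturating(self):
        i, e = generate_coupled_traces(SynthConfig(seed=3, noise_sd=0.0))
        assert np.all(np.diff(e.tip_position) >= -1e-12)
        assert e.tip_position[-1] == pytest.approx(10.0)  # configured plateau

    def test_default_lag_recovered_by_brute_force_scan(self):
        i, e = generate_coupled_traces(SynthConfig(seed=42))
        ni, ne = normalize_traces(i, e)
        scan = lag_scan(ni, ne, max_lag=60)
        # brute force: refit every candidate shift independently on raw arrays
        best, best_r2 = None, -1.0
        for shift in range(0, 31):
            x = ni.values[: len(ni.values) - shift if shift else None]
            y = ne.tip_position[shift:]
            r = np.corrcoef(x, y)[0, 1]
            if r * r > best_r2:
                best, best_r2 = shift * 2.0, r * r
        assert scan.peak_lag == best
        assert scan.peak_r2 == pytest.approx(best_r2, rel=1e-9)
        assert abs(scan.peak_lag - 20.0) <= 4.0
        assert scan.r2_at(20.0) >= 0.9

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError, match="coupling_gain"):
            SynthConfig(coupling_gain=-1.0)

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValueError, match="3x"):
            generate_coupled_traces(SynthConfig(n_frames=25, coupling_delay=20.0))


class TestLineage:
    def test_zero_variance_angles_all_36(self):
        cfg = SynthConfig(seed=5, spindle_angle_sd=0.0)
        _, events = generate_lineage(cfg)
        assert events
        assert all(e.angle == pytest.approx(36.0) for e in events)

    def test_one_founder_three_rounds_binary_tree(self):
        cfg = SynthConfig(seed=5, founders=(("ABa", 0.0, 90.0),), division_times=(100.0, 200.0, 300.0))
        tracks, events = generate_lineage(cfg)
        assert len(events) == 7
        terminal = [t for t in tracks if len(t.name) == 3 + 3]
        assert len(terminal) == 8
        assert len(tracks) == 15

    def test_sample_mean_angle_near_36(self):
        cfg = SynthConfig(seed=7, spindle_angle_sd=10.0, division_times=(100.0, 200.0, 300.0, 400.0))
        _, events = generate_lineage(cfg)
        angles = np.array([e.angle for e in events])
        assert len(angles) == 60  # 4 founders over 4 synchronous rounds
        se = 10.0 / np.sqrt(len(angles))
        assert abs(angles.mean() - 36.0) < 3 * se

    def test_empty_founders_rejected(self):
        with pytest.raises(ValueError, match="founder"):
            generate_lineage(SynthConfig(founders=()))

    def test_determinism(self):
        t1, e1 = generate_lineage(SynthConfig(seed=12))
        t2, e2 = generate_lineage(SynthConfig(seed=12))
        assert [t.name for t in t1] == [t.name for t in t2]
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.positions, b.positions)
        assert [(d.parent, d.time, d.angle) for d in e1] == [(d.parent, d.time, d.angle) for d in e2]

    def test_lineage_names_follow_suffix_convention(self):
        tracks, _ = generate_lineage(SynthConfig(seed=1))
        for t in tracks:
            if t.parent:
                assert t.name[:-1] == t.parent
                assert t.name[-1] in "ap"


class TestBlebs:
    def test_zero_rate_empty(self):
        assert generate_blebs(SynthConfig(bleb_rate=0.0)) == []

    def test_noiseless_events_lie_on_exact_line(self):
        from gastroquant.morpho import bleb_regression

        events = generate_blebs(SynthConfig(seed=8, bleb_noise_sd=0.0, bleb_slope=0.02))
        fit = bleb_regression(events)
        assert fit.slope == pytest.approx(0.02, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_retraction_durations_within_configured_range(self):
        events = generate_blebs(SynthConfig(seed=8))
        assert events
        for e in events:
            assert 30.0 <= e.retraction - e.onset <= 60.0

    def test_determinism(self):
        e1 = generate_blebs(SynthConfig(seed=3))
        e2 = generate_blebs(SynthConfig(seed=3))
        assert [(a.onset, a.area, a.translocation) for a in e1] == [
            (a.onset, a.area, a.translocation) for a in e2
        ]
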