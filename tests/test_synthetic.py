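"""Tests of the synthetic walking-study generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chestgait import (SimulationConfig, simulate_activity_session,
                       simulate_study, simulate_walk_segment)
from chestgait.synthetic import pendulum_excursion


class TestWalkSegment:
    def test_standing_still_is_one_g_with_no_events(self):
        rec, truth = simulate_walk_segment(0.0, 1.0, 10.0, 1.0, 128.0, 0.0)
        assert np.allclose(rec.vertical, 1.0)
        assert truth.events.n_initial == 0
        assert truth.bouts == []

    def test_step_count_matches_duration_over_step_period(self):
        # 10 s at 1 s stride time -> 20 steps (2 per stride)
        _, truth = simulate_walk_segment(1.2, 1.0, 10.0, 1.0, 128.0, 0.0)
        assert truth.step_count == 20

    def test_closed_form_vertical_excursion(self):
        # sl = 0.6 m, l = 1 m  ->  h = 1 - sqrt(1 - 0.09)
        _, truth = simulate_walk_segment(1.2, 1.0, 10.0, 1.0, 128.0, 0.0)
        h = truth.params["h_m"]
        assert h == pytest.approx(1.0 - np.sqrt(1.0 - 0.09), rel=1e-12)
        # substituting back recovers the step length
        assert 2 * np.sqrt(2 * h - h * h) == pytest.approx(0.6, rel=1e-12)

    def test_infeasible_geometry_raises(self):
        # step length 1.1 m with l = 0.5 m exceeds 2l
        with pytest.raises(ValueError, match="infeasible"):
            simulate_walk_segment(2.2, 1.0, 10.0, 0.5, 128.0, 0.0)

    def test_duration_below_one_stride_raises(self):
        with pytest.raises(ValueError, match="stride"):
            simulate_walk_segment(1.2, 1.0, 0.5, 1.0, 128.0, 0.0)

    def test_double_integration_recovers_excursion(self):
        """Noise-free vertical channel double-integrates to ~h per step."""
        from scipy.integrate import cumulative_trapezoid
        from scipy.signal import detrend

        rec, truth = simulate_walk_segment(1.3, 1.05, 20.0, 1.0, 128.0, 0.0)
        a = (rec.vertical - 1.0) * 9.80665
        fs = rec.fs
        idx = np.round(truth.events.initial_contacts * fs).astype(int)
        hs = []
        for i in range(len(idx) - 1):
            seg = a[idx[i]:idx[i + 1] + 1]
            seg = seg - seg[:-1].mean()
            v = cumulative_trapezoid(seg, dx=1 / fs, initial=0)
            v = v - v[:-1].mean()
            z = detrend(cumulative_trapezoid(v, dx=1 / fs, initial=0))
            hs.append(z.max() - z.min())
        assert np.mean(hs) == pytest.approx(truth.params["h_m"], rel=0.02)

    def test_events_lie_strictly_inside_bout(self):
        _, truth = simulate_walk_segment(1.2, 1.0, 12.0, 1.0, 128.0, 0.0)
        assert truth.contains_events()

    @given(speed=st.floats(0.6, 1.8), stride_time=st.floats(0.8, 1.4))
    @settings(max_examples=25, deadline=None)
    def test_ground_truth_closure(self, speed, stride_time):
        """stride length = speed * stride time, exactly, for every stride."""
        _, truth = simulate_walk_segment(speed, stride_time, 8.0, 1.0, 128.0, 0.0)
        st_tab = truth.strides
        assert np.all(st_tab["stride_length_m"]
                      == st_tab["gait_speed_mps"] * st_tab["stride_time_s"])
        assert np.all(np.diff(truth.events.initial_contacts) > 0)


class TestActivitySession:
    def test_walk_fraction_one_gives_single_spanning_bout(self):
        _, truth = simulate_activity_session(60.0, 1.0, 1.2, 1.0, 1.0, 128.0, 0.0)
        assert truth.bouts == [(0.0, 60.0)]

    def test_walk_fraction_zero_gives_no_bouts(self):
        rec, truth = simulate_activity_session(60.0, 0.0, 1.2, 1.0, 1.0, 128.0, 0.0)
        assert truth.bouts == []
        assert truth.step_count == 0
        # no periodic locomotor component: band fraction of a quiet session
        from chestgait.pipeline import window_features
        feats = window_features(rec.vertical[:384], rec.fs)
        assert feats[2] < 0.5  # autocorrelation peak stays low

    def test_total_walking_time_tracks_walk_fraction(self):
        """Monte-Carlo: realized walking time ~ walk_fraction * duration."""
        totals = []
        for seed in range(100):
            _, truth = simulate_activity_session(
                1200.0, 0.5, 1.25, 1.05, 1.0, 32.0, 0.0,
                mean_bout_s=30.0, seed=seed)
            totals.append(sum(b - a for a, b in truth.bouts))
        assert np.mean(totals) == pytest.approx(600.0, rel=0.05)

    def test_events_contained_in_bouts(self):
        _, truth = simulate_activity_session(200.0, 0.5, 1.2, 1.0, 1.0, 128.0,
                                             0.01, seed=9)
        assert truth.contains_events()
        assert truth.step_count == truth.events.n_initial


class TestStudy:
    def test_recording_count(self, small_bundle):
        cfg = small_bundle.config
        expected = cfg.n_subjects * cfg.n_visits * len(cfg.tasks) * 2
        assert len(small_bundle.recordings) == expected

    def test_same_seed_reproduces_bundle(self):
        cfg = dict(n_subjects=2, walk_task_duration_s=10.0,
                   inlab_activity_duration_s=30.0,
                   outside_activity_duration_s=30.0, seed=5)
        b1 = simulate_study(SimulationConfig(**cfg))
        b2 = simulate_study(SimulationConfig(**cfg))
        for key in b1.recordings:
            assert np.array_equal(b1.recordings[key].accel,
                                  b2.recordings[key].accel)
        pd.testing.assert_frame_equal(b1.metadata, b2.metadata)

    def test_zero_noise_equal_heights_gives_identical_channels(self):
        cfg = SimulationConfig(
            n_subjects=2, tasks=("walk_normal",), walk_task_duration_s=10.0,
            chest_bias_mps=0.0, noise_sd_g=0.0, orientation_jitter_deg=0.0,
            height_fraction={"chest": 0.53, "lumbar": 0.53}, seed=1)
        b = simulate_study(cfg)
        for (subj, visit, task, loc), rec in b.recordings.items():
            if loc == "chest":
                other = b.recordings[(subj, visit, task, "lumbar")]
                assert np.array_equal(rec.accel, other.accel)

    def test_ground_truth_shared_across_locations(self, small_bundle):
        # one truth per subject/visit/task, not per location
        cfg = small_bundle.config
        assert len(small_bundle.truths) == (cfg.n_subjects * cfg.n_visits
                                            * len(cfg.tasks))

    def test_visit_parameters_correlate_at_configured_rho(self):
        """Subject speeds across visits follow the bivariate-normal coupling."""
        cfg = SimulationConfig(n_subjects=400, n_visits=2, tasks=("walk_normal",),
                               walk_task_duration_s=4.0, visit_retest_rho=0.8,
                               stride_time_sd_s=0.0, seed=3)
        b = simulate_study(cfg)
        meta = b.metadata.drop_duplicates(["subject", "visit"])
        wide = meta.pivot(index="subject", columns="visit",
                          values="true_speed_mps")
        r = np.corrcoef(wide[1], wide[2])[0, 1]
        assert r == pytest.approx(0.8, abs=0.06)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(visit_retest_rho=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(speed_multipliers=(1.1, 1.3))
        with pytest.raises(ValueError):
            SimulationConfig(speed_sd_mps=-0.1)


def test_pendulum_excursion_closed_form():
    h = pendulum_excursion(0.6, 1.0)
    assert h == pytest.approx(0.04606, abs=5e-6)
    with pytest.raises(ValueError):
        pendulum_excursion(2.1, 1.0)
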