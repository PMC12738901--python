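import numpy as np
import pandas as pd
import pytest

from phototox.synthetic import (
    SyntheticScenario,
    expected_transition_fraction,
    occupancy_peak_offset,
    render_video,
    sample_events,
    write_scenario_outputs,
)


class TestSampleEvents:
    def test_same_seed_gives_identical_schedules(self):
        scenario = SyntheticScenario(n_cells=40, seed=11)
        pd.testing.assert_frame_equal(sample_events(scenario), sample_events(scenario))

    def test_all_cells_arrest_at_probability_one(self):
        scenario = SyntheticScenario(n_cells=30, arrest_prob=1.0, seed=1)
        schedule = sample_events(scenario)
        assert schedule["arrested"].all()
        assert schedule["t_division"].isna().all()

    def test_extra_delay_shifts_mean_rounding_time(self):
        base = SyntheticScenario(n_cells=400, field_shape=(1024, 1024), seed=21)
        delayed = SyntheticScenario(
            n_cells=400, field_shape=(1024, 1024), extra_delay=20.0, seed=21
        )
        shift = sample_events(delayed)["t_round_start"].mean() - sample_events(base)[
            "t_round_start"
        ].mean()
        tolerance = 2 * base.rounding_time_sd / np.sqrt(base.n_cells)
        assert abs(shift - 20.0) <= 2 * tolerance

    def test_division_follows_rounding_by_the_configured_duration(self):
        scenario = SyntheticScenario(n_cells=20, seed=3)
        schedule = sample_events(scenario)
        durations = schedule["t_division"] - schedule["t_round_start"]
        np.testing.assert_allclose(durations, scenario.rounding_duration)

    def test_event_times_truncated_at_zero(self):
        scenario = SyntheticScenario(
            n_cells=200, field_shape=(704, 704), rounding_time_mode=35.0, seed=5
        )
        assert (sample_events(scenario)["t_round_start"] >= 0).all()


class TestAnchoring:
    def test_occupancy_peak_offset_positive_and_below_total_window(self):
        scenario = SyntheticScenario()
        offset = occupancy_peak_offset(scenario)
        assert 0 < offset < scenario.rounding_duration + scenario.daughter_round_duration

    def test_expected_transition_fraction_near_half_at_the_mode(self):
        # with the default phase structure the median division time sits at
        # the configured occupancy peak, so ~half the cells have divided by it
        fraction = expected_transition_fraction(SyntheticScenario(), by_time=50.0)
        assert fraction == pytest.approx(0.5, abs=0.05)

    def test_arrest_scales_expected_transitions(self):
        base = expected_transition_fraction(SyntheticScenario(), 50.0)
        arrested = expected_transition_fraction(
            SyntheticScenario(arrest_prob=0.3), 50.0
        )
        assert arrested == pytest.approx(0.7 * base, rel=1e-9)


class TestRenderVideo:
    def test_deterministic_under_fixed_seed(self):
        scenario = SyntheticScenario(n_cells=9, field_shape=(192, 192), duration=40.0, seed=8)
        video_a, truth_a = render_video(scenario)
        video_b, truth_b = render_video(scenario)
        np.testing.assert_array_equal(video_a.frames, video_b.frames)
        np.testing.assert_array_equal(truth_a.masks.masks, truth_b.masks.masks)

    def test_nuclei_count_equals_cell_count(self, small_render, small_scenario):
        _, truth = small_render
        assert truth.nuclei_count == small_scenario.n_cells

    def test_masks_consistent_with_schedule(self, small_render, small_scenario):
        _, truth = small_render
        schedule = truth.schedule
        times = small_scenario.times
        for k in (0, len(times) // 2, len(times) - 1):
            t = times[k]
            expected_round = (
                (schedule["t_round_start"] <= t)
                & (schedule["arrested"] | (t < schedule["t_division"]))
            ).sum()
            expected_daughters = 2 * (
                (~schedule["arrested"])
                & (schedule["t_division"] <= t)
                & (t < schedule["t_daughters_end"])
            ).sum()
            n_instances = truth.masks.n_instances(k)
            assert n_instances == expected_round + expected_daughters

    def test_overfull_field_rejected(self):
        with pytest.raises(ValueError, match="cannot place"):
            render_video(SyntheticScenario(n_cells=10, field_shape=(128, 128)))

    def test_static_noise_free_scene_has_zero_activity(self):
        from phototox.activity import activity_trace
        from phototox.preprocess import preprocess_for_activity

        scenario = SyntheticScenario(
            n_cells=9, field_shape=(192, 192), duration=40.0, noise_sd=0.0,
            drift_factor=1.0, rounding_time_mode=500.0, rounding_time_sd=5.0, seed=3,
        )
        video, _ = render_video(scenario)
        trace = activity_trace(preprocess_for_activity(video))
        assert trace.activity.max() <= 1e-12

    def test_mask_only_rendering_matches_full_rendering(self):
        scenario = SyntheticScenario(n_cells=9, field_shape=(192, 192), duration=40.0, seed=8)
        _, truth_full = render_video(scenario)
        video, truth_masks = render_video(scenario, with_video=False)
        assert video is None
        np.testing.assert_array_equal(truth_full.masks.masks, truth_masks.masks.masks)


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"arrest_prob": 1.5},
            {"daughter_diameter": 25.0},
            {"mother_diameter": -1.0},
            {"rounding_time_law": "weibull"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticScenario(**kwargs)

    def test_gamma_law_supported(self):
        scenario = SyntheticScenario(
            n_cells=50, field_shape=(384, 384), rounding_time_law="gamma", seed=2
        )
        schedule = sample_events(scenario)
        assert (schedule["t_round_start"] >= 0).all()
        # right-skewed law: mean above mode-anchored location
        assert schedule["t_round_start"].mean() > 0


class TestScenarioOutputs:
    def test_written_artifacts_load_back(self, tmp_path):
        scenario = SyntheticScenario(n_cells=9, field_shape=(192, 192), duration=40.0, seed=8)
        paths = write_scenario_outputs(scenario, tmp_path / "out")
        from phototox.io_formats import read_label_masks, read_table, read_video

        video = read_video(paths["video"], scenario.pixel_size, scenario.frame_interval)
        masks = read_label_masks(paths["masks"], scenario.pixel_size)
        events = read_table(paths["events"])
        assert video.n_frames == masks.n_frames == scenario.n_frames
        assert len(events) == scenario.n_cells
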