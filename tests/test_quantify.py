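import numpy as np
import pandas as pd
import pytest

from phototox.detection import count_nuclei, masks_to_detections
from phototox.quantify import (
    RoundingCurve,
    classify_event,
    events_from_table,
    events_to_table,
    peak_time,
    population_curves,
    rounding_curve,
    transition_fraction,
)
from phototox.synthetic import SyntheticScenario, render_video


def _detections(frame_counts, interval=4.0):
    """DetectionTable stub with the given number of detections per frame."""
    rows = []
    for frame, count in enumerate(frame_counts):
        for i in range(count):
            rows.append(
                {
                    "frame_index": frame,
                    "time_min": frame * interval,
                    "instance_label": i + 1,
                    "area_px": 100,
                    "area_um2": 100.0,
                    "diameter_um": 11.3,
                    "centroid_row": 0.0,
                    "centroid_col": 0.0,
                    "size_class": "daughter",
                }
            )
    return pd.DataFrame(rows)


class TestRoundingCurve:
    def test_fraction_is_detections_over_nuclei(self):
        curve = rounding_curve(_detections([10]), count_nuclei(100), 4.0)
        assert curve.fraction[0] == pytest.approx(0.10)

    def test_frames_without_detections_are_zero(self):
        curve = rounding_curve(_detections([3, 0, 2]), count_nuclei(10), 4.0, n_frames=4)
        np.testing.assert_allclose(curve.fraction, [0.3, 0.0, 0.2, 0.0])

    def test_zero_nuclei_rejected(self):
        with pytest.raises(ValueError):
            rounding_curve(_detections([1]), count_nuclei(0), 4.0)

    def test_over_unity_fraction_warned_not_fatal(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            curve = rounding_curve(_detections([5]), count_nuclei(2), 4.0)
        assert curve.fraction[0] == pytest.approx(2.5)

    def test_curve_integral_matches_ground_truth_occupancy(self):
        scenario = SyntheticScenario(n_cells=50, field_shape=(384, 384), seed=9)
        _, truth = render_video(scenario, with_video=False)
        detections = masks_to_detections(truth.masks, scenario.frame_interval)
        curve = rounding_curve(
            detections, count_nuclei(truth.nuclei_count), scenario.frame_interval,
            n_frames=scenario.n_frames,
        )
        # each cell is detectable for its mother window plus two daughters
        # over the respreading window, so the per-cell expected number of
        # round detections is (duration + 2 * daughter_duration) / interval
        expected_per_cell = (
            scenario.rounding_duration + 2 * scenario.daughter_round_duration
        ) / scenario.frame_interval
        assert curve.fraction.sum() == pytest.approx(expected_per_cell, rel=0.1)


class TestPeakTime:
    def test_earliest_maximum(self):
        curve = RoundingCurve(times=[0.0, 4.0, 8.0], fraction=[0.1, 0.5, 0.3], n_nuclei=10)
        assert peak_time(curve) == 4.0

    def test_tie_breaks_to_earliest(self):
        curve = RoundingCurve(times=[4.0, 8.0], fraction=[0.5, 0.5], n_nuclei=10)
        assert peak_time(curve) == 4.0

    def test_all_zero_curve_reports_no_peak(self):
        curve = RoundingCurve(times=[0.0, 4.0], fraction=[0.0, 0.0], n_nuclei=10)
        assert peak_time(curve) is None

    def test_floor_suppresses_imperceptible_peaks(self):
        curve = RoundingCurve(times=[0.0, 4.0], fraction=[0.002, 0.005], n_nuclei=1000)
        assert peak_time(curve) is None
        assert peak_time(curve, no_peak_floor=0.001) == 4.0

    def test_matches_brute_force_scan(self, rng):
        for _ in range(10):
            fraction = rng.random(30)
            curve = RoundingCurve(
                times=np.arange(30) * 4.0, fraction=fraction, n_nuclei=100
            )
            best = min(
                (i for i in range(30) if fraction[i] == fraction.max()),
            )
            assert peak_time(curve) == best * 4.0


class TestPopulationCurves:
    def test_all_mothers_means_zero_daughters(self):
        det = _detections([4, 4])
        det["size_class"] = "mother"
        det["diameter_um"] = 20.0
        curves = population_curves(det)
        assert (curves["n_daughter"] == 0).all()
        assert (curves["n_mother"] == 4).all()

    def test_empty_table_gives_empty_curves(self):
        assert len(population_curves(_detections([]))) == 0

    def test_daughter_count_crosses_mother_count_at_division(self):
        # tight synchrony: every mother divides within a one-frame window
        scenario = SyntheticScenario(
            n_cells=30, field_shape=(512, 512), rounding_time_sd=1.0, seed=4
        )
        _, truth = render_video(scenario, with_video=False)
        detections = masks_to_detections(truth.masks, scenario.frame_interval)
        curves = population_curves(detections).set_index("time_min")
        median_division = truth.schedule["t_division"].median()
        crossing = None
        times = curves.index.to_numpy()
        for t in times:
            if curves.loc[t, "n_daughter"] > curves.loc[t, "n_mother"]:
                crossing = t
                break
        assert crossing is not None
        assert abs(crossing - median_division) <= scenario.frame_interval


class TestEvents:
    def test_division_yields_duration(self):
        event = classify_event("e1", 40.0, 70.0, 480.0)
        assert event.outcome == "divided"
        assert event.division_duration == pytest.approx(30.0)

    def test_no_daughters_by_end_is_arrested(self):
        event = classify_event("e2", 100.0, None, 480.0)
        assert event.outcome == "arrested" and event.t_division is None

    def test_division_after_window_end_is_arrested(self):
        assert classify_event("e3", 100.0, 500.0, 480.0).outcome == "arrested"

    def test_division_before_rounding_rejected(self):
        with pytest.raises(ValueError):
            classify_event("e4", 50.0, 40.0, 480.0)

    def test_transition_fraction_counts_divided_by_deadline(self):
        events = [
            classify_event(str(i), 10.0, 40.0 if i < 5 else 100.0, 480.0)
            for i in range(10)
        ]
        assert transition_fraction(events, by_time=50.0) == pytest.approx(0.5)
        assert transition_fraction(events, by_time=5.0) == 0.0

    def test_transition_fraction_needs_events(self):
        with pytest.raises(ValueError):
            transition_fraction([], 50.0)

    def test_event_table_round_trip(self):
        events = [
            classify_event("a", 10.0, 42.0, 480.0),
            classify_event("b", 30.0, None, 480.0),
        ]
        table = events_to_table(events, 480.0)
        back = events_from_table(table)
        assert [e.outcome for e in back] == ["divided", "arrested"]
        assert back[0].division_duration == pytest.approx(32.0)
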