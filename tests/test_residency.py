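import numpy as np
import pandas as pd
import pytest

from sharktrace.residency import (
    CorrectedTrack,
    correct_tagging_bias,
    daily_presence_matrix,
    monitoring_duration,
    residency_index,
    summarize_ri,
    track_summaries,
)

from _oracles import bias_correction_oracle
from conftest import EPOCH, det_frame


def _tags(tag_ids, tag_date="2012-01-01", station="A"):
    return pd.DataFrame(
        {
            "tag_id": tag_ids,
            "tag_date": [pd.Timestamp(tag_date).date()] * len(tag_ids),
            "tag_station": station,
            "sex": "F",
            "island_id": "Cocos",
            "battery_days": 1350,
        }
    )


def _visits(rows, tag="T1"):
    """rows: (station, start_h, end_h) -> visit frame."""
    return pd.DataFrame(
        {
            "tag_id": tag,
            "station_id": [r[0] for r in rows],
            "start": [EPOCH + pd.Timedelta(hours=r[1]) for r in rows],
            "end": [EPOCH + pd.Timedelta(hours=r[2]) for r in rows],
            "duration_s": [(r[2] - r[1]) * 3600.0 for r in rows],
        }
    )


class TestMonitoringDuration:
    def test_same_day_tag_and_last_detection_is_one_day(self):
        det = det_frame([("T1", "A", 12 * 3600.0)])
        assert monitoring_duration("2012-01-01", det, utc_offset_hours=0) == 1

    def test_inclusive_of_both_endpoints(self):
        det = det_frame([("T1", "A", 0.0), ("T1", "A", 4 * 86400.0)])
        assert monitoring_duration("2012-01-01", det, utc_offset_hours=0) == 5

    def test_no_detections_is_an_error(self):
        with pytest.raises(ValueError, match="no detections"):
            monitoring_duration("2012-01-01", det_frame([]).iloc[0:0], 0)

    def test_cohort_durations_match_recount_from_raw_dates(self, small_sim):
        summ = track_summaries(
            small_sim.detections, small_sim.tags, -6.0,
            stations=small_sim.stations, island_id="Cocos",
        )
        offset = pd.to_timedelta(-6.0, unit="h")
        for row in summ.dropna(subset=["monitoring_days"]).itertuples():
            d = small_sim.detections[small_sim.detections["tag_id"] == row.tag_id]
            dates = (d["timestamp"] + offset).dt.date
            assert row.monitoring_days == (dates.max() - row.tag_date).days + 1
            assert row.n_detected_days == dates.nunique()


class TestResidencyIndex:
    def test_detected_every_day_gives_one(self):
        det = det_frame([("T1", "A", d * 86400.0 + 3600) for d in range(5)])
        summ = track_summaries(det, _tags(["T1"]), utc_offset_hours=0)
        assert summ["residency_index"].iloc[0] == 1.0

    def test_three_of_five_days_gives_point_six(self):
        det = det_frame([("T1", "A", d * 86400.0 + 3600) for d in (0, 1, 4)])
        summ = track_summaries(det, _tags(["T1"]), utc_offset_hours=0)
        assert summ["residency_index"].iloc[0] == pytest.approx(0.6)

    def test_invariant_to_detection_multiplicity_within_day(self):
        base = [("T1", "A", d * 86400.0 + 3600) for d in (0, 2, 3)]
        doubled = base + [("T1", "A", d * 86400.0 + 7200) for d in (0, 2, 3)]
        s1 = track_summaries(det_frame(base), _tags(["T1"]), 0)
        s2 = track_summaries(det_frame(doubled), _tags(["T1"]), 0)
        assert s1["residency_index"].iloc[0] == s2["residency_index"].iloc[0]

    def test_mean_ri_matches_bernoulli_presence_simulation_oracle(self, rng):
        """Daily presence Bernoulli(0.5) over 400 days: implementation RI vs
        the detection-conditional expectation recomputed directly."""
        p, days, reps = 0.5, 400, 300
        oracle_vals, est_vals = [], []
        for _ in range(reps):
            present = rng.random(days) < p
            if not present.any():
                continue
            idx = np.flatnonzero(present)
            oracle_vals.append(len(idx) / (idx[-1] + 1))
            det = det_frame([("T1", "A", int(d) * 86400.0 + 43200) for d in idx])
            summ = track_summaries(det, _tags(["T1"]), 0)
            est_vals.append(summ["residency_index"].iloc[0])
        assert np.mean(est_vals) == pytest.approx(np.mean(oracle_vals), abs=1e-12)
        assert abs(np.mean(est_vals) - np.mean(oracle_vals)) < 0.02


class TestPresenceMatrix:
    def test_single_detection_single_one(self):
        det = det_frame([("T1", "A", 3600.0)])
        mat = daily_presence_matrix(det, _tags(["T1"]), 0)
        assert mat.to_numpy().sum() == 1

    def test_row_sums_equal_detected_days(self, small_sim):
        mat = daily_presence_matrix(small_sim.detections, small_sim.tags, -6.0)
        summ = track_summaries(small_sim.detections, small_sim.tags, -6.0)
        merged = summ.set_index("tag_id")["n_detected_days"].fillna(0)
        # matrix pools all islands, as do these summaries (no island filter)
        assert (mat.sum(axis=1) == merged).all()

    def test_season_alignment_pools_years(self):
        det = det_frame(
            [("T1", "A", 0.0), ("T1", "A", 365 * 86400.0)]  # Jan 1 2012 and Dec 31 2012
        )
        mat = daily_presence_matrix(det, _tags(["T1"]), 0, season_start=(7, 1))
        # Jan 1 is day 184 of a July-anchored season in both years
        assert mat.loc["T1", 184] == 1


class TestTaggingBiasCorrection:
    def test_rule_a_first_visit_elsewhere(self):
        v = _visits([("A", 0, 1), ("B", 2, 3), ("A", 4, 5)])
        track = correct_tagging_bias(v, "A")
        assert track.correction_rule_applied == "other_site_first"
        assert track.analysis_start == EPOCH + pd.Timedelta(hours=2)
        assert list(track.visits_retained["station_id"]) == ["B", "A"]

    def test_rule_b_never_fires_when_gaps_short(self):
        v = _visits([("A", 0, 1), ("A", 5, 6), ("A", 12, 13)])
        track = correct_tagging_bias(v, "A", absence_h=24.0)
        assert track.correction_rule_applied == "none_applicable"
        assert track.visits_retained.empty

    def test_rule_b_fires_after_24h_absence(self):
        v = _visits([("A", 0, 1), ("A", 30, 31), ("A", 40, 41)])
        track = correct_tagging_bias(v, "A", absence_h=24.0)
        assert track.correction_rule_applied == "absent_24h"
        assert track.analysis_start == EPOCH + pd.Timedelta(hours=30)
        assert len(track.visits_retained) == 2

    @pytest.mark.parametrize("n_visits", [1, 3, 8, 20])
    def test_randomized_sequences_match_brute_force_oracle(self, rng, n_visits):
        for _ in range(50):
            starts = np.sort(rng.uniform(0, 200, size=n_visits))
            rows = []
            t = 0.0
            for s in starts:
                t = max(t, s)
                end = t + rng.uniform(0.1, 5.0)
                rows.append((rng.choice(["A", "B", "C"]), t, end))
                t = end
            v = _visits(rows)
            track = correct_tagging_bias(v, "A", absence_h=24.0)
            want_start, want_rule = bias_correction_oracle(
                [{"station": r[0], "start": r[1], "end": r[2]} for r in rows], "A", 24.0
            )
            assert track.correction_rule_applied == want_rule
            if want_start is None:
                assert track.visits_retained.empty
            else:
                assert track.analysis_start == EPOCH + pd.Timedelta(hours=want_start)
                kept = [r for r in rows if r[1] >= want_start]
                assert len(track.visits_retained) == len(kept)

    def test_correction_is_idempotent(self, rng):
        rows = [("A", 0, 1), ("A", 30, 31), ("B", 35, 36)]
        track = correct_tagging_bias(_visits(rows), "A")
        again = correct_tagging_bias(track)
        assert again is track
        assert isinstance(again, CorrectedTrack)


class TestCohortSummary:
    def test_single_tag_sd_reported_as_zero_with_n_one(self):
        summ = pd.DataFrame({"tag_id": ["T1"], "monitoring_days": [5], "residency_index": [1.0]})
        out = summarize_ri(summ)
        assert out == {"mean_ri": 1.0, "sd_ri": 0.0, "n": 1}

    def test_two_tags_closed_form_mean_and_sample_sd(self):
        summ = pd.DataFrame(
            {"tag_id": ["T1", "T2"], "monitoring_days": [10, 10], "residency_index": [0.2, 0.6]}
        )
        out = summarize_ri(summ)
        assert out["mean_ri"] == pytest.approx(0.4)
        assert out["sd_ri"] == pytest.approx(0.28284271247, abs=1e-9)

    def test_min_monitoring_filter_and_empty_sentinel(self):
        summ = pd.DataFrame(
            {"tag_id": ["T1", "T2"], "monitoring_days": [10, 200], "residency_index": [0.2, 0.6]}
        )
        out = summarize_ri(summ, min_monitoring_days=120)
        assert out["n"] == 1 and out["mean_ri"] == 0.6
        empty = summarize_ri(summ, min_monitoring_days=10_000)
        assert empty["n"] == 0 and np.isnan(empty["mean_ri"])
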