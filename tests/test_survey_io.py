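"""Segmentation, sighting assignment, sea-state classification, effort ledger."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from wfdisp import survey_io
from wfdisp.survey_io import (
    SegmentTable,
    assign_sightings,
    classify_conditions,
    effort_ledger,
    segment_transects,
)

from conftest import track_from_utm

X0, Y0 = 450_000.0, 6_000_000.0  # arbitrary in-band UTM anchor


def straight_track(length_m, step_m=150.0, speed=5.0):
    xs = np.arange(0.0, length_m + step_m / 2, step_m)
    pts = np.column_stack([X0 + xs, np.full_like(xs, Y0)])
    return track_from_utm(pts, dt=step_m / speed)


class TestSegmentation:
    def test_exact_multiple_gives_equal_segments(self):
        segs = segment_transects(straight_track(1800.0), 600.0)
        assert len(segs) == 3
        # midpoints at chainages 300, 900, 1500 along +x
        np.testing.assert_allclose(segs["x"] - X0, [300, 900, 1500], atol=0.01)
        np.testing.assert_allclose(segs["effort_m"], 600.0, atol=0.01)

    def test_partial_terminal_segment_keeps_true_effort(self):
        segs = segment_transects(straight_track(2000.0, step_m=100.0), 600.0)
        np.testing.assert_allclose(segs["effort_m"], [600, 600, 600, 200], atol=0.01)

    def test_single_segment_when_length_equals_transect(self):
        segs = segment_transects(straight_track(1800.0), 1800.0)
        assert len(segs) == 1
        assert segs["effort_m"].iloc[0] == pytest.approx(1800.0, abs=0.01)

    def test_dogleg_midpoints_match_dense_polyline_walk(self):
        # polyline with a 90-degree bend; oracle = 1 m resampling point walk
        verts = np.array(
            [[0, 0], [400, 300], [800, 300], [800, 1100], [1500, 1100]], float
        )
        verts += [X0, Y0]
        track = track_from_utm(verts)
        segs = segment_transects(track, 600.0)

        # oracle: walk the polyline at 1 m resolution
        dense = []
        for a, b in zip(verts[:-1], verts[1:]):
            n = int(np.ceil(np.hypot(*(b - a))))
            frac = np.arange(n) / n
            dense.append(a + frac[:, None] * (b - a))
        dense.append(verts[-1:])
        dense = np.vstack(dense)
        chain = np.concatenate(
            [[0], np.cumsum(np.hypot(*np.diff(dense, axis=0).T))]
        )
        total = chain[-1]
        n_seg = int(np.ceil(total / 600.0))
        for k in range(n_seg):
            mid = min((k * 600 + min((k + 1) * 600, total)) / 2, total)
            i = np.searchsorted(chain, mid)
            assert np.hypot(
                segs["x"].iloc[k] - dense[i, 0], segs["y"].iloc[k] - dense[i, 1]
            ) < 2.0

    def test_partition_sums_to_polyline_length(self):
        rng = np.random.default_rng(0)
        steps = rng.normal([120, 30], 20, size=(40, 2))
        verts = np.vstack([[0, 0], np.cumsum(steps, axis=0)]) + [X0, Y0]
        track = track_from_utm(verts)
        segs = segment_transects(track, 500.0)
        chain = np.hypot(*np.diff(verts, axis=0).T).sum()
        assert abs(segs["effort_m"].sum() - chain) < 1.0

    def test_too_few_points_rejected(self):
        track = straight_track(1800.0).iloc[:1]
        with pytest.raises(ValueError, match="fewer than 2"):
            segment_transects(track, 600.0)


def _sightings(rows):
    recs = []
    if not rows:
        return pd.DataFrame(
            columns=["survey_id", "timestamp_iso8601", "species", "count", "behavior", "t"]
        )
    for t, species, count, behavior in rows:
        recs.append(
            {
                "survey_id": "S01",
                "timestamp_iso8601": pd.Timestamp(t, unit="s", tz="UTC").isoformat(),
                "species": species,
                "count": count,
                "behavior": behavior,
                "t": float(t),
            }
        )
    return pd.DataFrame(recs)


class TestAssignment:
    def setup_method(self):
        self.track = straight_track(1800.0)  # 30 s fixes, 5 m/s -> 360 s span
        self.segs = segment_transects(self.track, 600.0)

    def test_no_sightings_gives_zero_counts(self):
        table = assign_sightings(
            _sightings([]), self.track, self.segs, "guillemot", nominal_length=600.0
        )
        assert (table.rows["count"] == 0).all()

    def test_counts_summed_and_in_flight_dropped(self):
        sights = _sightings(
            [
                (10, "guillemot", 3, "on_sea"),
                (50, "guillemot", 2, "on_sea"),
                (60, "guillemot", 7, "in_flight"),
            ]
        )
        table = assign_sightings(
            sights, self.track, self.segs, "guillemot", nominal_length=600.0
        )
        assert table.rows["count"].tolist() == [5, 0, 0]

    def test_time_interpolated_position(self):
        # fixes 150 m apart every 30 s; a sighting midway between two fixes
        # sits 75 m along, verified against manual interpolation
        t_mid = 105.0  # between fixes at t=90 (450 m) and t=120 (600 m)
        sights = _sightings([(t_mid, "guillemot", 1, "on_sea")])
        table = assign_sightings(
            sights, self.track, self.segs, "guillemot", nominal_length=600.0
        )
        # chainage 525 m -> still segment 0? no: 525 < 600 -> segment 0
        assert table.rows["count"].tolist() == [1, 0, 0]
        # at exactly the boundary time the sighting moves to the next segment
        sights = _sightings([(120.0, "guillemot", 1, "on_sea")])
        table = assign_sightings(
            sights, self.track, self.segs, "guillemot", nominal_length=600.0
        )
        assert table.rows["count"].tolist() == [0, 1, 0]

    def test_out_of_span_sighting_excluded_and_counted(self):
        sights = _sightings([(9_999.0, "guillemot", 4, "on_sea")])
        table = assign_sightings(
            sights, self.track, self.segs, "guillemot", nominal_length=600.0
        )
        assert table.rows["count"].sum() == 0
        assert table.n_excluded == 1

    def test_assignment_independent_of_input_order(self):
        rows = [
            (10, "guillemot", 3, "on_sea"),
            (200, "guillemot", 2, "on_sea"),
            (310, "guillemot", 5, "on_sea"),
        ]
        t1 = assign_sightings(
            _sightings(rows), self.track, self.segs, "guillemot", nominal_length=600.0
        )
        t2 = assign_sightings(
            _sightings(rows[::-1]), self.track, self.segs, "guillemot",
            nominal_length=600.0,
        )
        assert t1.rows["count"].tolist() == t2.rows["count"].tolist()


class TestConditions:
    def _seastate(self, rows):
        return pd.DataFrame(
            [
                {
                    "survey_id": "S01",
                    "transect_id": "T01",
                    "timestamp_iso8601": pd.Timestamp(
                        t, unit="s", tz="UTC"
                    ).isoformat(),
                    "beaufort": b,
                    "t": float(t),
                }
                for t, b in rows
            ]
        )

    @pytest.mark.parametrize("beaufort,expected", [(0, "good"), (2, "good"), (3, "poor")])
    def test_beaufort_thresholds(self, beaufort, expected):
        track = straight_track(1800.0)
        segs = segment_transects(track, 600.0)
        out = classify_conditions(self._seastate([(0, beaufort)]), segs)
        assert (out["condition"] == expected).all()

    def test_most_recent_record_carried_forward(self):
        track = straight_track(6000.0)  # 1200 s span
        segs = segment_transects(track, 600.0)
        out = classify_conditions(self._seastate([(0, 1), (900, 4)]), segs)
        # segment midpoints at 60,180,...; t_mid = chainage/5 m/s
        poor = out[out["t_mid"] >= 900]
        good = out[out["t_mid"] < 900]
        assert (poor["condition"] == "poor").all()
        assert (good["condition"] == "good").all()

    def test_missing_leading_record_falls_back_to_first(self):
        track = straight_track(1800.0)
        segs = segment_transects(track, 600.0)
        out = classify_conditions(self._seastate([(350, 5)]), segs)
        assert (out["condition"] == "poor").all()


class TestEffortLedger:
    def _table(self):
        rows = []
        for survey, rate in [("S01", 1.0), ("S02", 2.0)]:
            for k in range(10):
                rows.append(
                    {
                        "segment_id": f"{survey}-T01-{k:03d}",
                        "survey_id": survey,
                        "transect_id": "T01",
                        "phase": "preconstruction",
                        "x": X0 + 500 + 1000.0 * k,
                        "y": Y0,
                        "effort_m": 1000.0,
                        "condition": "good",
                        "count": int(rate),
                    }
                )
        return SegmentTable("harbor_porpoise", 1000.0, pd.DataFrame(rows))

    def test_two_survey_rate_mean_and_se(self):
        ledger = effort_ledger(self._table())
        pre = ledger[ledger["phase"] == "preconstruction"].iloc[0]
        assert pre["rate_per_km"] == pytest.approx(1.5)
        assert pre["rate_se"] == pytest.approx(0.5)

    def test_phase_rows_sum_to_total(self, tiny_table):
        ledger = effort_ledger(tiny_table)
        phases = ledger[ledger["phase"] != "total"]
        total = ledger[ledger["phase"] == "total"].iloc[0]
        assert phases["effort_km"].sum() == pytest.approx(total["effort_km"])
        assert phases["observations"].sum() == total["observations"]

    def test_footprint_effort_subsets_total(self):
        table = self._table()
        fp = box(X0, Y0 - 100, X0 + 3000, Y0 + 100)
        ledger = effort_ledger(table, fp)
        pre = ledger[ledger["phase"] == "preconstruction"].iloc[0]
        assert pre["footprint_km"] == pytest.approx(6.0)  # 3 cells x 2 surveys


class TestCountConservation:
    def test_total_individuals_conserved(self, tiny_files, tiny_table):
        out, cfg, truth = tiny_files
        sights = survey_io.read_sightings(out / "sightings.csv")
        on_sea = sights[
            (sights["species"] == "guillemot") & (sights["behavior"] == "on_sea")
        ]
        # the simulator places every sighting inside its transect's time span,
        # so the segment table must conserve the filtered individual total
        assert tiny_table.n_excluded == 0
        assert tiny_table.rows["count"].sum() == on_sea["count"].sum()


class TestReaders:
    def test_invalid_beaufort_rejected(self, tmp_path):
        p = tmp_path / "ss.csv"
        p.write_text(
            "survey_id,transect_id,timestamp_iso8601,beaufort\n"
            "S01,T01,2020-01-01T00:00:00Z,7\n"
        )
        with pytest.raises(ValueError, match="Beaufort"):
            survey_io.read_seastate(p)

    def test_zero_count_sighting_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "survey_id,timestamp_iso8601,species,count,behavior\n"
            "S01,2020-01-01T00:00:00Z,guillemot,0,on_sea\n"
        )
        with pytest.raises(ValueError, match="count"):
            survey_io.read_sightings(p)

    def test_not_applicable_behavior_only_for_porpoise(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text(
            "survey_id,timestamp_iso8601,species,count,behavior\n"
            "S01,2020-01-01T00:00:00Z,guillemot,2,not_applicable\n"
        )
        with pytest.raises(ValueError, match="not_applicable"):
            survey_io.read_sightings(p)

    def test_unknown_phase_rejected(self, tmp_path):
        p = tmp_path / "p.csv"
        p.write_text("survey_id,phase\nS01,decommissioning\n")
        with pytest.raises(ValueError, match="phase"):
            survey_io.read_phases(p)
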