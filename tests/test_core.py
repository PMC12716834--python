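import datetime as dt
import io

import pytest

from lifespace.core import (DEFAULT_TAXONOMY, LOCAL_TZ, DiaryDay, GpsFix,
                            ParticipantDiary, StayNode, Taxonomy, TravelMode,
                            Trip, TripLeg, ValidationError, cohort_percentage,
                            diary_from_json, diary_to_json, parse_fixes,
                            validate_day)

from conftest import T0, make_fix, make_stop


class TestTypes:
    def test_taxonomy_has_exactly_14_unique_codes(self):
        assert DEFAULT_TAXONOMY.size == 14
        assert len(set(DEFAULT_TAXONOMY.codes)) == 14
        with pytest.raises(ValidationError):
            Taxonomy(codes=("home", "work"))
        with pytest.raises(ValidationError):
            Taxonomy(codes=("home",) * 14)

    @pytest.mark.parametrize("code,active", [
        ("walk", True), ("bicycle", True), ("bus", False), ("train", False),
        ("car_driver", False), ("taxi", False)])
    def test_active_modes_are_walk_and_bicycle(self, code, active):
        assert TravelMode(code).active is active

    @pytest.mark.parametrize("kw", [
        dict(lat=95.0, lon=103.8), dict(lat=1.3, lon=190.0),
        dict(lat=1.3, lon=103.8, accuracy_m=-1.0)])
    def test_fix_invariants_rejected_at_construction(self, kw):
        with pytest.raises(ValidationError):
            GpsFix(participant_id="p", t=T0, **kw)

    def test_stay_requires_positive_dwell(self):
        with pytest.raises(ValidationError):
            make_stop(100, 100)
        assert make_stop(0, 120).dwell_s == 120

    def test_trip_needs_legs_in_order(self):
        a, b = make_stop(0, 600), make_stop(2000, 3000)
        leg1 = TripLeg(start_t=T0 + dt.timedelta(seconds=600),
                       end_t=T0 + dt.timedelta(seconds=1200), mode="walk")
        leg0 = TripLeg(start_t=T0, end_t=T0 + dt.timedelta(seconds=500), mode="walk")
        with pytest.raises(ValidationError):
            Trip(origin=a, destination=b, legs=())
        with pytest.raises(ValidationError):
            Trip(origin=a, destination=b, legs=(leg1, leg0))

    def test_diary_requires_14_consecutive_days(self):
        days = tuple(DiaryDay(date=dt.date(2025, 3, 3) + dt.timedelta(days=i))
                     for i in range(13))
        with pytest.raises(ValidationError):
            ParticipantDiary(participant_id="p", days=days)
        gap = days + (DiaryDay(date=dt.date(2025, 3, 20)),)
        with pytest.raises(ValidationError):
            ParticipantDiary(participant_id="p", days=gap)


class TestParseFixes:
    HEADER = "id,timestamp,lat,lon\n"

    def test_well_formed_rows_kept_chronological(self):
        csv = self.HEADER + "\n".join(
            f"p1,2025-03-03T08:0{i}:00+08:00,1.35,103.85" for i in (2, 0, 1))
        res = parse_fixes(io.StringIO(csv))
        ts = [f.t for f in res.fixes["p1"]]
        assert ts == sorted(ts) and len(ts) == 3
        assert res.n_dropped == 0

    def test_out_of_bounds_and_bad_timestamp_rows_dropped(self):
        csv = (self.HEADER
               + "p1,2025-03-03T08:00:00+08:00,95.0,103.85\n"
               + "p1,not-a-time,1.35,103.85\n"
               + "p1,2025-03-03T08:01:00+08:00,1.35,103.85\n")
        res = parse_fixes(io.StringIO(csv))
        assert res.n_dropped == 2
        assert len(res.fixes["p1"]) == 1

    def test_duplicate_timestamps_collapse_last_wins(self):
        csv = (self.HEADER
               + "p1,2025-03-03T08:00:00+08:00,1.35,103.85\n"
               + "p1,2025-03-03T08:00:00+08:00,1.36,103.86\n")
        res = parse_fixes(io.StringIO(csv))
        assert len(res.fixes["p1"]) == 1
        assert res.fixes["p1"][0].lat == 1.36

    def test_missing_required_column_is_a_format_error(self):
        with pytest.raises(ValidationError, match="lon"):
            parse_fixes(io.StringIO("id,timestamp,lat\np1,2025-03-03T08:00:00,1.3\n"))


def _empty_diary(pid="p1"):
    days = tuple(
        validate_day(DiaryDay(date=dt.date(2025, 3, 3) + dt.timedelta(days=i)))
        for i in range(14))
    return ParticipantDiary(participant_id=pid, days=days)


class TestDiaryRoundtrip:
    def test_empty_14_day_diary_roundtrips(self):
        diary = _empty_diary()
        assert diary_from_json(diary_to_json(diary)) == diary

    def test_diary_with_three_leg_trip_preserves_leg_order(self):
        origin = make_stop(0, 600, node_type="home", is_home=True)
        dest = make_stop(3000, 4000, node_type="shopping")
        legs = tuple(
            TripLeg(start_t=T0 + dt.timedelta(seconds=600 + 800 * i),
                    end_t=T0 + dt.timedelta(seconds=600 + 800 * i + 700),
                    mode=m, linear_m=500.0, path_m=520.0)
            for i, m in enumerate(["walk", "bus", "walk"]))
        trip = Trip(origin=origin, destination=dest, legs=legs)
        day = DiaryDay(date=dt.date(2025, 3, 3), stops=(origin, dest), trips=(trip,))
        days = (day,) + tuple(
            DiaryDay(date=dt.date(2025, 3, 3) + dt.timedelta(days=i), valid=False,
                     invalid_reason="no_data") for i in range(1, 14))
        diary = ParticipantDiary(participant_id="p1", days=days)
        back = diary_from_json(diary_to_json(diary))
        assert back == diary
        assert [l.mode for l in back.days[0].trips[0].legs] == ["walk", "bus", "walk"]

    def test_truncated_json_raises_validation_error(self):
        text = diary_to_json(_empty_diary())
        with pytest.raises(ValidationError):
            diary_from_json(text[: len(text) // 2])


class TestValidateDay:
    def test_in_bounds_day_is_valid(self):
        day = DiaryDay(date=dt.date(2025, 3, 3), fixes=(make_fix(0, 1.35, 103.85),))
        out = validate_day(day)
        assert out.valid and out.invalid_reason == "none"

    def test_fix_outside_bounds_marks_out_of_country(self):
        day = DiaryDay(date=dt.date(2025, 3, 3),
                       fixes=(make_fix(0, 1.35, 103.85), make_fix(60, 3.1, 101.5)))
        assert validate_day(day).invalid_reason == "out_of_country"

    def test_zero_fixes_marks_no_data(self):
        assert validate_day(DiaryDay(date=dt.date(2025, 3, 3))).invalid_reason == "no_data"

    def test_declared_flag_wins_over_no_data(self):
        out = validate_day(DiaryDay(date=dt.date(2025, 3, 3)),
                           declared_flags={"declared_invalid"})
        assert out.invalid_reason == "declared_invalid"

    def test_idempotent(self):
        day = DiaryDay(date=dt.date(2025, 3, 3), fixes=(make_fix(0, 3.1, 101.5),))
        once = validate_day(day)
        assert validate_day(once) == once


def test_cohort_percentage_matches_reported_rounding():
    assert cohort_percentage(13, 1131, 1) == 1.1
    assert cohort_percentage(1062, 1118, 0) == 95
    with pytest.raises(ValidationError):
        cohort_percentage(1, 0)


def test_stops_export_as_geojson_feature_collection():
    import json as _json
    from lifespace.core import stops_to_geojson
    gj = _json.loads(stops_to_geojson([make_stop(0, 600, node_type="dining"),
                                       make_stop(700, 1400, node_type="home",
                                                 is_home=True)]))
    assert gj["type"] == "FeatureCollection"
    assert len(gj["features"]) == 2
    lon, lat = gj["features"][0]["geometry"]["coordinates"]
    assert (lat, lon) == (1.35, 103.85)
    assert gj["features"][1]["properties"]["is_home"] is True
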