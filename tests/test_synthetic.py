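import collections
import datetime as dt
import math

import numpy as np
import pytest

from lifespace.core import LOCAL_TZ
from lifespace.geometry import geodesic_m, hull_area_km2, radius_of_gyration_m
from lifespace.home import vertical_trips
from lifespace.pipeline import (ModeHeuristicConfig, StopDetectionConfig,
                                detect_stops, segment_trips)
from lifespace.synthetic import (ScenarioConfig, generate_cohort,
                                 generate_diary, render_barometer,
                                 render_fixes, signatures_for)


class TestGenerateDiary:
    def test_same_seed_reproduces_identical_ground_truth(self):
        cfg = ScenarioConfig(seed=7, days=14)
        a, b = generate_diary(cfg), generate_diary(cfg)
        assert a.true_metrics == b.true_metrics
        assert [(s.t0, s.t1, s.place_name) for s in a.stays] == \
               [(s.t0, s.t1, s.place_name) for s in b.stays]

    def test_zero_visit_intensity_gives_home_only_diary(self):
        cfg = ScenarioConfig(seed=1, days=5, visit_intensity={})
        gt = generate_diary(cfg)
        assert gt.true_metrics["n_trips"] == 0
        assert gt.activity_stays == []
        assert len(gt.home_stays) == 1  # one uninterrupted home stay

    def test_every_overnight_instant_is_at_home(self):
        cfg = ScenarioConfig(seed=5, days=14)
        gt = generate_diary(cfg)
        for d in range(cfg.days):
            instant = dt.datetime.combine(
                cfg.start_date + dt.timedelta(days=d), dt.time(3), tzinfo=LOCAL_TZ)
            assert any(s.t0 <= instant < s.t1 for s in gt.home_stays)

    def test_timeline_is_internally_consistent(self):
        gt = generate_diary(ScenarioConfig(seed=9, days=14))
        stays = sorted(gt.stays, key=lambda s: s.t0)
        for a, b in zip(stays, stays[1:]):
            assert a.t1 <= b.t0
        for trip in gt.trips:
            for a, b in zip(trip.legs, trip.legs[1:]):
                assert a.t1 <= b.t0

    def test_quota_mix_exact_for_divisible_n(self):
        cfg = ScenarioConfig(seed=3, n_participants=10, days=1)
        cohort = generate_cohort(cfg)
        frailty = collections.Counter(g.strata["frailty"] for g in cohort)
        housing = collections.Counter(g.strata["housing"] for g in cohort)
        age = collections.Counter(g.strata["age_bracket"] for g in cohort)
        assert frailty == {"prefrail_frail": 3, "robust": 7}
        assert housing == {"private": 2, "public": 8}
        assert age == {"50-62": 4, "63+": 6}


class TestRenderFixes:
    def test_noiseless_fixes_lie_on_schedule(self):
        cfg = ScenarioConfig(seed=2, days=2, gps_noise_sigma_m=1e-9,
                             indoor_dropout_prob=0.0)
        gt = generate_diary(cfg)
        fixes = render_fixes(gt, cfg)
        # every fix during a stay is at the stay point
        for stay in gt.stays:
            for f in fixes:
                if stay.t0 <= f.t < stay.t1:
                    assert geodesic_m(f.lat, f.lon, stay.lat, stay.lon) < 0.01

    def test_full_indoor_dropout_removes_stay_fixes(self):
        cfg = ScenarioConfig(seed=2, days=2, indoor_dropout_prob=1.0)
        gt = generate_diary(cfg)
        fixes = render_fixes(gt, cfg)
        for stay in gt.stays:
            if stay.indoor:
                assert not [f for f in fixes if stay.t0 <= f.t < stay.t1]

    def test_mean_absolute_error_matches_half_normal(self):
        # |error| per axis ~ half-normal; radial MAE = sigma * sqrt(pi/2)
        cfg = ScenarioConfig(seed=6, days=3, indoor_dropout_prob=0.0,
                             visit_intensity={})
        gt = generate_diary(cfg)
        fixes = render_fixes(gt, cfg)
        home = gt.home
        errs = [geodesic_m(f.lat, f.lon, home[0], home[1]) for f in fixes]
        expected = cfg.gps_noise_sigma_m * math.sqrt(math.pi / 2)
        assert np.mean(errs) == pytest.approx(expected, rel=0.05)

    def test_rendering_is_deterministic(self):
        cfg = ScenarioConfig(seed=8, days=2)
        gt = generate_diary(cfg)
        a = render_fixes(gt, cfg)
        b = render_fixes(generate_diary(cfg), cfg)
        assert [(f.t, f.lat, f.lon) for f in a] == [(f.t, f.lat, f.lon) for f in b]


class TestRenderBarometer:
    def test_home_entry_pressure_drop_matches_floor_height(self):
        cfg = ScenarioConfig(seed=21, days=3)
        gt = generate_diary(cfg)
        assert gt.floor > 0
        baro = render_barometer(gt, cfg)
        res = vertical_trips(baro, render_fixes(gt, cfg), gt.home)
        ups = [e.delta_hpa for e in res.events if e.floors_delta > 0]
        expected = -gt.floor * 3.0 / 8.43
        for dp in ups:
            assert dp == pytest.approx(expected, abs=0.1)

    def test_paired_entry_exit_events_cancel(self):
        cfg = ScenarioConfig(seed=21, days=5)
        gt = generate_diary(cfg)
        baro = render_barometer(gt, cfg)
        res = vertical_trips(baro, render_fixes(gt, cfg), gt.home)
        assert sum(e.floors_delta for e in res.events) == 0


class TestEndToEndRecovery:
    """Full pipeline on rendered streams recovers the schedule's metrics."""

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_counts_exact_and_geometry_within_10_percent(self, seed):
        cfg = ScenarioConfig(seed=seed, days=14)
        gt = generate_diary(cfg)
        fixes = render_fixes(gt, cfg)
        sigs = signatures_for(gt, cfg)
        stops = detect_stops(fixes, StopDetectionConfig(), sigs)
        trips = segment_trips(fixes, stops, ModeHeuristicConfig(), signatures=sigs)
        tm = gt.true_metrics

        mode_cfg = ModeHeuristicConfig()
        acts = [s for s in stops
                if s.dwell_s >= mode_cfg.transfer_max_dwell_s and not s.is_home]
        assert len(trips) == tm["n_trips"]
        assert sum(len(t.legs) for t in trips) == tm["n_legs"]
        assert len(acts) == tm["n_activity_stops"]
        assert len({s.node_type for s in acts}) == tm["node_diversity"]

        pts = [(s.centroid_lat, s.centroid_lon) for s in acts]
        rg = radius_of_gyration_m(pts)
        hull = hull_area_km2(pts + [gt.home]).area_km2
        assert rg == pytest.approx(tm["rg_m"], rel=0.10)
        assert hull == pytest.approx(tm["convex_hull_km2"], rel=0.10)

    def test_walk_dominates_within_two_km_of_home(self):
        """In a walkable-city scenario every sub-2-km trip is walked, so walk
        is the modal mode in the innermost distance band."""
        from lifespace.core import StayNode
        from lifespace.trips import mode_share_by_band, modal_mode_by_band
        cfg = ScenarioConfig(seed=14, days=14)
        gt = generate_diary(cfg)
        fixes = render_fixes(gt, cfg)
        sigs = signatures_for(gt, cfg)
        stops = detect_stops(fixes, StopDetectionConfig(), sigs)
        trips = segment_trips(fixes, stops, ModeHeuristicConfig(), signatures=sigs)
        home = StayNode(node_id="home", centroid_lat=gt.home[0],
                        centroid_lon=gt.home[1],
                        arrive_t=trips[0].start_t - dt.timedelta(hours=1),
                        depart_t=trips[0].start_t - dt.timedelta(minutes=1),
                        node_type="home", is_home=True)
        shares = mode_share_by_band(trips, home)
        assert modal_mode_by_band(shares)["0-2km"] == "walk"
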