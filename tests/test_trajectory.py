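"""Trajectory integration: stepping, stop rules, fans, stepping-stone chaining."""

import numpy as np
import pytest

import windborne as wb
from windborne.flight import local_clock_hours
from conftest import dusk_release

EQ_KM_PER_DEG = 6371.0 * np.pi / 180.0


def euler_oracle(field, release, duration_h, step_s=1.0, airspeed=3.0):
    """Independent explicit-Euler integration at a 1 s step."""
    t, lon, lat = release.time, release.lon, release.lat
    n = int(duration_h * 3600 / step_s)
    for _ in range(n):
        s = field.sample(t, lon, lat, release.altitude_m)
        u, v = wb.ground_velocity(s.u, s.v, airspeed)
        lat_new = lat + v * step_s / (6371000.0 * np.pi / 180.0) / 1.0
        lon += u * step_s / (6371000.0 * np.pi / 180.0) / np.cos(np.radians(lat))
        lat = lat_new
        t = t + np.timedelta64(int(step_s), "s")
    return lon, lat


class TestAdvance:
    def test_uniform_eastward_step_matches_closed_form(self, uniform_field):
        # (10 + 3) m/s for 300 s at the equator: 3900 m ~ 0.035072 degrees
        t0 = np.datetime64("2021-01-10T06:00:00")
        _, lon, lat = wb.advance(t0, 142.0, 0.0, 1000.0, uniform_field,
                                 wb.FlightParams(), "forward")
        assert lat == pytest.approx(0.0, abs=1e-12)
        assert lon - 142.0 == pytest.approx(3900.0 / (EQ_KM_PER_DEG * 1000), rel=1e-6)

    def test_backward_step_inverts_forward_in_constant_flow(self, uniform_field):
        t0 = np.datetime64("2021-01-10T06:00:00")
        t1, lon1, lat1 = wb.advance(t0, 142.0, -1.0, 1000.0, uniform_field,
                                    wb.FlightParams(), "forward")
        t2, lon2, lat2 = wb.advance(t1, lon1, lat1, 1000.0, uniform_field,
                                    wb.FlightParams(), "backward")
        assert t2 == t0
        assert lon2 == pytest.approx(142.0, abs=1e-6)
        assert lat2 == pytest.approx(-1.0, abs=1e-6)

    def test_high_latitude_step_scales_with_cos_lat(self):
        fld = wb.make_uniform_field(10.0, 0.0, 25.0, 0.0, extent=(0.0, 10.0, -1.0, 61.0))
        t0 = np.datetime64("2021-01-10T06:00:00")
        _, lon_eq, _ = wb.advance(t0, 5.0, 0.0, 1000.0, fld, wb.FlightParams(), "forward")
        _, lon_60, _ = wb.advance(t0, 5.0, 60.0, 1000.0, fld, wb.FlightParams(), "forward")
        assert (lon_eq - 5.0) / (lon_60 - 5.0) == pytest.approx(0.5, rel=1e-9)

    def test_rk2_matches_euler_oracle_on_smooth_flow(self, smooth_field):
        rel = wb.ReleaseSpec(144.0, -9.0, np.datetime64("2021-01-10T12:00:00"),
                             1000.0, "forward")
        traj = wb.integrate_fixed(rel, smooth_field, wb.FlightParams(step_s=300), 3.0)
        lon_o, lat_o = euler_oracle(smooth_field, rel, 3.0)
        err_km = wb.haversine_km(traj.endpoint.lon, traj.endpoint.lat, lon_o, lat_o)
        assert err_km < 0.5


class TestRunLeg:
    def test_all_land_leg_lands_at_dawn(self, uniform_field, land_mask):
        traj = wb.run_leg(dusk_release(142.0, 0.0), uniform_field, land_mask)
        assert traj.termination_reason == "dawn_landfall"
        assert traj.flight_duration_h == pytest.approx(10.0)

    def test_all_sea_leg_caps_at_exactly_36_h(self):
        fld = wb.make_uniform_field(3.0, 0.0, 25.0, 0.0,
                                    extent=(140.0, 152.0, -2.0, 2.0), duration_h=60.0)
        mask = wb.LandMask.all_sea(fld.lats, fld.lons)
        traj = wb.run_leg(dusk_release(141.0, 0.0), fld, mask)
        assert traj.termination_reason == "oversea_cap"
        assert traj.flight_duration_h == pytest.approx(36.0, abs=1e-9)

    def test_cold_release_is_zero_step(self):
        fld = wb.make_uniform_field(10.0, 0.0, 10.0, 0.0)
        mask = wb.LandMask.all_land(fld.lats, fld.lons)
        traj = wb.run_leg(dusk_release(142.0, -10.0), fld, mask)
        assert traj.termination_reason == "cold"
        assert len(traj.points) == 1 and traj.flight_duration_h == 0.0

    def test_release_outside_time_span_rejected(self, uniform_field, land_mask):
        rel = wb.ReleaseSpec(142.0, 0.0, np.datetime64("2030-01-01T00:00:00"),
                             1000.0, "forward")
        with pytest.raises(ValueError, match="span"):
            wb.run_leg(rel, uniform_field, land_mask)

    def test_constant_flow_displacement_closed_form(self, uniform_field, land_mask):
        traj = wb.run_leg(dusk_release(142.0, 0.0), uniform_field, land_mask)
        dist = wb.haversine_km(142.0, 0.0, traj.endpoint.lon, traj.endpoint.lat)
        assert dist == pytest.approx(13.0 * 3.6 * 10.0, rel=1e-3)  # 468 km

    def test_duration_consistent_with_point_count(self, uniform_field, land_mask):
        params = wb.FlightParams(step_s=600)
        traj = wb.run_leg(dusk_release(142.0, 0.0, params=params), uniform_field,
                          land_mask, params)
        assert traj.flight_duration_h == pytest.approx(
            (len(traj.points) - 1) * 600 / 3600.0)

    def test_cold_layer_blocks_high_launches(self):
        fld = wb.make_layered_field({500.0: (4.0, 0.0), 1500.0: (12.0, 0.0),
                                     2250.0: (12.0, 0.0)}, cold_above=1800.0,
                                    extent=(140.0, 152.0, -12.0, -8.0))
        mask = wb.LandMask.all_land(fld.lats, fld.lons)
        for alt in (2000.0, 2250.0):
            traj = wb.run_leg(dusk_release(142.0, -10.0, alt=alt), fld, mask)
            assert traj.termination_reason == "cold"
        ok = wb.run_leg(dusk_release(142.0, -10.0, alt=1500.0), fld, mask)
        assert ok.termination_reason == "dawn_landfall"

    def test_no_inflight_point_below_gate(self):
        fld = wb.make_smooth_field(seed=11, duration_h=48.0)
        mask = wb.LandMask.all_sea(fld.lats, fld.lons)
        params = wb.FlightParams()
        traj = wb.run_leg(dusk_release(145.0, -9.0, params=params), fld, mask, params)
        for p in traj.points[:-1]:
            assert p.temperature >= params.t_min


class TestFans:
    def test_default_fan_has_80_candidates(self, monsoon_one_leg):
        field, truth, mask = monsoon_one_leg
        fan = wb.run_backward_fan(*truth.expected_arrival_site,
                                  truth.expected_arrival_night, field, mask)
        assert len(fan) == 80
        assert all(t.direction == "backward" for t in fan)

    def test_restricted_altitudes_shrink_fan(self, monsoon_one_leg):
        field, truth, mask = monsoon_one_leg
        params = wb.FlightParams(altitudes_m=(500.0,))
        fan = wb.run_backward_fan(*truth.expected_arrival_site,
                                  truth.expected_arrival_night, field, mask, params)
        assert len(fan) == 10

    def test_some_candidate_reaches_truth_source(self, monsoon_one_leg):
        field, truth, mask = monsoon_one_leg
        fan = wb.run_backward_fan(*truth.expected_arrival_site,
                                  truth.expected_arrival_night, field, mask)
        dists = [wb.haversine_km(*truth.source_centroid, t.endpoint.lon, t.endpoint.lat)
                 for t in fan]
        assert min(dists) < 50.0


class TestMultiLeg:
    def test_one_leg_scenario_yields_only_single_leg_valid_paths(self, monsoon_one_leg):
        field, truth, mask = monsoon_one_leg
        paths = wb.run_multileg_backward(*truth.expected_arrival_site,
                                         truth.expected_arrival_night, field, mask)
        report = wb.filter_and_count(paths, mask)
        valid = [p for p in paths if p.valid]
        assert valid and all(len(p.legs) == 1 for p in valid)
        assert report.legs[1].count >= 1

    def test_max_legs_one_never_chains(self, monsoon_two_leg):
        field, truth, mask = monsoon_two_leg
        params = wb.FlightParams(max_legs=1)
        paths = wb.run_multileg_backward(*truth.expected_arrival_site,
                                         truth.expected_arrival_night, field, mask,
                                         params)
        assert all(len(p.legs) == 1 for p in paths)

    def test_two_leg_scenario_recovers_source(self, monsoon_two_leg_paths):
        paths, truth, mask = monsoon_two_leg_paths
        two_leg_valid = [p for p in paths if p.valid and len(p.legs) == 2]
        assert two_leg_valid
        best = min(wb.haversine_km(*truth.source_centroid,
                                   p.final_endpoint.lon, p.final_endpoint.lat)
                   for p in two_leg_valid)
        assert best < 50.0

    def test_no_path_exceeds_leg_cap(self, monsoon_two_leg_paths):
        paths, _, _ = monsoon_two_leg_paths
        assert max(len(p.legs) for p in paths) <= 2

    def test_no_leg_exceeds_oversea_cap(self, monsoon_two_leg_paths):
        paths, _, _ = monsoon_two_leg_paths
        assert all(leg.flight_duration_h <= 36.0 + 1e-9
                   for p in paths for leg in p.legs)

    def test_stopover_chain_is_spatially_consistent(self, monsoon_two_leg_paths):
        paths, _, _ = monsoon_two_leg_paths
        for p in paths:
            if len(p.legs) == 2:
                stop = p.stopovers[0]
                # leg-2 launches from (a representative of) leg-1's endpoint cell
                d = wb.haversine_km(stop.lon, stop.lat,
                                    p.legs[1].release.lon, p.legs[1].release.lat)
                assert d < 30.0


class TestInversionAndConvergence:
    def test_forward_backward_inversion_on_smooth_field(self, smooth_field):
        rng = np.random.default_rng(123)
        params = wb.FlightParams(step_s=60)
        for _ in range(20):
            lon = rng.uniform(142.5, 146.5)
            lat = rng.uniform(-10.5, -7.5)
            alt = rng.uniform(600.0, 2200.0)
            hours = rng.uniform(1.0, 5.0)
            t0 = (np.datetime64("2021-01-10T06:00:00")
                  + np.timedelta64(int(rng.uniform(0, 20 * 3600)), "s"))
            fwd = wb.integrate_fixed(wb.ReleaseSpec(lon, lat, t0, alt, "forward"),
                                     smooth_field, params, hours)
            end = fwd.endpoint
            back = wb.integrate_fixed(
                wb.ReleaseSpec(end.lon, end.lat, end.time, alt, "backward"),
                smooth_field, params, hours)
            err_km = wb.haversine_km(lon, lat, back.endpoint.lon, back.endpoint.lat)
            path_km = sum(wb.haversine_km(a.lon, a.lat, b.lon, b.lat)
                          for a, b in zip(fwd.points, fwd.points[1:]))
            assert err_km < max(1.0, 0.002 * path_km)

    def test_halving_the_step_barely_moves_endpoints(self, smooth_field):
        rel = wb.ReleaseSpec(144.5, -9.5, np.datetime64("2021-01-10T10:00:00"),
                             1500.0, "forward")
        coarse = wb.integrate_fixed(rel, smooth_field, wb.FlightParams(step_s=300), 6.0)
        fine = wb.integrate_fixed(rel, smooth_field, wb.FlightParams(step_s=150), 6.0)
        d = wb.haversine_km(coarse.endpoint.lon, coarse.endpoint.lat,
                            fine.endpoint.lon, fine.endpoint.lat)
        assert d < 0.5


class TestExport:
    def test_csv_frame_has_one_row_per_point(self, uniform_field, land_mask):
        traj = wb.run_leg(dusk_release(142.0, 0.0), uniform_field, land_mask)
        frame = wb.trajectories_to_frame([traj])
        assert len(frame) == len(traj.points)
        assert set(frame.columns) >= {"time", "lon", "lat", "altitude_m", "surface"}

    def test_geojson_linestrings(self, uniform_field, land_mask, tmp_path):
        traj = wb.run_leg(dusk_release(142.0, 0.0), uniform_field, land_mask)
        doc = wb.legs_to_geojson([traj])
        assert doc["features"][0]["geometry"]["type"] == "LineString"
        assert doc["features"][0]["properties"]["termination_reason"] == "dawn_landfall"
        wb.write_geojson([traj], tmp_path / "legs.geojson")
        assert (tmp_path / "legs.geojson").stat().st_size > 0
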