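"""Wind-rose climatology, sector statistics and downdraft diagnostics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import windborne as wb
from windborne.climatology import (CalmWindError, EmptyRoseError, WindSample,
                                   sector_of, SECTOR_NAMES)


def sample(u, v, month=1, site="S", year=2015, hour=22):
    return WindSample(site, np.datetime64("2015-01-01T12:00:00"), 850.0,
                      month, year, hour, u, v)


class TestDirectionConvention:
    @pytest.mark.parametrize("u,v,expected", [
        (10.0, 0.0, 270.0),        # westerly blows FROM the west
        (0.0, -10.0, 0.0),         # northerly
        (-7.07, -7.07, 45.0),      # northeasterly
        (0.0, 10.0, 180.0),        # southerly
        (-10.0, 0.0, 90.0),        # easterly
    ])
    def test_anchor_directions(self, u, v, expected):
        assert wb.met_direction(u, v) == pytest.approx(expected)

    def test_calm_raises(self):
        with pytest.raises(CalmWindError):
            wb.met_direction(0.0, 0.0)

    @given(st.floats(0.5, 20.0), st.floats(0.0, 360.0), st.floats(-180.0, 180.0))
    def test_rotation_equivariance(self, speed, direction, rotation):
        # rotating the wind vector rotates the reported direction equally
        rad = np.radians(270.0 - direction)   # vector heading for this origin
        u, v = speed * np.cos(rad), speed * np.sin(rad)
        base = wb.met_direction(u, v)
        rot = np.radians(-rotation)
        u2 = u * np.cos(rot) - v * np.sin(rot)
        v2 = u * np.sin(rot) + v * np.cos(rot)
        rotated = wb.met_direction(u2, v2)
        assert rotated == pytest.approx((base + rotation) % 360.0, abs=1e-6) \
            or abs(rotated - (base + rotation) % 360) == pytest.approx(360.0, abs=1e-6)


class TestSectors:
    @pytest.mark.parametrize("deg,name", [
        (270.0, "W"), (281.25, "WNW"), (358.9, "N"), (0.0, "N"), (11.24, "N"),
        (11.25, "NNE"), (45.0, "NE"), (348.75, "N"), (348.74, "NNW"),
    ])
    def test_bin_assignment(self, deg, name):
        assert SECTOR_NAMES[sector_of(deg)] == name

    @given(st.floats(0.0, 359.999))
    def test_sector_center_is_within_half_width(self, deg):
        k = sector_of(deg)
        center = k * 22.5
        dist = min(abs(deg - center), 360 - abs(deg - center))
        assert dist <= 11.25


class TestNightlySampling:
    def test_decade_stratification_gives_1500_per_month(self, climatology_decade):
        _, samples = climatology_decade
        for month in range(1, 13):
            assert sum(s.month == month for s in samples) == 1500

    def test_minimal_stratification_gives_one_sample(self):
        fld = wb.make_climatology_field(seed=0, years=[2015])
        samples = wb.nightly_level_samples(
            fld, {"Saibai": wb.CLIMATOLOGY_SITES["Saibai"]}, levels_hpa=[850.0],
            hours_local=[22], years=[2015], months=[1])
        assert len(samples) == 1

    def test_uniform_field_gives_identical_samples(self):
        fld = wb.make_uniform_field(5.0, 0.0, 24.0, 0.0,
                                    extent=(141.5, 144.5, -11.5, -8.5),
                                    duration_h=40 * 24,
                                    start="2015-01-01T00:00:00")
        samples = wb.nightly_level_samples(
            fld, {"Saibai": wb.CLIMATOLOGY_SITES["Saibai"]},
            levels_hpa=[850.0, 875.0], years=[2015], months=[1])
        assert len(samples) == 20  # 1 site x 2 levels x 10 hours x 1 year
        assert all(s.u == pytest.approx(5.0) and s.v == 0.0 for s in samples)

    def test_coverage_gap_is_reported(self):
        fld = wb.make_climatology_field(seed=0, years=[2015])
        with pytest.raises(wb.climatology.CoverageError, match="2016"):
            wb.nightly_level_samples(fld, {"S": (142.6, -9.4)}, years=[2016],
                                     months=[6])


class TestWindRose:
    def test_all_westerly_rose(self):
        samples = [sample(5.0, 0.0) for _ in range(40)]
        rose = wb.monthly_wind_rose(samples, 1)
        w = sector_of(270.0)
        assert rose.frequencies[w] == 1.0
        assert rose.mean_speed[w] == pytest.approx(5.0)
        assert rose.total == 40

    def test_two_sector_split(self):
        samples = [sample(5.0, 0.0) for _ in range(10)] + \
                  [sample(0.0, -5.0) for _ in range(10)]
        rose = wb.monthly_wind_rose(samples, 1)
        assert rose.frequencies[sector_of(270.0)] == 0.5
        assert rose.frequencies[sector_of(0.0)] == 0.5

    def test_counts_match_brute_force_tally(self, climatology_decade):
        _, samples = climatology_decade
        rose = wb.monthly_wind_rose(samples, 2)
        tally = np.zeros(16, int)
        for s in samples:
            if s.month != 2 or s.speed < 1e-9:
                continue
            d = (np.degrees(np.arctan2(-s.u, -s.v))) % 360.0
            tally[int(((d + 11.25) % 360) // 22.5)] += 1
        np.testing.assert_array_equal(rose.counts, tally)

    def test_frequencies_sum_to_one_and_counts_to_total(self, climatology_decade):
        _, samples = climatology_decade
        for month in (1, 6, 12):
            rose = wb.monthly_wind_rose(samples, month)
            assert rose.frequencies.sum() == pytest.approx(1.0, abs=1e-12)
            assert rose.counts.sum() == rose.total

    def test_empty_month_signals(self):
        with pytest.raises(EmptyRoseError):
            wb.monthly_wind_rose([sample(5, 0, month=1)], 7)

    def test_frame_export(self):
        rose = wb.monthly_wind_rose([sample(5.0, 0.0)], 1)
        frame = rose.to_frame()
        assert list(frame.columns)[:2] == ["month", "sector"] and len(frame) == 16


class TestSectorGroups:
    def test_all_westerly_single_sector_group(self):
        samples = [sample(5.0, 0.0) for _ in range(10)]
        freq, speed = wb.sector_group_stats(samples, 1, wb.WESTERLY_SECTORS)
        assert freq == 100.0 and speed == pytest.approx(5.0)

    def test_exhaustive_group_is_always_100_pct(self, climatology_decade):
        _, samples = climatology_decade
        freq, speed = wb.sector_group_stats(samples, range(1, 13), set(range(16)))
        assert freq == 100.0
        assert speed == pytest.approx(np.mean([s.speed for s in samples]))

    def test_mixed_fixture_fraction(self):
        in_group = [sample(5.0, 0.0) for _ in range(79)]          # W
        out_group = [sample(-5.0, 0.0) for _ in range(21)]        # E
        freq, _ = wb.sector_group_stats(in_group + out_group, 1, wb.WESTERLY_SECTORS)
        assert freq == pytest.approx(79.0)

    def test_monsoon_seasonality_of_decade_field(self, climatology_decade):
        _, samples = climatology_decade
        jan, _ = wb.sector_group_stats(samples, 1, wb.WESTERLY_POOLED_SECTORS)
        jul, _ = wb.sector_group_stats(samples, 7, wb.WESTERLY_POOLED_SECTORS)
        assert jan > 50.0 and jul < 10.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wb.sector_group_stats([sample(5, 0)], 1, set())


WINDOW = ("2021-01-10T18:00:00", "2021-01-11T00:00:00")


@pytest.fixture(scope="module")
def profile():
    fld = wb.make_downdraft_field(WINDOW, 0.5)
    return wb.vertical_velocity_profile(fld, "site", 142.0, -10.0)


class TestVerticalVelocity:
    WINDOW = WINDOW

    def test_profile_shape(self, profile):
        assert profile.omega.shape == (profile.times.size, profile.levels_hpa.size)

    def test_peak_inside_window(self, profile):
        inside = (profile.times >= np.datetime64(self.WINDOW[0])) & \
                 (profile.times <= np.datetime64(self.WINDOW[1]))
        assert profile.omega[inside].max() == pytest.approx(0.5, abs=0.01)
        assert np.abs(profile.omega[~inside]).max() < 0.05

    def test_zero_field_gives_zero_profile(self):
        fld = wb.make_uniform_field(5.0, 0.0, 25.0, 0.0)
        prof = wb.vertical_velocity_profile(fld, "s", 142.0, -10.0,
                                            levels_hpa=[850.0, 900.0])
        assert np.all(prof.omega == 0.0)

    def test_events_recover_generator_window(self, profile):
        events = wb.downdraft_events(profile, threshold=0.3)
        assert len(events) == 1
        assert events[0].start == np.datetime64(self.WINDOW[0])
        assert events[0].end == np.datetime64(self.WINDOW[1])
        assert events[0].max_omega == pytest.approx(0.5, abs=0.01)

    def test_subthreshold_peak_gives_no_events(self):
        fld = wb.make_downdraft_field(self.WINDOW, 0.2)
        prof = wb.vertical_velocity_profile(fld, "s", 142.0, -10.0)
        assert wb.downdraft_events(prof, threshold=0.3) == []

    def test_threshold_boundary_is_inclusive_by_default(self, profile):
        assert wb.downdraft_events(profile, threshold=0.5)          # 0.5 >= 0.5
        assert not wb.downdraft_events(profile, threshold=0.5, inclusive=False)

    def test_events_monotone_in_threshold(self, profile):
        spans = []
        for thr in (0.1, 0.3, 0.45):
            events = wb.downdraft_events(profile, threshold=thr)
            spans.append(sum((e.end - e.start) / np.timedelta64(1, "h")
                             for e in events))
        assert spans == sorted(spans, reverse=True)

    def test_moderate_downdraft_never_overwhelms_airspeed(self, profile):
        # omega <= 0.5 Pa/s at rose levels converts to |w| far below 3 m/s
        events = wb.downdraft_events(profile, threshold=0.3)
        assert all(not e.exceeds_airspeed for e in events)
        assert all(e.max_downdraft_ms < 0.1 for e in events)

    def test_profile_dataset_roundtrip(self, profile, tmp_path):
        ds = profile.to_dataset()
        assert ds.attrs["site"] == "site"
        path = tmp_path / "profile.nc"
        ds.to_netcdf(path, engine="scipy")
        assert path.stat().st_size > 0
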