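"""GPS processing: distances, land flags, trips, filters, interpolation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_fixes
from patchdive import tracks


class TestDistances:
    def test_zero_at_colony(self):
        c = tracks.Colony("X", -60.7, -45.6)
        assert tracks.dist_to_colony(-60.7, -45.6, c) == pytest.approx(0.0, abs=1e-9)

    def test_one_degree_latitude(self):
        d = tracks.haversine_km(-60.0, -45.0, -61.0, -45.0)
        assert d == pytest.approx(111.19, abs=0.01)

    def test_against_law_of_cosines_oracle(self):
        rng = np.random.default_rng(0)
        lat1, lat2 = rng.uniform(-65, -55, (2, 200))
        lon1, lon2 = rng.uniform(-50, -40, (2, 200))
        got = tracks.haversine_km(lat1, lon1, lat2, lon2)
        # independent formula: spherical law of cosines
        p1, p2, dl = np.radians(lat1), np.radians(lat2), np.radians(lon2 - lon1)
        oracle = tracks.EARTH_RADIUS_KM * np.arccos(
            np.clip(np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1)
        )
        np.testing.assert_allclose(got, oracle, atol=1e-3)  # 1 m

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform([-65, -50], [-55, -40], size=(50, 3, 2))
        for a, b, c in pts:
            dab = tracks.haversine_km(*a, *b)
            assert dab == pytest.approx(tracks.haversine_km(*b, *a), abs=1e-9)
            assert dab <= tracks.haversine_km(*a, *c) + tracks.haversine_km(*c, *b) + 1e-9


class TestFlagOnLand:
    def test_colony_is_land_and_offshore_is_sea(self, world):
        clat, clon = world.colony_position
        fixes = make_fixes([0, 60], [clat, clat], [clon, clon + 1.0])  # ~54 km east
        out = tracks.flag_on_land(fixes, world.polygon())
        assert out["on_land"].tolist() == [True, False]

    def test_invalid_polygon_rejected(self, world):
        from shapely.geometry import Polygon

        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError):
            tracks.flag_on_land(make_fixes([0], [0.5], [0.5]), bowtie)


def _trip_fixes(n_sea, span_s, world):
    clat, clon = world.colony_position
    # land fix, n_sea at-sea fixes 20+ km offshore, land fix
    times = [0] + [60 + i * span_s / max(n_sea - 1, 1) for i in range(n_sea)] + [span_s + 3600]
    lats = [clat] + [clat + 0.2 + 0.001 * i for i in range(n_sea)] + [clat]
    lons = [clon] * (n_sea + 2)
    fixes = make_fixes(times, lats, lons)
    return tracks.flag_on_land(fixes, world.polygon())


class TestSegmentTrips:
    def test_twelve_fixes_two_hours_is_one_trip(self, world):
        trips = tracks.segment_trips(_trip_fixes(12, 7200, world))
        assert len(trips) == 1
        assert trips[0].duration_h > 2.0  # bracketing land fixes included

    def test_nine_fixes_is_no_trip(self, world):
        assert tracks.segment_trips(_trip_fixes(9, 10800, world)) == []

    def test_under_one_hour_is_no_trip(self, world):
        assert tracks.segment_trips(_trip_fixes(15, 2700, world)) == []

    def test_unbracketed_trip_flagged(self, world):
        fixes = _trip_fixes(12, 7200, world).iloc[1:].reset_index(drop=True)  # drop leading land fix
        trips = tracks.segment_trips(fixes)
        assert len(trips) == 1 and not trips[0].bracketed

    def test_agrees_with_brute_force_rule(self, world):
        rng = np.random.default_rng(2)
        clat, clon = world.colony_position
        for _ in range(30):
            n = 60
            on_land = rng.uniform(size=n) < 0.3
            lats = np.where(on_land, clat, clat + 0.3)
            times = np.cumsum(rng.uniform(120, 900, n))
            fixes = make_fixes(times, lats, [clon] * n)
            fixes["on_land"] = on_land
            got = [(t.fixes.index[0], len(t.fixes)) for t in tracks.segment_trips(fixes)]
            # oracle: scan runs of at-sea fixes and apply both thresholds
            expected = []
            i = 0
            while i < n:
                if not on_land[i]:
                    j = i
                    while j < n and not on_land[j]:
                        j += 1
                    span = times[j - 1] - times[i]
                    if j - i >= 10 and span >= 3600:
                        expected.append((i, j - i))
                    i = j
                else:
                    i += 1
            assert got == expected


class TestSpeedFilter:
    def _track(self, world, displace=None, dt=50.0):
        clat, clon = world.colony_position
        n = 10
        lats = [clat + 0.4 + i * 0.0005 for i in range(n)]  # ~55 m steps: ~1 m/s
        if displace is not None:
            lats[5] += displace
        times = [i * dt for i in range(n)]
        return make_fixes(times, lats, [clon] * n)

    def test_double_fast_fix_removed(self, world):
        fixes = self._track(world, displace=0.009)  # ~1 km off: both legs ~20 m/s
        kept, removed = tracks.speed_filter(fixes, vmax=10.0)
        assert removed == 1 and len(kept) == 9

    def test_single_fast_leg_kept(self, world):
        clat, clon = world.colony_position
        # a jump then a slow return leg: only one adjacent speed > vmax
        lats = [clat + 0.4, clat + 0.4, clat + 0.409, clat + 0.4091, clat + 0.4092]
        fixes = make_fixes([0, 50, 100, 150, 200], lats, [clon] * 5)
        kept, removed = tracks.speed_filter(fixes, vmax=10.0)
        assert removed == 0

    def test_clean_track_untouched(self, world):
        kept, removed = tracks.speed_filter(self._track(world), vmax=10.0)
        assert removed == 0 and len(kept) == 10

    def test_agrees_with_brute_force_rule(self, world):
        rng = np.random.default_rng(3)
        clat, clon = world.colony_position
        for _ in range(30):
            n = 40
            lats = clat + 0.3 + np.cumsum(rng.normal(0, 0.002, n))
            times = np.cumsum(rng.uniform(30, 300, n))
            fixes = make_fixes(times, lats, [clon] * n)
            kept, removed = tracks.speed_filter(fixes, vmax=10.0)
            # oracle: recompute both adjacent speeds per fix from scratch
            d = tracks.haversine_km(lats[:-1], [clon] * (n - 1), lats[1:], [clon] * (n - 1)) * 1000
            v = d / np.diff(times)
            bad = np.zeros(n, dtype=bool)
            bad[1:-1] = (v[:-1] > 10.0) & (v[1:] > 10.0)
            assert removed == bad.sum()
            np.testing.assert_array_equal(kept["lat"].to_numpy(), lats[~bad])


class TestJumpOutlierFilter:
    def test_single_distant_fix_removed(self, world):
        clat, clon = world.colony_position
        lats = [clat + 0.3 + 0.001 * i for i in range(7)]
        lats[3] += 4.5  # ~500 km
        fixes = make_fixes([i * 600 for i in range(7)], lats, [clon] * 7)
        kept, removed = tracks.jump_outlier_filter(fixes, max_jump_km=50.0)
        assert removed == 1

    def test_smooth_track_unchanged(self, world):
        clat, clon = world.colony_position
        lats = [clat + 0.3 + 0.001 * i for i in range(7)]
        fixes = make_fixes([i * 600 for i in range(7)], lats, [clon] * 7)
        _, removed = tracks.jump_outlier_filter(fixes, max_jump_km=50.0)
        assert removed == 0

    def test_two_consecutive_displaced_fixes_kept(self, world, caplog):
        clat, clon = world.colony_position
        lats = [clat + 0.3 + 0.001 * i for i in range(8)]
        lats[3] += 4.5
        lats[4] += 4.5
        fixes = make_fixes([i * 600 for i in range(8)], lats, [clon] * 8)
        with caplog.at_level("WARNING", logger="patchdive.tracks"):
            _, removed = tracks.jump_outlier_filter(fixes, max_jump_km=50.0)
        assert removed == 0
        assert "consecutive" in caplog.text


class TestInterpolatePositions:
    def test_exact_at_fix_times(self, world):
        clat, clon = world.colony_position
        fixes = make_fixes([0, 300, 600], [clat, clat + 0.1, clat + 0.15], [clon, clon + 0.05, clon + 0.2])
        out = tracks.interpolate_positions(fixes, fixes["t"])
        np.testing.assert_allclose(out["lat"], fixes["lat"], atol=1e-12)
        np.testing.assert_allclose(out["lon"], fixes["lon"], atol=1e-12)

    def test_linear_data_interpolates_linearly(self, world):
        clat, clon = world.colony_position
        fixes = make_fixes([0, 300, 600], [clat, clat + 0.1, clat + 0.2], [clon, clon + 0.1, clon + 0.2])
        q = fixes["t"].iloc[0] + pd.Timedelta(seconds=150)
        out = tracks.interpolate_positions(fixes, [q])
        assert out.loc[0, "lat"] == pytest.approx(clat + 0.05, abs=1e-9)

    def test_query_in_long_gap_absent(self, world):
        clat, clon = world.colony_position
        fixes = make_fixes([0, 300, 300 + 7200, 300 + 7500], [clat] * 4, [clon] * 4)
        q = fixes["t"].iloc[1] + pd.Timedelta(seconds=3600)
        out = tracks.interpolate_positions(fixes, [q], max_gap_s=3600)
        assert np.isnan(out.loc[0, "lat"]) and out.loc[0, "reason"] == "gps_gap"

    def test_query_outside_span_absent_with_reason(self, world):
        clat, clon = world.colony_position
        fixes = make_fixes([0, 300], [clat] * 2, [clon] * 2)
        q = fixes["t"].iloc[1] + pd.Timedelta(seconds=600)
        out = tracks.interpolate_positions(fixes, [q])
        assert out.loc[0, "reason"] == "outside_fix_span"


class TestJulianDay:
    @pytest.mark.parametrize(
        "date,expected",
        [("2015-12-01", 335), ("2016-01-01", 366), ("2015-02-10", 406), ("2015-12-31", 365)],
    )
    def test_seasonal_axis(self, date, expected):
        assert tracks.julian_day(pd.Timestamp(date)) == expected

    def test_out_of_season_rejected(self):
        with pytest.raises(ValueError):
            tracks.julian_day(pd.Timestamp("2015-07-01"))
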