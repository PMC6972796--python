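"""Cleaning rules, haversine buffer, thinning and absence sampling."""

import numpy as np
import pandas as pd
import pytest

from ensemblesdm.grids import GridSpec
from ensemblesdm.occurrences import (EmptyResultError, build_buffer,
                                     clean_records, haversine_km,
                                     mean_pairwise_haversine, sample_absences,
                                     thin_to_pixels)


class TestHaversine:
    def test_identical_points_zero(self):
        assert mean_pairwise_haversine([10.0, 10.0], [5.0, 5.0]) == 0.0

    def test_three_point_mean_against_hand_arithmetic(self):
        # two 1-degree arcs of R*pi/180 = 111.1949 km and one diagonal
        R = 6371.0
        arc = R * np.pi / 180.0
        # diagonal (0,1)-(1,0) from the haversine formula directly
        lat1, lat2 = np.radians(1.0), np.radians(0.0)
        a = np.sin(np.radians(-1.0) / 2) ** 2 \
            + np.cos(lat1) * np.cos(lat2) * np.sin(np.radians(1.0) / 2) ** 2
        diag = 2 * R * np.arcsin(np.sqrt(a))
        expected = (arc + arc + diag) / 3
        got = mean_pairwise_haversine([0.0, 0.0, 1.0], [0.0, 1.0, 0.0])
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(126.54, abs=0.05)

    def test_longitude_wraparound_invariance(self):
        a = mean_pairwise_haversine([0.0, 1.0, 2.0], [0.0, 1.0, -1.0])
        b = mean_pairwise_haversine([360.0, 361.0, 362.0], [0.0, 1.0, -1.0])
        assert a == pytest.approx(b, rel=1e-9)

    def test_fewer_than_two_points_raises(self):
        with pytest.raises(ValueError):
            mean_pairwise_haversine([0.0], [0.0])


class TestCleanRecords:
    def test_zero_coordinate_rule(self, toy_records):
        kept, log = clean_records(toy_records)
        assert log["zero_coordinates"] == 1
        assert not ((kept["lon"] == 0) & (kept["lat"] == 0)).any()

    def test_imprecision_strictly_greater_than_10km(self):
        df = pd.DataFrame({
            "lon": [-20.0, -20.1], "lat": [5.0, 5.1], "detected": [1, 1],
            "source": ["online", "online"],
            "imprecision_m": [10_000.0, 10_001.0]})
        kept, log = clean_records(df)
        assert log["imprecision"] == 1
        assert kept["imprecision_m"].tolist() == [10_000.0]

    def test_survey_records_exempt_from_imprecision(self, toy_records):
        kept, _ = clean_records(toy_records)
        assert (kept["source"] == "survey").sum() == 3

    def test_retained_records_unaltered(self, toy_records):
        kept, _ = clean_records(toy_records)
        merged = kept.merge(toy_records, how="left",
                            on=["lon", "lat", "detected", "source"])
        assert len(merged) == len(kept)

    def test_buffer_rule_and_counts(self, toy_records, small_grid):
        buffer = build_buffer([-20.0], [5.0], 80.0, small_grid)
        kept, log = clean_records(toy_records, buffer=buffer)
        # (-21, 6) and (0, 0) and the imprecise online point are outside
        assert log["outside_buffer"] >= 2
        assert len(kept) + sum(log.values()) == len(toy_records)

    def test_all_removed_is_explicit(self):
        df = pd.DataFrame({"lon": [0.0], "lat": [0.0], "detected": [1],
                           "source": ["online"], "imprecision_m": [1.0]})
        with pytest.raises(EmptyResultError):
            clean_records(df)


class TestBuildBuffer:
    def test_tiny_radius_selects_single_anchor_pixel(self):
        grid = GridSpec(10, 10, 0.0, 0.0, 1.0)
        lon, lat = grid.center_of(4, 3)
        buf = build_buffer([float(lon)], [float(lat)], 5.0, grid)
        assert buf.member_mask.sum() == 1
        assert buf.member_mask[4, 3]

    def test_huge_radius_covers_grid(self, small_grid):
        buf = build_buffer([-20.0], [0.0], 50_000.0, small_grid)
        assert buf.member_mask.all()

    def test_membership_equals_brute_force_haversine(self):
        rng = np.random.default_rng(5)
        for trial in range(3):
            grid = GridSpec(50, 50, float(rng.uniform(-40, 0)),
                            float(rng.uniform(-20, 10)), 0.4)
            alon = rng.uniform(grid.lon_min, grid.lon_max, 8)
            alat = rng.uniform(grid.lat_min, grid.lat_max, 8)
            radius = float(rng.uniform(50, 600))
            buf = build_buffer(alon, alat, radius, grid)
            glon, glat = np.meshgrid(grid.lon_centers(), grid.lat_centers())
            oracle = np.zeros(grid.shape, dtype=bool)
            for i in range(grid.n_rows):
                for j in range(grid.n_cols):
                    d = haversine_km(glon[i, j], glat[i, j], alon, alat)
                    oracle[i, j] = bool((d <= radius).any())
            np.testing.assert_array_equal(buf.member_mask, oracle)

    def test_bad_radius_raises(self, small_grid):
        with pytest.raises(ValueError):
            build_buffer([0.0], [0.0], -1.0, small_grid)


class TestThinning:
    def test_presence_priority_within_pixel(self, small_env):
        grid = small_env.grid
        r, c = 5, 5
        lon, lat = grid.center_of(r, c)
        df = pd.DataFrame({
            "lon": [lon, lon + 0.1, lon - 0.1, lon + 0.05],
            "lat": [lat, lat + 0.1, lat - 0.1, lat - 0.05],
            "detected": [1, 0, 0, 0],
            "source": "survey", "imprecision_m": np.nan})
        ds = thin_to_pixels(df, small_env)
        assert len(ds.y) == 1
        assert ds.y[0] == 1

    def test_distinct_pixels_all_kept(self, small_env):
        grid = small_env.grid
        water = np.argwhere(~small_env.nodata_mask)[:5]
        lon, lat = grid.center_of(water[:, 0], water[:, 1])
        df = pd.DataFrame({"lon": lon, "lat": lat,
                           "detected": [1, 0, 1, 0, 0],
                           "source": "survey", "imprecision_m": np.nan})
        ds = thin_to_pixels(df, small_env)
        assert len(ds.y) == 5
        assert ds.y.sum() == 2

    def test_nodata_and_outside_records_dropped_with_log(self, small_env):
        grid = small_env.grid
        land = np.argwhere(small_env.nodata_mask)[0]
        lon_l, lat_l = grid.center_of(land[0], land[1])
        water = np.argwhere(~small_env.nodata_mask)[0]
        lon_w, lat_w = grid.center_of(water[0], water[1])
        df = pd.DataFrame({
            "lon": [float(lon_l), float(lon_w), 150.0],
            "lat": [float(lat_l), float(lat_w), 80.0],
            "detected": [1, 1, 1], "source": "survey",
            "imprecision_m": np.nan})
        ds = thin_to_pixels(df, small_env)
        assert ds.log["nodata_pixels"] == 1
        assert ds.log["outside_grid"] == 1
        assert len(ds.y) == 1

    def test_thinning_idempotent_at_dataset_level(self, strong_world,
                                                  strong_pixels):
        env, _, _, records = strong_world
        grid = env.grid
        ids = strong_pixels.pixel_ids
        lon, lat = grid.center_of(np.array([p[0] for p in ids]),
                                  np.array([p[1] for p in ids]))
        df = pd.DataFrame({"lon": lon, "lat": lat, "detected": strong_pixels.y,
                           "source": "survey", "imprecision_m": np.nan})
        again = thin_to_pixels(df, env)
        assert again.pixel_ids == strong_pixels.pixel_ids
        np.testing.assert_array_equal(again.y, strong_pixels.y)
        np.testing.assert_allclose(again.X, strong_pixels.X)


class TestSampleAbsences:
    def test_exact_one_to_ten_ratio(self, strong_pixels):
        ds = sample_absences(strong_pixels, ratio=10, seed=3)
        assert ds.n_absence == 10 * ds.n_presence
        assert ds.n_presence == strong_pixels.n_presence

    def test_presences_never_lost(self, strong_pixels):
        pres_ids = {p for p, yy in zip(strong_pixels.pixel_ids,
                                       strong_pixels.y) if yy == 1}
        for seed in range(5):
            ds = sample_absences(strong_pixels, ratio=10, seed=seed)
            kept = {p for p, yy in zip(ds.pixel_ids, ds.y) if yy == 1}
            assert kept == pres_ids

    def test_insufficient_absences_kept_with_warning(self, strong_pixels):
        few = sample_absences(strong_pixels, ratio=1, seed=0)
        # now ask for 10x from a set with equal classes
        with pytest.warns(UserWarning):
            out = sample_absences(few, ratio=10, seed=0)
        assert out.n_absence == few.n_absence

    def test_deterministic_given_seed(self, strong_pixels):
        a = sample_absences(strong_pixels, ratio=10, seed=99)
        b = sample_absences(strong_pixels, ratio=10, seed=99)
        assert a.pixel_ids == b.pixel_ids

    def test_no_presences_raises(self, strong_pixels):
        import dataclasses
        abs_only = dataclasses.replace(
            strong_pixels, y=np.zeros_like(strong_pixels.y))
        with pytest.raises(ValueError):
            sample_absences(abs_only, ratio=10, seed=0)
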