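"""Synthetic world generator: contiguity, determinism, detection, recovery."""

import numpy as np
import pandas as pd
import pytest

from latgaps import (
    BandGrid,
    DetectionModel,
    EffortProfile,
    NameStatusTable,
    NoiseConfig,
    WorldConfig,
    apply_qc,
    build_occupancy,
    make_world,
    recovery_report,
    simulate_records,
    toy_land_mask,
)


def rows_are_intervals(occupancy):
    """True iff every row's support is a contiguous run of bands."""
    for row in occupancy:
        occ = np.flatnonzero(row)
        if occ.size and not np.array_equal(occ, np.arange(occ[0], occ[-1] + 1)):
            return False
    return True


class TestMakeWorld:
    def test_deterministic_given_seed(self):
        cfg = WorldConfig(n_species=40, seed=123)
        a, b = make_world(cfg), make_world(cfg)
        assert np.array_equal(a.occupancy, b.occupancy)
        assert np.array_equal(a.range_low, b.range_low)
        assert a.species == b.species

    def test_single_species_band_arithmetic(self, grid):
        # a [−15, 15] range must occupy exactly the bands 13..19 of the
        # default grid ([−15,−10) through [15,20))
        assert list(grid.bands_for_interval(-15.0, 15.0)) == list(range(13, 20))

    def test_every_true_range_is_an_interval(self):
        for seed in range(10):
            world = make_world(WorldConfig(n_species=80, seed=seed))
            assert rows_are_intervals(world.occupancy)
            assert world.occupancy.any(axis=1).all()

    def test_tropical_shape_peaks_at_equator(self, grid):
        totals = np.zeros(grid.n_bands)
        for seed in range(15):
            world = make_world(
                WorldConfig(n_species=200, richness_shape="unimodal-tropical", seed=seed)
            )
            totals += world.true_richness
        peak = grid.band_bounds(int(np.argmax(totals)))
        assert peak[0] >= -10 and peak[1] <= 10  # maximum near the equator

    def test_degenerate_width_rejected(self):
        with pytest.raises(ValueError):
            WorldConfig(width_median=0.0)


class TestSimulateRecords:
    def test_zero_effort_zero_records(self):
        world = make_world(WorldConfig(n_species=10, seed=0))
        rec = simulate_records(world, EffortProfile.uniform(0.0, world.grid), seed=1)
        assert len(rec) == 0

    def test_reproducible_given_seed(self):
        world = make_world(WorldConfig(n_species=30, seed=2))
        eff = EffortProfile.uniform(20, world.grid)
        a = simulate_records(world, eff, seed=7)
        b = simulate_records(world, eff, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_perfect_detection_recovers_true_occupancy(self):
        world = make_world(WorldConfig(n_species=50, seed=3))
        eff = EffortProfile.uniform(30, world.grid)
        rec = simulate_records(world, eff, DetectionModel(p=1.0), seed=4)
        occ = build_occupancy(
            rec.rename(columns={"scientific_name": "species_name"}),
            world.grid, species=world.species,
        )
        assert np.array_equal(occ.presence, world.occupancy)

    def test_records_stay_off_the_toy_continent(self):
        world = make_world(WorldConfig(n_species=20, seed=5))
        rec = simulate_records(world, EffortProfile.uniform(30, world.grid), seed=6)
        assert not toy_land_mask(rec["latitude"], rec["longitude"]).any()

    def test_effort_profile_validation(self, grid):
        with pytest.raises(ValueError):
            EffortProfile(np.full(5, 1.0), grid)  # wrong length
        with pytest.raises(ValueError):
            EffortProfile.uniform(10, grid).with_equatorial_trough(0)

    def test_equatorial_trough_divides_tropical_rates(self, grid):
        eff = EffortProfile.uniform(300, grid).with_equatorial_trough(30)
        trop = grid.bands_for_interval(-22.5, 22.5)
        assert list(trop) == list(range(11, 21))  # the ten bands of [-25, 25)
        assert np.allclose(eff.lambdas[trop], 10.0)
        others = np.setdiff1d(np.arange(grid.n_bands), trop)
        assert np.allclose(eff.lambdas[others], 300.0)

    def test_bimodal_preset_shape(self, grid):
        lam = EffortProfile.bimodal(grid).lambdas
        eq = grid.band_index(2.5)
        north = grid.band_index(52.5)
        south = grid.band_index(-32.5)
        assert lam[north] > lam[south] > lam[eq]


class TestNoiseAndQC:
    def test_noise_rows_removed_by_qc(self):
        world = make_world(WorldConfig(n_species=60, seed=8))
        rec = simulate_records(
            world, EffortProfile.uniform(60, world.grid), seed=9, noise=NoiseConfig()
        )
        names = NameStatusTable.accept_all(world.species)
        clean, report = apply_qc(rec, names, land_mask=toy_land_mask)
        report.check()
        n = len(simulate_records(world, EffortProfile.uniform(60, world.grid), seed=9))
        assert report.removed("zero_coordinates") == round(0.01 * n)
        assert report.removed("on_land") == round(0.01 * n)
        assert report.removed("latitude_out_of_bounds") == round(0.01 * n)
        # duplicates + date-stripped duplicates both land in the dedup rule
        assert report.removed("duplicate_records") >= round(0.01 * n)
        assert not toy_land_mask(clean["latitude"], clean["longitude"]).any()


class TestRecoveryReport:
    def test_interior_miss_captured(self):
        grid = BandGrid(0, 25, 5)
        world = make_world(WorldConfig(n_species=1, grid=grid, seed=0))
        world.occupancy[0] = [1, 1, 1, 1, 0]
        obs = build_occupancy(
            pd.DataFrame(
                {"species_name": ["Simulatus sp0000"] * 3,
                 "latitude": [2.0, 7.0, 17.0],  # band 2 (10–15°) unsampled
                 "longitude": 1.0,
                 "event_date": pd.Timestamp("2000-01-01")}
            ),
            grid, species=world.species,
        )
        rep = recovery_report(world, obs)
        assert rep.n_unrecorded == 1 and rep.n_captured == 1
        assert rep.capture_fraction == 1.0
        assert rep.table.loc[2, "missing_richness"] == 1

    def test_edge_miss_not_captured(self):
        grid = BandGrid(0, 25, 5)
        world = make_world(WorldConfig(n_species=1, grid=grid, seed=0))
        world.occupancy[0] = [1, 1, 1, 1, 0]
        obs = build_occupancy(
            pd.DataFrame(
                {"species_name": ["Simulatus sp0000"] * 3,
                 "latitude": [2.0, 7.0, 12.0],  # range-edge band 3 unsampled
                 "longitude": 1.0,
                 "event_date": pd.Timestamp("2000-01-01")}
            ),
            grid, species=world.species,
        )
        rep = recovery_report(world, obs)
        assert rep.n_unrecorded == 1 and rep.n_captured == 0
        assert rep.capture_fraction == 0.0

    def test_perfect_sampling_capture_undefined(self):
        world = make_world(WorldConfig(n_species=25, seed=11))
        rec = simulate_records(world, EffortProfile.uniform(40, world.grid),
                               DetectionModel(p=1.0), seed=12)
        obs = build_occupancy(
            rec.rename(columns={"scientific_name": "species_name"}),
            world.grid, species=world.species,
        )
        rep = recovery_report(world, obs)
        assert rep.n_unrecorded == 0
        assert np.isnan(rep.capture_fraction)
        assert np.array_equal(
            rep.table["observed_richness"].to_numpy(), world.true_richness
        )

    def test_grid_mismatch_rejected(self):
        world = make_world(WorldConfig(n_species=5, seed=0))
        other = build_occupancy(
            pd.DataFrame({"species_name": ["Simulatus sp0000"], "latitude": [2.0],
                          "longitude": [1.0], "event_date": [pd.Timestamp("2000-01-01")]}),
            BandGrid(0, 25, 5),
        )
        with pytest.raises(ValueError):
            recovery_report(world, other)
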