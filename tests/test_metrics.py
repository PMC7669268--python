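import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctlswarm import (
    ArenaConfig,
    Frame,
    cytotoxicity_index,
    density_kymograph,
    fmi,
    infiltration_stats,
    instantaneous_fmi_kymograph,
    swarming_index,
    track_summary,
    transmigration_index,
)
from ctlswarm.metrics import cumulative_radial_counts

from conftest import make_tracks


def _perimeter_frame(arena, n=1000):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = arena.well_radius
    return Frame(t=0.0, positions=np.column_stack([r * np.cos(theta), r * np.sin(theta)]))


def _interior_frame(arena, n=1000, seed=0):
    rng = np.random.default_rng(seed)
    rho = arena.tumouroid_radius * np.sqrt(rng.uniform(0, 0.98, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return Frame(t=0.0, positions=np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))


def _uniform_annulus_frame(arena, n, seed=0):
    rng = np.random.default_rng(seed)
    rho = np.sqrt(rng.uniform(arena.tumouroid_radius**2, arena.well_radius**2, n))
    theta = rng.uniform(0, 2 * np.pi, n)
    return Frame(t=0.0, positions=np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))


class TestSwarmingIndex:
    def test_perimeter_anchor_is_minus_one(self, arena):
        assert swarming_index(_perimeter_frame(arena), arena) == pytest.approx(-1.0)

    def test_infiltrated_anchor_is_plus_one(self, arena):
        assert swarming_index(_interior_frame(arena), arena) == pytest.approx(1.0)

    def test_uniform_annulus_is_near_zero(self, arena):
        # per-cell score uniform on [-1, 1]; SE = 1/sqrt(3n)
        m = swarming_index(_uniform_annulus_frame(arena, 100_000, seed=42), arena)
        assert abs(m) < 0.01

    def test_half_perimeter_half_inside_is_zero(self, arena):
        half_out = _perimeter_frame(arena, 500).positions
        half_in = np.zeros((500, 2))
        m = swarming_index(Frame(t=0.0, positions=np.vstack([half_out, half_in])), arena)
        assert m == pytest.approx(0.0)

    def test_rotation_invariance(self, arena):
        frame = _uniform_annulus_frame(arena, 500, seed=3)
        for angle in (0.3, 1.2, np.pi):
            c, s = np.cos(angle), np.sin(angle)
            rot = frame.positions @ np.array([[c, -s], [s, c]]).T
            assert swarming_index(Frame(t=0.0, positions=rot), arena) == pytest.approx(
                swarming_index(frame, arena), abs=1e-12
            )

    def test_moving_one_cell_inward_never_decreases_m(self, arena):
        frame = _uniform_annulus_frame(arena, 200, seed=7)
        m0 = swarming_index(frame, arena)
        moved = frame.positions.copy()
        moved[0] *= 0.5                       # strictly smaller radius
        assert swarming_index(Frame(t=0.0, positions=moved), arena) >= m0

    def test_empty_frame_is_an_error(self, arena):
        with pytest.raises(ValueError):
            swarming_index(Frame(t=0.0, positions=np.empty((0, 2))), arena)

    def test_cell_outside_well_is_an_error(self, arena):
        with pytest.raises(ValueError, match="outside the well"):
            swarming_index(Frame(t=0.0, positions=[[4000.0, 0.0]]), arena)

    @given(st.integers(0, 10_000))
    def test_bounded_in_minus_one_one(self, seed):
        arena = ArenaConfig()
        rng = np.random.default_rng(seed)
        rho = arena.well_radius * np.sqrt(rng.uniform(0, 1, 50))
        theta = rng.uniform(0, 2 * np.pi, 50)
        frame = Frame(t=0.0, positions=np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))
        assert -1.0 <= swarming_index(frame, arena) <= 1.0


class TestFMI:
    @pytest.mark.parametrize(
        "net, u, expected",
        [
            ((10.0, 0.0, 0.0), (1, 0, 0), 1.0),
            ((10.0, 0.0, 0.0), (-1, 0, 0), -1.0),
            ((-3.0, 4.0, 0.0), (-1, 0, 0), 0.6),
        ],
    )
    def test_known_projections(self, net, u, expected):
        positions = np.array([[0.0, 0.0, 0.0], list(net)])
        assert fmi(positions, u) == pytest.approx(expected)

    def test_reversed_track_flips_sign(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(size=(20, 3)), axis=0)
        assert fmi(pos[::-1], (1, 0, 0)) == pytest.approx(-fmi(pos, (1, 0, 0)))

    def test_bounded_for_random_tracks(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            pos = np.cumsum(rng.normal(size=(10, 3)), axis=0)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            assert abs(fmi(pos, u)) <= 1.0 + 1e-12

    def test_zero_displacement_is_an_error(self):
        with pytest.raises(ValueError):
            fmi([[0, 0, 0], [1, 1, 1], [0, 0, 0]], (1, 0, 0))


class TestTrackSummary:
    def test_square_path(self):
        pts = [(0, 0, 0, 0), (1, 10, 0, 0), (2, 10, 10, 0), (3, 0, 10, 0), (4, 0, 0.001, 0)]
        df = make_tracks({"sq": pts})
        out = track_summary(df, (1, 0, 0))
        row = out.stats.iloc[0]
        assert row["displacement"] == pytest.approx(0.001)
        assert row["mean_speed"] == pytest.approx(10.0, rel=1e-3)

    def test_straight_track(self):
        pts = [(0, 0, 0, 0), (10, -60, 0, 0)]
        out = track_summary(make_tracks({"s": pts}), (-1, 0, 0))
        row = out.stats.iloc[0]
        assert row["displacement"] == pytest.approx(60.0)
        assert row["mean_speed"] == pytest.approx(6.0)
        assert row["fmi"] == pytest.approx(1.0)

    def test_speed_at_least_displacement_rate(self, small_tracks):
        out = track_summary(small_tracks, (1, 0, 0))
        assert np.all(
            out.stats["mean_speed"] >= out.stats["displacement"] / out.stats["duration"] - 1e-9
        )

    def test_single_point_track_reported(self):
        df = make_tracks({"one": [(0, 1, 2, 3)], "ok": [(0, 0, 0, 0), (1, 5, 0, 0)]})
        out = track_summary(df, (1, 0, 0))
        assert list(out.excluded["track_id"]) == ["one"]
        assert len(out.stats) == 1


class TestInfiltration:
    def test_all_outside(self, arena):
        frame = _perimeter_frame(arena, 10)
        out = infiltration_stats(frame, arena)
        assert out.fraction_infiltrated == 0.0
        assert len(out.depths) == 0
        assert np.isnan(out.mean_depth)

    def test_cell_at_centre_depth_is_radius(self, arena):
        out = infiltration_stats(Frame(t=0.0, positions=[[0.0, 0.0]]), arena)
        assert out.depths[0] == pytest.approx(1200.0)
        assert out.fraction_infiltrated == 1.0

    def test_cell_just_inside_depth_near_zero(self, arena):
        out = infiltration_stats(Frame(t=0.0, positions=[[1199.9, 0.0]]), arena)
        assert out.depths[0] == pytest.approx(0.1)

    def test_mixed_fraction(self, arena):
        frame = Frame(t=0.0, positions=[[0.0, 0.0], [2000.0, 0.0], [3000.0, 0.0], [500.0, 0.0]])
        assert infiltration_stats(frame, arena).fraction_infiltrated == pytest.approx(0.5)


class TestDensityKymograph:
    def test_cumulative_counts_match_brute_force(self, arena):
        frame = _uniform_annulus_frame(arena, 2000, seed=5)
        r_grid = np.linspace(0, 2200, 23)
        counts = cumulative_radial_counts(frame, arena, r_grid)
        rho = np.hypot(frame.positions[:, 0], frame.positions[:, 1])
        d = rho - arena.tumouroid_radius
        brute = np.array([np.sum((d >= 0) & (d <= r)) for r in r_grid], dtype=float)
        np.testing.assert_array_equal(counts, brute)

    def test_total_cells_conserved_pre_smoothing(self, arena):
        frame = _uniform_annulus_frame(arena, 1234, seed=6)
        grid = density_kymograph([frame], arena)
        assert grid.counts[0, -1] == 1234

    def test_uniform_frame_gives_flat_density(self, arena):
        # Monte-Carlo under uniformity: per-area density constant within
        # ±10% across the middle 80% of r at n = 50,000
        frame = _uniform_annulus_frame(arena, 50_000, seed=9)
        grid = density_kymograph([frame], arena)
        nr = len(grid.r)
        mid = slice(int(0.1 * nr), int(0.9 * nr))
        dens = grid.density[0, mid]
        assert dens.max() / dens.mean() < 1.10
        assert dens.min() / dens.mean() > 0.90

    def test_thin_shell_peak_located(self, arena):
        rng = np.random.default_rng(4)
        r0 = 800.0
        theta = rng.uniform(0, 2 * np.pi, 5000)
        rho = arena.tumouroid_radius + r0 + rng.normal(0, 5, 5000)
        frame = Frame(t=0.0, positions=np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))
        grid = density_kymograph([frame], arena)
        peak_r = grid.r[np.argmax(grid.density[0])]
        dr = grid.r[1] - grid.r[0]
        assert abs(peak_r - r0) <= dr

    def test_density_nonnegative(self, arena):
        frame = _uniform_annulus_frame(arena, 300, seed=11)
        grid = density_kymograph([frame], arena)
        assert np.all(grid.density >= 0)


class TestInstantaneousFMI:
    def test_straight_inward_tracks_score_one(self, arena):
        tracks = {}
        for i, start in enumerate([(3000.0, 0.0), (0.0, 3000.0), (-2500.0, 500.0)]):
            s = np.array(start)
            pts = [(j / 3.0, *(s * (1 - 0.02 * j)), 30.0) for j in range(10)]
            tracks[f"t{i}"] = pts
        df = make_tracks(tracks)
        out = instantaneous_fmi_kymograph(
            df, arena, r_bins=np.linspace(0, 2200, 5), t_bins=np.array([0.0, 5.0])
        )
        vals = out.to_numpy()
        assert np.nanmin(vals) == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_tracks_average_near_zero(self, arena, small_tracks):
        # Monte-Carlo: undirected steps have zero mean radial alignment
        shifted = small_tracks.copy()
        shifted["x"] += 2300.0                # place in the annulus
        out = instantaneous_fmi_kymograph(
            shifted, arena, r_bins=np.linspace(0, 2200, 3), t_bins=np.array([0.0, 20.0])
        )
        grand = np.nanmean(out.to_numpy())
        assert abs(grand) < 0.05

    def test_empty_bins_are_nan_not_zero(self, arena):
        df = make_tracks({"a": [(0, 2000, 0, 30), (1 / 3, 2010, 0, 30)]})
        out = instantaneous_fmi_kymograph(
            df, arena, r_bins=np.array([0.0, 1100.0, 2200.0]), t_bins=np.array([0.0, 5.0])
        )
        vals = out.to_numpy().ravel()
        assert np.isnan(vals).sum() == 1
        assert np.isfinite(vals).sum() == 1


class TestPlateAssayIndices:
    @pytest.mark.parametrize("s, c, expected", [(500, 250, 2.0), (100, 100, 1.0), (0, 50, 0.0)])
    def test_transmigration_ratio(self, s, c, expected):
        assert transmigration_index(s, c) == expected

    def test_transmigration_zero_control_error(self):
        with pytest.raises(ValueError):
            transmigration_index(10, 0)

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((100, 100, 50, 100), 50.0),
            ((100, 100, 100, 100), 0.0),   # no killing
            ((100, 100, 0, 100), 100.0),   # complete elimination
        ],
    )
    def test_cytotoxicity_formula(self, counts, expected):
        assert cytotoxicity_index(*counts) == pytest.approx(expected)

    def test_cytotoxicity_zero_denominator_error(self):
        with pytest.raises(ValueError):
            cytotoxicity_index(100, 0, 50, 100)
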