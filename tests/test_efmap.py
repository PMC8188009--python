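"""Per-voxel EF assignment, run averaging, statistics, Flinn data, secondary images."""

import numpy as np
import pytest

from trabshape import (
    BinaryVolume,
    Ellipsoid,
    EFRun,
    RunConfig,
    assign_ef,
    average_runs,
    ef_of_ellipsoid,
    flinn_data,
    make_plate,
    make_rod,
    make_sphere,
    run_ef,
    secondary_images,
    summary_stats,
)
from trabshape.efmap import contains
from trabshape.ellipsoid import rotation_matrix


class TestEFFormula:
    @pytest.mark.parametrize(
        "radii, expected",
        [((5, 5, 5), 0.0), ((1, 1, 10), 0.9), ((1, 10, 10), -0.9), ((2, 4, 8), 0.0)],
    )
    def test_difference_of_sorted_axis_ratios(self, radii, expected):
        assert ef_of_ellipsoid(Ellipsoid([0, 0, 0], radii)) == pytest.approx(expected)

    def test_always_in_unit_interval(self, rng):
        for _ in range(200):
            radii = np.sort(rng.uniform(0.1, 20, 3))
            ef = ef_of_ellipsoid(Ellipsoid([0, 0, 0], radii))
            assert -1.0 <= ef <= 1.0

    def test_contains_matches_quadratic_form(self, rng):
        e = Ellipsoid([4, 4, 4], [1, 2, 3], rotation_matrix([1, 2, 3], 0.8))
        for _ in range(50):
            p = rng.uniform(0, 8, 3)
            q = (p - e.centre) @ e.axes.T
            assert contains(e, p) == (((q / e.radii) ** 2).sum() <= 1 + 1e-12)


def _brute_force_assign(data, ellipsoids):
    """All-pairs oracle: per voxel, EF of the largest containing ellipsoid."""
    order = sorted(ellipsoids, key=lambda e: -e.volume)
    ef = np.full(data.shape, np.nan, dtype=np.float32)
    for z, y, x in np.argwhere(data):
        for e in order:
            if e.contains([z, y, x]):
                ef[z, y, x] = ef_of_ellipsoid(e)
                break
    return ef


def _random_ellipsoids(rng, dims, k):
    out = []
    for _ in range(k):
        radii = np.sort(rng.uniform(0.8, max(dims) / 2, 3))
        centre = rng.uniform(0, np.array(dims) - 1)
        rot = rotation_matrix(rng.standard_normal(3), rng.uniform(0, np.pi))
        out.append(Ellipsoid(centre, radii, rot))
    return out


class TestAssignEF:
    def test_no_ellipsoids_all_nan(self):
        vol = make_sphere(5, 16)
        run = assign_ef(vol, [])
        assert np.isnan(run.ef_grid).all()
        assert run.filling_percentage == 0.0

    def test_single_covering_ellipsoid_uniform(self):
        vol = make_sphere(5, 16)
        e = Ellipsoid([7.5, 7.5, 7.5], [8, 8, 8])
        run = assign_ef(vol, [e])
        assert run.filling_percentage == 100.0
        covered = run.ef_grid[vol.data]
        np.testing.assert_allclose(covered, ef_of_ellipsoid(e), atol=1e-7)

    def test_concentric_overlap_takes_larger(self):
        vol = BinaryVolume(np.ones((16, 16, 16), bool))
        small = Ellipsoid([7.5, 7.5, 7.5], [2, 3, 4])
        large = Ellipsoid([7.5, 7.5, 7.5], [4, 5, 6])
        run = assign_ef(vol, [small, large])
        assert run.ef_grid[7, 7, 7] == pytest.approx(ef_of_ellipsoid(large), abs=1e-7)

    def test_background_stays_nan(self):
        vol = make_sphere(4, 16)
        run = assign_ef(vol, [Ellipsoid([7.5, 7.5, 7.5], [10, 10, 10])])
        assert np.isnan(run.ef_grid[~vol.data]).all()

    @pytest.mark.parametrize("trial", range(6))
    def test_spatial_index_equals_brute_force(self, trial):
        rng = np.random.default_rng(4000 + trial)
        dims = tuple(int(d) for d in rng.integers(8, 24, 3))
        vol = BinaryVolume(rng.random(dims) < 0.6)
        ells = _random_ellipsoids(rng, dims, int(rng.integers(1, 12)))
        run = assign_ef(vol, ells)
        oracle = _brute_force_assign(vol.data, ells)
        np.testing.assert_array_equal(np.isnan(run.ef_grid), np.isnan(oracle))
        np.testing.assert_allclose(
            run.ef_grid[~np.isnan(oracle)], oracle[~np.isnan(oracle)], atol=1e-6
        )

    def test_average_over_two_largest(self):
        vol = BinaryVolume(np.ones((12, 12, 12), bool))
        e1 = Ellipsoid([5.5, 5.5, 5.5], [5, 5, 5])
        e2 = Ellipsoid([5.5, 5.5, 5.5], [1, 2, 4])
        run = assign_ef(vol, [e1, e2], average_over_largest_n=2)
        expected = (ef_of_ellipsoid(e1) + ef_of_ellipsoid(e2)) / 2
        assert run.ef_grid[5, 5, 5] == pytest.approx(expected, abs=1e-6)


class TestRunEF:
    cfg = RunConfig(skeleton_points_per_ellipsoid=1)

    def test_sphere_filling_and_median(self):
        """A ball is the worst case for filling: the voxel-rounding contact
        rule stops fits ~half a voxel short of the surface, capping a
        single run near (1 - 0.5/R)^3; averaging runs recovers the rest."""
        run = run_ef(make_sphere(12, 32), self.cfg, rng_seed=1)
        vals = run.ef_grid[~np.isnan(run.ef_grid)]
        assert run.filling_percentage >= 80.0
        assert -0.2 <= np.median(vals) <= 0.2

    def test_rod_median_positive(self):
        run = run_ef(make_rod(6, 0, 64), self.cfg, rng_seed=1)
        vals = run.ef_grid[~np.isnan(run.ef_grid)]
        assert np.median(vals) > 0.5

    def test_plate_median_negative(self):
        run = run_ef(make_plate(6, 0, 64), RunConfig(), rng_seed=1)
        vals = run.ef_grid[~np.isnan(run.ef_grid)]
        assert np.median(vals) < -0.5

    def test_ef_values_within_bounds(self):
        run = run_ef(make_rod(5, 0, 48), self.cfg, rng_seed=3)
        vals = run.ef_grid[~np.isnan(run.ef_grid)]
        assert vals.max() <= 1.0 and vals.min() >= -1.0

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            run_ef(BinaryVolume(np.zeros((4, 4, 4), bool)), self.cfg)

    def test_rotated_phantom_same_median(self):
        """90-degree rotation of the volume leaves the EF median (almost)
        unchanged: the method has no preferred grid direction."""
        from trabshape import make_gyroid

        vol = make_gyroid(16, 0.4, 48)
        rot = BinaryVolume(np.rot90(vol.data, axes=(0, 2)).copy())
        run_a = run_ef(vol, RunConfig(), rng_seed=5)
        run_b = run_ef(rot, RunConfig(), rng_seed=105)
        med_a = np.nanmedian(run_a.ef_grid)
        med_b = np.nanmedian(run_b.ef_grid)
        assert abs(med_a - med_b) <= 0.05


def _mini_run(ef_values, foreground=None):
    grid = np.asarray(ef_values, dtype=np.float32)
    fg = int((~np.isnan(grid)).sum()) if foreground is None else foreground
    covered = (~np.isnan(grid)).sum()
    return EFRun(
        ef_grid=grid,
        claim_id=np.where(np.isnan(grid), -1, 0).astype(np.int32),
        ellipsoids=[],
        filling_percentage=100.0 * covered / fg if fg else 0.0,
        foreground_count=fg,
    )


class TestAverageRuns:
    def test_identical_runs_zero_change(self):
        grid = np.full((2, 2, 2), 0.25, dtype=np.float32)
        res = average_runs([_mini_run(grid)] * 4)
        assert all(v == 0.0 for v in res.median_change.values())
        assert all(v == 0.0 for v in res.maximum_change.values())

    def test_nan_aware_mean_uses_covering_subset(self):
        nan = np.nan
        r1 = _mini_run([[[nan, 0.5]]], foreground=2)
        r2 = _mini_run([[[0.3, 0.7]]], foreground=2)
        res = average_runs([r1, r2])
        assert res.ef_grid[0, 0, 0] == pytest.approx(0.3)  # covered only in run 2
        assert res.ef_grid[0, 0, 1] == pytest.approx(0.6)

    def test_cumulative_filling_non_decreasing(self):
        nan = np.nan
        runs = [
            _mini_run([[[0.1, nan, nan]]], foreground=3),
            _mini_run([[[nan, 0.2, nan]]], foreground=3),
            _mini_run([[[0.1, nan, nan]]], foreground=3),
        ]
        res = average_runs(runs)
        fills = res.filling_per_run
        assert fills == sorted(fills)
        assert res.filling_percentage == pytest.approx(100 * 2 / 3)

    def test_change_statistics_on_running_mean(self):
        r1 = _mini_run([[[0.0, 0.4]]], foreground=2)
        r2 = _mini_run([[[0.2, 0.0]]], foreground=2)
        res = average_runs([r1, r2])
        # running mean moves from (0.0, 0.4) to (0.1, 0.2)
        assert res.median_change[2] == pytest.approx(0.15)
        assert res.maximum_change[2] == pytest.approx(0.2)

    def test_mismatched_dimensions_rejected(self):
        with pytest.raises(ValueError):
            average_runs([_mini_run([[[0.1]]]), _mini_run([[[0.1, 0.2]]])])


class TestSummaryStats:
    def test_uniform_grid_collapses(self):
        res = average_runs([_mini_run(np.full((2, 2, 2), 0.5, np.float32))])
        stats = summary_stats(res)
        assert stats["min EF"] == stats["max EF"] == stats["median EF"] == 0.5
        assert stats["mode EF"] == pytest.approx(0.5, abs=0.05)

    def test_median_of_symmetric_values(self):
        res = average_runs([_mini_run([[[-0.5, 0.0, 0.0, 0.5]]])])
        assert summary_stats(res)["median EF"] == 0.0

    def test_mode_bin_centre(self):
        vals = np.concatenate([np.full(60, 0.91), np.linspace(-1, 0.5, 40)])
        res = average_runs([_mini_run(vals.reshape(1, 1, -1).astype(np.float32))])
        mode = summary_stats(res, mode_bin_width=0.05)["mode EF"]
        assert 0.875 <= mode <= 0.925


class TestFlinnAndSecondary:
    def _run_with(self, ellipsoids, dims=(16, 16, 16)):
        return assign_ef(BinaryVolume(np.ones(dims, bool)), ellipsoids)

    def test_spheres_plot_at_unit_corner(self):
        run = self._run_with([Ellipsoid([7.5, 7.5, 7.5], [6, 6, 6])])
        data = flinn_data(run)
        np.testing.assert_allclose(data.peak_points, [[1.0, 1.0]])

    def test_isoline_identity_y_minus_x_is_ef(self, rng):
        ells = _random_ellipsoids(rng, (16, 16, 16), 8)
        run = self._run_with(ells)
        data = flinn_data(run)
        for (x, y), e in zip(data.all_points, run.ellipsoids):
            assert y - x == pytest.approx(ef_of_ellipsoid(e), abs=1e-12)

    def test_unclaiming_ellipsoid_absent_from_peak_plot(self):
        big = Ellipsoid([7.5, 7.5, 7.5], [8, 8, 8])
        hidden = Ellipsoid([7.5, 7.5, 7.5], [1, 1, 1])  # fully shadowed
        run = self._run_with([big, hidden])
        data = flinn_data(run)
        assert data.peak_points.shape[0] == 1
        assert data.all_points.shape[0] == 2

    def test_secondary_images_consistent(self, rng):
        ells = _random_ellipsoids(rng, (16, 16, 16), 6)
        run = self._run_with(ells)
        imgs = secondary_images(run)
        covered = ~np.isnan(run.ef_grid)
        np.testing.assert_allclose(
            run.ef_grid[covered],
            (imgs["a_b"] - imgs["b_c"])[covered],
            atol=1e-5,
        )
        # volume constant within one ellipsoid's claimed region
        for eid in np.unique(run.claim_id[run.claim_id >= 0]):
            region = run.claim_id == eid
            vals = imgs["volume"][region]
            assert np.allclose(vals, vals.flat[0], rtol=1e-6)
            assert imgs["volume"][region].flat[0] == pytest.approx(
                run.ellipsoids[eid].volume, rel=1e-6
            )
        ids = imgs["id"][covered]
        assert ids.min() >= 0 and ids.max() < len(run.ellipsoids)
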