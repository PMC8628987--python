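"""Imaging thresholds, boundary extraction, surface metrics, ICDF, threshold scan."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gliodensity as gd
from gliodensity.edema import (
    ImagingThresholds,
    boundary_distance_icdf,
    boundary_voxels,
    threshold_scan,
)
from gliodensity.grids import ScalarVolume, VoxelGrid

GRID8 = VoxelGrid((8, 8, 8), (1.0,) * 3)


class TestImagingThresholds:
    def test_defaults_and_ordering(self):
        th = ImagingThresholds()
        assert th.c_enhancing == 0.80 and th.c_edema == 0.16
        with pytest.raises(ValueError):
            ImagingThresholds(c_enhancing=0.1, c_edema=0.5)

    def test_mask_above_and_below_threshold(self):
        c = np.full((4, 4, 4), 0.5)
        assert gd.imaging_mask(c, 0.16).all()
        assert not gd.imaging_mask(c, 0.80).any()

    def test_ramp_field_boundary_at_level_set(self):
        # linear ramp: the mask edge sits within one voxel of the c=t plane
        shape = (40, 4, 4)
        c = np.linspace(0.0, 1.0, 40)[:, None, None] * np.ones((1, 4, 4))
        mask = gd.imaging_mask(c, 0.5)
        edge = np.nonzero(np.diff(mask[:, 0, 0].astype(int)))[0][0]
        analytic = 0.5 * 39  # index where the ramp crosses 0.5
        assert abs((edge + 1) - analytic) <= 1.0


def _brute_force_boundary(mask):
    out = set()
    shape = mask.shape
    for idx in np.argwhere(mask):
        i, j, k = idx
        for di, dj, dk in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            ni, nj, nk = i + di, j + dj, k + dk
            inside = 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]
            if not inside or not mask[ni, nj, nk]:
                out.add((i, j, k))
                break
    return out


class TestBoundaryVoxels:
    def test_single_voxel_is_its_own_boundary(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[3, 3, 3] = True
        b = boundary_voxels(mask, GRID8)
        assert len(b) == 1 and tuple(b.indices[0]) == (3, 3, 3)

    def test_cube_boundary_is_shell(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        b = boundary_voxels(mask, GRID8)
        assert len(b) == 26  # 3^3 minus the single interior voxel

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        mask = rng.random((8, 8, 8)) > 0.6
        mask[4, 4, 4] = True
        b = boundary_voxels(mask, GRID8)
        assert set(map(tuple, b.indices)) == _brute_force_boundary(mask)

    def test_ball_boundary_close_to_sphere_area(self):
        shape = (24, 24, 24)
        grid = VoxelGrid(shape, (1.0,) * 3)
        idx = np.indices(shape)
        r = np.sqrt(((idx - 11.5) ** 2).sum(axis=0))
        mask = r <= 10.0
        b = boundary_voxels(mask, grid)
        assert set(map(tuple, b.indices)) == _brute_force_boundary(mask)
        # face-count estimate: a digital sphere exposes ~6*pi*r^2 faces
        # (pi*r^2 per axis direction) at ~2 exposed faces per boundary
        # voxel, so the boundary holds ~3*pi*r^2 voxels
        estimate = 3 * np.pi * 100.0
        assert abs(len(b) - estimate) / estimate < 0.10

    def test_empty_and_full_masks_rejected(self):
        with pytest.raises(ValueError):
            boundary_voxels(np.zeros((4, 4, 4), bool), VoxelGrid((4, 4, 4), (1.0,) * 3))
        with pytest.raises(ValueError):
            boundary_voxels(np.ones((4, 4, 4), bool), VoxelGrid((4, 4, 4), (1.0,) * 3))

    def test_domain_restriction_ignores_foreign_tissue(self):
        # a mask filling its domain slab has no boundary against the slab's
        # non-domain sides, only against domain voxels beyond the mask
        mask = np.zeros((8, 8, 8), bool)
        mask[:, :, 2:4] = True
        domain = np.zeros((8, 8, 8), bool)
        domain[:, :, 2:6] = True
        b = boundary_voxels(mask, GRID8, domain=domain)
        assert (b.indices[:, 2] == 3).all()  # only the face adjacent to z=4


def _pair(n=40, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(0, 20, (n, 3)), rng.uniform(0, 20, (n, 3))


def _brute_hausdorff(a, b):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return max(d.min(axis=0).max(), d.min(axis=1).max())


def _brute_assd(a, b):
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return (d.min(axis=0).sum() + d.min(axis=1).sum()) / (len(a) + len(b))


class TestSurfaceMetrics:
    def test_identical_sets_give_zero(self):
        a, _ = _pair()
        assert gd.hausdorff(a, a) == 0.0
        assert gd.assd(a, a) == 0.0

    def test_two_point_example(self):
        a = np.array([[0.0, 0.0, 0.0]])
        b = np.array([[3.0, 0.0, 0.0]])
        assert gd.hausdorff(a, b) == pytest.approx(3.0)
        assert gd.assd(a, b) == pytest.approx(3.0)

    def test_asymmetric_configuration_brute_force(self):
        a = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        b = np.array([[0.0, 0.0, 0.0]])
        assert gd.hausdorff(a, b) == pytest.approx(10.0)
        a2 = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        b2 = np.array([[1.0, 0.0, 0.0]])
        assert gd.assd(a2, b2) == pytest.approx(1.0)  # (1 + 1 + 1) / 3

    @given(st.integers(0, 10))
    def test_matches_brute_force_and_identities(self, seed):
        a, b = _pair(seed=seed)
        h, s = gd.hausdorff(a, b), gd.assd(a, b)
        assert h == pytest.approx(_brute_hausdorff(a, b), rel=1e-12)
        assert s == pytest.approx(_brute_assd(a, b), rel=1e-12)
        assert h == pytest.approx(gd.hausdorff(b, a), rel=1e-12)
        assert s == pytest.approx(gd.assd(b, a), rel=1e-12)
        assert s <= h + 1e-12

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            gd.hausdorff(np.empty((0, 3)), np.zeros((1, 3)))


class TestBoundaryDistanceICDF:
    def test_iso_outline_is_step(self, phantom96, distance96, domain96):
        em = gd.make_edema_mask(distance96, "iso", 20.0)
        b = boundary_voxels(em.mask, phantom96.grid, domain=domain96)
        icdf = boundary_distance_icdf(b, distance96)
        assert icdf["range_mm"] <= phantom96.grid.voxel_diagonal_mm
        table = icdf["table"]
        assert table["fraction"].iloc[0] == 1.0
        assert (np.diff(table["fraction"]) <= 1e-12).all()
        assert (table["fraction"] >= 0).all() and (table["fraction"] <= 1).all()
        assert icdf["max_mm"] == table["x_mm"].iloc[-1]

    def test_perturbed_outline_is_not_step(self, phantom96, distance96, domain96):
        # derived contrast: the perturbed upper-tail gap dwarfs the iso one
        iso = gd.make_edema_mask(distance96, "iso", 20.0)
        per = gd.make_edema_mask(distance96, "perturbed", 20.0, 10.0, 15.0, seed=1)
        gaps = {}
        for name, em in [("iso", iso), ("perturbed", per)]:
            b = boundary_voxels(em.mask, phantom96.grid, domain=domain96)
            q = boundary_distance_icdf(b, distance96)["quantiles"]
            gaps[name] = q[0.01] - q[0.05]
        assert gaps["perturbed"] > 0.5
        assert gaps["perturbed"] > 10 * gaps["iso"]

    def test_all_infinite_distances_rejected(self):
        grid = VoxelGrid((6, 6, 6), (1.0,) * 3)
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        b = boundary_voxels(mask, grid)
        dmap = ScalarVolume(grid, np.full((6, 6, 6), np.inf))
        with pytest.raises(ValueError):
            boundary_distance_icdf(b, dmap)


class TestThresholdScan:
    def test_iso_self_match_recovers_threshold(self, distance96, domain96):
        em = gd.make_edema_mask(distance96, "iso", 20.0)
        scan = threshold_scan(distance96, em.mask, 1.0, None, 0.5, domain=domain96)
        diag = 0.5 * np.sqrt(3.0)
        assert abs(scan.best_t_hausdorff - 20.0) <= 0.5 + diag
        assert abs(scan.best_t_assd - 20.0) <= 0.5 + diag
        assert scan.min_hausdorff <= diag
        assert scan.min_assd <= diag

    def test_perturbed_hausdorff_min_far_exceeds_assd_min(self, distance96, domain96):
        em = gd.make_edema_mask(distance96, "perturbed", 20.0, 10.0, 15.0, seed=1)
        scan = threshold_scan(distance96, em.mask, 1.0, None, 0.5, domain=domain96)
        assert scan.min_hausdorff > 2.0 * scan.min_assd

    def test_halving_step_moves_argmin_at_most_one_coarse_step(self, distance96, domain96):
        em = gd.make_edema_mask(distance96, "iso", 20.0)
        coarse = threshold_scan(distance96, em.mask, 1.0, 28.0, 1.0, domain=domain96)
        fine = threshold_scan(distance96, em.mask, 1.0, 28.0, 0.5, domain=domain96)
        assert abs(fine.best_t_hausdorff - coarse.best_t_hausdorff) <= 1.0 + 1e-9
        assert abs(fine.best_t_assd - coarse.best_t_assd) <= 1.0 + 1e-9

    def test_invalid_step_rejected(self, distance96):
        with pytest.raises(ValueError):
            threshold_scan(distance96, np.ones(distance96.grid.shape, bool), step=0.0)
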