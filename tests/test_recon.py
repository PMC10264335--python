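"""Projector, attenuation, sensitivity map and list-mode MLEM."""

import math

import numpy as np
import pytest

from monopet import _kernels
from monopet.coincidence import CoincidenceList
from monopet.constants import WATER
from monopet.grids import ImageVolume, MuMap, VoxelGrid, voxelise_mu_map
from monopet.phantoms import CylinderZ, PhantomModel
from monopet.recon import (
    attenuation_factors,
    blur_lor_endpoints,
    compute_sensitivity_map,
    reconstruct_mlem,
    tof_sigma_mm,
)


def make_coinc(p1, p2, dt_ns=None):
    n = len(p1)
    position = np.stack([np.asarray(p1, float), np.asarray(p2, float)], axis=1)
    time = np.zeros((n, 2))
    if dt_ns is not None:
        time[:, 0] = np.asarray(dt_ns) / 2.0
        time[:, 1] = -np.asarray(dt_ns) / 2.0
    return CoincidenceList(
        np.tile([0, 140], (n, 1)).astype(np.int32),
        position,
        np.full((n, 2), 511.0, dtype=np.float32),
        time,
        np.zeros((n, 2), dtype=np.int64),
        np.zeros((n, 2), dtype=np.int16),
        np.zeros(n, dtype=np.int8),
    )


def random_lors(rng, n, radius=350.0, z=150.0):
    phi = rng.uniform(0, 2 * math.pi, n)
    z1 = rng.uniform(-z, z, n)
    z2 = rng.uniform(-z, z, n)
    p1 = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z1])
    p2 = np.column_stack([-radius * np.cos(phi), -radius * np.sin(phi), z2])
    return p1, p2


class TestProjector:
    def test_uniform_image_gives_chord_length(self):
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (32, 32, 32))
        x = np.ones(32 * 32 * 32)
        p1 = np.array([[-100.0, 5.0, 3.0]])
        p2 = np.array([[100.0, 5.0, 3.0]])
        out = _kernels.forward_project(
            p1, p2, *grid.origin, *grid.voxel_size, *grid.shape, x
        )
        assert out[0] == pytest.approx(64.0, rel=1e-9)  # 32 voxels x 2 mm

    def test_adjointness(self, rng):
        grid = VoxelGrid.centred((0, 0, 0), 3.0, (8, 9, 7))
        n = 60
        p1 = rng.uniform(-40, 40, (n, 3))
        p2 = rng.uniform(-40, 40, (n, 3))
        x = rng.uniform(0, 1, 8 * 9 * 7)
        y = rng.uniform(0, 1, n)
        px = _kernels.forward_project(
            p1, p2, *grid.origin, *grid.voxel_size, *grid.shape, x
        )
        bty = _kernels.back_project(
            p1, p2, *grid.origin, *grid.voxel_size, *grid.shape, y
        )
        assert np.dot(px, y) == pytest.approx(np.dot(x, bty), rel=1e-10)


class TestBlurEndpoints:
    def test_zero_fwhm_identity(self, geom_a):
        p1, p2 = random_lors(np.random.default_rng(0), 100)
        coinc = make_coinc(p1, p2)
        coinc.module[:] = [3 * 40, 3 * 40 + 20]
        out = blur_lor_endpoints(coinc, geom_a, 0.0, rng=1)
        assert np.array_equal(out.position, coinc.position)

    def test_blur_statistics_and_clamping(self, geom_a, rng):
        n = 30_000
        # endpoints at the centre of the central-ring module at azimuth 0
        p = np.tile([358.0, 0.0, 0.0], (n, 1))
        q = np.tile([-358.0, 0.0, 0.0], (n, 1))
        coinc = make_coinc(p, q)
        coinc.module[:, 0] = 3 * 40
        coinc.module[:, 1] = 3 * 40 + 20
        out = blur_lor_endpoints(coinc, geom_a, 1.15, rng)
        dz = out.position[:, 0, 2] - 0.0
        fwhm = np.std(dz) / (1.0 / 2.3548200450309493)
        assert fwhm == pytest.approx(1.15, rel=0.03)
        # all blurred endpoints stay inside their 16 mm slab
        depth = np.hypot(out.position[:, 0, 0], out.position[:, 0, 1])
        assert np.all(depth >= 350.0 - 1e-9)
        assert np.all(depth <= 366.0 + 1e-9)

    def test_negative_fwhm_rejected(self, geom_a):
        with pytest.raises(ValueError):
            blur_lor_endpoints(make_coinc([[0, 0, 0]], [[1, 1, 1]]), geom_a, -1.0)


class TestAttenuation:
    def test_vacuum_factor_is_one(self):
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (16, 16, 16))
        mu = MuMap(grid, np.zeros(grid.shape))
        f = attenuation_factors(
            np.array([[-100.0, 0, 0]]), np.array([[100.0, 0, 0]]), mu
        )
        assert f[0] == pytest.approx(1.0)

    def test_200mm_water(self):
        phantom = PhantomModel(
            [CylinderZ(WATER, 0.0, np.zeros(3), 100.0, 100.0)], [-1]
        )
        grid = VoxelGrid.centred((0, 0, 0), 1.0, (220, 220, 40))
        mu = voxelise_mu_map(phantom, grid)
        p1 = np.array([[-300.0, 0.0, 0.0]])
        p2 = np.array([[300.0, 0.0, 0.0]])
        f = attenuation_factors(p1, p2, mu)
        assert f[0] == pytest.approx(math.exp(-WATER.mu_511 * 200.0), rel=0.01)

    def test_direction_reversal_symmetric(self, rng):
        phantom = PhantomModel(
            [CylinderZ(WATER, 0.0, np.zeros(3), 80.0, 80.0)], [-1]
        )
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (90, 90, 90))
        mu = voxelise_mu_map(phantom, grid)
        p1, p2 = random_lors(rng, 50, z=60.0)
        assert np.allclose(
            attenuation_factors(p1, p2, mu), attenuation_factors(p2, p1, mu),
            rtol=1e-9,
        )


class TestSensitivityMap:
    def test_central_voxel_maximal_and_axially_symmetric(self, geom_a):
        grid = VoxelGrid.centred((0, 0, 0), (20.0, 20.0, 20.0), (3, 3, 17))
        sens = compute_sensitivity_map(geom_a, grid, n_directions=3000, rng=5)
        axis = sens.values[1, 1, :]
        assert np.argmax(axis) in (7, 8, 9)
        sym = np.abs(axis - axis[::-1]) / axis.max()
        assert np.all(sym < 0.1)

    def test_zero_map_refused(self, geom_a):
        # a grid far outside the scanner sees no coincidences at all
        grid = VoxelGrid((2000.0, 2000.0, 2000.0), (5.0, 5.0, 5.0), (4, 4, 4))
        with pytest.raises(ValueError):
            compute_sensitivity_map(geom_a, grid, n_directions=64, rng=0)

    def test_coarse_evaluation_close_to_fine(self, geom_a):
        grid = VoxelGrid.centred((0, 0, 0), 10.0, (12, 12, 12))
        fine = compute_sensitivity_map(geom_a, grid, n_directions=800, rng=2)
        coarse = compute_sensitivity_map(
            geom_a, grid, n_directions=800, rng=2, coarsen=2
        )
        inner = (slice(2, -2),) * 3
        rel = np.abs(coarse.values[inner] - fine.values[inner]) / fine.values.max()
        assert np.median(rel) < 0.05


class TestMLEM:
    def _point_data(self, rng, n=3000, origin=(0.0, 0.0, 0.0)):
        origin = np.asarray(origin)
        cos_t = rng.uniform(-0.3, 0.3, n)
        phi = rng.uniform(0, 2 * math.pi, n)
        sin_t = np.sqrt(1 - cos_t**2)
        d = np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
        p1 = origin + 400.0 * d
        p2 = origin - 400.0 * d
        return make_coinc(p1, p2)

    def test_point_recovery(self, rng):
        grid = VoxelGrid.centred((0, 0, 0), 1.0, (21, 21, 21))
        coinc = self._point_data(rng)
        sens = ImageVolume(grid, np.ones(grid.shape))
        res = reconstruct_mlem(coinc, grid, 10, sensitivity=sens)
        vals = res.image.values
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        assert peak == (10, 10, 10)
        neighbourhood = vals[8:13, 8:13, 8:13].sum()
        assert neighbourhood / vals.sum() > 0.9

    def test_count_conservation_and_nonnegativity(self, rng):
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (16, 16, 16))
        coinc = self._point_data(rng, n=500)
        sens = ImageVolume(grid, np.full(grid.shape, 0.7))
        res = reconstruct_mlem(coinc, grid, 5, sensitivity=sens, keep_snapshots=True)
        for snap in res.snapshots:
            assert np.all(snap >= 0)
            assert (snap * 0.7).sum() == pytest.approx(len(coinc), rel=1e-9)

    def test_likelihood_nondecreasing(self, rng):
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (16, 16, 16))
        coinc = self._point_data(rng, n=400)
        sens = ImageVolume(grid, np.ones(grid.shape))
        res = reconstruct_mlem(
            coinc, grid, 8, sensitivity=sens, track_likelihood=True
        )
        diffs = np.diff(res.log_likelihood)
        assert np.all(diffs > -1e-6)

    def test_tof_with_infinite_ctr_matches_plain_mlem(self, rng):
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (12, 12, 12))
        coinc = self._point_data(rng, n=400)
        sens = ImageVolume(grid, np.ones(grid.shape))
        plain = reconstruct_mlem(coinc, grid, 5, sensitivity=sens)
        tof = reconstruct_mlem(coinc, grid, 5, sensitivity=sens, tof_ctr_ps=1e9)
        denom = plain.image.values.max()
        assert np.allclose(
            tof.image.values / denom, plain.image.values / denom, atol=1e-6
        )

    def test_tof_kernel_width(self):
        # 200 ps CTR -> 30 mm FWHM localisation along the LOR
        assert tof_sigma_mm(200.0) * 2.3548200450309493 == pytest.approx(
            29.98, abs=0.01
        )

    def test_tof_localises_off_centre_source(self, rng):
        """TOF weighting shifts mass towards the annihilation estimate."""
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (32, 32, 8))
        n = 2000
        phi = rng.uniform(0, 2 * math.pi, n)
        d = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])
        origin = np.array([20.0, 0.0, 0.0])
        p1 = origin + 350.0 * d
        p2 = origin - 350.0 * d
        c = 299.792458
        dt = (
            np.linalg.norm(p1 - origin, axis=1)
            - np.linalg.norm(p2 - origin, axis=1)
        ) / c
        coinc = make_coinc(p1, p2, dt_ns=dt)
        sens = ImageVolume(grid, np.ones(grid.shape))
        res = reconstruct_mlem(coinc, grid, 4, sensitivity=sens, tof_ctr_ps=200.0)
        vals = res.image.values
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        x_peak = grid.voxel_centers()[0][peak[0]]
        assert abs(x_peak - 20.0) <= 4.0

    def test_empty_data_rejected(self, geom_a):
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (8, 8, 8))
        empty = make_coinc(np.zeros((0, 3)), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            reconstruct_mlem(empty, grid, 2, geom=geom_a)

    def test_zero_sensitivity_refused(self, rng):
        grid = VoxelGrid.centred((0, 0, 0), 2.0, (8, 8, 8))
        coinc = self._point_data(rng, n=50)
        sens = ImageVolume(grid, np.zeros(grid.shape))
        with pytest.raises(ValueError):
            reconstruct_mlem(coinc, grid, 2, sensitivity=sens)
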