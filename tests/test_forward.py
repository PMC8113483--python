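"""Jacobian assembly, Born projection, noise model, raw-scan layout."""

import numpy as np
import pytest

from iftomo import (
    OpticalProperties,
    RawScan,
    ScanGeometry,
    VoxelGrid,
    add_noise,
    assemble_jacobian,
    diffusion_green,
    forward_project,
    measurement_size,
    normalize_by_power,
)


@pytest.fixture(scope="module")
def small_model(tissue_props):
    grid = VoxelGrid(extent=(2.0, 2.0, 1.0), voxel_size=(0.25, 0.25, 0.25))
    geom = ScanGeometry(fov=(2.0, 2.0), scan_step=0.5, detector_grid=(3, 3),
                        detector_pitch=0.5)
    model = assemble_jacobian(tissue_props, geom, grid, engine="diffusion")
    return geom, grid, model


class TestJacobianAssembly:
    def test_shape_and_nonnegativity(self, small_model):
        geom, grid, model = small_model
        assert model.shape == (measurement_size(geom), grid.n_voxels)
        assert (model.matrix >= 0).all()
        assert not np.any(np.all(model.matrix == 0, axis=1))  # no all-zero rows

    def test_entries_are_green_function_products(self, small_model, tissue_props):
        """Independent re-derivation: one entry equals the voxel-averaged
        excitation Green times the voxel-averaged adjoint emission Green
        times the voxel volume."""
        geom, grid, model = small_model
        sources = geom.scan_positions()
        si, di = 7, 3  # arbitrary source / included-detector indices
        det = model.detectors[di]
        r0, c0 = geom.center_detector_index
        off = ((det[1] - c0) * geom.detector_pitch, (det[0] - r0) * geom.detector_pitch)
        det_pos = sources[si] + np.asarray(off)
        xs, ys, zs = grid.centers()
        vi = (1, 3, 2)  # (iz, iy, ix)
        sub = (np.arange(2) + 0.5) / 2 - 0.5
        pts = np.array(
            [
                (
                    xs[vi[2]] + ox * grid.voxel_size[0],
                    ys[vi[1]] + oy * grid.voxel_size[1],
                    zs[vi[0]] + oz * grid.voxel_size[2],
                )
                for ox in sub for oy in sub for oz in sub
            ]
        )
        gx = diffusion_green(tissue_props, (*sources[si], 0.0), pts).mean()
        gm = diffusion_green(tissue_props, (*det_pos, 0.0), pts).mean()
        col = np.ravel_multi_index(vi, grid.shape)
        row = si * len(model.detectors) + di
        assert model.matrix[row, col] == pytest.approx(
            gx * gm * grid.voxel_volume, rel=1e-9
        )

    def test_deeper_voxel_less_sensitive_at_small_separation(self, small_model):
        geom, grid, model = small_model
        nz, ny, nx = grid.shape
        A3 = model.matrix.reshape(model.shape[0], nz, ny, nx)
        # source 7 sits at (1.5, 0.5); nearest detector offset 0.5 mm
        col = A3[7 * len(model.detectors) + 1, :, 2, 2]
        assert np.all(np.diff(col[1:]) < 0)

    def test_sensitivity_depth_increases_with_separation(self, tissue_props):
        """Wider source-detector separations collect photons that
        travelled deeper: the depth of the maximally sensitive voxel is
        non-decreasing in separation."""
        grid = VoxelGrid(extent=(3.0, 3.0, 2.0), voxel_size=(0.25, 0.25, 0.1))
        geom = ScanGeometry(fov=(0.0, 0.0), scan_step=1.0, detector_grid=(1, 7),
                            detector_pitch=0.5, exclude_center=False)
        model = assemble_jacobian(tissue_props, geom, grid, engine="diffusion")
        _xs, _ys, zs = grid.centers()
        seps, depths = [], []
        r0, c0 = geom.center_detector_index
        for di, det in enumerate(model.detectors):
            sep = abs(det[1] - c0) * geom.detector_pitch
            col = model.matrix[di].reshape(grid.shape)
            depths.append(zs[np.unravel_index(np.argmax(col), grid.shape)[0]])
            seps.append(sep)
        order = np.argsort(seps)
        d = np.asarray(depths)[order]
        assert np.all(np.diff(d) >= 0)

    def test_mc_and_diffusion_jacobians_agree(self, tissue_props):
        """The two transport engines give consistent sensitivities on a
        coarse wide-separation geometry: median relative deviation over
        entries above 1% of the column max is below 15%."""
        grid = VoxelGrid(extent=(3.0, 3.0, 1.2), voxel_size=(0.5, 0.5, 0.2))
        geom = ScanGeometry(fov=(0.0, 0.0), scan_step=1.0, detector_grid=(3, 3),
                            detector_pitch=1.0)
        Ad = assemble_jacobian(tissue_props, geom, grid, engine="diffusion")
        Am = assemble_jacobian(tissue_props, geom, grid, engine="mc",
                               photons=100_000, seed=7)
        D, M = Ad.matrix, Am.matrix
        mask = D > 0.01 * D.max(axis=0, keepdims=True)
        rel = np.abs(M[mask] - D[mask]) / D[mask]
        assert np.median(rel) < 0.15

    def test_unknown_engine_rejected(self, tissue_props, small_grid, small_geometry):
        with pytest.raises(ValueError):
            assemble_jacobian(tissue_props, small_geometry, small_grid, engine="fem")


class TestForwardProjection:
    def test_zero_map_projects_to_zero(self, small_model):
        _geom, grid, model = small_model
        assert np.all(forward_project(model, np.zeros(grid.shape)) == 0)

    def test_exact_linearity_and_superposition(self, small_model):
        _geom, grid, model = small_model
        rng = np.random.default_rng(0)
        x1 = rng.random(grid.shape)
        x2 = rng.random(grid.shape)
        b1, b2 = forward_project(model, x1), forward_project(model, x2)
        assert np.allclose(forward_project(model, 10.0 * x1), 10.0 * b1, rtol=1e-13)
        assert np.allclose(forward_project(model, x1 + x2), b1 + b2, rtol=1e-12)

    def test_grid_mismatch_rejected(self, small_model):
        _geom, _grid, model = small_model
        with pytest.raises(ValueError, match="grid"):
            forward_project(model, np.zeros((2, 2, 2)))


class TestNoise:
    def test_zero_level_is_identity(self):
        b = np.linspace(0, 5, 20)
        assert np.array_equal(add_noise(b, "gaussian_relative", 0.0, seed=1), b)
        assert np.array_equal(add_noise(b, "shot", 0.0, seed=1), b)

    def test_relative_gaussian_calibrated(self):
        """Per-element scatter of the noise generator matches the nominal
        1% relative level over many repetitions."""
        b = np.full(3, 100.0)
        draws = np.stack(
            [add_noise(b, "gaussian_relative", 0.01, seed=s) for s in range(10_000)]
        )
        rel_sd = draws.std(axis=0) / draws.mean(axis=0)
        assert np.allclose(rel_sd, 0.01, rtol=0.10)

    def test_same_seed_identical(self):
        b = np.linspace(0.1, 3, 50)
        a1 = add_noise(b, "gaussian_relative", 0.05, seed=3)
        a2 = add_noise(b, "gaussian_relative", 0.05, seed=3)
        assert np.array_equal(a1, a2)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.ones(3), "salt_pepper", 0.1)


class TestRawScanLayout:
    def _scan(self, geom, seed=0):
        rng = np.random.default_rng(seed)
        shape = geom.scan_shape + tuple(geom.detector_grid)
        return RawScan(data=rng.random(shape), geometry=geom)

    def test_vector_round_trip_preserves_corners(self):
        geom = ScanGeometry(fov=(1.0, 1.0), scan_step=0.5)
        scan = self._scan(geom)
        b = scan.to_vector()
        assert b.size == measurement_size(geom)
        back = RawScan.from_vector(b, geom,
                                   center_image=scan.center_detector_image())
        ny, nx = geom.scan_shape
        rows, cols = geom.detector_grid
        for sy, sx in [(0, 0), (0, nx - 1), (ny - 1, 0), (ny - 1, nx - 1)]:
            for dr, dc in [(0, 0), (0, cols - 1), (rows - 1, 0), (rows - 1, cols - 1),
                           geom.center_detector_index]:
                assert back.data[sy, sx, dr, dc] == scan.data[sy, sx, dr, dc]

    def test_excluded_center_not_in_vector(self):
        geom = ScanGeometry(fov=(0.5, 0.5), scan_step=0.5)
        scan = self._scan(geom)
        b = scan.to_vector()
        # zeroing the centre detector does not change the vector
        scan.data[:, :, 3, 3] = 0.0
        assert np.array_equal(scan.to_vector(), b)

    def test_power_normalization(self):
        geom = ScanGeometry(fov=(0.5, 0.5), scan_step=0.5)
        scan = self._scan(geom)
        assert np.array_equal(normalize_by_power(scan, 1.0).data, scan.data)
        doubled = RawScan(data=2.0 * scan.data, geometry=geom)
        assert np.allclose(normalize_by_power(doubled, 2.0).data, scan.data)
        for power in [1.0, 2.0, 5.0]:  # the instrument's stated power range
            assert np.allclose(
                normalize_by_power(RawScan(data=power * scan.data, geometry=geom),
                                   power).data,
                scan.data,
            )

    def test_zero_power_rejected(self):
        geom = ScanGeometry(fov=(0.5, 0.5), scan_step=0.5)
        with pytest.raises(ValueError):
            normalize_by_power(self._scan(geom), 0.0)
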