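"""Histology extrapolation, calibration fit, integrated signal, volumes
and longitudinal summaries."""

import numpy as np
import pytest

from iftomo import (
    CalibrationModel,
    ReconVolume,
    SliceCount,
    ThresholdReport,
    VoxelGrid,
    estimate_slice_cells,
    fit_calibration,
    integrated_signal,
    longitudinal_summary,
    tumor_total_cells,
    tumor_volume,
)

GRID = VoxelGrid(extent=(2.0, 2.0, 1.0), voxel_size=(0.25, 0.25, 0.1))


def _recon(values):
    return ReconVolume(values=np.asarray(values, dtype=float), grid=GRID, lam=0.0)


def _report(mask):
    mask = np.asarray(mask, dtype=bool)
    return ThresholdReport(
        thresholds=np.array([0.0]), mi_values=np.array([0.0]),
        chosen_threshold=0.0, mask=mask, surviving_voxels=int(mask.sum()),
    )


class TestSliceExtrapolation:
    @pytest.mark.parametrize(
        "a1,a2,c,expected",
        [(1.0, 0.1, 500, 5000.0), (0.7, 0.7, 123, 123.0), (2.0, 0.5, 100, 400.0)],
    )
    def test_density_extrapolation(self, a1, a2, c, expected):
        assert estimate_slice_cells(a1, a2, c) == pytest.approx(expected)

    def test_density_invariance(self):
        assert estimate_slice_cells(1.0, 0.1, 500) == estimate_slice_cells(
            1.0, 0.2, 1000
        )

    def test_subarea_larger_than_tumor_rejected(self):
        with pytest.raises(ValueError):
            estimate_slice_cells(0.5, 0.6, 100)
        with pytest.raises(ValueError):
            SliceCount(a1=0.5, a2=0.6, c_sub=100)

    def test_single_slice_total(self):
        s = SliceCount(a1=1.0, a2=0.25, c_sub=200)
        assert tumor_total_cells([s]) == pytest.approx(800.0)

    def test_empty_slice_list_rejected(self):
        with pytest.raises(ValueError):
            tumor_total_cells([])


class TestSyntheticHistologyOracle:
    """Virtual sectioning of a simulated nucleus cloud: the A1/A2/C_sub
    extrapolation recovers the true count at homogeneous density and shows
    the expected bias under density heterogeneity."""

    SLICE_UM = 4.5

    def _section(self, nuclei, extent, sub_half, rng):
        """Slice a nucleus cloud and extrapolate per-slice counts from a
        sub-area of half width ``sub_half`` (area fraction (2*sub_half)^2 /
        extent^2 of the slice)."""
        a1 = extent * extent
        a2 = (2 * sub_half) ** 2
        dz = self.SLICE_UM * 1e-3
        edges = np.arange(0.0, nuclei[:, 2].max() + dz, dz)
        slices = []
        cx = cy = extent / 2.0
        for z0 in edges:
            inside = (nuclei[:, 2] >= z0) & (nuclei[:, 2] < z0 + dz)
            sub = inside & (np.abs(nuclei[:, 0] - cx) < sub_half) & (
                np.abs(nuclei[:, 1] - cy) < sub_half
            )
            if sub.sum() == 0:
                continue
            slices.append(SliceCount(a1=a1, a2=a2, c_sub=int(sub.sum()),
                                     thickness_um=self.SLICE_UM))
        return slices

    def test_homogeneous_density_recovered_within_ten_percent(self):
        rng = np.random.default_rng(0)
        extent, depth, n = 1.0, 0.5, 60_000
        nuclei = rng.random((n, 3)) * [extent, extent, depth]
        slices = self._section(nuclei, extent, sub_half=0.25, rng=rng)
        total = tumor_total_cells(slices)
        assert total == pytest.approx(n, rel=0.10)

    def test_heterogeneous_density_biases_estimate(self):
        """Doubling the density in the sampled region relative to the rest
        inflates the extrapolation by ~1/3 — the order of the stated
        20-30% uncertainty of the histology route."""
        rng = np.random.default_rng(1)
        extent, depth = 1.0, 0.5
        sub_half = extent * np.sqrt(0.5) / 2  # sampled area = half the slice
        n_in, n_out = 40_000, 20_000  # 2x density inside the sampled window
        cx = extent / 2.0
        inside = np.column_stack([
            cx + (rng.random(n_in) - 0.5) * 2 * sub_half,
            cx + (rng.random(n_in) - 0.5) * 2 * sub_half,
            rng.random(n_in) * depth,
        ])
        rest = []
        while len(rest) < n_out:
            p = rng.random(3) * [extent, extent, depth]
            if not (abs(p[0] - cx) < sub_half and abs(p[1] - cx) < sub_half):
                rest.append(p)
        nuclei = np.vstack([inside, np.array(rest)])
        slices = self._section(nuclei, extent, sub_half=sub_half, rng=rng)
        bias = tumor_total_cells(slices) / len(nuclei) - 1.0
        assert 0.20 <= bias <= 0.45


class TestCalibration:
    def test_exact_line(self):
        pairs = [(x, 2.0 * x) for x in [1.0, 2.0, 3.0, 4.0]]
        cal = fit_calibration(pairs)
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(0.0, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.rmse == pytest.approx(0.0, abs=1e-9)

    def test_noisy_slope_recovery(self):
        """n=8 pairs from a 3e4 cells/a.u. law with 5% noise recover the
        slope within 10%."""
        rng = np.random.default_rng(7)
        slope = 3e4
        sig = np.linspace(1.0, 20.0, 8)
        cells = slope * sig * (1 + 0.05 * rng.standard_normal(8))
        cal = fit_calibration(np.column_stack([sig, cells]))
        assert cal.slope == pytest.approx(slope, rel=0.10)
        assert cal.n == 8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        pairs = np.column_stack([np.arange(1.0, 9.0), rng.random(8) * 100])
        c1 = fit_calibration(pairs)
        c2 = fit_calibration(pairs[rng.permutation(8)])
        assert c1.slope == pytest.approx(c2.slope)
        assert c1.rmse == pytest.approx(c2.rmse)

    def test_round_trip_machine_precision(self):
        pairs = [(x, 5.0 * x + 3.0) for x in np.linspace(0.5, 9.0, 6)]
        cal = fit_calibration(pairs)
        assert cal.slope == pytest.approx(5.0, rel=1e-12)
        assert cal.intercept == pytest.approx(3.0, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 2.0), (1.0, 3.0)])
        with pytest.raises(ValueError):
            fit_calibration([(2.0, 1.0), (2.0, 2.0), (2.0, 3.0)])


class TestSignalAndVolume:
    def test_empty_mask_zero(self):
        recon = _recon(np.ones(GRID.shape))
        report = _report(np.zeros(GRID.shape))
        assert integrated_signal(recon, report) == 0.0
        assert tumor_volume(recon, report) == 0.0

    def test_scaling_and_single_voxel(self):
        vol = np.zeros(GRID.shape)
        vol[3, 2, 1] = 4.2
        recon = _recon(vol)
        report = _report(vol > 0)
        assert integrated_signal(recon, report) == pytest.approx(4.2)
        assert integrated_signal(_recon(3.0 * vol), report) == pytest.approx(3 * 4.2)
        assert tumor_volume(recon, report) == pytest.approx(GRID.voxel_volume)

    def test_volume_arithmetic_full_grid(self):
        grid = VoxelGrid(extent=(10.0, 10.0, 2.0), voxel_size=(0.25, 0.25, 0.1))
        recon = ReconVolume(values=np.ones(grid.shape), grid=grid, lam=0.0)
        mask = np.ones(grid.shape, dtype=bool)
        report = ThresholdReport(
            thresholds=np.array([0.0]), mi_values=np.array([0.0]),
            chosen_threshold=0.0, mask=mask, surviving_voxels=int(mask.sum()),
        )
        assert tumor_volume(recon, report) == pytest.approx(200.0)

    def test_integrated_signal_invariant_to_voxel_order(self):
        rng = np.random.default_rng(9)
        vol = rng.random(GRID.shape)
        mask = vol > 0.5
        sig = integrated_signal(_recon(vol), _report(mask))
        perm = rng.permutation(vol.size)
        vol_p = vol.ravel()[perm].reshape(GRID.shape)
        mask_p = mask.ravel()[perm].reshape(GRID.shape)
        assert integrated_signal(_recon(vol_p), _report(mask_p)) == pytest.approx(sig)


class TestLongitudinal:
    def _series_from_maps(self, maps):
        out = []
        for m in maps:
            m = np.asarray(m, dtype=float)
            out.append((_recon(m), _report(m > 0)))
        return out

    def test_flat_series_fold_change_one(self):
        vol = np.zeros(GRID.shape)
        vol[2, 2:4, 2:4] = 5.0
        series = self._series_from_maps([vol] * 4)
        summaries = longitudinal_summary(series)
        sigs = [s.integrated_signal for s in summaries]
        assert np.allclose(sigs, sigs[0])
        assert all(s.normalized_volume == pytest.approx(1.0) for s in summaries)

    def test_volume_constant_while_count_grows(self):
        """Count/volume decoupling: densifying a fixed-shape tumor raises
        the calibrated count but leaves normalized volume at 1."""
        base = np.zeros(GRID.shape)
        base[2:5, 2:5, 2:5] = 1.0
        series = self._series_from_maps([base, 3.0 * base, 9.0 * base])
        cal = CalibrationModel(slope=100.0, intercept=0.0, r_squared=1.0,
                               rmse=0.0, n=8)
        summaries = longitudinal_summary(series, calibration=cal)
        counts = [s.cell_count for s in summaries]
        assert counts[1] == pytest.approx(3 * counts[0])
        assert all(s.normalized_volume == pytest.approx(1.0) for s in summaries)

    def test_first_timepoint_is_volume_baseline(self):
        a = np.zeros(GRID.shape); a[2, 2:6, 2:6] = 1.0
        b = np.zeros(GRID.shape); b[2:4, 2:6, 2:6] = 1.0
        summaries = longitudinal_summary(self._series_from_maps([a, b]))
        assert summaries[0].normalized_volume == pytest.approx(1.0)
        assert summaries[1].normalized_volume == pytest.approx(2.0)

    def test_single_timepoint_rejected(self):
        vol = np.ones(GRID.shape)
        with pytest.raises(ValueError):
            longitudinal_summary(self._series_from_maps([vol]))
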