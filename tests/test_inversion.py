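"""L1 solver oracle checks, L-curve selection and MI fine-tuning."""

import numpy as np
import pytest

from iftomo import (
    OpticalProperties,
    ScanGeometry,
    VoxelGrid,
    assemble_jacobian,
    fista,
    forward_project,
    l_curve_select,
    mi_fine_tune,
    solve_l1,
)
from iftomo.pipeline import default_lambda_candidates


def ista_oracle(A, b, lam, n_iter=100_000, nonneg=True):
    """Independent slow proximal-descent reference (plain ISTA, fixed
    conservative step), deliberately separate from the package solver."""
    L = 2.0 * np.linalg.norm(A, ord=2) ** 2
    t = 1.0 / (L * 1.05)
    x = np.zeros(A.shape[1])
    for _ in range(n_iter):
        x = x - t * 2.0 * (A.T @ (A @ x - b))
        if nonneg:
            x = np.maximum(x - lam * t, 0.0)
        else:
            x = np.sign(x) * np.maximum(np.abs(x) - lam * t, 0.0)
    r = A @ x - b
    return x, float(r @ r + lam * np.abs(x).sum())


def objective(A, b, x, lam):
    r = A @ x - b
    return float(r @ r + lam * np.abs(x).sum())


class TestFista:
    def test_orthogonal_columns_lambda_zero_recovers_least_squares(self):
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 10)))
        x0 = rng.random(10)  # non-negative ground truth
        b = Q @ x0
        x, trace = fista(Q, b, 0.0, tol=1e-15, max_iter=50)
        assert np.allclose(x, x0, atol=1e-12)

    def test_null_threshold_gives_exact_zero(self):
        """lambda >= ||2 A^T b||_inf makes x = 0 the exact minimizer of
        ||Ax-b||^2 + lambda ||x||_1."""
        rng = np.random.default_rng(1)
        A = rng.normal(size=(20, 50))
        b = rng.normal(size=20)
        lam = float(np.abs(2.0 * A.T @ b).max())
        x, _ = fista(A, b, lam, nonneg=False, max_iter=200)
        assert np.all(x == 0.0)
        xn, _ = fista(A, b, lam, nonneg=True, max_iter=200)
        assert np.all(xn == 0.0)

    @pytest.mark.parametrize("lam_frac", [0.02, 0.1, 0.3])
    def test_matches_slow_oracle_on_random_system(self, lam_frac):
        rng = np.random.default_rng(42)
        A = rng.normal(size=(20, 50))
        x_true = np.zeros(50)
        x_true[rng.choice(50, 5, replace=False)] = rng.random(5) + 0.5
        b = A @ x_true + 0.01 * rng.normal(size=20)
        lam = lam_frac * float(np.abs(2.0 * A.T @ b).max())
        x, trace = fista(A, b, lam, tol=1e-14, max_iter=20_000)
        _, obj_oracle = ista_oracle(A, b, lam, n_iter=100_000)
        assert trace[-1] == pytest.approx(obj_oracle, rel=1e-6)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(30, 60))
        b = rng.normal(size=30)
        _, trace = fista(A, b, 1.0, nonneg=False, max_iter=500)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(15, 30))
        b = rng.normal(size=15)
        x1, _ = fista(A, b, 0.5, max_iter=300)
        x2, _ = fista(A, b, 0.5, max_iter=300)
        assert np.array_equal(x1, x2)

    def test_invalid_arguments_rejected(self):
        A = np.eye(3)
        with pytest.raises(ValueError):
            fista(A, np.ones(3), -1.0)
        with pytest.raises(ValueError):
            fista(A, np.ones(2), 1.0)


@pytest.fixture(scope="module")
def toy_model(tissue_props):
    """Small diffusion-engine model with a sparse ground truth."""
    grid = VoxelGrid(extent=(2.0, 2.0, 1.0), voxel_size=(0.25, 0.25, 0.25))
    geom = ScanGeometry(fov=(2.0, 2.0), scan_step=0.5, detector_grid=(3, 3),
                        detector_pitch=0.5)
    model = assemble_jacobian(tissue_props, geom, grid, engine="diffusion")
    x_true = np.zeros(grid.shape)
    x_true[2, 4, 4] = 50.0
    x_true[2, 3, 4] = 30.0
    b = forward_project(model, x_true)
    return model, x_true, b


class TestLCurve:
    def test_noiseless_data_selects_low_lambda_and_recovers_support(self, toy_model):
        model, x_true, b = toy_model
        cands = default_lambda_candidates(model, b, n=7)
        lam, sched = l_curve_select(model, b, cands, tol=1e-8)
        assert lam <= np.median(cands)
        vol = solve_l1(model, b, lam, tol=1e-8)
        support_true = x_true.ravel() > 0
        assert np.all(vol.values.ravel()[support_true] > 0)

    def test_pure_noise_selects_upper_range(self, toy_model):
        model, _x, b = toy_model
        rng = np.random.default_rng(0)
        noise = np.abs(rng.normal(size=b.shape)) * b.mean()
        cands = default_lambda_candidates(model, noise, n=7)
        lam, _ = l_curve_select(model, noise, cands)
        vol = solve_l1(model, noise, lam)
        # heavily regularized: solution shrunk well below the light-lambda fit
        lo = solve_l1(model, noise, float(cands[0]))
        assert lam >= np.median(cands)
        assert vol.l1_norm <= 0.75 * lo.l1_norm

    def test_single_candidate_returned(self, toy_model):
        model, _x, b = toy_model
        lam, sched = l_curve_select(model, b, np.array([0.123]))
        assert lam == 0.123
        assert sched.stage == "l_curve"

    def test_l1_norm_non_increasing_in_lambda(self, toy_model):
        """Solution-path monotonicity over the candidate grid."""
        model, _x, b = toy_model
        cands = default_lambda_candidates(model, b, n=6)
        _, sched = l_curve_select(model, b, cands, tol=1e-8)
        assert np.all(np.diff(sched.l1_norms) <= 1e-6 * sched.l1_norms[0])


class TestMiFineTune:
    def _reference(self, model, x_true):
        from iftomo.postprocess import mip

        # noiseless projection image stands in for the raw reference
        return mip(x_true if x_true.ndim == 3 else x_true.reshape(model.grid.shape))

    def test_single_factor_returns_initial(self, toy_model):
        model, x_true, b = toy_model
        ref = self._reference(model, x_true)
        lam, sched, _vol = mi_fine_tune(model, b, 0.01, ref, factors=(1.0,))
        assert lam == 0.01
        assert sched.stage == "mi_fine_tune"

    def test_chosen_lambda_beats_extreme_scalings(self, toy_model):
        """On a synthetic fixture the fine-tuned lambda attains at least
        the MI of gross over/under-regularization."""
        from iftomo.postprocess import mi_threshold_scan

        model, x_true, b = toy_model
        ref = self._reference(model, x_true)
        cands = default_lambda_candidates(model, b, n=7)
        lam0, _ = l_curve_select(model, b, cands)
        lam, sched, vol = mi_fine_tune(model, b, lam0, ref)
        mi_star = sched.mi_scores.max()
        for factor in (10.0, 0.1):
            other = solve_l1(model, b, factor * lam)
            if np.all(other.values == 0):
                continue
            mi_other = mi_threshold_scan(other.values, ref).mi_values.max()
            assert mi_star >= mi_other - 1e-12

    def test_tie_broken_toward_initial(self, toy_model, monkeypatch):
        model, _x, b = toy_model
        import iftomo.inversion as inv_mod

        # identical MI for every candidate -> the factor-1 lambda must win
        def fake_scan(values, reference, n_thresholds=50):
            from iftomo.postprocess import ThresholdReport

            return ThresholdReport(
                thresholds=np.array([0.0]), mi_values=np.array([0.7]),
                chosen_threshold=0.0, mask=values > -1, surviving_voxels=values.size,
            )

        monkeypatch.setattr("iftomo.postprocess.mi_threshold_scan", fake_scan)
        lam, _sched, _vol = mi_fine_tune(model, b, 0.05, np.zeros((8, 8)))
        assert lam == pytest.approx(0.05)

    def test_over_regularized_raises(self, toy_model):
        model, _x, b = toy_model
        lam_huge = float(np.abs(2.0 * model.matrix.T @ b).max()) * 10
        with pytest.raises(RuntimeError, match="over-regularized"):
            mi_fine_tune(model, b, lam_huge, np.zeros((8, 8)),
                         factors=(1.0, 2.0, 4.0))
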