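"""TpV ADM solver: p-shrinkage, operators, subproblem solvers, and the
p = 1 equivalence with an independent TV-ADM implementation."""

import numpy as np
import pytest

from cbctrec.geometry import (ConeBeamGeometry, ProjectionSet, SiddonProjector,
                              Volume, VolumeGrid, forward_project)
from cbctrec.tpv import (TpVParams, div, estimate_operator_norm, grad,
                         laplacian_eigenvalues, p_shrink, p_shrink_signed,
                         project_data_ball, shrink_gradient,
                         solve_x_subproblem, tpv_reconstruct)

from tv_admm_reference import tv_admm_reconstruct


def _prox_oracle(t, beta, p):
    """Dense grid search + local refinement for argmin 0.5*beta*(u-t)^2 + u^p
    over u >= 0 (the exact l_p proximal point)."""
    def f(u):
        return 0.5 * beta * (u - t) ** 2 + u ** p

    grid = np.linspace(0.0, max(2 * t, 1.0), 200_001)
    best = grid[np.argmin(f(grid))]
    lo, hi = max(best - 1e-4, 0.0), best + 1e-4
    for _ in range(80):
        m1 = lo + (hi - lo) / 3
        m2 = hi - (hi - lo) / 3
        if f(m1) < f(m2):
            hi = m2
        else:
            lo = m1
    refined = 0.5 * (lo + hi)
    return refined if f(refined) < f(0.0) else 0.0


class TestPShrink:
    def test_zero_maps_to_zero(self):
        for beta, p in [(0.5, 1.0), (2.0, 0.9), (10.0, 0.5)]:
            assert p_shrink(0.0, beta, p) == 0.0

    def test_p1_is_soft_thresholding(self):
        assert p_shrink(1.0, 2.0, 1.0) == pytest.approx(0.5)
        ts = np.linspace(0, 3, 50)
        np.testing.assert_allclose(p_shrink(ts, 2.0, 1.0),
                                   np.maximum(ts - 0.5, 0.0))

    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_p09_close_to_exact_proximal_point(self, t):
        # the generalized shrinkage is a one-step surrogate of the exact
        # l_p prox; agreement is within ~2% of max(t, 1) at these scales
        s = p_shrink(t, 10.0, 0.9)
        exact = _prox_oracle(t, 10.0, 0.9)
        assert abs(s - exact) <= 0.02 * max(t, 1.0)

    def test_signed_variant_restores_sign(self, rng):
        x = rng.standard_normal(100)
        out = p_shrink_signed(x, 3.0, 0.9)
        np.testing.assert_allclose(np.abs(out), p_shrink(np.abs(x), 3.0, 0.9))
        assert np.all(out * x >= 0)

    def test_never_increases_magnitude(self, rng):
        t = rng.random(1000) * 10
        assert np.all(p_shrink(t, 5.0, 0.9) <= t)

    def test_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            p_shrink(-1.0, 2.0, 0.9)


class TestGradDiv:
    def test_constant_volume_has_zero_gradient(self):
        assert np.all(grad(np.full((6, 6, 6), 2.5)) == 0)

    def test_adjointness(self, rng):
        x = rng.standard_normal((7, 8, 9))
        z = rng.standard_normal((3, 7, 8, 9))
        lhs = float((grad(x) * z).sum())
        rhs = -float((x * div(z)).sum())
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_single_voxel_step_support(self):
        x = np.zeros((6, 6, 6))
        x[2, 3, 3] = 1.0
        g0 = grad(x)[0]
        assert np.count_nonzero(g0) == 2

    def test_laplacian_eigenvalues_match_operator(self, rng):
        shape = (4, 5, 6)
        x = rng.standard_normal(shape)
        lap = -div(grad(x))  # grad^T grad
        via_fft = np.fft.ifftn(np.fft.fftn(x) * laplacian_eigenvalues(shape)).real
        np.testing.assert_allclose(lap, via_fft, atol=1e-10)


class TestSubproblems:
    def test_z_update_zero_for_constant_x(self):
        v = grad(np.full((5, 5, 5), 1.0))
        assert np.all(shrink_gradient(v, 10.0, 0.9) == 0)

    def test_z_update_p1_equals_isotropic_soft_threshold(self, rng):
        v = rng.standard_normal((3, 6, 6, 6))
        beta = 4.0
        out = shrink_gradient(v, beta, 1.0)
        mag = np.sqrt((v ** 2).sum(axis=0))
        scale = np.where(mag > 0, np.maximum(mag - 1 / beta, 0) /
                         np.where(mag > 0, mag, 1), 0.0)
        np.testing.assert_allclose(out, v * scale[None], atol=1e-12)

    def test_shrinkage_never_increases_per_voxel_magnitude(self, rng):
        v = rng.standard_normal((3, 6, 6, 6))
        out = shrink_gradient(v, 2.0, 0.9)
        assert np.all(np.sqrt((out ** 2).sum(0))
                      <= np.sqrt((v ** 2).sum(0)) + 1e-12)

    def test_x_solve_matches_dense_solve(self, rng):
        shape = (8, 8, 8)
        beta1, beta2tau = 3.0, 7.0
        n = np.prod(shape)
        # assemble the dense operator column by column
        M = np.empty((n, n))
        for j in range(n):
            ej = np.zeros(n)
            ej[j] = 1.0
            ejv = ej.reshape(shape)
            M[:, j] = (beta1 * (-div(grad(ejv))) + beta2tau * ejv).ravel()
        rhs = rng.standard_normal(shape)
        J = beta1 * laplacian_eigenvalues(shape) + beta2tau
        via_fft = solve_x_subproblem(rhs, J)
        dense = np.linalg.solve(M, rhs.ravel()).reshape(shape)
        np.testing.assert_allclose(via_fft, dense, rtol=1e-8, atol=1e-10)

    def test_data_ball_projection(self, rng):
        r = rng.standard_normal(50)
        r *= 2.0 / np.linalg.norm(r)  # ||r|| = 2
        e = project_data_ball(r, 1.0)
        np.testing.assert_allclose(e, r / 2.0)
        assert np.linalg.norm(e) ** 2 == pytest.approx(1.0)
        # interior point: unchanged
        np.testing.assert_allclose(project_data_ball(r, 100.0), r)
        # eps = 0: e = 0
        assert np.all(project_data_ball(r, 0.0) == 0)


class TestTpvReconstruct:
    def test_zero_data_gives_zero_volume(self, small_setup):
        geom, grid = small_setup
        rows, cols = geom.detector_shape
        proj = ProjectionSet(geom, np.zeros((geom.n_views, rows, cols)))
        out = tpv_reconstruct(proj, grid, TpVParams(n_iterations=3, tau=100.0))
        assert np.all(out.values == 0)

    def test_p1_matches_independent_tv_admm(self, small_phantom_data):
        truth, projections, geom, grid = small_phantom_data
        P = SiddonProjector(geom, grid)
        tau = 1.1 * estimate_operator_norm(P, grid.n_voxels)
        params = TpVParams(p=1.0, beta1=10.0, beta2=1.0, eta=1.5,
                           eps_data=0.0, tau=tau, n_iterations=20)
        ours = tpv_reconstruct(projections, grid, params, projector=P)
        ref = tv_admm_reconstruct(P, projections.frames.ravel(), grid.shape,
                                  beta1=10.0, beta2=1.0, eta=1.5, tau=tau,
                                  n_iterations=20)
        scale = np.abs(ref).max()
        np.testing.assert_allclose(ours.values, ref, atol=1e-6 * scale)

    def test_feasibility_norms_trend_downward(self, small_phantom_data):
        truth, projections, geom, grid = small_phantom_data
        P = SiddonProjector(geom, grid)
        tau = 1.1 * estimate_operator_norm(P, grid.n_voxels)
        params = TpVParams(tau=tau, n_iterations=30)
        _, state = tpv_reconstruct(projections, grid, params, projector=P,
                                   return_state=True)
        # non-increasing up to a 1.1 slack for transient rises
        for hist in (state.feas_grad, state.feas_data):
            tail = hist[2:]
            assert all(b <= 1.1 * a for a, b in zip(tail, tail[1:]))

    def test_nonnegative_output(self, small_phantom_data):
        truth, projections, geom, grid = small_phantom_data
        out = tpv_reconstruct(projections, grid,
                              TpVParams(n_iterations=5, tau=2000.0))
        assert out.values.min() >= 0

    def test_exact_recovery_single_voxel_feature(self):
        # abundant views, eps = 0: converges to the ground truth
        grid = VolumeGrid((8, 8, 8))
        geom = ConeBeamGeometry.circular(
            n_views=24, detector_shape=(16, 16), detector_pixel=(3.0, 3.0))
        truth = np.zeros(grid.shape)
        truth[4, 4, 4] = 1.0
        projections = forward_project(Volume(grid, truth), geom)
        P = SiddonProjector(geom, grid)
        tau = 1.1 * estimate_operator_norm(P, grid.n_voxels)
        params = TpVParams(p=0.9, beta1=10.0, eta=1.5, tau=tau,
                           n_iterations=400)
        out = tpv_reconstruct(projections, grid, params, projector=P)
        assert np.sqrt(np.mean((out.values - truth) ** 2)) < 1e-3

    def test_param_validation(self):
        with pytest.raises(ValueError):
            TpVParams(p=0.0)
        with pytest.raises(ValueError):
            TpVParams(eta=2.0)
        with pytest.raises(ValueError):
            TpVParams(eps_data=-1.0)
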