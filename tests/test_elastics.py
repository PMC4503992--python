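"""Green's tensor, forward convolution and regularized/constrained inversion."""

import numpy as np
import pytest

from cytomech.elastics import (
    CellMask,
    DisplacementField,
    GelSubstrate,
    GridSpec,
    TractionField,
    boussinesq_greens_tensor,
    constrained_inverse,
    forward_solve,
    fttc_inverse,
    select_lambda,
)
from cytomech.synthio import DipoleSpec, simulate_traction_scene

from conftest import relative_l2


class TestGreensTensor:
    def test_on_axis_value(self, gel_soft):
        # closed form: G_xx = (1+nu)/(pi E r) * [(1-nu) + nu] = 1.5/(pi*1000*10)
        G = boussinesq_greens_tensor((10.0, 0.0), gel_soft)
        assert G[0, 0] == pytest.approx(1.5 / (np.pi * 1000.0 * 10.0), rel=1e-12)
        assert G[0, 1] == pytest.approx(0.0, abs=1e-18)

    def test_off_axis_value(self, gel_soft):
        # r on the y-axis: only the (1-nu) term feeds G_xx -> 0.75/(pi E r)
        G = boussinesq_greens_tensor((0.0, 10.0), gel_soft)
        assert G[0, 0] == pytest.approx(0.75 / (np.pi * 1000.0 * 10.0), rel=1e-12)

    def test_even_symmetry(self, gel_soft):
        rng = np.random.default_rng(1)
        for _ in range(10):
            r = rng.normal(size=2) * 10
            np.testing.assert_allclose(
                boussinesq_greens_tensor(r, gel_soft),
                boussinesq_greens_tensor(-r, gel_soft),
                rtol=1e-14,
            )

    def test_symmetric_tensor(self, gel_soft):
        G = boussinesq_greens_tensor((3.0, -7.0), gel_soft)
        assert G[0, 1] == pytest.approx(G[1, 0], rel=1e-14)

    def test_singular_origin_rejected(self, gel_soft):
        with pytest.raises(ValueError, match="singular"):
            boussinesq_greens_tensor((0.0, 0.0), gel_soft)

    def test_decay(self, gel_soft):
        G1 = boussinesq_greens_tensor((5.0, 0.0), gel_soft)
        G2 = boussinesq_greens_tensor((10.0, 0.0), gel_soft)
        assert G2[0, 0] == pytest.approx(G1[0, 0] / 2.0, rel=1e-12)


class TestGelSubstrate:
    @pytest.mark.parametrize("E,nu", [(-1.0, 0.5), (0.0, 0.5), (1e3, 0.0), (1e3, 0.6)])
    def test_invalid_parameters(self, E, nu):
        with pytest.raises(ValueError):
            GelSubstrate(E, nu)


class TestForwardSolve:
    def test_zero_traction(self, gel_soft, grid64):
        zero = TractionField(grid64, np.zeros((*grid64.shape, 2)))
        u = forward_solve(zero, gel_soft).u
        assert np.all(u == 0)

    def test_linearity(self, gel_soft, grid64):
        rng = np.random.default_rng(2)
        t1 = rng.normal(size=(*grid64.shape, 2))
        t2 = rng.normal(size=(*grid64.shape, 2))
        u1 = forward_solve(TractionField(grid64, t1), gel_soft).u
        u2 = forward_solve(TractionField(grid64, t2), gel_soft).u
        u12 = forward_solve(TractionField(grid64, t1 + t2), gel_soft).u
        assert relative_l2(u12, u1 + u2) < 1e-10

    def test_point_force_limit(self, gel_soft):
        # 100 pN x-force spread over a narrow Gaussian patch: u_x at (10,0)
        # approaches G_xx * F = 4.7746e-3 um
        grid = GridSpec(origin=(-32.0, -32.0), spacing=1.0, shape=(64, 64))
        X, Y = grid.meshgrid()
        g = np.exp(-(X**2 + Y**2) / (2.0 * 1.0**2))
        g /= g.sum() * grid.cell_area
        t = np.zeros((*grid.shape, 2))
        t[..., 0] = 100.0 * g
        u = forward_solve(TractionField(grid, t), gel_soft).u
        iy = np.argmin(np.abs(grid.y))
        ix = np.argmin(np.abs(grid.x - 10.0))
        expected = 100.0 * 1.5 / (np.pi * 1000.0 * 10.0)
        assert u[iy, ix, 0] == pytest.approx(expected, rel=0.02)

    def test_stiffness_scaling(self, grid64, compact_dipole_scene):
        truth, _, _ = compact_dipole_scene
        u1 = forward_solve(truth, GelSubstrate(1e3, 0.5)).u
        u2 = forward_solve(truth, GelSubstrate(2e3, 0.5)).u
        assert relative_l2(u2, 0.5 * u1) < 1e-12

    def test_nan_rejected(self, gel_soft, grid64):
        bad = np.zeros((*grid64.shape, 2))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            TractionField(grid64, bad)


class TestFttcInverse:
    def test_round_trip_identity(self, gel_soft, compact_dipole_scene):
        truth, disp, _ = compact_dipole_scene
        recovered = fttc_inverse(disp, gel_soft, reg_lambda=0.0)
        assert relative_l2(recovered.t, truth.t) < 0.01

    def test_large_lambda_kills_traction(self, gel_soft, compact_dipole_scene):
        truth, disp, _ = compact_dipole_scene
        t = fttc_inverse(disp, gel_soft, reg_lambda=1e6).t
        assert np.abs(t).max() < 1e-6 * np.abs(truth.t).max()

    def test_noise_lcurve_beats_unregularized(self, gel_soft, grid64, reference_dipole_scene):
        truth, disp, _ = reference_dipole_scene
        rng = np.random.default_rng(11)
        sd = 0.05 * np.sqrt(np.mean(disp.u**2))
        noisy = DisplacementField(grid64, disp.u + rng.normal(0.0, sd, disp.u.shape))
        lam, _ = select_lambda(noisy, gel_soft)
        err_l = relative_l2(fttc_inverse(noisy, gel_soft, lam).t, truth.t)
        err_0 = relative_l2(fttc_inverse(noisy, gel_soft, 0.0).t, truth.t)
        assert err_l < err_0

    def test_small_grid_rejected(self, gel_soft):
        grid = GridSpec(origin=(0, 0), spacing=1.0, shape=(4, 4))
        with pytest.raises(ValueError, match="too small"):
            fttc_inverse(DisplacementField(grid, np.zeros((4, 4, 2))), gel_soft)

    def test_negative_lambda_rejected(self, gel_soft, compact_dipole_scene):
        _, disp, _ = compact_dipole_scene
        with pytest.raises(ValueError):
            fttc_inverse(disp, gel_soft, reg_lambda=-0.1)

    def test_rotation_equivariance(self, gel_soft, grid64, reference_dipole_scene):
        _, disp, _ = reference_dipole_scene

        def rot(v):
            w = np.rot90(v, k=1, axes=(0, 1)).copy()
            return np.stack([-w[..., 1], w[..., 0]], axis=-1)

        t1 = fttc_inverse(disp, gel_soft, 1e-3).t
        t2 = fttc_inverse(DisplacementField(grid64, rot(disp.u)), gel_soft, 1e-3).t
        assert np.abs(t2 - rot(t1)).max() < 1e-10 * np.abs(t1).max()

    def test_traction_scaling(self, gel_soft, grid64, compact_dipole_scene):
        _, disp, _ = compact_dipole_scene
        t1 = fttc_inverse(disp, gel_soft, 1e-3).t
        t2 = fttc_inverse(DisplacementField(grid64, 2.0 * disp.u), gel_soft, 1e-3).t
        assert relative_l2(t2, 2.0 * t1) < 1e-12


class TestConstrainedInverse:
    def test_round_trip(self, gel_soft, reference_dipole_scene):
        truth, disp, mask = reference_dipole_scene
        recovered, info = constrained_inverse(disp, mask, gel_soft, reg_lambda=1e-4)
        assert relative_l2(recovered.t, truth.t) < 0.05
        assert info.converged

    def test_zero_outside_mask(self, gel_soft, grid64, reference_dipole_scene):
        _, disp, mask = reference_dipole_scene
        recovered, _ = constrained_inverse(disp, mask, gel_soft, reg_lambda=1e-4)
        outside = ~mask.raster_on(grid64)
        assert np.abs(recovered.t[outside]).max() == 0.0

    def test_whole_grid_mask_matches_unconstrained(self, gel_soft, grid64, compact_dipole_scene):
        _, disp, _ = compact_dipole_scene
        full = CellMask(raster=np.ones(grid64.shape, dtype=bool), area=float(np.prod(grid64.shape)))
        constrained, _ = constrained_inverse(disp, full, gel_soft, reg_lambda=1e-4)
        free = fttc_inverse(disp, gel_soft, reg_lambda=1e-4)
        assert relative_l2(constrained.t, free.t) < 1e-8

    def test_force_balance(self, gel_soft, grid64):
        rng = np.random.default_rng(4)
        for angle in (0.3, 1.2):
            dip = DipoleSpec(
                center=(31.5, 31.5), axis_angle=angle,
                force_magnitude=float(rng.uniform(50, 200)),
                separation=16.0, patch_radius=2.0,
            )
            _, disp, mask = simulate_traction_scene([dip], gel_soft, grid64)
            t, _ = constrained_inverse(disp, mask, gel_soft, reg_lambda=1e-4)
            dA = grid64.cell_area
            net = np.linalg.norm(t.t.sum(axis=(0, 1)) * dA)
            total = np.hypot(t.t[..., 0], t.t[..., 1]).sum() * dA
            assert net / total < 0.05

    def test_empty_mask_rejected(self, gel_soft, grid64, compact_dipole_scene):
        _, disp, _ = compact_dipole_scene
        empty = CellMask(raster=np.zeros(grid64.shape, dtype=bool), area=1.0)
        with pytest.raises(ValueError, match="overlap"):
            constrained_inverse(disp, empty, gel_soft)

    def test_nonconvergence_warns(self, gel_soft, grid64, reference_dipole_scene):
        _, disp, mask = reference_dipole_scene
        with pytest.warns(RuntimeWarning, match="did not converge"):
            _, info = constrained_inverse(
                disp, mask, gel_soft, reg_lambda=1e-4, tol=0.0, max_iter=1
            )
        assert not info.converged


class TestLcurve:
    def test_corner_interior(self, gel_soft, grid64, reference_dipole_scene):
        _, disp, _ = reference_dipole_scene
        rng = np.random.default_rng(5)
        sd = 0.05 * np.sqrt(np.mean(disp.u**2))
        noisy = DisplacementField(grid64, disp.u + rng.normal(0.0, sd, disp.u.shape))
        lam, diag = select_lambda(noisy, gel_soft)
        lams = diag["lambdas"]
        assert lams[0] < lam < lams[-1]
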