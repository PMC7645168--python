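"""The constrained solver, R2* estimation and echo fusion."""

import numpy as np
import pytest

from scswim import (VoxelGrid, SusceptibilityVolume, ScswimParams,
                    make_dipole_kernel, forward_field, scswim_solve,
                    scswim_objective, r2star_from_echoes, fuse_echoes,
                    PhantomSpec, simulate_stage, ideal_masks,
                    run_stage_pipeline)
from scswim.constraints import MaskSet
from scswim.grids import apply_dipole, gradient, gradient_adjoint
from scswim.solver import _CHI_SCALE, _FIELD_SCALE


def _uniform_masks(grid):
    ones = np.ones(grid.shape)
    return MaskSet(P=(ones, ones, ones), R=ones, W=ones,
                   brain_mask=ones.astype(bool), grid=grid)


@pytest.fixture(scope="module")
def sphere48():
    grid = VoxelGrid((48, 48, 48))
    kernel = make_dipole_kernel(grid)
    x, y, z = grid.coordinates_mm()
    chi_true = np.where(x ** 2 + y ** 2 + z ** 2 <= 8 ** 2, 500.0, 0.0)
    field = forward_field(SusceptibilityVolume(chi_true, grid), kernel)
    return grid, kernel, chi_true, field


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScswimParams(lambda2=-1.0)
        with pytest.raises(ValueError):
            ScswimParams(outer_max_iter=0)
        with pytest.raises(ValueError):
            ScswimParams(cg_tol=0.0)

    def test_lambda1_is_ratio_times_lambda2(self):
        p = ScswimParams(lambda2=2e-3, lambda1_ratio=0.005)
        assert p.lambda1 == pytest.approx(1e-5)


class TestScswimSolve:
    def test_fidelity_only_solution_fits_data(self, sphere48):
        """With both penalties off the solver is a least-squares dipole
        inversion: the noiseless field is reproduced to < 1e-3 relative."""
        grid, kernel, _, field = sphere48
        params = ScswimParams(lambda2=0.0, lambda1_ratio=0.0,
                              cg_tol=1e-6, cg_max_iter=400, outer_max_iter=2)
        chi, _ = scswim_solve(field, kernel, _uniform_masks(grid), params,
                              SusceptibilityVolume(np.zeros(grid.shape), grid))
        resid = apply_dipole(chi.values * _CHI_SCALE, kernel) \
            - field.values * _FIELD_SCALE
        assert np.linalg.norm(resid) < 1e-3 * np.linalg.norm(
            field.values * _FIELD_SCALE)

    def test_objective_not_worse_than_init(self, sphere48):
        grid, kernel, chi_true, field = sphere48
        params = ScswimParams(lambda2=1.47e-3)
        masks = _uniform_masks(grid)
        init = SusceptibilityVolume(chi_true * 0.8, grid)
        chi, record = scswim_solve(field, kernel, masks, params, init)
        f_init = scswim_objective(init.values, field, kernel, masks, params)
        f_final = scswim_objective(chi.values, field, kernel, masks, params)
        assert f_final <= f_init

    def test_irls_objective_monotone(self, sphere48):
        """The eps-smoothed objective is non-increasing (within 1%)."""
        grid, kernel, chi_true, field = sphere48
        params = ScswimParams(lambda2=1.47e-3, outer_max_iter=6)
        masks = _uniform_masks(grid)
        _, record = scswim_solve(field, kernel, masks, params,
                                 SusceptibilityVolume(chi_true * 0.5, grid))
        objs = record.objective_smoothed
        for prev, cur in zip(objs, objs[1:]):
            assert cur <= prev * 1.01

    def test_stationarity(self, sphere48):
        """The smoothed-objective gradient at the solution is tiny compared
        with the gradient at the initial point."""
        grid, kernel, chi_true, field = sphere48
        params = ScswimParams(lambda2=1.47e-3, outer_max_iter=10,
                              outer_tol=1e-4, cg_tol=1e-6, cg_max_iter=400)
        masks = _uniform_masks(grid)
        init = SusceptibilityVolume(np.zeros(grid.shape), grid)
        chi, _ = scswim_solve(field, kernel, masks, params, init)

        def grad(chi_ppb):
            x = chi_ppb * _CHI_SCALE
            g = apply_dipole(masks.W ** 2 * (apply_dipole(x, kernel)
                             - field.values * _FIELD_SCALE), kernel)
            g = g + params.lambda2 * masks.R ** 2 * x
            eps = params.irls_epsilon
            for ax in range(3):
                v = masks.P[ax] * gradient(x, grid, ax)
                g = g + params.lambda1 * gradient_adjoint(
                    masks.P[ax] * v / np.sqrt(v ** 2 + eps ** 2), grid, ax)
            return np.linalg.norm(g)

        assert grad(chi.values) < 1e-3 * grad(init.values)

    def test_invalid_inputs(self, sphere48):
        grid, kernel, _, field = sphere48
        bad_init = SusceptibilityVolume(np.zeros(grid.shape), grid)
        bad_init.values[0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            scswim_solve(field, kernel, _uniform_masks(grid), ScswimParams(),
                         bad_init)


class TestProtectionProperty:
    def test_lambda2_shields_protected_rois(self):
        """Raising lambda2 10x smooths unprotected tissue but moves the
        protected deep-gray means by < 3%."""
        from scswim.phantom import LABEL_CODES
        ds = simulate_stage(PhantomSpec.tiny(), snr=10.0, seed=3)
        masks = ideal_masks(ds.chi_truth.values, ds.structural, ds.labels,
                            ds.grid, ds.brain_mask)
        results = {}
        for lam2 in (1.47e-3, 1.47e-2):
            res = run_stage_pipeline(
                ds, params=ScswimParams(lambda2=lam2),
                masks=masks, lambda2_per_echo=(lam2,) * 4)
            results[lam2] = res.fused.values
        wm = ds.labels == LABEL_CODES["WM"]
        assert results[1.47e-2][wm].std() <= results[1.47e-3][wm].std() * 1.05
        for name in ("GP-L", "GP-R", "RN-L", "RN-R"):
            sel = ds.labels == LABEL_CODES[name]
            m1 = results[1.47e-3][sel].mean()
            m2 = results[1.47e-2][sel].mean()
            assert abs(m2 - m1) <= 0.03 * abs(m1)


class TestR2Star:
    def test_equal_magnitudes_give_zero(self):
        rho = np.full((4, 4, 4), 2.0)
        assert np.all(r2star_from_echoes(rho, rho, 0.0075, 0.0175) == 0.0)

    def test_exact_decay_recovered(self):
        rho1 = np.full((4, 4, 4), 1.3)
        rho2 = rho1 * np.exp(-(0.0175 - 0.0075) * 30.0)
        r2s = r2star_from_echoes(rho1, rho2, 0.0075, 0.0175)
        np.testing.assert_allclose(r2s, 30.0, rtol=1e-12)

    def test_nonpositive_magnitude_maps_to_zero(self):
        rho1 = np.array([[[0.0, 1.0]]])
        rho2 = np.array([[[1.0, 1.0]]])
        r2s = r2star_from_echoes(rho1, rho2, 0.0075, 0.0175)
        assert r2s[0, 0, 0] == 0.0

    def test_equal_tes_rejected(self):
        with pytest.raises(ValueError):
            r2star_from_echoes(np.ones((2, 2, 2)) + 1, np.ones((2, 2, 2)),
                               0.01, 0.01)


class TestFuseEchoes:
    def _grid(self):
        return VoxelGrid((8, 8, 8))

    def test_identical_echoes_unchanged(self):
        grid = self._grid()
        chi = SusceptibilityVolume(np.full(grid.shape, 42.0), grid)
        fused = fuse_echoes([chi, chi], [0.0075, 0.0175],
                            np.full(grid.shape, 30.0))
        np.testing.assert_allclose(fused.values, 42.0)

    def test_hand_value(self):
        """R2* = 40/s, TEs 7.5/17.5 ms, chi {100, 80} -> 85.803..."""
        grid = self._grid()
        a = SusceptibilityVolume(np.full(grid.shape, 100.0), grid)
        b = SusceptibilityVolume(np.full(grid.shape, 80.0), grid)
        fused = fuse_echoes([a, b], [0.0075, 0.0175],
                            np.full(grid.shape, 40.0))
        assert fused.values[0, 0, 0] == pytest.approx(85.80324686496837,
                                                      rel=1e-12)

    def test_zeroed_echo_contributes_nothing(self):
        grid = self._grid()
        a = SusceptibilityVolume(np.full(grid.shape, 100.0), grid)
        b = SusceptibilityVolume(np.zeros(grid.shape), grid)
        fused = fuse_echoes([a, b], [0.0075, 0.0175],
                            np.full(grid.shape, 40.0))
        np.testing.assert_allclose(fused.values, 100.0)

    def test_order_invariance(self, rng):
        grid = self._grid()
        chis = [SusceptibilityVolume(rng.normal(size=grid.shape), grid)
                for _ in range(4)]
        tes = [0.0075, 0.0175, 0.00875, 0.01875]
        r2s = np.full(grid.shape, 25.0)
        a = fuse_echoes(chis, tes, r2s)
        order = [2, 0, 3, 1]
        b = fuse_echoes([chis[i] for i in order], [tes[i] for i in order], r2s)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            fuse_echoes([], [], np.zeros((8, 8, 8)))
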