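import dataclasses

import numpy as np
import pytest

from deeptms import build_circular_loop, field_on_grid
from deeptms.coils import StimulusSpec
from deeptms.phantom import ConductivityMap
from deeptms.solver import (
    SolverError,
    assemble_system,
    check_current_conservation,
    compute_e_field,
    solve,
    solve_potential,
)
from deeptms.volumes import FieldVolume, Grid

STIM = StimulusSpec(5000.0, 2500.0)


def uniform_a0(grid, vec):
    a = np.zeros(grid.shape + (3,))
    a[:] = np.asarray(vec)
    return FieldVolume(a, grid, "A0")


@pytest.fixture()
def slab():
    """Layered conductivity slab along x inside an insulating box."""
    grid = Grid((40, 8, 8), 0.002, np.zeros(3))
    sigma = np.zeros(grid.shape)
    profile = np.repeat([0.4, 0.01, 1.6, 0.2], 10)
    sigma[:] = profile[:, None, None]
    return ConductivityMap(sigma, grid)


class TestAssembly:
    def test_row_sums_vanish(self, rng):
        """Pure-Neumann operator: every row of the assembled matrix sums to
        zero (brute-force on a 5^3 grid with random conductivities)."""
        grid = Grid((5, 5, 5), 0.001, np.zeros(3))
        sigma = rng.uniform(0.05, 2.0, grid.shape)
        system = assemble_system(
            ConductivityMap(sigma, grid), uniform_a0(grid, (1e-4, 0, 0)), STIM
        )
        row_sums = np.asarray(system.matrix.sum(axis=1)).ravel()
        assert np.abs(row_sums).max() < 1e-12 * system.matrix.diagonal().max()

    def test_rhs_telescopes_to_zero(self, rng):
        grid = Grid((6, 6, 6), 0.002, np.zeros(3))
        sigma = rng.uniform(0.0, 1.0, grid.shape)
        sigma[sigma < 0.3] = 0.0  # ragged lossy domain
        sigma[3, 3, 3] = 1.0
        a = FieldVolume(rng.normal(size=grid.shape + (3,)) * 1e-4, grid, "A0")
        system = assemble_system(ConductivityMap(sigma, grid), a, STIM)
        assert abs(system.rhs.sum()) < 1e-12 * np.abs(system.rhs).max()

    def test_single_lossy_voxel_degenerate(self):
        grid = Grid((3, 3, 3), 0.001, np.zeros(3))
        sigma = np.zeros(grid.shape)
        sigma[1, 1, 1] = 1.0
        res = solve(ConductivityMap(sigma, grid), uniform_a0(grid, (1e-4, 0, 0)), STIM)
        assert res.phi.values[1, 1, 1] == pytest.approx(0.0)
        assert res.iterations == 0

    def test_rejects_grid_mismatch_and_empty(self):
        grid = Grid((4, 4, 4), 0.002, np.zeros(3))
        other = Grid((4, 4, 5), 0.002, np.zeros(3))
        with pytest.raises(ValueError):
            assemble_system(
                ConductivityMap(np.ones(grid.shape), grid),
                uniform_a0(other, (1, 0, 0)),
                STIM,
            )
        with pytest.raises(ValueError):
            assemble_system(
                ConductivityMap(np.zeros(grid.shape), grid),
                uniform_a0(grid, (1, 0, 0)),
                STIM,
            )


class TestSolve:
    def test_zero_rhs_gives_zero_phi(self):
        grid = Grid((6, 6, 6), 0.002, np.zeros(3))
        sigma = ConductivityMap(np.ones(grid.shape), grid)
        res = solve(sigma, uniform_a0(grid, (0.0, 0.0, 0.0)), STIM)
        assert np.nanmax(np.abs(res.phi.values)) == 0.0
        assert np.nanmax(np.abs(res.e_field.values)) == 0.0

    def test_slab_charge_buildup_cancels_source(self, slab):
        """Uniform A0 across a layered slab with insulating ends: the charge
        layers cancel the induction term and E vanishes (1-D analytic:
        sigma (omega A + dphi/dx) = 0 with zero end flux)."""
        a0 = uniform_a0(slab.grid, (1e-4, 0.0, 0.0))
        res = solve(slab, a0, STIM, tolerance=1e-12)
        w_a_i = STIM.omega * STIM.current * 1e-4
        assert np.nanmax(np.abs(res.e_field.values)) < 1e-6 * w_a_i

    def test_uniform_a0_in_ball_gives_zero_field(self):
        # phi = -omega I a.x satisfies the discrete system exactly on any
        # voxelized domain, so E = 0 to solver precision
        grid = Grid((20, 20, 20), 0.004, -0.04 * np.ones(3))
        r = np.linalg.norm(grid.voxel_centers(), axis=-1)
        sigma = ConductivityMap(np.where(r < 0.035, 0.275, 0.0), grid)
        res = solve(sigma, uniform_a0(grid, (0, 1e-4, 0)), STIM, tolerance=1e-12)
        assert np.nanmax(np.abs(res.e_field.values)) < 1e-6 * STIM.omega * STIM.current * 1e-4

    def test_linearity_in_current_and_superposition(self, slab, rng):
        a1 = FieldVolume(rng.normal(size=slab.grid.shape + (3,)) * 1e-5, slab.grid, "A0")
        a2 = FieldVolume(rng.normal(size=slab.grid.shape + (3,)) * 1e-5, slab.grid, "A0")
        both = FieldVolume(a1.values + a2.values, slab.grid, "A0")
        stim_double = StimulusSpec(2 * STIM.current, STIM.frequency)
        r1 = solve(slab, a1, STIM, tolerance=1e-12)
        r2 = solve(slab, a2, STIM, tolerance=1e-12)
        r12 = solve(slab, both, STIM, tolerance=1e-12)
        rd = solve(slab, a1, stim_double, tolerance=1e-12)
        m = slab.lossy_mask
        scale = np.abs(r12.phi.values[m]).max()
        np.testing.assert_allclose(
            r12.phi.values[m], (r1.phi.values + r2.phi.values)[m], atol=1e-8 * scale
        )
        np.testing.assert_allclose(
            rd.phi.values[m], 2 * r1.phi.values[m], atol=1e-8 * scale
        )

    def test_nonconvergence_raises_with_history(self, slab):
        a0 = uniform_a0(slab.grid, (1e-4, 0.0, 0.0))
        with pytest.raises(SolverError) as exc:
            solve(slab, a0, STIM, tolerance=1e-14, max_iterations=2)
        assert exc.value.residual_history

    def test_coil_driven_sphere_solve(self, rng):
        """Off-axis coil over a two-layer ball: converged solve satisfies
        discrete current conservation at the residual scale."""
        grid = Grid((30, 30, 30), 0.004, -0.06 * np.ones(3))
        r = np.linalg.norm(grid.voxel_centers(), axis=-1)
        sigma_arr = np.where(r < 0.05, 0.3, 0.0)
        sigma_arr[r < 0.03] = 0.05
        sigma = ConductivityMap(sigma_arr, grid)
        coil = build_circular_loop(0.04, center=(0.02, 0.0, 0.08), n_segments=64)
        a0 = field_on_grid(coil, grid, which="A0", mask=sigma.lossy_mask)
        res = solve(sigma, a0, STIM, tolerance=1e-10)
        assert res.residual <= 1e-10
        b = res.system.rhs - res.system.rhs.mean()
        tol_scale = 1e-10 * np.linalg.norm(b) / res.system.face_current_scale
        assert check_current_conservation(res) <= 10 * tol_scale

    def test_grid_convergence_at_probe_points(self):
        """|E| at interior probe points changes <5% when the spacing halves
        (2 mm -> 1 mm) on a three-layer sphere driven by an offset coil."""
        from scipy.ndimage import map_coordinates

        def run(h):
            half = int(round(0.055 / h)) + 1
            n = 2 * half
            grid = Grid((n, n, n), h, -half * h * np.ones(3))
            r = np.linalg.norm(grid.voxel_centers(), axis=-1)
            s = np.zeros(grid.shape)
            s[r < 0.050] = 0.465
            s[r < 0.044] = 0.010
            s[r < 0.038] = 0.275
            smap = ConductivityMap(s, grid)
            coil = build_circular_loop(0.04, center=(0.015, 0, 0.065), n_segments=64)
            a0 = field_on_grid(coil, grid, which="A0", mask=smap.lossy_mask)
            return solve(smap, a0, STIM), grid

        probes = np.array(
            [[0.01, 0.005, 0.0], [0.0, -0.015, 0.01],
             [-0.02, 0.0, -0.005], [0.005, 0.02, 0.015]]
        )

        def interp(res, grid):
            mag = np.linalg.norm(np.nan_to_num(res.e_field.values), axis=-1)
            ijk = ((probes - grid.origin) / grid.spacing - 0.5).T
            return map_coordinates(mag, ijk, order=1)

        coarse = interp(*run(0.002))
        fine = interp(*run(0.001))
        assert np.abs(coarse - fine).max() < 0.05 * fine.max()

    def test_perturbed_potential_breaks_conservation(self, slab):
        a0 = uniform_a0(slab.grid, (1e-4, 0.0, 0.0))
        res = solve(slab, a0, STIM, tolerance=1e-12)
        good = check_current_conservation(res)
        bad_phi = res.phi.values.copy()
        bad_phi[10, 4, 4] += 1.0  # inject a spurious charge
        bad = dataclasses.replace(res, phi=FieldVolume(bad_phi, slab.grid, "phi"))
        assert check_current_conservation(bad) > 100 * good


class TestEField:
    def test_zero_inputs_zero_field(self):
        grid = Grid((5, 5, 5), 0.002, np.zeros(3))
        sigma = ConductivityMap(np.ones(grid.shape), grid)
        phi = FieldVolume(np.zeros(grid.shape), grid, "phi")
        e = compute_e_field(phi, uniform_a0(grid, (0, 0, 0)), sigma, STIM)
        assert np.all(e.values == 0.0)

    def test_masked_outside_lossy_domain(self, slab):
        a0 = uniform_a0(slab.grid, (1e-4, 0, 0))
        res = solve(slab, a0, STIM)
        assert np.isnan(res.e_field.values[~slab.lossy_mask]).all()
        assert np.isfinite(res.e_field.values[slab.lossy_mask]).all()

    def test_gradient_is_one_sided_at_boundaries(self):
        # linear phi on a half-lossy grid: one-sided differences at the
        # domain edge must reproduce the exact slope, no air contamination
        grid = Grid((10, 4, 4), 0.002, np.zeros(3))
        sigma_arr = np.zeros(grid.shape)
        sigma_arr[:5] = 1.0
        sigma = ConductivityMap(sigma_arr, grid)
        x = grid.voxel_centers()[..., 0]
        phi = FieldVolume(np.where(sigma_arr > 0, 3.0 * x, np.nan), grid, "phi")
        e = compute_e_field(phi, uniform_a0(grid, (0, 0, 0)), sigma, STIM)
        np.testing.assert_allclose(e.values[:5, ..., 0], -3.0, rtol=1e-12)
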