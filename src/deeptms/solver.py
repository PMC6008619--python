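"""Finite-volume magneto-quasistatic scalar-potential solver.

In the magneto-quasistatic regime the induced electric field splits into the
primary (induction) part ``-omega I A0`` and a secondary part ``-grad phi``
from charge accumulation at conductivity interfaces.  Charge conservation
``div(sigma E) = 0`` gives the scalar-potential equation

    div(sigma grad phi) = -omega I div(sigma A0)

with insulating boundaries (vanishing normal current at the tissue-air
interface and the domain box).  The problem is real-valued under the peak-
phasor convention: ``sigma >> omega eps`` for head tissues at kHz, so the
permittivity never enters and the factor j*omega becomes the amplitude
scaling omega.

Discretization: 7-point finite volumes on the voxel grid.  Face conductances
use the harmonic mean of the two adjacent voxel conductivities, which is
zero across any face touching a sigma = 0 voxel and thereby realizes the
zero-Neumann condition without boundary bookkeeping; the source term is the
discrete divergence of sigma * omega * A0 over the same face set with A0
averaged from the two adjacent voxel centers.  The pure-Neumann operator is
symmetric positive semidefinite with a constant nullspace; the right-hand
side telescopes to zero by construction and the gauge is fixed by removing
the sigma-weighted mean of phi.  Solved with Jacobi-preconditioned conjugate
gradients.

The electric field is reconstructed only on the lossy (sigma > 0) domain:
``E = -(omega I A0 + grad phi)`` with central differences for grad phi,
falling back to one-sided differences at lossy-domain boundaries so values
from outside the domain (where phi is undefined) never contaminate E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coils import StimulusSpec
from .phantom import ConductivityMap
from .volumes import FieldVolume, Grid

__all__ = [
    "QSSystem",
    "SolveResult",
    "SolverError",
    "assemble_system",
    "solve_potential",
    "compute_e_field",
    "solve",
    "check_current_conservation",
]


class SolverError(RuntimeError):
    """Raised when the iterative solve does not reach tolerance."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history or []


@dataclass
class QSSystem:
    """Assembled sparse operator ``L phi = b`` restricted to lossy voxels.

    ``L`` applies ``sum_faces g_f (phi_i - phi_j)`` with ``g_f`` the
    harmonic-mean face conductance [S]; ``b`` is the integrated source flux
    [A].  ``index`` maps grid voxels to unknown ordering (-1 outside).
    """

    matrix: sp.csr_matrix
    rhs: np.ndarray
    index: np.ndarray
    grid: Grid
    sigma: np.ndarray
    face_current_scale: float  # mean |source face current| [A], for diagnostics


def _face_quantities(sigma: np.ndarray, a0_axis: np.ndarray, axis: int, h: float):
    """Harmonic-mean face conductance and face source flux along one axis."""
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    s1, s2 = sigma[tuple(lo)], sigma[tuple(hi)]
    both = (s1 > 0) & (s2 > 0)
    g = np.zeros_like(s1)
    np.divide(2.0 * s1 * s2, s1 + s2, out=g, where=both)
    a_face = 0.5 * (a0_axis[tuple(lo)] + a0_axis[tuple(hi)])
    a_face = np.where(both, a_face, 0.0)
    # conductance [S] = sigma_f * area / h = sigma_f * h ; source flux [A]
    # through the face = sigma_f * (omega I A0_f . n) * area (omega I applied
    # by the caller)
    return g * h, g * a_face * h * h, both


def assemble_system(
    sigma_map: ConductivityMap, a0: FieldVolume, stimulus: StimulusSpec
) -> QSSystem:
    """Assemble the 7-point finite-volume system on the sigma > 0 voxels.

    ``a0`` is the per-unit-current magnetostatic vector potential on the same
    grid; the drive amplitude and angular frequency from ``stimulus`` scale
    the right-hand side.
    """
    if not sigma_map.grid.same_geometry(a0.grid):
        raise ValueError("sigma and A0 grids differ")
    if not a0.is_vector:
        raise ValueError("A0 must be a vector field")
    sigma = sigma_map.sigma
    lossy = sigma > 0
    n_unknown = int(lossy.sum())
    if n_unknown == 0:
        raise ValueError("no lossy voxels: nothing to solve")
    a0_values = a0.values
    if np.isnan(a0_values[lossy]).any():
        raise ValueError("A0 is undefined (NaN) on some lossy voxels")

    grid = sigma_map.grid
    h = grid.spacing
    index = np.full(grid.shape, -1, dtype=np.int64)
    index[lossy] = np.arange(n_unknown)

    omega_i = stimulus.omega * stimulus.current
    rows, cols, vals = [], [], []
    diag = np.zeros(n_unknown)
    b = np.zeros(n_unknown)
    flux_mags = []
    for axis in range(3):
        g, flux, both = _face_quantities(
            sigma, np.nan_to_num(a0_values[..., axis]), axis, h
        )
        flux *= omega_i
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        i_lo = index[tuple(lo)][both]
        i_hi = index[tuple(hi)][both]
        g_f = g[both]
        f_f = flux[both]
        rows.append(i_lo)
        cols.append(i_hi)
        vals.append(-g_f)
        rows.append(i_hi)
        cols.append(i_lo)
        vals.append(-g_f)
        np.add.at(diag, i_lo, g_f)
        np.add.at(diag, i_hi, g_f)
        # outward source flux: +f on the low cell (outward normal +axis),
        # -f on the high cell
        np.add.at(b, i_lo, f_f)
        np.add.at(b, i_hi, -f_f)
        flux_mags.append(np.abs(f_f))
    rows.append(np.arange(n_unknown))
    cols.append(np.arange(n_unknown))
    vals.append(diag)
    matrix = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unknown, n_unknown),
    )
    all_flux = np.concatenate(flux_mags) if flux_mags else np.zeros(1)
    scale = float(all_flux.mean()) if all_flux.size else 0.0
    return QSSystem(
        matrix=matrix, rhs=b, index=index, grid=grid, sigma=sigma,
        face_current_scale=scale,
    )


def solve_potential(
    system: QSSystem,
    tolerance: float = 1e-8,
    max_iterations: int = 10_000,
) -> tuple[FieldVolume, float, int]:
    """CG solve of the pure-Neumann system; returns (phi, residual, iters).

    The right-hand side is projected onto the operator range (zero mean) and
    the gauge is fixed by removing the sigma-weighted mean of phi.  phi is
    NaN outside the lossy domain.
    """
    b = system.rhs - system.rhs.mean()  # compatibility projection
    n = b.size
    diag = system.matrix.diagonal()
    inv_diag = np.where(diag > 0, 1.0 / np.where(diag > 0, diag, 1.0), 1.0)
    precond = spla.LinearOperator((n, n), matvec=lambda x: inv_diag * x)
    history: list[float] = []
    b_norm = np.linalg.norm(b)
    if b_norm == 0.0:
        x = np.zeros(n)
        iters = 0
    else:
        iters = 0

        def count(_xk):
            nonlocal iters
            iters += 1

        x, info = spla.cg(
            system.matrix, b, rtol=tolerance, atol=0.0,
            maxiter=max_iterations, M=precond, callback=count,
        )
        resid = float(np.linalg.norm(system.matrix @ x - b) / b_norm)
        history.append(resid)
        if info != 0:
            raise SolverError(
                f"CG did not converge in {max_iterations} iterations "
                f"(relative residual {resid:.3e})",
                history,
            )
    residual = float(np.linalg.norm(system.matrix @ x - b) / b_norm) if b_norm else 0.0
    # sigma-weighted zero-mean gauge
    w = system.sigma[system.sigma > 0]
    x = x - float(np.average(x, weights=w))
    phi = np.full(system.grid.shape, np.nan)
    phi[system.sigma > 0] = x
    return FieldVolume(values=phi, grid=system.grid, kind="phi"), residual, iters


def _masked_gradient(phi: np.ndarray, lossy: np.ndarray, h: float) -> np.ndarray:
    """grad phi on the lossy domain: central where possible, one-sided at
    lossy-domain boundaries, zero where no lossy neighbor exists."""
    grad = np.zeros(phi.shape + (3,))
    p = np.where(lossy, phi, 0.0)
    for axis in range(3):
        fwd_ok = np.zeros_like(lossy)
        bwd_ok = np.zeros_like(lossy)
        p_fwd = np.zeros_like(p)
        p_bwd = np.zeros_like(p)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        fwd_ok[tuple(lo)] = lossy[tuple(hi)]
        bwd_ok[tuple(hi)] = lossy[tuple(lo)]
        p_fwd[tuple(lo)] = p[tuple(hi)]
        p_bwd[tuple(hi)] = p[tuple(lo)]
        both = fwd_ok & bwd_ok
        g = np.zeros_like(p)
        g[both] = (p_fwd[both] - p_bwd[both]) / (2 * h)
        only_f = fwd_ok & ~bwd_ok
        g[only_f] = (p_fwd[only_f] - p[only_f]) / h
        only_b = bwd_ok & ~fwd_ok
        g[only_b] = (p[only_b] - p_bwd[only_b]) / h
        grad[..., axis] = g
    grad[~lossy] = np.nan
    return grad


def compute_e_field(
    phi: FieldVolume,
    a0: FieldVolume,
    sigma_map: ConductivityMap,
    stimulus: StimulusSpec,
) -> FieldVolume:
    """Peak-amplitude induced field ``E = -(omega I A0 + grad phi)`` [V/m].

    Defined (finite) only on the lossy domain; NaN elsewhere.
    """
    if not (phi.grid.same_geometry(a0.grid) and phi.grid.same_geometry(sigma_map.grid)):
        raise ValueError("phi, A0 and sigma grids differ")
    lossy = sigma_map.lossy_mask
    grad = _masked_gradient(phi.values, lossy, phi.grid.spacing)
    e = -(stimulus.omega * stimulus.current * np.nan_to_num(a0.values) + grad)
    e[~lossy] = np.nan
    return FieldVolume(values=e, grid=phi.grid, kind="E")


@dataclass
class SolveResult:
    """Solved potential and field with convergence diagnostics."""

    phi: FieldVolume
    e_field: FieldVolume
    residual: float
    iterations: int
    system: QSSystem

    def conservation(self) -> float:
        return check_current_conservation(self)


def solve(
    sigma_map: ConductivityMap,
    a0: FieldVolume,
    stimulus: StimulusSpec,
    tolerance: float = 1e-8,
    max_iterations: int = 10_000,
) -> SolveResult:
    """Assemble, solve and reconstruct E in one call."""
    system = assemble_system(sigma_map, a0, stimulus)
    phi, residual, iters = solve_potential(system, tolerance, max_iterations)
    e = compute_e_field(phi, a0, sigma_map, stimulus)
    return SolveResult(phi=phi, e_field=e, residual=residual, iterations=iters,
                       system=system)


def check_current_conservation(result: SolveResult) -> float:
    """Max voxel imbalance of discrete face currents, normalized.

    Recomputes the face currents ``J_f = g_f (phi_i - phi_j) + source_f``
    implied by the solved potential and returns the largest per-voxel net
    current over lossy voxels divided by the mean face-current magnitude.
    For a converged solve this sits at the linear-solver residual scale.
    """
    system = result.system
    lossy = system.sigma > 0
    phi_flat = result.phi.values[lossy]
    imbalance = system.matrix @ phi_flat - (system.rhs - system.rhs.mean())
    scale = system.face_current_scale
    if scale == 0.0:
        return float(np.abs(imbalance).max())
    return float(np.abs(imbalance).max() / scale)
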