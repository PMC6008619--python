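"""Biot-Savart evaluation of A0 and B for segmented coils.

The coil polyline model admits exact closed forms per straight segment, so no
quadrature tolerance enters:

* flux density ``B`` uses the stable two-endpoint form
  ``B = (mu0 I w / 4 pi) (s1 + s2) (r1 x r2) / (s1 s2 (s1 s2 + r1.r2))``
* vector potential ``A0`` (Coulomb gauge) is directed along the segment with
  magnitude ``(mu0 I w / 4 pi) ln((s1 + s2 + L) / (s1 + s2 - L))``

with ``r1``/``r2`` the vectors from the endpoints to the field point and
``s1``/``s2`` their norms.  Permeability is mu0 everywhere (no magnetic
materials), so the magnetostatic A0 of the source current is the vector
potential of the full quasistatic problem.

Points closer to a wire than the exclusion radius (default 1 mm) are returned
as NaN: the 1/r singularity there is an artifact of the zero-thickness wire
model.  Head voxels are never excluded because coils sit >= 10 mm off the
scalp; the guard matters only for visualization grids through the windings.

Fields are evaluated per unit drive current unless a current is given;
the solver scales A0 by the stimulus amplitude.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit, prange

from .coils import CoilGeometry, StimulusSpec
from .volumes import FieldVolume, Grid

__all__ = [
    "MU_0",
    "segment_b_field",
    "segment_vector_potential",
    "b_field",
    "vector_potential",
    "field_on_grid",
    "quasistatic_check",
]

MU_0 = 4.0e-7 * math.pi  # vacuum permeability [H/m]
DEFAULT_WIRE_EXCLUSION = 1.0e-3  # [m]


@njit(cache=True, parallel=True, fastmath=True)
def _bs_kernel(starts, ends, weights, points, out, want_b, r_excl):
    """Sum per-segment closed forms over all points; NaN inside r_excl."""
    n_pts = points.shape[0]
    n_seg = starts.shape[0]
    for ip in prange(n_pts):
        px, py, pz = points[ip, 0], points[ip, 1], points[ip, 2]
        ax = ay = az = 0.0
        excluded = False
        for s in range(n_seg):
            r1x = px - starts[s, 0]
            r1y = py - starts[s, 1]
            r1z = pz - starts[s, 2]
            r2x = px - ends[s, 0]
            r2y = py - ends[s, 1]
            r2z = pz - ends[s, 2]
            lx = ends[s, 0] - starts[s, 0]
            ly = ends[s, 1] - starts[s, 1]
            lz = ends[s, 2] - starts[s, 2]
            l2 = lx * lx + ly * ly + lz * lz
            # distance from the point to the segment (wire-exclusion guard)
            t = (r1x * lx + r1y * ly + r1z * lz) / l2
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            dx = r1x - t * lx
            dy = r1y - t * ly
            dz = r1z - t * lz
            if dx * dx + dy * dy + dz * dz < r_excl * r_excl:
                excluded = True
                break
            s1 = math.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
            s2 = math.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
            w = weights[s]
            if want_b:
                cx = r1y * r2z - r1z * r2y
                cy = r1z * r2x - r1x * r2z
                cz = r1x * r2y - r1y * r2x
                denom = s1 * s2 * (s1 * s2 + r1x * r2x + r1y * r2y + r1z * r2z)
                if denom > 0.0:
                    f = w * (s1 + s2) / denom
                    ax += f * cx
                    ay += f * cy
                    az += f * cz
            else:
                length = math.sqrt(l2)
                f = w * math.log((s1 + s2 + length) / (s1 + s2 - length)) / length
                ax += f * lx
                ay += f * ly
                az += f * lz
        if excluded:
            out[ip, 0] = np.nan
            out[ip, 1] = np.nan
            out[ip, 2] = np.nan
        else:
            out[ip, 0] = ax
            out[ip, 1] = ay
            out[ip, 2] = az


def _evaluate(
    coil: CoilGeometry,
    points: np.ndarray,
    which: str,
    current: float,
    wire_exclusion: float,
) -> np.ndarray:
    points = np.atleast_2d(np.ascontiguousarray(points, dtype=float))
    out = np.empty_like(points)
    _bs_kernel(
        np.ascontiguousarray(coil.starts),
        np.ascontiguousarray(coil.ends),
        np.ascontiguousarray(coil.weights),
        points,
        out,
        which == "B",
        wire_exclusion,
    )
    out *= MU_0 * current / (4.0 * math.pi)
    return out


def b_field(
    coil: CoilGeometry,
    points,
    current: float = 1.0,
    wire_exclusion: float = DEFAULT_WIRE_EXCLUSION,
) -> np.ndarray:
    """Magnetic flux density [T] at ``points`` ((m, 3) or (3,)), exact per segment."""
    pts = np.asarray(points, dtype=float)
    res = _evaluate(coil, pts, "B", current, wire_exclusion)
    return res[0] if pts.ndim == 1 else res


def vector_potential(
    coil: CoilGeometry,
    points,
    current: float = 1.0,
    wire_exclusion: float = DEFAULT_WIRE_EXCLUSION,
) -> np.ndarray:
    """Magnetostatic vector potential A0 [V*s/m] at ``points`` (Coulomb gauge)."""
    pts = np.asarray(points, dtype=float)
    res = _evaluate(coil, pts, "A0", current, wire_exclusion)
    return res[0] if pts.ndim == 1 else res


def segment_b_field(start, end, point, current: float = 1.0, weight: float = 1.0,
                    wire_exclusion: float = DEFAULT_WIRE_EXCLUSION) -> np.ndarray:
    """B [T] of a single straight segment at one point."""
    seg = CoilGeometry(starts=[start], ends=[end], weights=[weight])
    return b_field(seg, np.asarray(point, float), current, wire_exclusion)


def segment_vector_potential(start, end, point, current: float = 1.0, weight: float = 1.0,
                             wire_exclusion: float = DEFAULT_WIRE_EXCLUSION) -> np.ndarray:
    """A0 [V*s/m] of a single straight segment at one point."""
    seg = CoilGeometry(starts=[start], ends=[end], weights=[weight])
    return vector_potential(seg, np.asarray(point, float), current, wire_exclusion)


def field_on_grid(
    coil: CoilGeometry,
    grid: Grid,
    which: str = "B",
    current: float = 1.0,
    mask: np.ndarray | None = None,
    wire_exclusion: float = DEFAULT_WIRE_EXCLUSION,
) -> FieldVolume:
    """Evaluate A0 or B at voxel centers, optionally only where ``mask``.

    Unevaluated and wire-excluded voxels are NaN.  The result is per unit
    drive current unless ``current`` is given.
    """
    if which not in ("A0", "B"):
        raise ValueError("which must be 'A0' or 'B'")
    centers = grid.voxel_centers()
    values = np.full(grid.shape + (3,), np.nan)
    if mask is None:
        pts = centers.reshape(-1, 3)
        values = _evaluate(coil, pts, which, current, wire_exclusion).reshape(
            grid.shape + (3,)
        )
    else:
        if mask.shape != grid.shape:
            raise ValueError("mask shape does not match grid")
        values[mask] = _evaluate(coil, centers[mask], which, current, wire_exclusion)
    return FieldVolume(values=values, grid=grid, kind=which)


def quasistatic_check(frequency: float, sigma: float, mu: float = MU_0, d: float = 0.25) -> float:
    """Magnitude of the quasistatic smallness parameter omega*mu*sigma*d^2.

    In the sigma >> omega*eps regime this is |omega^2 mu eps~ d^2| for a
    characteristic length ``d``; the quasistatic treatment (source field
    unperturbed by induced currents) requires it to be << 1.
    """
    if min(frequency, sigma, mu, d) < 0:
        raise ValueError("all inputs must be nonnegative")
    return 2.0 * math.pi * frequency * mu * sigma * d * d
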