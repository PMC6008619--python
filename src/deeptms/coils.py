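"""Parametric TMS coil models as polylines of straight current segments.

Every coil is reduced to an ordered list of straight segments with a signed
dimensionless current weight (the multiplier of the drive current; the sign
encodes winding sense).  Spiral windings are approximated by bundles of
concentric closed circular loops, each discretized as a regular polygon —
the standard simplification in TMS field modeling, with error second order
in the winding pitch and in the chord angle.

Coil library:

* circular loop           — primitive for everything below
* Halo                    — 5 large coplanar windings encircling the head
* double-cone (DC)        — two spiral wings at a 120 degree dihedral angle,
                            opposite senses, bending toward the head
* figure-of-eight (Fo8)   — the flat (180 degree) limit of the double cone
* Magstim D70             — 9-winding Fo8 used for the line-scan validation
* HFA / HDA               — Halo + Fo8 and Halo + double-cone combinations

Sign convention: a ``direction`` of +1 traverses counterclockwise about the
loop normal (right-hand rule).  For the combined coils the Halo runs
counterclockwise seen from above and the double-cone/Fo8 right wing runs the
same way (left wing opposite), so the right side of the head sees co-directed
currents from both coils and the induced field is reinforced there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .volumes import LabelVolume

__all__ = [
    "CoilGeometry",
    "StimulusSpec",
    "build_circular_loop",
    "build_halo",
    "build_double_cone",
    "build_figure_of_eight",
    "build_magstim_d70",
    "combine_coils",
    "place_on_head",
]

DEFAULT_SEGMENTS_PER_LOOP = 128  # <0.1% loop-center field error


@dataclass
class CoilGeometry:
    """An ordered set of straight current segments.

    ``starts``/``ends`` are ``(n, 3)`` arrays in meters; ``weights`` is the
    signed dimensionless multiplier of the drive current per segment.
    ``reference_point`` is the placement anchor (bottom of the windings for
    head-mounted coils, ring center for the Halo).
    """

    starts: np.ndarray
    ends: np.ndarray
    weights: np.ndarray
    name: str = "coil"
    reference_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.starts = np.atleast_2d(np.asarray(self.starts, dtype=float))
        self.ends = np.atleast_2d(np.asarray(self.ends, dtype=float))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.reference_point = np.asarray(self.reference_point, dtype=float)
        n = len(self.starts)
        if self.ends.shape != (n, 3) or self.weights.shape != (n,):
            raise ValueError("segment arrays have inconsistent shapes")
        lengths = np.linalg.norm(self.ends - self.starts, axis=1)
        if np.any(lengths <= 0):
            raise ValueError("zero-length segment in coil")

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    def translated(self, shift) -> "CoilGeometry":
        shift = np.asarray(shift, dtype=float)
        return replace(
            self,
            starts=self.starts + shift,
            ends=self.ends + shift,
            reference_point=self.reference_point + shift,
        )

    def reversed(self) -> "CoilGeometry":
        """Same geometry with all current senses flipped."""
        return replace(self, weights=-self.weights, name=self.name + "_reversed")

    def max_closure_gap(self) -> float:
        """How far the segment graph is from closed loops.

        In a union of closed polylines every segment end coincides with some
        segment start; returns the largest end-to-nearest-start distance.
        """
        from scipy.spatial import cKDTree

        tree = cKDTree(self.starts)
        dist, _ = tree.query(self.ends, k=1)
        return float(dist.max())


@dataclass(frozen=True)
class StimulusSpec:
    """Drive: peak current amplitude [A] and pulse-equivalent frequency [Hz]."""

    current: float = 5000.0
    frequency: float = 2500.0

    def __post_init__(self) -> None:
        if self.current <= 0 or self.frequency <= 0:
            raise ValueError("current and frequency must be positive")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency


def _orthonormal_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors u, v with u x v = normal."""
    n = np.asarray(normal, dtype=float)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _check_unit(vec, what: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if abs(np.linalg.norm(vec) - 1.0) > 1e-6:
        raise ValueError(f"{what} must be a unit vector")
    return vec


def build_circular_loop(
    radius: float,
    center=(0.0, 0.0, 0.0),
    normal=(0.0, 0.0, 1.0),
    n_segments: int = DEFAULT_SEGMENTS_PER_LOOP,
    direction: int = 1,
    weight: float = 1.0,
    name: str = "loop",
) -> CoilGeometry:
    """Closed regular polygon inscribed in a circle.

    ``direction=+1`` traverses counterclockwise about ``normal`` (right-hand
    rule); the polygon chords underestimate the loop-center field by
    ~(pi/n)^2/6, below 0.1% for n >= 64.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_segments < 8:
        raise ValueError("n_segments must be >= 8 (chord error too large)")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    normal = _check_unit(normal, "normal")
    center = np.asarray(center, dtype=float)
    u, v = _orthonormal_frame(normal)
    theta = direction * 2.0 * np.pi * np.arange(n_segments + 1) / n_segments
    pts = center + radius * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
    pts[-1] = pts[0]  # exact closure
    return CoilGeometry(
        starts=pts[:-1],
        ends=pts[1:],
        weights=np.full(n_segments, float(weight)),
        name=name,
        reference_point=center,
    )


def _concentric_loops(
    radii,
    center,
    normal,
    n_segments: int,
    direction: int,
    name: str,
) -> CoilGeometry:
    loops = [
        build_circular_loop(r, center, normal, n_segments, direction, name=name)
        for r in radii
    ]
    return combine_coils(*loops, name=name, reference_point=np.asarray(center, float))


def build_halo(
    n_windings: int = 5,
    inner_radius: float = 0.138,
    outer_radius: float = 0.150,
    center=(0.0, 0.0, 0.0),
    normal=(0.0, 0.0, 1.0),
    n_segments: int = DEFAULT_SEGMENTS_PER_LOOP,
    direction: int = 1,
) -> CoilGeometry:
    """Halo coil: large coplanar windings that encircle the head.

    Defaults are 5 windings with radii linearly spaced 138 -> 150 mm, all the
    same sense.  The ring is worn below the vertex and pairs with a
    vertex-mounted coil to boost the field at depth.
    """
    if n_windings < 1:
        raise ValueError("n_windings must be >= 1")
    if n_windings > 1 and not inner_radius < outer_radius:
        raise ValueError("inner_radius must be smaller than outer_radius")
    radii = np.linspace(inner_radius, outer_radius, n_windings)
    return _concentric_loops(radii, center, normal, n_segments, direction, "halo")


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = np.asarray(axis, dtype=float)
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle) * kx + (1 - math.cos(angle)) * (kx @ kx)


def build_double_cone(
    turns_per_wing: int = 10,
    inner_diameter: float = 0.015,
    outer_diameter: float = 0.040,
    wing_angle_deg: float = 120.0,
    apex=(0.0, 0.0, 0.0),
    axis=(0.0, 0.0, 1.0),
    wing_axis=(1.0, 0.0, 0.0),
    n_segments: int = DEFAULT_SEGMENTS_PER_LOOP,
    right_wing_direction: int = 1,
    name: str = "double_cone",
) -> CoilGeometry:
    """Double-cone coil: two spiral wings meeting at the apex.

    Each wing is ``turns_per_wing`` concentric loops with diameters linearly
    spaced ``inner_diameter -> outer_diameter``, lying in a plane tilted by
    (180 - wing_angle)/2 degrees from the flat position so the two planes
    meet at the ``wing_angle_deg`` dihedral angle.  The wings bend toward the
    head (the apex is the wire point farthest from the scalp along ``axis``)
    and carry opposite senses, so the current under the apex is co-directed.

    ``wing_axis`` is the in-plane direction separating the wings (+x puts the
    wings over the two hemispheres).  ``reference_point`` is the bottom of
    the windings directly under the apex.
    """
    if turns_per_wing < 1:
        raise ValueError("turns_per_wing must be >= 1")
    if not 0 < inner_diameter < outer_diameter:
        raise ValueError("need 0 < inner_diameter < outer_diameter")
    if not 0 < wing_angle_deg <= 180:
        raise ValueError("wing angle must lie in (0, 180]")
    axis = _check_unit(axis, "axis")
    wing_axis = _check_unit(wing_axis, "wing_axis")
    if abs(axis @ wing_axis) > 1e-9:
        raise ValueError("wing_axis must be perpendicular to axis")
    apex = np.asarray(apex, dtype=float)
    tangent = np.cross(axis, wing_axis)  # shared apex tangent line
    tilt = math.radians(180.0 - wing_angle_deg) / 2.0
    r_outer = outer_diameter / 2.0
    radii = np.linspace(inner_diameter, outer_diameter, turns_per_wing) / 2.0

    wings = []
    for side, direction in ((+1, right_wing_direction), (-1, -right_wing_direction)):
        # tilt rotates the wing down toward the head about the apex tangent
        rot = _rotation_about_axis(tangent, -side * tilt)
        radial = rot @ (side * wing_axis)
        wing_normal = rot @ axis
        center = apex + r_outer * radial
        wings.append(
            _concentric_loops(radii, center, wing_normal, n_segments, direction, name)
        )
    coil = combine_coils(*wings, name=name)
    # reference: bottom-of-windings level, directly under the apex
    axial = np.concatenate([coil.starts @ axis, coil.ends @ axis]).min()
    coil.reference_point = apex + (axial - apex @ axis) * axis
    return coil


def build_figure_of_eight(
    turns_per_wing: int = 10,
    inner_diameter: float = 0.015,
    outer_diameter: float = 0.040,
    center=(0.0, 0.0, 0.0),
    normal=(0.0, 0.0, 1.0),
    wing_axis=(1.0, 0.0, 0.0),
    n_segments: int = DEFAULT_SEGMENTS_PER_LOOP,
    right_wing_direction: int = 1,
) -> CoilGeometry:
    """Flat figure-of-eight: the 180-degree limit of the double cone."""
    coil = build_double_cone(
        turns_per_wing,
        inner_diameter,
        outer_diameter,
        wing_angle_deg=180.0,
        apex=center,
        axis=normal,
        wing_axis=wing_axis,
        n_segments=n_segments,
        right_wing_direction=right_wing_direction,
        name="figure_of_eight",
    )
    return coil


def build_magstim_d70(
    n_windings: int = 9,
    inner_diameter: float = 0.032,
    outer_diameter: float = 0.048,
    winding_gap: float = 0.001,
    center=(0.0, 0.0, 0.0),
    normal=(0.0, 0.0, 1.0),
    wing_axis=(1.0, 0.0, 0.0),
    n_segments: int = DEFAULT_SEGMENTS_PER_LOOP,
    right_wing_direction: int = 1,
) -> CoilGeometry:
    """Magstim 70 mm double coil: two flat wings of 9 windings each.

    The windings span radii ``inner_diameter/2 -> outer_diameter/2`` at a
    radial pitch of ``winding_gap`` (defaults: 16 -> 24 mm at 1 mm pitch, the
    only layout consistent with all three printed numbers).  Wings are
    adjacent (tangent at the junction) with opposite senses.
    """
    if min(n_windings, inner_diameter, outer_diameter, winding_gap) <= 0:
        raise ValueError("geometric parameters must be positive")
    span = (outer_diameter - inner_diameter) / 2.0
    needed = (n_windings - 1) * winding_gap
    if abs(needed - span) > 1e-9 and needed > span + 1e-12:
        raise ValueError(
            f"{n_windings} windings at {winding_gap * 1e3:.3g} mm pitch need a "
            f"{needed * 1e3:.3g} mm radial span; only {span * 1e3:.3g} mm available"
        )
    normal = _check_unit(normal, "normal")
    wing_axis = _check_unit(wing_axis, "wing_axis")
    center = np.asarray(center, dtype=float)
    r_outer = outer_diameter / 2.0
    radii = inner_diameter / 2.0 + winding_gap * np.arange(n_windings)
    wings = []
    for side, direction in ((+1, right_wing_direction), (-1, -right_wing_direction)):
        c = center + side * r_outer * wing_axis
        wings.append(
            _concentric_loops(radii, c, normal, n_segments, direction, "magstim_d70")
        )
    coil = combine_coils(*wings, name="magstim_d70")
    coil.reference_point = center
    return coil


def combine_coils(*coils: CoilGeometry, name: str = "combined", reference_point=None) -> CoilGeometry:
    """Concatenate segment lists; all sub-coils share the drive current."""
    if not coils:
        raise ValueError("need at least one coil")
    ref = reference_point if reference_point is not None else coils[0].reference_point
    return CoilGeometry(
        starts=np.concatenate([c.starts for c in coils]),
        ends=np.concatenate([c.ends for c in coils]),
        weights=np.concatenate([c.weights for c in coils]),
        name=name,
        reference_point=np.asarray(ref, dtype=float),
    )


def place_on_head(
    coil: CoilGeometry,
    head: LabelVolume,
    mode: str = "vertex-offset",
    offset: float = 0.010,
) -> CoilGeometry:
    """Translate a coil into position relative to a labeled head volume.

    ``vertex-offset`` puts the coil reference point ``offset`` above the
    topmost scalp voxel plane along the superior axis, laterally centered on
    the topmost head layer.  ``halo-ring`` puts the coil plane ``offset``
    below the vertex (default for the Halo: 0.097 m), centered on the head's
    axial centroid.
    """
    mask = head.head_mask()
    if not mask.any():
        raise ValueError("head volume has no labeled voxels")
    ax = head.superior_axis
    grid = head.grid
    centers = grid.voxel_centers()
    top_center = centers[mask][:, ax].max()
    vertex = top_center + 0.5 * grid.spacing  # topmost scalp voxel plane

    if mode == "vertex-offset":
        top_layer = mask & (np.abs(centers[..., ax] - top_center) < 0.5 * grid.spacing)
        target = centers[top_layer].mean(axis=0)
        target[ax] = vertex + offset
    elif mode == "halo-ring":
        target = centers[mask].mean(axis=0)
        target[ax] = vertex - offset
    else:
        raise ValueError(f"unknown placement mode {mode!r}")
    return coil.translated(target - coil.reference_point)
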