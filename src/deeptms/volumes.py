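"""Voxel-grid containers shared across the package.

All grids are uniform and isotropic: voxel ``(i, j, k)`` has its center at
``origin + (index + 0.5) * spacing``.  World coordinates are in meters with a
RAS-like convention (+x right, +y anterior, +z superior) for generated
phantoms; loaded volumes carry their own affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["Grid", "FieldVolume", "LabelVolume"]


@dataclass(frozen=True)
class Grid:
    """Geometry of a uniform voxel grid: shape, isotropic spacing, origin."""

    shape: tuple[int, int, int]
    spacing: float
    origin: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError("shape must be three positive integers")

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """All voxel centers as an ``(nx, ny, nz, 3)`` array [m]."""
        xs, ys, zs = (self.axis_centers(a) for a in range(3))
        out = np.empty(self.shape + (3,), dtype=float)
        out[..., 0] = xs[:, None, None]
        out[..., 1] = ys[None, :, None]
        out[..., 2] = zs[None, None, :]
        return out

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing**3)

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= tol
            and bool(np.all(np.abs(self.origin - other.origin) <= tol))
        )


def _affine(spacing: float, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= spacing * 1000.0  # NIfTI convention is mm
    aff[:3, 3] = (np.asarray(origin) + 0.5 * spacing) * 1000.0
    return aff


@dataclass
class FieldVolume:
    """A scalar or 3-vector field sampled at voxel centers.

    ``values`` has shape ``grid.shape`` (scalar) or ``grid.shape + (3,)``
    (vector).  ``kind`` tags the physical quantity (``"A0"`` [V*s/m per A],
    ``"B"`` [T], ``"E"`` [V/m], ``"phi"`` [V]).  NaN marks voxels where the
    field is undefined (outside the lossy domain, or inside the
    wire-exclusion radius).
    """

    values: np.ndarray
    grid: Grid
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape not in (self.grid.shape, self.grid.shape + (3,)):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def is_vector(self) -> bool:
        return self.values.ndim == 4

    def magnitude(self) -> np.ndarray:
        if self.is_vector:
            return np.linalg.norm(self.values, axis=-1)
        return np.abs(self.values)

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(
            self.values.astype(np.float32), _affine(self.grid.spacing, self.grid.origin)
        )

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)


@dataclass
class LabelVolume:
    """Integer tissue labels on a uniform grid.

    Label 0 is air/background (zero conductivity).  ``label_names`` maps every
    nonzero label to a tissue name.  ``superior_axis`` indexes the axis
    pointing toward the vertex (+z for generated phantoms).
    """

    labels: np.ndarray
    grid: Grid
    label_names: dict[int, str] = field(default_factory=dict)
    superior_axis: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without a name: {sorted(missing)}")

    @property
    def name_to_label(self) -> dict[str, int]:
        return {v: k for k, v in self.label_names.items()}

    def mask(self, *tissue_names: str) -> np.ndarray:
        """Boolean mask of voxels carrying any of the named tissues."""
        lut = self.name_to_label
        out = np.zeros(self.grid.shape, dtype=bool)
        for name in tissue_names:
            if name not in lut:
                raise KeyError(f"tissue {name!r} not present in volume")
            out |= self.labels == lut[name]
        return out

    def head_mask(self) -> np.ndarray:
        return self.labels != 0

    def save(self, path: str) -> None:
        """Write the labels as NIfTI plus a ``<path>.labels.json`` sidecar.

        The sidecar carries the label->tissue map and the superior axis,
        neither of which fits in NIfTI header fields.
        """
        import json

        img = nib.Nifti1Image(
            self.labels.astype(np.int16), _affine(self.grid.spacing, self.grid.origin)
        )
        nib.save(img, path)
        sidecar = {
            "label_names": {str(k): v for k, v in self.label_names.items()},
            "superior_axis": self.superior_axis,
        }
        with open(str(path) + ".labels.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
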