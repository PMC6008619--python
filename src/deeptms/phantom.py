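"""Synthetic head phantoms, labeled-volume I/O and conductivity assignment.

The layered-sphere phantom emulates the gross architecture of an anatomical
head model: concentric scalp / skull / CSF / gray-matter shells around a
white-matter core, with deep-structure analogs (hippocampus, nucleus
accumbens, amygdala as mirrored left/right ellipsoid pairs; thalamus and
hypothalamus at the midline; a cerebellum blob inferior-posterior) embedded
in the core.  Voxels are assigned by a center-point membership test, so the
construction is fully deterministic.

What it deliberately does not emulate: cortical folding (gyri/sulci), skull
inhomogeneity, the neck, and anisotropic white matter.  Field magnitudes on
the phantom are therefore indicative, not anatomical predictions; the
phantom's role is to exercise every pipeline stage on a head-like topology
with known symmetries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volumes import Grid, LabelVolume

__all__ = [
    "DeepStructure",
    "ConductivityMap",
    "default_deep_structures",
    "build_layered_sphere_phantom",
    "load_label_volume",
    "load_tissue_table",
    "labels_to_sigma",
]

SHELL_TISSUES = ("scalp", "skull", "csf", "gray_matter", "white_matter")


@dataclass(frozen=True)
class DeepStructure:
    """An ellipsoidal deep-structure analog inside the white-matter core."""

    tissue: str
    center: tuple[float, float, float]  # [m], phantom frame
    semi_axes: tuple[float, float, float]  # [m]
    side: str = "midline"  # left / right / midline

    def membership(self, centers: np.ndarray) -> np.ndarray:
        d = (centers - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return (d**2).sum(axis=-1) < 1.0


def _mirrored(tissue: str, center, semi_axes) -> list[DeepStructure]:
    cx, cy, cz = center
    return [
        DeepStructure(tissue, (-cx, cy, cz), semi_axes, "left"),
        DeepStructure(tissue, (+cx, cy, cz), semi_axes, "right"),
    ]


def default_deep_structures(scale: float = 1.0) -> list[DeepStructure]:
    """Deep-structure analogs at anatomically motivated phantom positions.

    Positions and sizes are laid out for the default 71 mm white-matter core
    and multiplied by ``scale`` (phantoms of other sizes pass
    core_radius / 0.071): bilateral hippocampi posterior-lateral, amygdalae
    anterior to them, accumbens analogs anterior-medial-inferior, thalamus
    and hypothalamus at the midline, cerebellum inferior-posterior.
    +x is right, +y anterior, +z superior.
    """
    if scale != 1.0:
        return [
            DeepStructure(
                s.tissue,
                tuple(scale * c for c in s.center),
                tuple(scale * a for a in s.semi_axes),
                s.side,
            )
            for s in default_deep_structures()
        ]
    out: list[DeepStructure] = []
    out += _mirrored("hippocampus", (0.028, -0.020, -0.005), (0.010, 0.018, 0.008))
    out += _mirrored("nucleus_accumbens", (0.009, 0.026, -0.013), (0.005, 0.006, 0.005))
    out += _mirrored("amygdala", (0.024, 0.010, -0.012), (0.008, 0.007, 0.006))
    out.append(DeepStructure("thalamus", (0.0, -0.005, 0.008), (0.013, 0.011, 0.009)))
    out.append(DeepStructure("hypothalamus", (0.0, 0.004, -0.014), (0.006, 0.005, 0.004)))
    out.append(DeepStructure("cerebellum", (0.0, -0.028, -0.036), (0.024, 0.016, 0.014)))
    return out


def build_layered_sphere_phantom(
    outer_radius: float = 0.090,
    layer_thicknesses: tuple[float, float, float, float] = (0.005, 0.007, 0.003, 0.004),
    spacing: float = 0.002,
    structures: list[DeepStructure] | None = None,
    pad_voxels: int = 1,
) -> LabelVolume:
    """Concentric-sphere head phantom with embedded deep-structure analogs.

    ``layer_thicknesses`` are (scalp, skull, CSF, gray matter) from the
    outside in; everything deeper is white matter.  The grid is mirror
    symmetric about all three mid-planes (no voxel center lies exactly on
    x = 0), so left/right structure pairs occupy equal voxel counts.
    """
    if outer_radius <= 0 or spacing <= 0:
        raise ValueError("outer_radius and spacing must be positive")
    thick = np.asarray(layer_thicknesses, dtype=float)
    if thick.shape != (4,) or np.any(thick <= 0):
        raise ValueError("need four positive layer thicknesses")
    if thick.sum() >= outer_radius:
        raise ValueError("layers do not nest: thicknesses exceed the radius")

    half = int(np.ceil(outer_radius / spacing)) + pad_voxels
    n = 2 * half
    grid = Grid(shape=(n, n, n), spacing=spacing, origin=-half * spacing * np.ones(3))
    centers = grid.voxel_centers()
    r = np.linalg.norm(centers, axis=-1)

    # shell radii from the outside in; innermost is the white-matter core
    radii = outer_radius - np.concatenate([[0.0], np.cumsum(thick)])
    labels = np.zeros(grid.shape, dtype=np.int16)
    for lab, (r_out, name) in enumerate(zip(radii, SHELL_TISSUES), start=1):
        labels[r < r_out] = lab
    label_names = {i + 1: name for i, name in enumerate(SHELL_TISSUES)}

    wm_label = len(SHELL_TISSUES)
    defaults_used = structures is None
    if defaults_used:
        core_radius = outer_radius - float(thick.sum())
        structures = default_deep_structures(scale=core_radius / 0.071)
    name_to_label = {v: k for k, v in label_names.items()}
    next_label = wm_label + 1
    for s in structures:
        inside = s.membership(centers)
        if not inside.any():
            if defaults_used:
                # auto-scaled default too small for this spacing: skip it
                continue
            raise ValueError(f"structure {s.tissue}/{s.side} contains no voxel")
        hit = labels[inside]
        if np.any(hit != wm_label):
            clash = {label_names.get(int(l), "air") for l in np.unique(hit) if l != wm_label}
            raise ValueError(
                f"structure {s.tissue}/{s.side} leaves the white-matter core "
                f"(overlaps {sorted(clash)})"
            )
        if s.tissue not in name_to_label:
            name_to_label[s.tissue] = next_label
            label_names[next_label] = s.tissue
            next_label += 1
        labels[inside] = name_to_label[s.tissue]
    return LabelVolume(labels=labels, grid=grid, label_names=label_names)


def load_label_volume(
    path,
    label_names: dict[int, str] | None = None,
    grouping: dict[int, str] | None = None,
    strict: bool = True,
    superior_axis: int = 2,
) -> LabelVolume:
    """Load an integer labeled volume (NIfTI) into a :class:`LabelVolume`.

    The label->tissue map comes from, in order of precedence: ``grouping``
    (merges source labels into named tissues), ``label_names``, or the
    ``.labels.json`` sidecar written by :meth:`LabelVolume.save`.  In strict
    mode unmapped nonzero labels are an error; otherwise they are reported
    and mapped to background.  Anisotropic voxel spacing beyond 1% is
    rejected (resampling is out of scope here), as is a volume without a
    gray-matter label (the V50 threshold needs a cortex).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("volume is not integer-labeled")
        data = rounded.astype(np.int32)
    aff = img.affine
    diag = np.diag(aff)[:3]
    if np.any(diag <= 0) or np.any(np.abs(aff[:3, :3] - np.diag(diag)) > 1e-6 * abs(diag).max()):
        raise ValueError("only axis-aligned volumes with positive spacing are supported")
    spacings = diag / 1000.0  # NIfTI affines are in mm
    if (spacings.max() - spacings.min()) / spacings.mean() > 0.01:
        raise ValueError(
            f"anisotropic spacing {spacings * 1e3} mm: resample to isotropic first"
        )
    spacing = float(spacings.mean())
    origin = aff[:3, 3] / 1000.0 - 0.5 * spacing

    mapping = label_names
    if mapping is None and grouping is None:
        sidecar = Path(str(path) + ".labels.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            mapping = {int(k): v for k, v in meta["label_names"].items()}
            superior_axis = meta.get("superior_axis", superior_axis)
    if grouping is not None:
        # merge source labels into named tissues with fresh compact labels
        tissues = sorted(set(grouping.values()))
        new_label = {t: i + 1 for i, t in enumerate(tissues)}
        out = np.zeros_like(data, dtype=np.int16)
        for src, tissue in grouping.items():
            out[data == src] = new_label[tissue]
        data = out
        mapping = {v: k for k, v in new_label.items()}
    if mapping is None:
        raise ValueError("no label->tissue map: pass label_names or grouping")

    present = set(np.unique(data).tolist()) - {0}
    unknown = sorted(present - set(mapping))
    if unknown:
        if strict:
            raise ValueError(f"unmapped labels present: {unknown}")
        for lab in unknown:
            data = np.where(data == lab, 0, data)
    if "gray_matter" not in mapping.values():
        raise ValueError("volume has no gray_matter label; V50 needs a cortex")
    grid = Grid(shape=data.shape, spacing=spacing, origin=origin)
    keep = {k: v for k, v in mapping.items() if k in present}
    return LabelVolume(
        labels=data.astype(np.int16), grid=grid,
        label_names=keep or dict(mapping), superior_axis=superior_axis,
    )


@dataclass
class ConductivityMap:
    """Voxelwise electrical conductivity [S/m]; zero exactly on background."""

    sigma: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != self.grid.shape:
            raise ValueError("sigma shape does not match grid")
        if np.any(self.sigma < 0):
            raise ValueError("conductivity must be nonnegative")

    @property
    def lossy_mask(self) -> np.ndarray:
        return self.sigma > 0


def load_tissue_table(path=None) -> pd.DataFrame:
    """Tissue->conductivity table (S/m at the stimulation frequency).

    Defaults to the packaged low-frequency head-tissue table; see the CSV
    header for provenance and version.
    """
    if path is None:
        ref = resources.files("deeptms") / "data" / "tissue_conductivity_2500Hz.csv"
        with resources.as_file(ref) as p:
            table = pd.read_csv(p, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    required = {"tissue", "sigma_S_per_m"}
    if not required <= set(table.columns):
        raise ValueError(f"tissue table must have columns {sorted(required)}")
    if (table["sigma_S_per_m"] < 0).any():
        raise ValueError("negative conductivity in tissue table")
    return table


def labels_to_sigma(volume: LabelVolume, table: pd.DataFrame) -> ConductivityMap:
    """Voxelwise conductivity lookup; background stays exactly zero."""
    lut = dict(zip(table["tissue"], table["sigma_S_per_m"]))
    missing = [t for t in volume.label_names.values() if t not in lut]
    if missing:
        raise ValueError(f"tissues without a conductivity: {sorted(set(missing))}")
    sigma = np.zeros(volume.grid.shape, dtype=float)
    for lab, tissue in volume.label_names.items():
        sigma[volume.labels == lab] = lut[tissue]
    return ConductivityMap(sigma=sigma, grid=volume.grid)
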