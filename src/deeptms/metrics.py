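"""Exposure statistics: cortical peak field, V50 spread, hemispheric split.

V50 is the percentage of a tissue's volume exposed to an electric-field
amplitude at or above half the cortical peak, where "peak" is the 99th
percentile of the gray-matter amplitude distribution rather than the raw
maximum — voxel models carry localized staircasing artifacts at tissue
boundaries, and the percentile is robust to them.  V50 is scale invariant
(the threshold follows the cortical peak) and quantifies field *spread*:
deep-penetrating coils buy depth with larger V50 in the cortex.

Asymmetric coil combinations (Halo + double-cone / figure-of-eight) are
reported per hemisphere; the hemispheric V50 denominator is the tissue
volume within that hemisphere, so each side can independently reach 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volumes import FieldVolume, LabelVolume

__all__ = [
    "cortical_peak",
    "v50",
    "hemisphere_masks",
    "metrics_table",
    "spread_table_pivot",
    "BRAIN_TISSUES",
]

# tissues reported in the spread table, in report order
BRAIN_TISSUES = (
    "gray_matter",
    "white_matter",
    "hippocampus",
    "nucleus_accumbens",
    "cerebellum",
    "thalamus",
    "hypothalamus",
    "amygdala",
)


def cortical_peak(e_field: FieldVolume, gm_mask: np.ndarray, percentile: float = 99.0) -> float:
    """Cortical peak |E| [V/m]: percentile of the GM amplitude distribution.

    Linear-interpolation percentile convention, voxels equally weighted
    (uniform grid).
    """
    if gm_mask.shape != e_field.grid.shape:
        raise ValueError("mask shape does not match grid")
    if not gm_mask.any():
        raise ValueError("empty gray-matter mask")
    mag = e_field.magnitude()[gm_mask]
    mag = mag[np.isfinite(mag)]
    if mag.size == 0:
        raise ValueError("no finite field values in the gray-matter mask")
    return float(np.percentile(mag, percentile, method="linear"))


def v50(
    e_field: FieldVolume,
    tissue_mask: np.ndarray,
    e_peak_cortex: float,
    fraction: float = 0.5,
) -> float:
    """Percentage of tissue voxels with |E| >= fraction * cortical peak.

    The threshold is inclusive.  Returns NaN for an empty mask (absent
    tissue), never a silent zero.
    """
    if e_peak_cortex <= 0:
        raise ValueError("cortical peak must be positive")
    if not tissue_mask.any():
        return float("nan")
    mag = e_field.magnitude()[tissue_mask]
    mag = np.nan_to_num(mag)  # undefined field counts as below threshold
    return float(100.0 * np.count_nonzero(mag >= fraction * e_peak_cortex) / mag.size)


def hemisphere_masks(
    volume: LabelVolume, plane_axis: int = 0, plane_position: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint (left, right) partition of head voxels by the mid-sagittal plane.

    ``plane_axis`` is the left-right axis (+ pointing right); the plane
    defaults to the head centroid along that axis.  Voxels exactly on the
    plane go to the right (documented tie-break; affects at most one voxel
    layer and none on the mirror-symmetric phantom grid).
    """
    head = volume.head_mask()
    coords = volume.grid.axis_centers(plane_axis)
    if plane_position is None:
        idx = np.nonzero(head)[plane_axis]
        plane_position = float(coords[idx].mean()) if idx.size else 0.0
    shape = [1, 1, 1]
    shape[plane_axis] = -1
    signed = np.broadcast_to(coords.reshape(shape) - plane_position, volume.grid.shape)
    right = head & (signed >= 0)
    left = head & ~(signed >= 0)
    return left, right


def metrics_table(
    e_fields: dict[str, FieldVolume],
    volume: LabelVolume,
    tissues: tuple[str, ...] = BRAIN_TISSUES,
    split_coils: tuple[str, ...] | None = None,
    plane_axis: int = 0,
    plane_position: float | None = None,
    threshold_fraction: float = 0.5,
    percentile: float = 99.0,
) -> pd.DataFrame:
    """Per-coil, per-tissue V50 table with optional hemispheric split.

    ``e_fields`` maps coil name -> solved E field on ``volume``'s grid.
    Coils named in ``split_coils`` (default: names containing "hfa"/"hda")
    are reported per hemisphere; the rest over the whole tissue.  Absent
    tissues are reported as NaN.  Columns: coil, tissue, hemisphere,
    v50_percent, n_voxels, volume_m3, e_peak_cortex_V_per_m.
    """
    present = set(volume.label_names.values())
    left, right = hemisphere_masks(volume, plane_axis, plane_position)
    if split_coils is None:
        split_coils = tuple(
            name for name in e_fields if any(tag in name.lower() for tag in ("hfa", "hda"))
        )
    vox_vol = volume.grid.voxel_volume
    rows = []
    for coil, e in e_fields.items():
        if not e.grid.same_geometry(volume.grid):
            raise ValueError(f"E field for {coil!r} is not on the volume grid")
        peak = cortical_peak(e, volume.mask("gray_matter"), percentile)
        # a coil that induces no field anywhere spreads nothing: report 0,
        # not the degenerate 100% a zero threshold would imply
        zero_field = peak == 0.0
        hemis = (("right", right), ("left", left)) if coil in split_coils else (("whole", None),)
        for tissue in tissues:
            t_mask = volume.mask(tissue) if tissue in present else None
            for hemi_name, hemi_mask in hemis:
                if t_mask is None:
                    rows.append((coil, tissue, hemi_name, np.nan, 0, 0.0, peak))
                    continue
                m = t_mask if hemi_mask is None else (t_mask & hemi_mask)
                if not m.any():
                    val = np.nan
                elif zero_field:
                    val = 0.0
                else:
                    val = v50(e, m, peak, threshold_fraction)
                rows.append(
                    (coil, tissue, hemi_name, val, int(m.sum()), m.sum() * vox_vol, peak)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "coil", "tissue", "hemisphere", "v50_percent",
            "n_voxels", "volume_m3", "e_peak_cortex_V_per_m",
        ],
    )


def spread_table_pivot(df: pd.DataFrame) -> pd.DataFrame:
    """Publication-style V50 layout: one row per coil (suffixed _R/_L for
    hemisphere-split coils), one column per tissue."""
    d = df.copy()
    suffix = d["hemisphere"].map({"right": "_R", "left": "_L", "whole": ""})
    d["row"] = d["coil"].str.upper() + suffix
    pivot = d.pivot(index="row", columns="tissue", values="v50_percent")
    order = [t for t in BRAIN_TISSUES if t in pivot.columns]
    return pivot[order]
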