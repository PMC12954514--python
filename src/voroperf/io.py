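"""Reading, writing and resampling of perfusion volumes, masks and PFT tables.

Volumes and masks are NIfTI files (``.nii``/``.nii.gz``) on a common grid; the
PFT table is an RFC-4180 CSV with columns ``case_id, dlco_pct, fev1_pct,
fvc_pct, fev1_fvc``.  All downstream geometry assumes an isotropic working
grid, produced by :func:`resample_isotropic` (trilinear for intensities,
nearest-neighbour for labels).
"""

from __future__ import annotations

import math
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import (
    LUNG_LABELS,
    AlignmentError,
    DegenerateCaseError,
    LungMask,
    MaskCodingError,
    PftRecord,
    VolumeGrid,
    validate_pair,
)

PFT_COLUMNS = ("case_id", "dlco_pct", "fev1_pct", "fvc_pct", "fev1_fvc")


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return np.asarray(data), tuple(float(z) for z in zooms)


def read_case(volume_path, mask_path) -> tuple[VolumeGrid, LungMask]:
    """Read a co-registered perfusion volume + lung mask pair.

    Raises :class:`AlignmentError` on shape/spacing mismatch,
    :class:`MaskCodingError` for labels outside {0,1,2}, and
    :class:`DegenerateCaseError` if either lung is empty.
    """
    vol_data, vol_spacing = _load_nifti(volume_path)
    mask_data, mask_spacing = _load_nifti(mask_path)
    grid = VolumeGrid(vol_data.astype(np.float64), vol_spacing)
    mask = LungMask(mask_data, mask_spacing)
    validate_pair(grid, mask)
    mask.require_lungs()
    return grid, mask


def write_case(volume_path, mask_path, grid: VolumeGrid, mask: LungMask) -> None:
    """Write a volume/mask pair as NIfTI with a diagonal spacing affine."""
    validate_pair(grid, mask)
    for path, arr, spacing in (
        (volume_path, grid.values, grid.spacing),
        (mask_path, mask.labels.astype(np.int16), mask.spacing),
    ):
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        img = nib.Nifti1Image(arr, affine)
        img.header.set_zooms(spacing)
        nib.save(img, str(path))


def _trilinear(values: np.ndarray, coords: list[np.ndarray]) -> np.ndarray:
    """Trilinear interpolation at fractional index coordinates (edge-clamped).

    Uses the nested-lerp form ``a + t*(b - a)`` so constant fields are
    reproduced bit-exactly, not merely to roundoff.
    """
    shape = values.shape
    lo = []
    hi = []
    frac = []
    for c, n in zip(coords, shape):
        c = np.clip(c, 0.0, n - 1)
        f = np.floor(c).astype(np.intp)
        f = np.minimum(f, n - 2) if n > 1 else np.zeros_like(f)
        lo.append(f)
        hi.append(np.minimum(f + 1, n - 1))
        frac.append(c - f)

    def lerp(a, b, t):
        return a + t * (b - a)

    c00 = lerp(values[lo[0], lo[1], lo[2]], values[hi[0], lo[1], lo[2]], frac[0])
    c01 = lerp(values[lo[0], lo[1], hi[2]], values[hi[0], lo[1], hi[2]], frac[0])
    c10 = lerp(values[lo[0], hi[1], lo[2]], values[hi[0], hi[1], lo[2]], frac[0])
    c11 = lerp(values[lo[0], hi[1], hi[2]], values[hi[0], hi[1], hi[2]], frac[0])
    c0 = lerp(c00, c10, frac[1])
    c1 = lerp(c01, c11, frac[1])
    return lerp(c0, c1, frac[2])


def resample_isotropic(
    grid: VolumeGrid, mask: LungMask, iso_mm: float = 2.0
) -> tuple[VolumeGrid, LungMask]:
    """Resample a volume/mask pair onto an isotropic ``iso_mm`` grid.

    Intensities are interpolated trilinearly, labels by nearest neighbour.
    Voxel centres sit at ``index * spacing``, so new centre ``i * iso_mm``
    maps to fractional old index ``i * iso_mm / old_spacing``.  The output
    shape covers the input physical extent (``ceil(extent / iso_mm)``).
    """
    if iso_mm <= 0:
        raise ValueError(f"iso_mm must be > 0, got {iso_mm}")
    validate_pair(grid, mask)
    old_spacing = np.asarray(grid.spacing, dtype=float)
    new_shape = tuple(
        int(math.ceil(n * s / iso_mm)) for n, s in zip(grid.shape, old_spacing)
    )
    axes = [np.arange(n) * iso_mm / s for n, s in zip(new_shape, old_spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    values = _trilinear(grid.values, coords)
    labels = ndimage.map_coordinates(mask.labels, coords, order=0, mode="nearest")
    out_grid = VolumeGrid(values, (iso_mm,) * 3)
    out_mask = LungMask(labels.astype(mask.labels.dtype), (iso_mm,) * 3)
    for lab in LUNG_LABELS:
        if mask.lung_voxel_count(lab) > 0 and out_mask.lung_voxel_count(lab) == 0:
            raise DegenerateCaseError(
                f"lung label {lab} vanished at iso_mm={iso_mm}; choose a finer spacing"
            )
    return out_grid, out_mask


def read_pft_table(csv_path) -> list[PftRecord]:
    """Parse the cohort PFT table.

    Only ``dlco_pct`` may be empty (recorded as missing); an empty cell in any
    other column is rejected.
    """
    df = pd.read_csv(csv_path, dtype={"case_id": str})
    missing_cols = [c for c in PFT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{csv_path}: missing required columns {missing_cols}")
    records: list[PftRecord] = []
    for _, row in df.iterrows():
        for name in ("fev1_pct", "fvc_pct", "fev1_fvc"):
            if pd.isna(row[name]):
                raise ValueError(
                    f"{csv_path}: case {row['case_id']}: {name} is empty "
                    "(only dlco_pct may be missing)"
                )
        dlco = None if pd.isna(row["dlco_pct"]) else float(row["dlco_pct"])
        records.append(
            PftRecord(
                case_id=str(row["case_id"]),
                dlco_pct=dlco,
                fev1_pct=float(row["fev1_pct"]),
                fvc_pct=float(row["fvc_pct"]),
                fev1_fvc=float(row["fev1_fvc"]),
            )
        )
    return records


def pft_frame(records: list[PftRecord]) -> pd.DataFrame:
    """PFT records as a DataFrame indexed by case_id (missing DLCO -> NaN)."""
    return pd.DataFrame(
        {
            "dlco_pct": [np.nan if r.dlco_pct is None else r.dlco_pct for r in records],
            "fev1_pct": [r.fev1_pct for r in records],
            "fvc_pct": [r.fvc_pct for r in records],
            "fev1_fvc": [r.fev1_fvc for r in records],
        },
        index=pd.Index([r.case_id for r in records], name="case_id"),
    )


def load_cohort_dir(cohort_dir) -> tuple[list[tuple[str, VolumeGrid, LungMask]], list[PftRecord]]:
    """Load a cohort laid out as ``<case_id>/perfusion.nii.gz`` + ``lungs.nii.gz``
    and a top-level ``pft.csv``."""
    cohort_dir = Path(cohort_dir)
    records = read_pft_table(cohort_dir / "pft.csv")
    cases = []
    for rec in records:
        case_dir = cohort_dir / rec.case_id
        grid, mask = read_case(case_dir / "perfusion.nii.gz", case_dir / "lungs.nii.gz")
        cases.append((rec.case_id, grid, mask))
    return cases, records


__all__ = [
    "read_case",
    "write_case",
    "resample_isotropic",
    "read_pft_table",
    "pft_frame",
    "load_cohort_dir",
    "AlignmentError",
    "MaskCodingError",
    "DegenerateCaseError",
]
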