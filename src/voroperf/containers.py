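"""Core in-memory containers for perfusion volumes and lung masks.

A :class:`VolumeGrid` is a 3D scalar field (perfusion intensity, arbitrary
units, or per-lung percentiles in (0, 1]) together with its voxel spacing in
millimetres.  A :class:`LungMask` is an integer label volume on the same grid
coding 0 = background, 1 = left lung, 2 = right lung.

The physical position of a voxel centre is ``index * spacing`` (0-based
indices); file origins/affines are honoured at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LEFT_LUNG = 1
RIGHT_LUNG = 2
LUNG_LABELS = (LEFT_LUNG, RIGHT_LUNG)


class AlignmentError(ValueError):
    """Volume and mask do not share shape/spacing."""


class MaskCodingError(ValueError):
    """Mask contains labels outside {0, 1, 2}."""


class DegenerateCaseError(ValueError):
    """A lung region required by an operation is empty."""


def _as_spacing(spacing) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing!r}")
    return sp


@dataclass
class VolumeGrid:
    """3D scalar field with voxel spacing (mm/voxel)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.values.ndim}")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class LungMask:
    """Left/right lung label volume: 0=background, 1=left, 2=right."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(self.labels)
            if not np.array_equal(rounded, self.labels):
                raise MaskCodingError("mask labels are not integer-valued")
            self.labels = rounded.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.labels), [0, LEFT_LUNG, RIGHT_LUNG])
        if bad.size:
            raise MaskCodingError(f"mask contains labels outside {{0,1,2}}: {bad.tolist()}")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def lung_voxel_count(self, lung_label: int) -> int:
        return int(np.count_nonzero(self.labels == lung_label))

    def require_lungs(self) -> None:
        """Raise unless both lungs are nonempty (a valid clinical case)."""
        for lab in LUNG_LABELS:
            if self.lung_voxel_count(lab) == 0:
                side = "left" if lab == LEFT_LUNG else "right"
                raise DegenerateCaseError(f"{side} lung (label {lab}) is empty")


def validate_pair(grid: VolumeGrid, mask: LungMask, *, rtol: float = 1e-5) -> None:
    """Check a volume/mask pair shares grid geometry and has finite in-mask values."""
    if grid.shape != mask.shape:
        raise AlignmentError(f"shape mismatch: volume {grid.shape} vs mask {mask.shape}")
    if not np.allclose(grid.spacing, mask.spacing, rtol=rtol):
        raise AlignmentError(
            f"spacing mismatch: volume {grid.spacing} vs mask {mask.spacing}"
        )
    inside = mask.labels > 0
    if inside.any() and not np.isfinite(grid.values[inside]).all():
        raise ValueError("non-finite perfusion values inside the lung mask")


@dataclass
class PftRecord:
    """One case's pulmonary function test results (percent-predicted values).

    ``dlco_pct`` may be ``None`` (DLCO is not measured for every case); the
    spirometric values are mandatory.
    """

    case_id: str
    dlco_pct: float | None
    fev1_pct: float
    fvc_pct: float
    fev1_fvc: float

    def __post_init__(self) -> None:
        for name in ("fev1_pct", "fvc_pct", "fev1_fvc"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite value >= 0, got {v!r}")
            setattr(self, name, float(v))
        if self.dlco_pct is not None:
            if not np.isfinite(self.dlco_pct) or self.dlco_pct < 0:
                raise ValueError(f"dlco_pct must be >= 0 or missing, got {self.dlco_pct!r}")
            self.dlco_pct = float(self.dlco_pct)
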