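"""Synthetic perfusion cohorts with defect-driven lung function.

The generator emulates the structure of a clinical perfusion/PFT cohort so the
whole pipeline is testable without protected data: each case gets

* a two-lobed lung mask (jittered ellipsoids, left label 1, right label 2);
* a strictly positive, smoothly heterogeneous raw perfusion field (blurred
  noise, in-lung mean ~1) with hypoperfused spherical defect regions inserted
  per lung to a requested in-lung volume fraction (intensities multiplied by a
  defect multiplier, so percentile maps stay informative);
* PFT values coupled monotonically (decreasing, with Gaussian noise, truncated
  at 0) to the case's volume-weighted total defect fraction, with DLCO set
  missing for a small fraction of cases.

Left and right defect burdens are drawn independently so left-right
combination operators are exercised asymmetrically.  All randomness descends
from one master seed; case ``i`` uses substream ``seed + i``, so cohorts are
extensible without reshuffling existing cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import DegenerateCaseError, LungMask, PftRecord, VolumeGrid
from .io import write_case

# (intercept, slope, noise_sd): measure = intercept - slope * total_defect_fraction + noise
DEFAULT_PFT_COUPLING = {
    "dlco_pct": (92.0, 85.0, 4.0),
    "fev1_pct": (96.0, 90.0, 4.0),
    "fvc_pct": (100.0, 60.0, 6.0),
    "fev1_fvc": (84.0, 55.0, 3.5),
}


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_cases: int = 36
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    iso_mm: float = 2.0
    left_center: tuple[float, float, float] = (20.0, 32.0, 32.0)
    left_axes: tuple[float, float, float] = (9.0, 12.0, 20.0)
    right_center: tuple[float, float, float] = (44.0, 32.0, 32.0)
    right_axes: tuple[float, float, float] = (10.0, 13.0, 21.0)
    center_jitter_sd: float = 1.5  # voxels
    axes_jitter_frac: float = 0.05
    smoothness_sd: float = 4.0  # Gaussian blur, voxels
    heterogeneity: float = 0.25  # relative sd of the base field around mean 1
    defect_fraction_range: tuple[float, float] = (0.0, 0.5)  # per lung, uniform
    defect_radius_range: tuple[float, float] = (4.0, 8.0)  # voxels
    defect_multiplier: float = 0.2
    dlco_missing_frac: float = 3.0 / 36.0
    pft_coupling: dict = field(default_factory=lambda: dict(DEFAULT_PFT_COUPLING))
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 4:
            raise ValueError("n_cases must be >= 4")
        if not (0.0 <= self.defect_multiplier < 1.0):
            raise ValueError("defect_multiplier must lie in [0, 1)")
        lo, hi = self.defect_fraction_range
        if not (0.0 <= lo <= hi <= 0.6):
            raise ValueError("defect fractions must lie in [0, 0.6]")
        for center, axes in ((self.left_center, self.left_axes), (self.right_center, self.right_axes)):
            for c, a, n in zip(center, axes, self.grid_shape):
                if a <= 0 or c - a < 0 or c + a > n - 1:
                    raise ValueError(
                        f"ellipsoid (center {center}, axes {axes}) does not fit grid {self.grid_shape}"
                    )
        for name, (icpt, slope, sd) in self.pft_coupling.items():
            if sd < 0 or slope < 0:
                raise ValueError(f"{name}: slope and noise sd must be >= 0")


@dataclass
class SyntheticCase:
    case_id: str
    grid: VolumeGrid
    mask: LungMask
    pft: PftRecord
    defect_fraction_left: float
    defect_fraction_right: float
    defect_fraction_total: float


def _ellipsoid(shape, center, axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return q <= 1.0


def make_lung_mask(config: CohortConfig, rng: np.random.Generator, max_retries: int = 10) -> LungMask:
    """Two disjoint jittered ellipsoids labelled 1 (left) and 2 (right)."""
    config.validate()
    shape = config.grid_shape
    for _ in range(max_retries):
        labels = np.zeros(shape, dtype=np.int16)
        ok = True
        regions = []
        for center, axes in ((config.left_center, config.left_axes), (config.right_center, config.right_axes)):
            c = np.asarray(center) + rng.normal(0.0, config.center_jitter_sd, 3)
            a = np.asarray(axes) * (1.0 + rng.normal(0.0, config.axes_jitter_frac, 3))
            if np.any(a <= 1.0) or np.any(c - a < 0) or np.any(c + a > np.asarray(shape) - 1):
                ok = False
                break
            region = _ellipsoid(shape, c, a)
            if not region.any():
                ok = False
                break
            regions.append(region)
        if not ok:
            continue
        left, right = regions
        if (left & right).any():
            continue
        labels[left] = 1
        labels[right] = 2
        return LungMask(labels, (config.iso_mm,) * 3)
    raise DegenerateCaseError("could not place disjoint lungs after retries")


def _insert_defects(
    base: np.ndarray,
    lung_sel: np.ndarray,
    fraction: float,
    config: CohortConfig,
    rng: np.random.Generator,
    max_iter: int = 500,
) -> tuple[np.ndarray, float]:
    """Multiply spherical regions by the defect multiplier until the requested
    in-lung volume fraction is covered (within +/-0.05)."""
    n_lung = int(lung_sel.sum())
    target = fraction * n_lung
    if target <= 0:
        return np.zeros_like(lung_sel), 0.0
    lung_idx = np.argwhere(lung_sel)
    defect = np.zeros_like(lung_sel)
    shape = np.asarray(base.shape)
    r_lo, r_hi = config.defect_radius_range
    covered = 0
    for _ in range(max_iter):
        if covered >= target:
            break
        center = lung_idx[rng.integers(lung_idx.shape[0])]
        radius = rng.uniform(r_lo, r_hi)
        # cap the sphere volume at the remaining deficit so the achieved
        # fraction cannot overshoot the +/-0.05 band
        remaining = target - covered
        r_cap = max(1.5, (remaining * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0))
        radius = min(radius, r_cap)
        lo = np.maximum(0, np.floor(center - radius).astype(int))
        hi = np.minimum(shape, np.ceil(center + radius).astype(int) + 1)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        sphere = sum((g - c) ** 2 for g, c in zip(grids, center)) <= radius**2
        new = sphere & lung_sel[sub] & ~defect[sub]
        defect[sub] |= new
        covered += int(new.sum())
    achieved = covered / n_lung
    if abs(achieved - fraction) > 0.05:
        raise ValueError(
            f"could not reach defect fraction {fraction:.2f} "
            f"(achieved {achieved:.2f}) with radii {config.defect_radius_range}"
        )
    return defect, achieved


def make_perfusion_map(
    mask: LungMask,
    defect_fraction_left: float,
    defect_fraction_right: float,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[VolumeGrid, tuple[float, float]]:
    """Strictly positive heterogeneous perfusion field with inserted defects.

    Returns the raw-valued grid and the achieved per-lung defect fractions.
    """
    for f in (defect_fraction_left, defect_fraction_right):
        if not (0.0 <= f <= 0.6):
            raise ValueError("defect fractions must lie in [0, 0.6]")
    noise = rng.random(mask.shape)
    base = ndimage.gaussian_filter(noise, config.smoothness_sd)
    sd = base.std()
    if sd > 0:
        base = 1.0 + config.heterogeneity * (base - base.mean()) / sd
    else:  # pathologically smooth field
        base = np.ones_like(base)
    base = np.clip(base, 0.05, None)
    achieved = []
    for lab, frac in ((1, defect_fraction_left), (2, defect_fraction_right)):
        sel = mask.labels == lab
        defect, ach = _insert_defects(base, sel, frac, config, rng)
        base = np.where(defect, base * config.defect_multiplier, base)
        achieved.append(ach)
    return VolumeGrid(base, mask.spacing), (achieved[0], achieved[1])


def pft_from_fraction(
    total_fraction: float, config: CohortConfig, rng: np.random.Generator
) -> dict[str, float]:
    """PFT values as noisy decreasing functions of total defect burden."""
    out = {}
    for name, (icpt, slope, sd) in config.pft_coupling.items():
        out[name] = max(0.0, icpt - slope * total_fraction + rng.normal(0.0, sd))
    return out


def sample_fractions(config: CohortConfig, rng: np.random.Generator) -> tuple[float, float]:
    lo, hi = config.defect_fraction_range
    return float(rng.uniform(lo, hi)), float(rng.uniform(lo, hi))


def make_cohort(config: CohortConfig) -> list[SyntheticCase]:
    """Generate a full deterministic cohort from the master seed."""
    config.validate()
    cohort_rng = np.random.default_rng(config.seed)
    n_missing = int(round(config.dlco_missing_frac * config.n_cases))
    missing_dlco = set(
        cohort_rng.choice(config.n_cases, size=n_missing, replace=False).tolist()
    ) if n_missing else set()
    cases = []
    for i in range(config.n_cases):
        rng = np.random.default_rng(config.seed + i)
        case_id = f"case{i:03d}"
        mask = make_lung_mask(config, rng)
        f_left, f_right = sample_fractions(config, rng)
        grid, (ach_l, ach_r) = make_perfusion_map(mask, f_left, f_right, config, rng)
        n_l = mask.lung_voxel_count(1)
        n_r = mask.lung_voxel_count(2)
        total = (ach_l * n_l + ach_r * n_r) / (n_l + n_r)
        vals = pft_from_fraction(total, config, rng)
        pft = PftRecord(
            case_id=case_id,
            dlco_pct=None if i in missing_dlco else vals["dlco_pct"],
            fev1_pct=vals["fev1_pct"],
            fvc_pct=vals["fvc_pct"],
            fev1_fvc=vals["fev1_fvc"],
        )
        cases.append(SyntheticCase(case_id, grid, mask, pft, ach_l, ach_r, total))
    return cases


def write_cohort(cases: list[SyntheticCase], outdir) -> None:
    """Write the standard case layout: per-case NIfTI pair + pft.csv + truth.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pft_rows = []
    truth_rows = []
    for case in cases:
        case_dir = outdir / case.case_id
        case_dir.mkdir(exist_ok=True)
        write_case(
            case_dir / "perfusion.nii.gz", case_dir / "lungs.nii.gz", case.grid, case.mask
        )
        pft_rows.append(
            {
                "case_id": case.case_id,
                "dlco_pct": "" if case.pft.dlco_pct is None else case.pft.dlco_pct,
                "fev1_pct": case.pft.fev1_pct,
                "fvc_pct": case.pft.fvc_pct,
                "fev1_fvc": case.pft.fev1_fvc,
            }
        )
        truth_rows.append(
            {
                "case_id": case.case_id,
                "defect_fraction_left": case.defect_fraction_left,
                "defect_fraction_right": case.defect_fraction_right,
                "defect_fraction_total": case.defect_fraction_total,
            }
        )
    pd.DataFrame(pft_rows).to_csv(outdir / "pft.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)


__all__ = [
    "CohortConfig",
    "SyntheticCase",
    "make_lung_mask",
    "make_perfusion_map",
    "pft_from_fraction",
    "sample_fractions",
    "make_cohort",
    "write_cohort",
]
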