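"""Hierarchical perfusion statistics: percentile maps, intra-/inter-subvolume
and left-right metrics, and the per-case global score.

A perfusion map is condensed into one scalar per :class:`MetricSpec` through
up to three levels:

1. *intra-subvolume* — summarize voxel intensities within each Voronoi
   subvolume (min, max, median, mean, CoV, 25th/75th percentile, skewness,
   mode/median);
2. *inter-subvolume* — aggregate the per-subvolume values within the lung(s)
   (P_N, CoV, mode/median, median, 25th/75th percentile, skewness), where
   ``P_N`` is the percentage of lung volume belonging to subvolumes whose value
   lies at or below N% of the maximum subvolume value;
3. *left-right* — combine the two per-lung values into one patient-level score
   (min/max/averages/volume- or perfusion-based selectors).

Conventions (documented because the field has competing ones): CoV is the
population standard deviation divided by the *median*; skewness is the
normalized third central moment m3/m2^1.5 with no bias correction; the mode is
the midpoint of the highest-count bin of a 64-bin equal-width histogram over
[min, max]; quantiles interpolate linearly between order statistics.

Undefined values (e.g. a ratio with zero median) are carried as NaN and poison
every score that depends on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import LUNG_LABELS, DegenerateCaseError, LungMask, VolumeGrid
from .voronoi import Partition

UNDEFINED = math.nan

SCENARIOS = (
    "full_lr_together",
    "full_lr_split",
    "voronoi_lr_together",
    "voronoi_lr_split",
)
INTRA_METRICS = (
    "min",
    "max",
    "median",
    "mean",
    "cov",
    "p25",
    "p75",
    "skewness",
    "mode_over_median",
)
INTER_METRICS = ("p_n", "cov", "mode_over_median", "median", "p25", "p75", "skewness")
LR_METRICS = (
    "min",
    "max",
    "avg",
    "vol_weighted_avg",
    "perf_weighted_avg",
    "largest_vol",
    "smallest_vol",
    "most_perf",
    "least_perf",
)
VALUE_KINDS = ("raw", "percentile")

MODE_HISTOGRAM_BINS = 64


# ---------------------------------------------------------------------------
# scalar statistics


def _histogram_mode(values: np.ndarray, bins: int = MODE_HISTOGRAM_BINS) -> float:
    lo = float(values.min())
    hi = float(values.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))  # ties -> lowest bin
    return float((edges[i] + edges[i + 1]) / 2.0)


def _stat_scalar(values: np.ndarray, metric: str) -> float:
    """One descriptive statistic of a nonempty 1D array (shared by the intra
    and inter levels)."""
    if metric == "min":
        return float(values.min())
    if metric == "max":
        return float(values.max())
    if metric == "median":
        return float(np.median(values))
    if metric == "mean":
        return float(values.mean())
    if metric == "p25":
        return float(np.quantile(values, 0.25))
    if metric == "p75":
        return float(np.quantile(values, 0.75))
    if metric == "cov":
        med = float(np.median(values))
        if med == 0.0:
            return UNDEFINED
        return float(values.std()) / med  # population sd
    if metric == "skewness":
        m = values.mean()
        d = values - m
        m2 = float(np.mean(d * d))
        if m2 == 0.0:
            return 0.0
        m3 = float(np.mean(d * d * d))
        return m3 / m2**1.5
    if metric == "mode_over_median":
        med = float(np.median(values))
        if med == 0.0:
            return UNDEFINED
        return _histogram_mode(values) / med
    raise ValueError(f"unknown metric {metric!r}")


def intra_stat(values, metric: str) -> float:
    """Intra-subvolume statistic of a nonempty multiset of voxel values."""
    if metric not in INTRA_METRICS:
        raise ValueError(f"unknown intra metric {metric!r}")
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("intra_stat requires a nonempty value set")
    if not np.isfinite(values).all():
        raise ValueError("intra_stat requires finite values")
    return _stat_scalar(values, metric)


def p_n_defect(subvalues: np.ndarray, weights: np.ndarray, n_threshold: float) -> float:
    """P_N: percentage of lung volume in subvolumes at or below N% of the
    maximum subvolume value."""
    cutoff = (n_threshold / 100.0) * float(subvalues.max())
    total = float(weights.sum())
    return 100.0 * float(weights[subvalues <= cutoff].sum()) / total


def inter_stat(
    subvalues, weights=None, metric: str = "median", n_threshold: float | None = None
) -> float:
    """Inter-subvolume statistic over per-subvolume values.

    ``weights`` (subvolume voxel counts) enter only ``P_N``; the descriptive
    statistics are applied unweighted to the subvolume values, mirroring the
    intra level.
    """
    if metric not in INTER_METRICS:
        raise ValueError(f"unknown inter metric {metric!r}")
    subvalues = np.asarray(subvalues, dtype=np.float64).ravel()
    if subvalues.size == 0:
        raise ValueError("inter_stat requires a nonempty value list")
    if np.isnan(subvalues).any():
        return UNDEFINED
    if metric == "p_n":
        if n_threshold is None:
            raise ValueError("P_N requires n_threshold")
        if weights is None:
            weights = np.ones_like(subvalues)
        weights = np.asarray(weights, dtype=np.float64).ravel()
        if weights.shape != subvalues.shape or (weights <= 0).any():
            raise ValueError("weights must be positive and match subvalues")
        return p_n_defect(subvalues, weights, float(n_threshold))
    return _stat_scalar(subvalues, metric)


def lr_combine(
    left: float,
    right: float,
    left_vol: float,
    right_vol: float,
    left_perf_total: float,
    right_perf_total: float,
    op: str,
) -> float:
    """Combine per-lung values into one patient-level value.

    Volume/perfusion ties on the selector operators go to the left lung.
    """
    if op not in LR_METRICS:
        raise ValueError(f"unknown LR metric {op!r}")
    if left_vol <= 0 or right_vol <= 0:
        raise ValueError("lung volumes must be positive")
    if math.isnan(left) or math.isnan(right):
        return UNDEFINED
    if op == "min":
        return min(left, right)
    if op == "max":
        return max(left, right)
    if op == "avg":
        return (left + right) / 2.0
    if op == "vol_weighted_avg":
        return (left * left_vol + right * right_vol) / (left_vol + right_vol)
    if op == "perf_weighted_avg":
        tot = left_perf_total + right_perf_total
        if tot == 0:
            return UNDEFINED
        return (left * left_perf_total + right * right_perf_total) / tot
    if op == "largest_vol":
        return left if left_vol >= right_vol else right
    if op == "smallest_vol":
        return left if left_vol <= right_vol else right
    if op == "most_perf":
        return left if left_perf_total >= right_perf_total else right
    if op == "least_perf":
        return left if left_perf_total <= right_perf_total else right
    raise AssertionError


# ---------------------------------------------------------------------------
# percentile maps


def to_percentile_map(grid: VolumeGrid, mask: LungMask) -> VolumeGrid:
    """Map raw intensities to per-lung empirical percentiles in (0, 1].

    Each lung is ranked independently; a voxel's value becomes its average
    rank divided by the lung voxel count (ties share their average rank).
    Background voxels are set to 0 and ignored downstream.
    """
    out = np.zeros_like(grid.values)
    for lab in LUNG_LABELS:
        sel = mask.labels == lab
        n = int(np.count_nonzero(sel))
        if n == 0:
            raise DegenerateCaseError(f"lung label {lab} is empty")
        out[sel] = rankdata(grid.values[sel], method="average") / n
    return VolumeGrid(out, grid.spacing)


# ---------------------------------------------------------------------------
# metric specifications


@dataclass(frozen=True)
class MetricSpec:
    """One point in the metric search space.

    The scenario fixes which fields are meaningful: Full scenarios have no
    radius/intra metric (each voxel is its own subvalue with weight 1); L+R
    scenarios pool both lungs and have no LR operator.
    """

    scenario: str
    inter_metric: str
    value_kind: str = "raw"
    radius_r: float | None = None
    intra_metric: str | None = None
    n_threshold: float | None = None
    lr_metric: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.value_kind!r}")
        if self.inter_metric not in INTER_METRICS:
            raise ValueError(f"unknown inter metric {self.inter_metric!r}")
        voronoi = self.scenario.startswith("voronoi")
        split = self.scenario.endswith("split")
        if voronoi:
            if self.radius_r is None or self.radius_r < 1:
                raise ValueError("Voronoi scenarios require radius_r >= 1")
            if self.intra_metric not in INTRA_METRICS:
                raise ValueError("Voronoi scenarios require a valid intra_metric")
        else:
            if self.radius_r is not None or self.intra_metric is not None:
                raise ValueError("Full scenarios take no radius/intra metric")
        if split:
            if self.lr_metric not in LR_METRICS:
                raise ValueError("L/R scenarios require a valid lr_metric")
        elif self.lr_metric is not None:
            raise ValueError("L+R scenarios take no LR metric")
        if self.inter_metric == "p_n":
            if self.n_threshold is None or not (5.0 <= self.n_threshold <= 95.0):
                raise ValueError("P_N requires n_threshold in [5, 95]")
        elif self.n_threshold is not None:
            raise ValueError("n_threshold is only valid with inter_metric='p_n'")

    @property
    def key(self) -> str:
        """Canonical, parseable identifier (score-matrix column name)."""
        r = "-" if self.radius_r is None else f"{self.radius_r:g}"
        n = "-" if self.n_threshold is None else f"{self.n_threshold:g}"
        return "|".join(
            [
                self.value_kind,
                self.scenario,
                f"r={r}",
                self.intra_metric or "-",
                self.inter_metric,
                f"N={n}",
                self.lr_metric or "-",
            ]
        )

    @classmethod
    def from_key(cls, key: str) -> "MetricSpec":
        kind, scenario, r, intra, inter, n, lr = key.split("|")
        r_val = r.removeprefix("r=")
        n_val = n.removeprefix("N=")
        return cls(
            scenario=scenario,
            inter_metric=inter,
            value_kind=kind,
            radius_r=None if r_val == "-" else float(r_val),
            intra_metric=None if intra == "-" else intra,
            n_threshold=None if n_val == "-" else float(n_val),
            lr_metric=None if lr == "-" else lr,
        )


@dataclass
class GlobalScore:
    """One global perfusion score for one case and metric specification."""

    spec: MetricSpec
    value: float
    n_realizations_used: int
    case_id: str | None = None

    @property
    def is_defined(self) -> bool:
        return not math.isnan(self.value)


# ---------------------------------------------------------------------------
# global score (readable reference path; the bulk extractor reuses the same
# scalar routines and must agree with this bit-for-bit)


def _lung_values(values: np.ndarray, mask: LungMask, lab: int) -> np.ndarray:
    return values[mask.labels == lab]


def _intra_values(values: np.ndarray, part: Partition, metric: str) -> np.ndarray:
    flat_vals = values.ravel()
    flat_labels = part.subvolume_labels.ravel()
    out = np.empty(part.n_subvolumes, dtype=np.float64)
    for i in range(part.n_subvolumes):
        out[i] = intra_stat(flat_vals[flat_labels == i + 1], metric)
    return out


def global_score(
    grid: VolumeGrid,
    mask: LungMask,
    spec: MetricSpec,
    partitions: list[tuple[Partition, Partition]] | None = None,
    case_id: str | None = None,
) -> GlobalScore:
    """Condense a (raw-valued) perfusion map into one score per ``spec``.

    ``grid`` always holds the raw map; the percentile transform is applied
    here when ``spec.value_kind == 'percentile'``.  Voronoi scenarios require
    ``partitions`` (one (left, right) pair per realization) and average the
    per-realization scores; a NaN in any realization makes the score NaN.
    """
    mask.require_lungs()
    voronoi = spec.scenario.startswith("voronoi")
    split = spec.scenario.endswith("split")
    if voronoi and not partitions:
        raise ValueError("Voronoi scenarios require partition realizations")

    values = (
        to_percentile_map(grid, mask).values
        if spec.value_kind == "percentile"
        else grid.values
    )
    left_voxels = _lung_values(values, mask, 1)
    right_voxels = _lung_values(values, mask, 2)
    vols = (float(left_voxels.size), float(right_voxels.size))
    perfs = (float(left_voxels.sum()), float(right_voxels.sum()))

    def inter_of(subvals, weights):
        return inter_stat(subvals, weights, spec.inter_metric, spec.n_threshold)

    if not voronoi:
        if split:
            s_left = inter_of(left_voxels, np.ones(left_voxels.size))
            s_right = inter_of(right_voxels, np.ones(right_voxels.size))
            value = lr_combine(s_left, s_right, *vols, *perfs, spec.lr_metric)
        else:
            pooled = np.concatenate([left_voxels, right_voxels])
            value = inter_of(pooled, np.ones(pooled.size))
        return GlobalScore(spec, value, 1, case_id)

    per_real = []
    for left_part, right_part in partitions:
        left_iv = _intra_values(values, left_part, spec.intra_metric)
        right_iv = _intra_values(values, right_part, spec.intra_metric)
        lw = left_part.subvolume_sizes.astype(np.float64)
        rw = right_part.subvolume_sizes.astype(np.float64)
        if split:
            s_left = inter_of(left_iv, lw)
            s_right = inter_of(right_iv, rw)
            score = lr_combine(s_left, s_right, *vols, *perfs, spec.lr_metric)
        else:
            score = inter_of(np.concatenate([left_iv, right_iv]), np.concatenate([lw, rw]))
        per_real.append(score)
    return GlobalScore(spec, float(np.mean(per_real)), len(per_real), case_id)


__all__ = [
    "UNDEFINED",
    "SCENARIOS",
    "INTRA_METRICS",
    "INTER_METRICS",
    "LR_METRICS",
    "VALUE_KINDS",
    "MetricSpec",
    "GlobalScore",
    "intra_stat",
    "inter_stat",
    "lr_combine",
    "p_n_defect",
    "to_percentile_map",
    "global_score",
]
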