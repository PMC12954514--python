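"""Brute-force metric search ranked by Spearman correlation with PFTs.

Every consistent metric specification (scenario x radius x intra x inter(+N)
x LR operator x value kind) is evaluated on the cohort and correlated with
each pulmonary function measure using Spearman's rank coefficient; the
combinations with the largest |rho| are reported.  Cases missing a measure
(DLCO is not always acquired) are excluded pairwise.  P-values come from the
two-sided t approximation and are descriptive only (star annotations; no
multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .metrics import (
    INTER_METRICS,
    INTRA_METRICS,
    LR_METRICS,
    SCENARIOS,
    VALUE_KINDS,
    MetricSpec,
)

PFT_MEASURES = ("DLCO", "FEV1", "FVC", "FEV1_FVC")
MEASURE_COLUMNS = {
    "DLCO": "dlco_pct",
    "FEV1": "fev1_pct",
    "FVC": "fvc_pct",
    "FEV1_FVC": "fev1_fvc",
}

DEFAULT_RADII = tuple(range(10, 91))  # grid search r in [10, 90]
DEFAULT_N_GRID = tuple(np.round(np.arange(5.0, 95.0 + 1e-9, 0.1), 1))
COARSE_RADII = tuple(range(10, 91, 10))
COARSE_N_GRID = tuple(float(n) for n in range(5, 96, 5))


def spearman(x, y) -> tuple[float, float]:
    """Tie-safe Spearman rho with two-sided t-approximation p-value.

    Returns ``(nan, nan)`` when either variable has zero rank variance; a
    perfect |rho| = 1 reports the smallest positive float instead of p = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("spearman requires two equal-length 1D arrays, n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("spearman requires finite inputs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return (np.nan, np.nan)
    rho, p = stats.spearmanr(x, y)
    if abs(rho) >= 1.0:
        p = float(np.finfo(np.float64).tiny)
    return float(rho), float(p)


def significance_stars(p_value: float) -> str:
    """Star annotation: *** P<0.005, ** P<0.01, * P<0.05."""
    if not (0 < p_value <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p_value}")
    if p_value < 0.005:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def enumerate_specs(
    radii=DEFAULT_RADII,
    n_grid=DEFAULT_N_GRID,
    scenarios=SCENARIOS,
    value_kinds=VALUE_KINDS,
    intra_metrics=INTRA_METRICS,
    inter_metrics=INTER_METRICS,
    lr_metrics=LR_METRICS,
) -> list[MetricSpec]:
    """All consistent metric specifications for the given grids.

    Full scenarios take no radius/intra metric; L+R scenarios take no LR
    operator; ``p_n`` expands over the N grid.
    """
    if not radii or not n_grid or not scenarios or not value_kinds:
        raise ValueError("search grids must be nonempty")
    inter_expanded: list[tuple[str, float | None]] = []
    for m in inter_metrics:
        if m == "p_n":
            inter_expanded.extend(("p_n", float(n)) for n in n_grid)
        else:
            inter_expanded.append((m, None))
    specs: list[MetricSpec] = []
    for kind in value_kinds:
        for scenario in scenarios:
            voronoi = scenario.startswith("voronoi")
            split = scenario.endswith("split")
            r_opts = [float(r) for r in radii] if voronoi else [None]
            intra_opts = list(intra_metrics) if voronoi else [None]
            lr_opts = list(lr_metrics) if split else [None]
            for r in r_opts:
                for intra in intra_opts:
                    for inter, n in inter_expanded:
                        for lr in lr_opts:
                            specs.append(
                                MetricSpec(
                                    scenario=scenario,
                                    inter_metric=inter,
                                    value_kind=kind,
                                    radius_r=r,
                                    intra_metric=intra,
                                    n_threshold=n,
                                    lr_metric=lr,
                                )
                            )
    return specs


@dataclass
class CorrelationResult:
    spec: MetricSpec
    pft_measure: str
    rho: float
    p_value: float
    n_cases: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def _rank_columns(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def spearman_matrix(scores: pd.DataFrame, pft_values: pd.Series) -> pd.DataFrame:
    """Vectorized Spearman rho + p of every score column against one PFT
    measure, with pairwise deletion of cases missing the measure.

    Columns containing any undefined (NaN) score are excluded.  Equals
    :func:`spearman` per column to floating-point roundoff.
    """
    pft_values = pft_values.reindex(scores.index)
    usable = pft_values.notna().to_numpy()
    y = pft_values.to_numpy(dtype=np.float64)[usable]
    n = int(usable.sum())
    if n < 3:
        raise ValueError(f"need >= 3 cases with the measure present, got {n}")
    x = scores.to_numpy(dtype=np.float64)[usable, :]
    defined = ~np.isnan(x).any(axis=0)
    x = x[:, defined]
    cols = scores.columns[defined]

    rx = _rank_columns(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean(axis=0)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=0) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c * ry_c[:, None]).sum(axis=0) / denom
    rho[denom == 0] = np.nan

    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = np.finfo(np.float64).tiny
    return pd.DataFrame({"rho": rho, "p_value": p, "n_cases": n}, index=cols)


def rank_specs(
    scores: pd.DataFrame, pft: pd.DataFrame, measure: str, k: int = 5
) -> list[CorrelationResult]:
    """Top-k metric specs by |rho| against one PFT measure.

    Ties break by smaller p-value, then canonical spec key.  Specs undefined
    for any usable case are dropped.
    """
    if measure not in MEASURE_COLUMNS:
        raise ValueError(f"unknown PFT measure {measure!r}")
    mat = spearman_matrix(scores, pft[MEASURE_COLUMNS[measure]])
    mat = mat.dropna(subset=["rho"])
    order = sorted(
        mat.index,
        key=lambda key: (-abs(mat.at[key, "rho"]), mat.at[key, "p_value"], key),
    )
    out = []
    for key in order[: max(k, 0)]:
        out.append(
            CorrelationResult(
                spec=MetricSpec.from_key(key),
                pft_measure=measure,
                rho=float(mat.at[key, "rho"]),
                p_value=float(mat.at[key, "p_value"]),
                n_cases=int(mat.at[key, "n_cases"]),
            )
        )
    return out


def best_rho_by_scenario(
    scores: pd.DataFrame, pft: pd.DataFrame, measures=PFT_MEASURES
) -> pd.DataFrame:
    """Best |rho| per (scenario, measure): the heatmap-style summary."""
    rows = {}
    for scenario in SCENARIOS:
        cols = [c for c in scores.columns if MetricSpec.from_key(c).scenario == scenario]
        row = {}
        for measure in measures:
            if not cols:
                row[measure] = np.nan
                continue
            mat = spearman_matrix(scores[cols], pft[MEASURE_COLUMNS[measure]])
            mat = mat.dropna(subset=["rho"])
            row[measure] = float(np.abs(mat["rho"]).max()) if len(mat) else np.nan
        rows[scenario] = row
    return pd.DataFrame(rows).T


class SpearmanSpecRanker(BaseEstimator):
    """Estimator ranking metric specs by Spearman correlation per PFT measure.

    After ``fit(scores, pft)``, ``results_`` maps each measure to its top-k
    :class:`CorrelationResult` list and ``heatmap_`` holds the best |rho| per
    scenario x measure.
    """

    def __init__(self, k: int = 5, measures=PFT_MEASURES):
        self.k = k
        self.measures = measures

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        self.results_ = {m: rank_specs(X, y, m, self.k) for m in self.measures}
        self.heatmap_ = best_rho_by_scenario(X, y, self.measures)
        return self


__all__ = [
    "PFT_MEASURES",
    "MEASURE_COLUMNS",
    "DEFAULT_RADII",
    "DEFAULT_N_GRID",
    "COARSE_RADII",
    "COARSE_N_GRID",
    "spearman",
    "significance_stars",
    "enumerate_specs",
    "CorrelationResult",
    "spearman_matrix",
    "rank_specs",
    "best_rho_by_scenario",
    "SpearmanSpecRanker",
]
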