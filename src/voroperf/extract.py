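"""Bulk computation of the case x MetricSpec global-score matrix.

:func:`score_cases` evaluates many metric specifications at once while
honouring a strict caching contract: per-subvolume intra-level values are
computed once per (case, radius, realization, intra metric) and reused across
every inter/LR combination, and the whole path reuses the exact scalar
routines of :mod:`voroperf.metrics`, so the resulting matrix is bit-identical
to calling :func:`voroperf.metrics.global_score` spec by spec (this is
asserted in the test suite).

The only algebraic shortcut is the evaluation of the P_N defect statistic over
a whole threshold grid from one sort + cumulative sum; because subvolume
weights are integer voxel counts this is exact, not merely close.

:class:`PerfusionScoreExtractor` wraps the same computation as a
scikit-learn-style stateless transformer over ``(case_id, VolumeGrid,
LungMask)`` triples.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import LungMask, VolumeGrid
from .metrics import (
    UNDEFINED,
    MetricSpec,
    _stat_scalar,
    intra_stat,
    lr_combine,
    to_percentile_map,
)
from .voronoi import DEFAULT_K_ATTEMPTS, DEFAULT_N_REALIZATIONS, partition_realizations

Case = tuple[str, VolumeGrid, LungMask]


def _p_n_bulk(subvalues: np.ndarray, weights: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """P_N over a threshold grid; exact match of the per-N formula for
    integer-valued weights."""
    order = np.argsort(subvalues, kind="stable")
    sv = subvalues[order]
    cw = np.cumsum(weights[order])
    total = float(cw[-1])
    cutoffs = (thresholds / 100.0) * sv[-1]
    idx = np.searchsorted(sv, cutoffs, side="right")
    sums = np.where(idx > 0, cw[np.maximum(idx - 1, 0)], 0.0)
    return 100.0 * sums / total


def _inter_values(
    subvalues: np.ndarray, weights: np.ndarray, inter_keys: list[tuple[str, float | None]]
) -> dict[tuple[str, float | None], float]:
    """Inter-level statistics for a batch of (metric, N) requests on one unit."""
    out: dict[tuple[str, float | None], float] = {}
    if np.isnan(subvalues).any():
        return {k: UNDEFINED for k in inter_keys}
    pn = [k for k in inter_keys if k[0] == "p_n"]
    if pn:
        thr = np.array([k[1] for k in pn], dtype=np.float64)
        vals = _p_n_bulk(subvalues, weights, thr)
        out.update(zip(pn, (float(v) for v in vals)))
    for key in inter_keys:
        if key[0] != "p_n":
            out[key] = _stat_scalar(subvalues, key[0])
    return out


def _group_specs(specs: list[MetricSpec]):
    """Nested grouping: kind -> scenario family -> (radius | None) -> intra
    metric (None for Full) -> list of specs."""
    grouped: dict = defaultdict(lambda: defaultdict(lambda: defaultdict(list)))
    for spec in specs:
        r = spec.radius_r if spec.scenario.startswith("voronoi") else None
        grouped[spec.value_kind][(spec.scenario, r)][spec.intra_metric].append(spec)
    return grouped


def _score_one_case(
    grid: VolumeGrid,
    mask: LungMask,
    grouped,
    kinds: list[str],
    radii: list[float],
    n_realizations: int,
    base_seed: int,
    k_attempts: int,
) -> dict[str, float]:
    mask.require_lungs()
    sel_left = mask.labels == 1
    sel_right = mask.labels == 2

    maps: dict[str, np.ndarray] = {}
    lungs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    vols: dict[str, tuple[float, float]] = {}
    perfs: dict[str, tuple[float, float]] = {}
    for kind in kinds:
        values = (
            to_percentile_map(grid, mask).values if kind == "percentile" else grid.values
        )
        maps[kind] = values
        lv, rv = values[sel_left], values[sel_right]
        lungs[kind] = (lv, rv)
        vols[kind] = (float(lv.size), float(rv.size))
        perfs[kind] = (float(lv.sum()), float(rv.sum()))

    result: dict[str, float] = {}

    def finish_unit(specs_for_intra, units, kind, accumulate=None):
        """Evaluate the inter/LR level for one realization (or the Full case).

        ``units`` maps 'pooled' -> (subvals, weights) or 'split' -> per-lung
        pairs.  ``accumulate`` collects per-realization scores for averaging.
        """
        together = [s for s in specs_for_intra if not s.scenario.endswith("split")]
        split = [s for s in specs_for_intra if s.scenario.endswith("split")]
        if together:
            subv, w = units["pooled"]
            keys = sorted({(s.inter_metric, s.n_threshold) for s in together},
                          key=lambda k: (k[0], -1.0 if k[1] is None else k[1]))
            vals = _inter_values(subv, w, keys)
            for s in together:
                v = vals[(s.inter_metric, s.n_threshold)]
                (accumulate[s.key].append(v) if accumulate is not None
                 else result.__setitem__(s.key, v))
        if split:
            (lv, lw), (rv, rw) = units["split"]
            keys = sorted({(s.inter_metric, s.n_threshold) for s in split},
                          key=lambda k: (k[0], -1.0 if k[1] is None else k[1]))
            left_vals = _inter_values(lv, lw, keys)
            right_vals = _inter_values(rv, rw, keys)
            for s in split:
                k = (s.inter_metric, s.n_threshold)
                v = lr_combine(
                    left_vals[k], right_vals[k], *vols[kind], *perfs[kind], s.lr_metric
                )
                (accumulate[s.key].append(v) if accumulate is not None
                 else result.__setitem__(s.key, v))

    # Full scenarios: each voxel is its own subvalue with weight 1.
    for kind in kinds:
        for (scenario, r), by_intra in grouped[kind].items():
            if r is not None:
                continue
            specs_here = by_intra[None]
            lv, rv = lungs[kind]
            pooled = np.concatenate([lv, rv])
            units = {
                "pooled": (pooled, np.ones(pooled.size)),
                "split": ((lv, np.ones(lv.size)), (rv, np.ones(rv.size))),
            }
            finish_unit(specs_here, units, kind)

    # Voronoi scenarios: partitions are shared across value kinds and specs.
    for r in radii:
        parts = partition_realizations(mask, r, n_realizations, base_seed, k_attempts)
        acc: dict[str, list[float]] = defaultdict(list)
        for left_part, right_part in parts:
            sub_left = _subvolume_arrays(left_part)
            sub_right = _subvolume_arrays(right_part)
            lw = left_part.subvolume_sizes.astype(np.float64)
            rw = right_part.subvolume_sizes.astype(np.float64)
            for kind in kinds:
                flat = maps[kind].ravel()
                intra_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
                needed_intra = set()
                for (scenario, rr), by_intra in grouped[kind].items():
                    if rr == r:
                        needed_intra.update(by_intra.keys())
                for m in sorted(needed_intra):
                    liv = np.array([intra_stat(flat[ix], m) for ix in sub_left])
                    riv = np.array([intra_stat(flat[ix], m) for ix in sub_right])
                    intra_cache[m] = (liv, riv)
                for (scenario, rr), by_intra in grouped[kind].items():
                    if rr != r:
                        continue
                    for m, specs_here in by_intra.items():
                        liv, riv = intra_cache[m]
                        units = {
                            "pooled": (
                                np.concatenate([liv, riv]),
                                np.concatenate([lw, rw]),
                            ),
                            "split": ((liv, lw), (riv, rw)),
                        }
                        finish_unit(specs_here, units, kind, accumulate=acc)
        for key, per_real in acc.items():
            result[key] = float(np.mean(per_real))
    return result


def _subvolume_arrays(part) -> list[np.ndarray]:
    """Flat voxel indices per subvolume, in C order (matches boolean-mask
    extraction used by the reference path)."""
    flat_labels = part.subvolume_labels.ravel()
    order = np.argsort(flat_labels, kind="stable")
    sorted_labels = flat_labels[order]
    start = np.searchsorted(sorted_labels, 1)
    bounds = np.searchsorted(sorted_labels, np.arange(1, part.n_subvolumes + 2))
    return [order[bounds[i] : bounds[i + 1]] for i in range(part.n_subvolumes)]


def score_cases(
    cases: list[Case],
    specs: list[MetricSpec],
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    base_seed: int = 0,
    k_attempts: int = DEFAULT_K_ATTEMPTS,
) -> pd.DataFrame:
    """Score every case against every metric spec.

    Returns a DataFrame indexed by case_id with one column per canonical spec
    key.  Voronoi partitions are regenerated per case with
    :func:`partition_realizations` (``base_seed`` drives all randomness), so
    reruns are bit-identical.
    """
    if not specs:
        raise ValueError("no metric specs supplied")
    keys = [s.key for s in specs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate metric specs")
    grouped = _group_specs(specs)
    kinds = sorted(grouped.keys())
    radii = sorted({s.radius_r for s in specs if s.radius_r is not None})
    rows = []
    ids = []
    for case_id, grid, mask in cases:
        res = _score_one_case(
            grid, mask, grouped, kinds, radii, n_realizations, base_seed, k_attempts
        )
        rows.append([res[k] for k in keys])
        ids.append(case_id)
    return pd.DataFrame(
        np.asarray(rows, dtype=np.float64),
        index=pd.Index(ids, name="case_id"),
        columns=keys,
    )


class PerfusionScoreExtractor(BaseEstimator, TransformerMixin):
    """Transformer turning perfusion cases into a global-score matrix.

    Parameters
    ----------
    specs : list of MetricSpec
        Metric combinations to evaluate (see ``search.enumerate_specs``).
    n_realizations : int
        Independent Voronoi discretizations averaged per score.
    base_seed : int
        Seed driving all Poisson-disk sampling.
    k_attempts : int
        Bridson rejection budget per active point.
    """

    def __init__(
        self,
        specs: list[MetricSpec] | None = None,
        n_realizations: int = DEFAULT_N_REALIZATIONS,
        base_seed: int = 0,
        k_attempts: int = DEFAULT_K_ATTEMPTS,
    ):
        self.specs = specs
        self.n_realizations = n_realizations
        self.base_seed = base_seed
        self.k_attempts = k_attempts

    def fit(self, X: list[Case], y=None):
        if not self.specs:
            raise ValueError("PerfusionScoreExtractor requires a nonempty spec list")
        self.n_specs_ = len(self.specs)
        return self

    def transform(self, X: list[Case]) -> pd.DataFrame:
        if not hasattr(self, "n_specs_"):
            self.fit(X)
        return score_cases(
            X,
            self.specs,
            n_realizations=self.n_realizations,
            base_seed=self.base_seed,
            k_attempts=self.k_attempts,
        )


__all__ = ["score_cases", "PerfusionScoreExtractor"]
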