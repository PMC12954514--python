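import math
import random
import statistics

import numpy as np
import pytest

from voroperf.containers import LungMask, VolumeGrid
from voroperf.extract import score_cases
from voroperf.metrics import (
    INTER_METRICS,
    INTRA_METRICS,
    LR_METRICS,
    MetricSpec,
    global_score,
    inter_stat,
    intra_stat,
    lr_combine,
    to_percentile_map,
)
from voroperf.voronoi import partition_realizations

from conftest import ellipsoid_mask


# ---------------------------------------------------------------------------
# independent reference implementations (pure python)


def ref_quantile(xs, q):
    """Linear interpolation between order statistics (type-7)."""
    s = sorted(xs)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def ref_mode(xs, bins=64):
    lo, hi = min(xs), max(xs)
    if lo == hi:
        return lo
    width = (hi - lo) / bins
    counts = [0] * bins
    for x in xs:
        b = min(int((x - lo) / width), bins - 1)
        counts[b] += 1
    best = counts.index(max(counts))
    return lo + (best + 0.5) * width


def ref_stat(xs, metric):
    n = len(xs)
    mean = sum(xs) / n
    med = statistics.median(xs)
    m2 = sum((x - mean) ** 2 for x in xs) / n
    if metric == "min":
        return min(xs)
    if metric == "max":
        return max(xs)
    if metric == "mean":
        return mean
    if metric == "median":
        return med
    if metric == "p25":
        return ref_quantile(xs, 0.25)
    if metric == "p75":
        return ref_quantile(xs, 0.75)
    if metric == "cov":
        return math.nan if med == 0 else math.sqrt(m2) / med
    if metric == "skewness":
        if m2 == 0:
            return 0.0
        m3 = sum((x - mean) ** 3 for x in xs) / n
        return m3 / m2**1.5
    if metric == "mode_over_median":
        return math.nan if med == 0 else ref_mode(xs) / med
    raise ValueError(metric)


def ref_p_n(values, weights, n_pct):
    cutoff = n_pct / 100.0 * max(values)
    hit = sum(w for v, w in zip(values, weights) if v <= cutoff)
    return 100.0 * hit / sum(weights)


# ---------------------------------------------------------------------------
# intra / inter statistics


class TestIntraStat:
    def test_symmetric_sequence(self):
        vals = [1, 2, 3, 4, 5]
        assert intra_stat(vals, "median") == 3
        assert intra_stat(vals, "p25") == 2
        assert intra_stat(vals, "p75") == 4

    def test_constant_multiset(self):
        vals = [2.5] * 10
        assert intra_stat(vals, "skewness") == 0.0
        assert intra_stat(vals, "cov") == 0.0
        assert intra_stat(vals, "mode_over_median") == 1.0

    def test_skewness_matches_moment_oracle(self, rng):
        """Right-skewed mixture: agree with an independently coded moment formula."""
        from scipy.stats import skew

        vals = np.concatenate(
            [rng.normal(1.0, 0.2, 800), rng.exponential(2.0, 200) + 1.0]
        )
        ours = intra_stat(vals, "skewness")
        assert ours > 0.5  # genuinely right-skewed
        assert abs(ours - skew(vals, bias=True)) < 1e-12
        assert abs(ours - ref_stat(list(vals), "skewness")) < 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            intra_stat([], "median")

    def test_zero_median_gives_undefined(self):
        assert math.isnan(intra_stat([-1.0, 0.0, 1.0], "cov"))
        assert math.isnan(intra_stat([-1.0, 0.0, 1.0], "mode_over_median"))

    def test_bruteforce_oracle_all_metrics(self):
        """All statistics agree with pure-python references on random multisets."""
        rnd = random.Random(7)
        for trial in range(100):
            n = rnd.choice([1, 2, 3, 5, 17, 101, 1000])
            style = trial % 3
            if style == 0:
                xs = [rnd.uniform(0.1, 10) for _ in range(n)]
            elif style == 1:
                xs = [float(rnd.randint(1, 5)) for _ in range(n)]  # heavy ties
            else:
                xs = [rnd.lognormvariate(0, 1) for _ in range(n)]
            for metric in INTRA_METRICS:
                got = intra_stat(xs, metric)
                want = ref_stat(xs, metric)
                assert got == pytest.approx(want, abs=1e-10), (metric, n, style)


class TestInterStat:
    def test_p_n_direct_count(self):
        got = inter_stat([10, 5, 1], [1, 1, 1], "p_n", n_threshold=95)
        assert got == pytest.approx(200.0 / 3.0)

    def test_p_n_constant_positive_is_zero(self):
        # cutoff = N% * v < v for N < 100, so no subvolume qualifies
        assert inter_stat([3.0, 3.0, 3.0], [1, 2, 3], "p_n", n_threshold=90) == 0.0

    def test_p_n_weighted_hand_case(self):
        assert inter_stat([1, 10], [9, 1], "p_n", n_threshold=50) == pytest.approx(90.0)

    def test_p_n_monotone_in_threshold(self, rng):
        for _ in range(100):
            n = rng.integers(2, 30)
            vals = rng.uniform(0.1, 5.0, n)
            w = rng.integers(1, 50, n)
            thresholds = np.sort(rng.uniform(5, 95, 8))
            pn = [inter_stat(vals, w, "p_n", n_threshold=t) for t in thresholds]
            assert all(a <= b + 1e-12 for a, b in zip(pn, pn[1:]))

    def test_p_n_zero_below_minimum(self, rng):
        vals = rng.uniform(1.0, 2.0, 10)
        # cutoff below the minimum subvalue -> nothing qualifies
        t = 100.0 * 0.99 * vals.min() / vals.max()
        if 5 <= t <= 95:
            assert inter_stat(vals, np.ones(10), "p_n", n_threshold=t) == 0.0

    def test_bruteforce_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            vals = list(rng.uniform(0.1, 10.0, n))
            w = list(rng.integers(1, 100, n).astype(float))
            for metric in INTER_METRICS:
                if metric == "p_n":
                    t = float(rng.uniform(5, 95))
                    got = inter_stat(vals, w, metric, n_threshold=t)
                    assert got == pytest.approx(ref_p_n(vals, w, t), abs=1e-10)
                else:
                    got = inter_stat(vals, w, metric)
                    want = ref_stat(vals, metric)
                    if math.isnan(want):
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(want, abs=1e-10)


class TestScaleInvariance:
    def test_cov_and_skewness_invariant_under_positive_rescale(self, rng):
        for _ in range(50):
            vals = rng.lognormal(0, 0.5, int(rng.integers(3, 200)))
            scale = float(rng.uniform(0.01, 100))
            for metric in ("cov", "skewness"):
                a = intra_stat(vals, metric)
                b = intra_stat(vals * scale, metric)
                assert abs(a - b) < 1e-12


class TestLrCombine:
    def test_symmetry(self):
        for op in LR_METRICS:
            assert lr_combine(4.2, 4.2, 100, 200, 10.0, 20.0, op) == 4.2

    def test_volume_weighted_average(self):
        assert lr_combine(2.0, 6.0, 300, 100, 1, 1, "vol_weighted_avg") == 3.0

    def test_selectors(self):
        assert lr_combine(1.0, 9.0, 300, 100, 5.0, 2.0, "largest_vol") == 1.0
        assert lr_combine(1.0, 9.0, 100, 300, 5.0, 2.0, "largest_vol") == 9.0
        assert lr_combine(1.0, 9.0, 100, 300, 5.0, 2.0, "most_perf") == 1.0
        assert lr_combine(1.0, 9.0, 100, 300, 2.0, 5.0, "least_perf") == 1.0

    def test_volume_tie_goes_left(self):
        assert lr_combine(1.0, 9.0, 100, 100, 1.0, 1.0, "largest_vol") == 1.0
        assert lr_combine(1.0, 9.0, 100, 100, 1.0, 1.0, "smallest_vol") == 1.0

    def test_zero_perfusion_weighted_average_undefined(self):
        assert math.isnan(lr_combine(1.0, 2.0, 10, 10, 0.0, 0.0, "perf_weighted_avg"))


# ---------------------------------------------------------------------------
# percentile maps


class TestPercentileMap:
    def _tiny_case(self, left_vals, right_vals):
        shape = (max(len(left_vals), len(right_vals)), 2, 1)
        values = np.zeros(shape)
        labels = np.zeros(shape, dtype=np.int16)
        for i, v in enumerate(left_vals):
            values[i, 0, 0] = v
            labels[i, 0, 0] = 1
        for i, v in enumerate(right_vals):
            values[i, 1, 0] = v
            labels[i, 1, 0] = 2
        return VolumeGrid(values), LungMask(labels)

    def test_distinct_values_rank_over_n(self):
        grid, mask = self._tiny_case([3, 1, 4, 2], [1, 2])
        pct = to_percentile_map(grid, mask)
        left = pct.values[mask.labels == 1]
        assert np.allclose(left, [0.75, 0.25, 1.0, 0.5])

    def test_constant_lung_average_rank(self):
        grid, mask = self._tiny_case([7, 7, 7, 7, 7], [1, 2])
        pct = to_percentile_map(grid, mask)
        n = 5
        assert np.allclose(pct.values[mask.labels == 1], (n + 1) / (2 * n))

    def test_per_lung_independence(self):
        grid, mask = self._tiny_case([5, 1, 9], [9, 5, 1])
        pct = to_percentile_map(grid, mask)
        left = np.sort(pct.values[mask.labels == 1])
        right = np.sort(pct.values[mask.labels == 2])
        assert np.allclose(left, right)

    def test_values_in_unit_interval(self, small_case):
        grid, mask = small_case
        pct = to_percentile_map(grid, mask)
        for lab in (1, 2):
            v = pct.values[mask.labels == lab]
            assert v.min() > 0 and v.max() <= 1.0

    def test_invariant_under_increasing_transform(self, small_case):
        grid, mask = small_case
        a = to_percentile_map(grid, mask)
        transformed = VolumeGrid(np.exp(2.0 * grid.values) + 1.0, grid.spacing)
        b = to_percentile_map(transformed, mask)
        assert np.array_equal(a.values, b.values)


# ---------------------------------------------------------------------------
# global scores


class TestGlobalScore:
    def test_degenerate_partition_reduces_to_lung_medians(self, small_case):
        grid, mask = small_case
        parts = partition_realizations(mask, 200.0, 1, base_seed=0)
        spec = MetricSpec(
            scenario="voronoi_lr_together",
            inter_metric="median",
            radius_r=200.0,
            intra_metric="median",
        )
        got = global_score(grid, mask, spec, parts).value
        med = [np.median(grid.values[mask.labels == lab]) for lab in (1, 2)]
        assert got == pytest.approx(np.median(med), abs=1e-12)

    def test_full_split_median_avg_composition(self, small_case):
        grid, mask = small_case
        spec = MetricSpec(
            scenario="full_lr_split", inter_metric="median", lr_metric="avg"
        )
        got = global_score(grid, mask, spec).value
        med = [np.median(grid.values[mask.labels == lab]) for lab in (1, 2)]
        assert got == pytest.approx(np.mean(med), abs=1e-12)

    @pytest.mark.parametrize("metric", ["median", "p25", "p75"])
    def test_one_subvolume_voronoi_equals_full(self, small_case, metric):
        """With r beyond lung diameter the Voronoi path reduces to the Full path."""
        grid, mask = small_case
        parts = partition_realizations(mask, 500.0, 2, base_seed=1)
        vor = MetricSpec(
            scenario="voronoi_lr_split",
            inter_metric="median",
            radius_r=500.0,
            intra_metric=metric,
            lr_metric="avg",
        )
        got = global_score(grid, mask, vor, parts).value
        per_lung = [
            intra_stat(grid.values[mask.labels == lab], metric) for lab in (1, 2)
        ]
        assert got == pytest.approx(np.mean(per_lung), abs=1e-12)

    def test_realization_mean_recomposition(self, small_case):
        grid, mask = small_case
        parts = partition_realizations(mask, 9.0, 5, base_seed=3)
        spec = MetricSpec(
            scenario="voronoi_lr_split",
            inter_metric="p_n",
            radius_r=9.0,
            intra_metric="p75",
            n_threshold=80.0,
            lr_metric="vol_weighted_avg",
        )
        full = global_score(grid, mask, spec, parts).value
        singles = [global_score(grid, mask, spec, [p]).value for p in parts]
        assert full == pytest.approx(np.mean(singles), abs=0)
        again = global_score(grid, mask, spec, parts).value
        assert full == again

    def test_missing_partitions_rejected(self, small_case):
        grid, mask = small_case
        spec = MetricSpec(
            scenario="voronoi_lr_together",
            inter_metric="median",
            radius_r=10.0,
            intra_metric="mean",
        )
        with pytest.raises(ValueError):
            global_score(grid, mask, spec)


class TestMetricSpec:
    def test_key_roundtrip(self):
        spec = MetricSpec(
            scenario="voronoi_lr_split",
            inter_metric="p_n",
            value_kind="percentile",
            radius_r=23.0,
            intra_metric="p75",
            n_threshold=89.6,
            lr_metric="max",
        )
        assert MetricSpec.from_key(spec.key) == spec

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(scenario="full_lr_together", inter_metric="median", radius_r=10.0),
            dict(scenario="voronoi_lr_together", inter_metric="median"),
            dict(scenario="full_lr_together", inter_metric="median", lr_metric="avg"),
            dict(scenario="full_lr_split", inter_metric="median"),
            dict(scenario="full_lr_together", inter_metric="p_n", n_threshold=99.0),
            dict(scenario="full_lr_together", inter_metric="median", n_threshold=50.0),
        ],
    )
    def test_inconsistent_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MetricSpec(**kwargs)


class TestCachedPathConsistency:
    def test_bulk_matrix_bitwise_equals_reference(self, small_case, rng):
        """The cached/bulk extractor must be bit-identical to global_score."""
        grid, mask = small_case
        specs = [
            MetricSpec(scenario="full_lr_together", inter_metric="p_n", n_threshold=40.0),
            MetricSpec(scenario="full_lr_together", inter_metric="skewness",
                       value_kind="percentile"),
            MetricSpec(scenario="full_lr_split", inter_metric="cov", lr_metric="min"),
            MetricSpec(scenario="voronoi_lr_together", inter_metric="p_n",
                       radius_r=9.0, intra_metric="p75", n_threshold=85.0),
            MetricSpec(scenario="voronoi_lr_together", inter_metric="median",
                       radius_r=9.0, intra_metric="mode_over_median",
                       value_kind="percentile"),
            MetricSpec(scenario="voronoi_lr_split", inter_metric="p25",
                       radius_r=14.0, intra_metric="cov", lr_metric="perf_weighted_avg"),
            MetricSpec(scenario="voronoi_lr_split", inter_metric="p_n",
                       radius_r=14.0, intra_metric="median", n_threshold=55.0,
                       lr_metric="largest_vol", value_kind="percentile"),
        ]
        matrix = score_cases([("c0", grid, mask)], specs, n_realizations=2, base_seed=4)
        parts = {
            r: partition_realizations(mask, r, 2, base_seed=4) for r in (9.0, 14.0)
        }
        for spec in specs:
            expected = global_score(
                grid, mask, spec, parts.get(spec.radius_r)
            ).value
            assert matrix.loc["c0", spec.key] == expected, spec.key
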