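# Methods

## Scope and data model

`voroperf` consumes already co-registered pairs of a 3D perfusion scalar
volume and a left/right lung label mask (NIfTI; 0 = background, 1 = left,
2 = right) on a common grid, plus a per-case PFT table. Upstream steps —
SPECT reconstruction, attenuation correction, lung segmentation, deformable
registration, CT-based perfusion estimation — are out of scope; any perfusion
map provenance is acceptable. Voxel centres sit at `index * spacing`
(0-based); file affines are honoured only at the I/O boundary. Perfusion
values outside the mask are ignored everywhere; there is no background
normalization.

All geometry downstream of I/O assumes an isotropic working grid. The default
working spacing is 2.0 mm (configurable), between typical SPECT in-plane and
slice resolutions. Intensities are resampled trilinearly; labels by nearest
neighbour. The trilinear kernel uses the nested-lerp form `a + t·(b − a)`,
which reproduces constant fields bit-exactly — a property the test suite
relies on.

## Percentile scaling

Raw maps are optionally rescaled per lung to empirical percentiles: each
voxel receives `average-rank / n_lung_voxels ∈ (0, 1]`, ties sharing their
average rank. This destroys absolute units but preserves ranks exactly, so
any strictly increasing transform of the raw map yields the identical
percentile map (property-tested). The convention maps a constant lung to
`(n+1)/(2n)` rather than 0 or 1; the choice is documented because competing
conventions (min → 0) exist.

## Parcellation

Seeds are drawn per lung by Bridson Poisson-disk sampling adapted to a masked
domain: the initial point is a uniformly drawn lung voxel centre; candidates
are generated around active points in the spherical annulus `[r, 2r)`
(uniform direction, radius ~ U[r, 2r); the annulus sampling law is a free
choice and this is the common implementation), 30 attempts per activation
(Bridson's canonical default, configurable); a candidate is accepted iff its
containing voxel carries the lung label and it lies at distance ≥ r from all
accepted points, with an `r/√3`-cell background grid for neighbour lookup.
The radius `r` is expressed in isotropic-voxel units — the limit "r → 1 gives
voxel-sized subvolumes" only makes sense in voxel units — so its physical
meaning scales with the configured working spacing.

Voronoi assignment labels every lung voxel with its nearest seed (Euclidean,
voxel units); exact distance ties go to the lowest seed index, making the
labelling order-stable and deterministic. Only the voxelized labelling is
computed, never the continuous cell geometry. Because seeding is stochastic,
scores are averaged over independent realizations (default 5; realization k
seeds its RNG with `base_seed + k`). Averaging applies to the final global
score, not to intermediate levels.

## Hierarchical statistics

Conventions, where the field has competing definitions:

* **CoV** is the *population* standard deviation divided by the **median**
  (subvolumes are full enumerations, not samples; the median-denominator is
  deliberate and nonstandard). Undefined (NaN) when the median is 0.
* **Skewness** is `m3 / m2^1.5` with central moments and no bias correction;
  0 when the variance is 0.
* **Mode** is the midpoint of the highest-count bin of a 64-bin equal-width
  histogram over `[min, max]` (single bin when min = max; count ties go to
  the lowest bin). Bin count configurable via `metrics.MODE_HISTOGRAM_BINS`.
* **Quantiles** interpolate linearly between order statistics (the "type 7"
  convention).
* **P_N** uses `≤` ("at or below") against the cutoff `(N/100) · max` of the
  subvalues within the unit being summarized — per lung when lungs are
  treated separately, pooled when together. Consequently a constant positive
  subvalue set has P_N = 0 for N < 100.
* **LR selectors** (largest/smallest volume, most/least perfusion) break
  exact ties toward the left lung. Lung perfusion totals are sums of in-mask
  voxel values of the map actually being scored (raw or percentile).

Undefined values propagate as NaN: any undefined constituent makes the
case's score undefined for that metric spec, and the ranking stage drops
specs undefined for at least one usable case.

Four processing scenarios route the levels: Full L+R applies inter statistics
directly to the pooled voxel values (each voxel its own subvalue, weight 1);
Full L/R applies inter per lung then the LR operator; Voronoi L+R applies
intra per subvolume and inter over the pooled subvolumes of both lungs
(weights = subvolume voxel counts); Voronoi L/R runs the full three-level
path. Seeding stays per-lung even for L+R — pooling happens at the statistics
level, not the geometry level.

### Bulk evaluation

The search-scale extractor (`extract.score_cases`) computes intra-level
values once per (case, radius, realization, intra metric) and reuses them
across every inter/LR combination, and evaluates P_N over a whole threshold
grid from one sort + cumulative weight sum. Because subvolume weights are
integer voxel counts, the cumulative sums are exact, so the bulk path is
*bit-identical* to evaluating `metrics.global_score` spec by spec — asserted
in the tests, not merely assumed.

## Correlation search

Spearman's ρ is used throughout (tie-safe average ranks; two-sided p from the
t approximation; |ρ| = 1 reports the smallest positive float rather than 0).
The bulk ranking computes average ranks per column and a vectorized Pearson
step, verified against `scipy.stats.spearmanr` to 1e-12. Cases missing a
measure (DLCO is not always acquired) are deleted pairwise. P-values are
descriptive only — star annotations at P < 0.05 / 0.01 / 0.005, no
multiple-testing correction — matching common reporting for this kind of
exploratory search.

Default grids: radius 10–90 step 1, N 5–95% step 0.1 ("full" preset); the
"coarse" preset (step 10 / step 5, 2 realizations) exists for quick runs. The
N step is a free choice — only the interval is principled — and both grids
are configurable.

## Classification

Abnormal lung function: DLCO < 60%, FEV1 < 70% or FEV1/FVC < 70 (strict
inequalities; FEV1/FVC is compared as recorded, no unit conversion). Cases
with missing DLCO are dropped from classification so every case is labelled
under the full criteria.

The model is leave-one-out cross-validated logistic regression: per fold,
covariates are z-scored on the training cases (standardization is assumed
because candidate covariates live on wildly different scales), an unpenalized
maximum-likelihood fit is made (`lbfgs`, tol 1e-10), and the held-out
probability recorded. A tiny ridge (α = 1e-8) is the fallback when the
unpenalized optimizer fails (e.g. perfectly separable folds); its use is
flagged in the report. AUC is computed over the pooled held-out
probabilities; F1/accuracy/confusion use threshold 0.5 (no threshold is
principled here; 0.5 is the convention). Coefficients are reported as
mean ± sd over the n fold fits, on the standardized scale.

The candidate pool for the best-subset search is the top-5 specs per measure
for DLCO, FEV1 and FEV1/FVC (FVC is excluded as the consistently
weakest-correlated measure). Every non-empty subset is evaluated by LOOCV
AUC — ties break by higher F1, then fewer covariates, then canonical column
order — optionally capped by subset size (`subset_cap`); the library default
searches all subsets of a ≤ 15-covariate pool. Note the protocol selects and
evaluates on the same LOOCV, which is optimistic; the package reproduces the
protocol and documents the optimism rather than nesting the CV.

VIF diagnostics: `VIF_j = 1/(1 − R²_j)` from regressing covariate j on the
other covariates with intercept; exact collinearity reports +inf. The
cross-group variant regresses only on covariates ranked for *other* PFT
measures, since within-measure candidates are collinear by construction.

A caveat worth knowing when reading null baselines: pooled LOOCV predictions
of a label-independent covariate are *pessimistically* biased (AUC well below
0.5), because removing a case tilts the fold's fit away from that case's own
label. The test suite asserts absence of optimism rather than a 0.5 null
mean.

## Synthetic cohorts

The generator emulates the structure, not the physics, of a clinical
perfusion cohort:

* **Masks**: two disjoint jittered ellipsoids on a 64³ grid at 2 mm
  (left semi-axes 9×12×20 voxels, right 10×13×21; centre jitter sd 1.5
  voxels, axes jitter 5%) — roughly lung-proportioned, right slightly larger.
* **Perfusion**: uniform noise blurred with a 4-voxel Gaussian, normalized to
  in-lung mean ≈ 1 with 25% relative heterogeneity, clipped strictly
  positive. Hypoperfused defects are spheres (radius 4–8 voxels) multiplied
  by 0.2, inserted per lung until a requested in-lung volume fraction is
  covered (achieved within ±0.05; sphere volume is capped at the remaining
  deficit so the band cannot be overshot). Defects *multiply* rather than
  replace intensities so percentile maps remain informative.
* **Lung function**: per-lung defect fractions are drawn independently
  (U[0, 0.5]) so LR operators see asymmetric disease; each PFT value is
  `intercept − slope · total_defect_fraction + N(0, sd)`, truncated at 0,
  with (intercept, slope, sd) = (92, 85, 4) for DLCO, (96, 90, 4) for FEV1,
  (100, 60, 6) for FVC (deliberately the weakest coupling) and (84, 55, 3.5)
  for FEV1/FVC. These slopes put the generator-level |Spearman| near 0.9 at
  n = 30 — strong but noisy coupling. DLCO is set missing for ~1/12 of cases.
* **Determinism**: case i uses RNG substream `master_seed + i`, so cohorts
  are extensible without reshuffling existing cases; everything is
  bit-reproducible from the master seed.

What passing tests on these cohorts shows: the pipeline recovers monotone
perfusion–function coupling and discriminates defect-driven abnormality.
What it does not show: performance on real SPECT noise, attenuation
artifacts, anatomically realistic vasculature, or genuinely nonlinear
perfusion–PFT physiology — none of which the generator models.

Because the synthetic defect burden is a *volume fraction* by construction,
voxel-level defect statistics (the non-discretized P_N) are already
near-ideal correlates on synthetic data, so Voronoi discretization is not
expected to dominate here as it can on clinical maps; the recovery tests
therefore require the best Voronoi spec to be within 0.05 of the best Full
spec, not to beat it.

## Problem sizes and numerical choices

The test suite and the acceptance script run the coarse preset: 30-case
cohorts (12 for the determinism check), radius grid {10, …, 90} step 10, N
grid {5, …, 95} step 5, two seed realizations, both value kinds (41 000 metric
specs), and a best-subset search capped at two covariates — sizes chosen so a
full synthetic study is a minutes-scale, single-CPU computation while
exercising every code path. Oracle tolerances: statistics vs brute-force
references 1e-10; scale-invariance and rank/AUC identities 1e-12; LOOCV
probabilities vs an independent per-fold refit 1e-6; VIF vs normal-equations
solve 1e-8. Voronoi-vs-brute-force label agreement is exact, as is the
bulk-vs-reference score matrix and pipeline rerun determinism.
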