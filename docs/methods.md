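# Methods

## The problem

Ecological niche models (ENMs) relate species occurrence records to gridded
environmental predictors to estimate habitat suitability.  When the
candidate predictor collection is large (tens to hundreds of layers, e.g. a
reanalysis extract), fitting one model on everything is slow, collinear and
hard to interpret.  `nichescreen` implements a Monte Carlo screening
strategy: many *small*, independent presence/background model fits — each on
a random subset of V variables (pairs by default) — are tallied by
permutation importance, and the per-variable average importance over the
whole ensemble ranks the collection.  The top-k set then passes through
pairwise collinearity pruning and an AICc-based settings sweep before a
final model is fit and evaluated.

## Ensemble scheduling

To give each of N variables an expected S appearances with V variables per
run, the ensemble needs

    C_max = ceil(N·S / V)

runs, which is also the core count at which the ensemble is perfectly
parallel.  On C logical workers each worker repeats

    R = ceil(C_max / C)

sequential runs, for R·C total runs; the achieved sampling rate R·C·V/N is
therefore ≥ S (the planner reports it).  Given an observed ensemble wall
time T, the fully-parallel floor is estimated as T_min = T/R, reported to
one decimal (minutes).  The "bracket" in the repeat factor is a ceiling:
that is the only reading consistent with R = 22 for C_max = 2150 on 100
cores.

Workers are *logical*: C fixes the schedule and the per-worker seed
streams, while the number of OS processes that execute them is a pure
execution detail (`n_jobs` / `--workers`) that never changes any output.
Each worker writes its tally as a `<worker>.tt` TSV into a shared
directory; aggregation is an element-wise sum and is associative and
commutative, so any partition of the tally files gives the same global
table.  A failed fit (degenerate subset, non-convergence) is logged and
skipped without retry; its variables' use counts are not incremented, and
the achieved-S accounting reflects the shortfall.

By default three independent ensembles are run and each variable's average
importance is averaged across the ensembles in which it was used before
re-ranking (at S = 50 every variable appears in every ensemble, so the
proviso only matters in tiny smoke configurations).

## The niche model

The engine is a presence/background maximum-entropy (Gibbs) model.
Covariates are min-max normalized to [0, 1] using the combined
presence+background range, then expanded into feature classes:

* **L** — the normalized covariate itself;
* **Q** — its square;
* **P** — pairwise products of distinct covariates;
* **H** — forward hinges max(0, (x−t)/(1−t)) and reverse hinges
  max(0, (t−x)/t) at 16 equally spaced knots t per variable
  (configurable; hinge placement inside closed-source implementations is
  version-specific, so a fixed uniform grid was chosen for
  reproducibility).

With feature vector f(x) and coefficients β, the raw output is
exp(β·f(x))/Z with Z summed over the background sample.  Coefficients
minimize the penalized negative log-likelihood per presence,

    −f̄·β + log Σ_bg exp(β·f(x)) + Σ_j λ_j |β_j| ,

with per-feature penalties λ_j = RM · β_class(m) · sd_j/√m, where m is the
presence count, sd_j the presence-sample standard deviation of feature j
(floored at 1e-3), and β_class an interpolated schedule in m (heavier for
small samples; hinge features use a constant 0.5).  The regularization
multiplier RM scales all penalties, which is what the calibration grid
sweeps.

**Optimization.**  The solver is proximal Newton: each outer iteration
freezes the Gibbs weights, builds the exact (small, d×d) Hessian, solves
the L1 quadratic subproblem by cyclic coordinate descent (numba-compiled),
and backtracks on the true objective.  Convergence is declared when no KKT
condition is violated by more than `kkt_rel` (default 5·10⁻³) of the
penalty scale; at that point predictions, AUC and log-likelihood agree with
tightly-converged solutions to ~4 decimals while fits are orders of
magnitude faster, which matters because a screening study performs tens of
thousands of fits.  Coefficients are boxed to ±30: a feature (typically an
extreme-knot hinge) whose support misses the background sample has an
unbounded unpenalized optimum, and a coordinate pinned at the box satisfies
the projected KKT conditions.  The solver is deterministic, so fits are
bit-reproducible under a fixed configuration.

**Outputs.**  Logistic suitability uses the entropy convention
p = e^H·raw/(1 + e^H·raw) with H the entropy of the fitted raw
distribution over the background, so a featureless model scores 0.5
everywhere (the default-prevalence-0.5 convention); cloglog output is
available as an option.  `k_params` counts nonzero coefficients (the
soft-threshold produces exact zeros).

**Permutation importance** permutes one variable's values jointly across
the combined presence+background rows, re-evaluates training AUC, floors
the drop at zero, averages 3 repeats, and normalizes the drops to
percentages summing to 100 (all-zero drops return an all-zero map with a
warning).  **Replicate cross-validation** (default 10-fold over presences;
the screening experiments here use 3) reports replicate-mean AUC and
importance; fold assignment is a seeded shuffle.

## Refinement

Pairwise Pearson r, r² and VIF = 1/(1−r²) are computed over the same
presence+background covariate rows used for fitting (self-contained and
independent of raster size).  A pair is flagged when any of |r| > 0.8,
r² > 0.8, VIF > 10 holds — the thresholds are individually configurable and
a conjunctive rule is available.  The disjunctive default is deliberate:
the three thresholds are mutually redundant (VIF > 10 ⟺ r² > 0.9), and a
conjunctive reading would only ever bind at |r| > 0.949, under which a
predictor pair correlated at r ≈ 0.9 — exactly the situation the
refinement step exists to resolve — would never be flagged.  While any
pair is flagged, the flagged-pair member with the lowest screening
importance is dropped (one variable per iteration, so a variable collinear
with several others is dropped once) and flags are recomputed among
survivors; the top-ranked variable can never be dropped.

One practical caveat: for a pair correlated at r ≈ 0.9, the two members'
screening importances typically differ by only a few points — within the
Monte Carlo noise of the ensemble estimate — so *which* member of a
flagged pair is eliminated can flip between repetitions.  Either outcome
resolves the collinearity (exactly one member survives), but downstream
interpretation should not read the survivor of a near-tied flagged pair as
the causally favored variable.

## Calibration and the final model

The retained predictors are swept over five feature-class settings
(L, LQ, H, LQH, LQHP) × eight regularization multipliers (0.5–4.0 step
0.5).  Every cell is a single full-data fit (no CV replicates, so k and
lnL are well-defined for one model) against one shared, seeded background
sample (so AICc is comparable across cells).  The presence log-likelihood
normalizes the raw output over the background sample, lnL = Σ_presences
(η − log Σ_bg e^η), and

    AICc = 2k − 2·lnL + 2k(k+1)/(n−k−1)

with n = the number of presences and k = nonzero coefficients; cells with
n ≤ k+1 are inadmissible (+∞).  The minimum-AICc cell wins; ties prefer
fewer parameters, then lower RM, then the feature-class order above.  The
winner supplies the final model, a suitability map over the collection grid
(nodata wherever any input layer is nodata), and evaluation metrics.

## Evaluation statistics

* **AUC** — rank-based Mann-Whitney probability that a presence outscores a
  background point, ties counted ½.
* **PCC / TSS** — from the thresholded confusion matrix (score ≥ threshold
  predicts presence); PCC = (TP+TN)/total as a proportion,
  TSS = sensitivity + specificity − 1.  The threshold defaults to the
  max-TSS threshold over observed score values (recorded in the output);
  any fixed threshold can be supplied instead.
* **Niche overlap** — for two suitability maps normalized to sum to one
  over their shared valid mask: Schoener's D = 1 − ½Σ|p−q| and Warren's
  I = 1 − ½Σ(√p−√q)² (so D ≤ I always), plus Pearson's r on the raw cell
  values (undefined, returned as NaN with a warning, for constant maps).

## Synthetic landscapes

The generator stands in for real predictor stacks so that recovery,
refinement and calibration are testable offline.  Each layer is seeded
white noise smoothed by a Gaussian filter (default scale 5 cells — enough
spatial autocorrelation to look like an interpolated climate surface
without geostatistics machinery) and min-max rescaled to [0, 1].  Decoys
are α·source + √(1−α²)·residual with the residual field orthogonalized
against the source, so the sample correlation equals the target exactly
(min-max rescaling is affine and preserves it); the generator verifies the
achieved correlation on every build.  True suitability is a logistic
function of a linear combination of driver layers, centered so median
suitability is near 0.5; a log-linear response (a Gibbs density whose log
is exactly linear in the drivers) is available for experiments where the
true response class matters.  Presences are drawn without replacement
∝ suitability at cell centers, so extraction and thinning are exactly
testable.

`benchmark_default` mirrors the 19-variable screening scale: a 100×100
grid, 19 layers, two drivers with log-odds slopes +10 and −10 on the unit-
scaled layers (giving presence/background separation typical of a
moderately well-determined niche, training AUC ≈ 0.6–0.7 for a driver
pair), one decoy correlated at r = 0.9 with a driver, and 300 presences.
Passing recovery on this benchmark shows the ranking statistics separate
signal from noise under spatially autocorrelated, partially collinear
predictors; it does not emulate real climate physics, sampling bias, or
observation error in occurrence data.

## Occurrence handling

Occurrence CSVs (`species,longitude,latitude`; extra columns ignored with
a warning) are deduplicated on exact coordinates.  Spatial thinning to a
minimum pairwise distance (e.g. 16 km) is greedy and randomized: points
are visited in a seeded random order and kept iff at least the buffer
distance (haversine, Earth radius 6371.0088 km) from every kept point —
the simplest reproducible contract satisfying the pairwise-distance
guarantee, verified in tests against an O(n²) oracle.

## Problem sizes and reproducibility

The test suite runs the recovery experiment as 20 seeded repetitions of
one full S = 50 ensemble each (475 runs per repetition), with the reduced
engine settings used for screening experiments: 3 CV replicates and 2,000
background points.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence`, fanned out per (ensemble, worker, run), so any
single model fit can be re-executed in isolation and all scientific
outputs are invariant to the physical process count.

## Known limitations

* No numerical parity with the Java MaxEnt implementations is promised —
  the model family and the semantics of FC/RM tuning are the same, exact
  coefficients are not.
* Categorical and threshold feature classes, clamping/extrapolation
  analysis and bias files are not implemented.
* Rasters must be co-registered already; there is no reprojection or
  resampling, and no NetCDF ingestion.
* Pairwise VIF only; full multivariate VIF and clustering-based predictor
  reduction are out of scope.
* The screening stage has no automatic stopping rule; S is fixed up front.
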