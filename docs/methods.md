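# Methods

`occunet` implements a static, network-extended species occupancy
analysis for organisms that breed in discrete habitat patches — the
motivating system is the Yosemite toad (*Anaxyrus canorus*), which
breeds in shallow water in high-elevation Sierra Nevada meadows, with
~2,558 candidate meadows of which roughly half have ever been surveyed.
This note records the model, its assumptions, the numerical choices, and
what the synthetic landscapes do and do not establish.

## Intrinsic ("environmental") model

Breeding detection at surveyed patch *i* is modelled as a Bernoulli GLM
with logit link on patch-level environmental covariates. Because
presence records are rare (~13% of surveyed patches, a ~7:1
absence:presence ratio), the production model is a balanced-subsample
ensemble: each of `n_members = 100` members is fitted by bidirectional
stepwise AIC selection on **all** presences plus an equal-size random
absence subsample (drawn without replacement within a member,
independently across members). The ensemble prediction is the arithmetic
mean of member probabilities. Balancing does not improve ranking much —
ranks correlate > 0.9 with a plain full GLM on the same data — but it
spreads predicted probabilities across (0, 1) instead of compressing
them near the prevalence, which makes threshold-based management maps
readable.

Choices that were genuinely open:

* **Stepwise start point** is the full model (`start="full"`), with
  `start="null"` available; both directions (add/drop) are evaluated
  every round and ties in AIC are broken lexicographically by term name
  so results are reproducible.
* **Perfect separation** raises an error naming the worst term rather
  than silently returning a shrunk or runaway fit; inside the stepwise
  search a separating move is skipped with a warning. Detection is
  empirical (perfect training classification at ~zero deviance, or any
  coefficient beyond ±40), because IRLS can stall on separated data
  while reporting convergence.
* **No imperfect-detection likelihood.** Detection probability (~0.75
  per survey in this system) enters only the synthetic generator; the
  fitted GLM targets *observed* breeding, so its probabilities are
  detection-thinned. A MacKenzie-style occupancy likelihood is out of
  scope.
* Covariates with pairwise |Pearson r| > 0.9 are pruned before fitting,
  greedily in column order, keeping the earlier column. Which member of
  a correlated pair to keep is an expert choice in field practice; the
  order-based rule is deterministic and the order is configurable.

## Evaluation and extrapolation

Models are scored on a held-out test set with fixed class counts
(default 25 presences, 177 absences, mirroring the ~13% prevalence) by
ROC AUC and the **maximum discrimination threshold** (MDT): thresholds
0, 0.01, …, 1 are scanned, a patch is called breeding iff its
probability is *strictly* greater than the threshold, and the MDT is the
smallest threshold minimizing |true-presence rate − true-absence rate|.
The absolute difference and the smallest-threshold tie-break are fixed
conventions; at the balance point they coincide with any reasonable
reading of "minimize the difference".

The landscape-wide breeding total extrapolates the test-set rates to
unsurveyed patches: with `n_above` unsurveyed patches above the MDT
expected to breed at the true-presence rate and `n_below` below it at
(1 − true-absence rate), the predicted count is the sum of the two
products, each rounded half-up, plus the known breeding count. With the
census inputs (179 known; 277 above at 0.84; 937 below at 0.16) this
gives 233 + 150 = 383 unsurveyed and 562 total.

## Network boosting

Each patch's intrinsic probability P_i is raised by neighbors within
dispersal range:

    P_i_total = 1 − (1 − P_i) · Π_j (1 − P_i · P_j · D_ji)

with D_ji a dispersal kernel on centroid distance — by default linear,
`max(0, 1 − d/1000 m)`, zero at 1 km (the scale of maximum recorded
adult toad movements; kernel value 1 at distance 0 by convention). A
beta(2, 2) kernel peak-normalized on [0, cutoff] and a 5× cutoff are
available as robustness variants.

Iteration semantics: sweeps are synchronous (Jacobi-style, so the fixed
point cannot depend on patch order); neighbor values P_j update each
sweep while the focal patch's own factors — the (1 − P_i) headroom and
the P_i receptivity inside the product — stay at the intrinsic value.
This propagates neighbor-of-neighbor influence while keeping each
patch's receptivity fixed; the fully self-consistent alternative (focal
factors also updating) is noted but not implemented as a default. Each
sweep is elementwise non-decreasing and bounded by 1, so the iteration
converges monotonically; we stop when the largest per-patch change drops
below `tol = 1e-6` (`max_iter = 100`, flagged rather than raised).
Default landscapes settle in roughly 15–25 sweeps; small networks match
direct algebraic fixed-point solutions to 1e-8.

Per-patch derived quantities:

* **NNI** = (P_total − P)/(1 − P) ∈ [0, 1], the realized fraction of a
  patch's probability headroom — "network quality". A patch with P = 1
  has no headroom and its NNI is defined as 0.
* **Deletion influence** G_i = ExpBreed_T − ExpBreed_i, where
  ExpBreed_T = Σ P_total and ExpBreed_i re-runs the boost with patch i
  fully disconnected (all incident edges removed, both directions),
  patch i contributing only its intrinsic P_i. Monotonicity implies
  G_i ≥ 0; deletions are solved per connected component (only the focal
  component can change) at `tol = 1e-10`, and differences within
  truncation error below zero are clipped to 0.
* **Quadrants** cross "high environmental quality" (P_env strictly
  above the MDT) with "high network quality" (NNI strictly above 0.5):
  2 = high/high connected hotspots, 3 = high/low isolated good patches,
  1 = low/high network-dependent patches, 4 = low/low.

Distances are Euclidean between centroids in a projected metric CRS; the
package never reprojects coordinates. Least-cost or resistance distances
are out of scope (terrain enters only as a covariate).

## Synthetic landscapes

No public dataset accompanies this system, so `occunet.synthetic`
generates landscapes with the statistical structure the analysis
assumes, and all tests run against them:

* **Geometry**: 2,558 patches in a 60 × 60 km square (≈ the 3,000 km²
  scale of the park), scattered around 200 uniform cluster centers with
  900 m Gaussian spread, giving a mean of ~5 neighbors within the 1 km
  cutoff — enough connectivity for boosting to matter without saturating
  every boosted probability at 1. Watersheds are Voronoi cells of 50
  anchor points; only membership is used downstream.
* **Covariates**: 15 unit-variance Gaussian random fields with
  exponential spatial covariance (range 5 km); the first two consecutive
  column pairs are mixed to a population correlation of 0.95 to exercise
  the r > 0.9 pruning step (mirroring near-collinear pairs such as mean
  temperature vs elevation in real covariate compilations).
* **Truth and surveys**: true breeding is Bernoulli of a logit-linear
  model with slopes (0.9, 0, 0.7, 0, −0.6, 0, 0.5, 0, 0.4, 0, −0.35, 0,
  0.3, 0, 0.25) — signal on the first member of each correlated pair —
  and intercept −2.15, calibrated once so that with 75% per-survey
  detection and 1344/2558 patches surveyed the detected prevalence among
  surveyed patches averages ~179/1344 ≈ 13.3% (measured 13.7% ± 0.5%
  SEM over 50 seeds; between-seed spread ~3.5 points comes from the
  spatially correlated fields). Every generator is a pure function of
  its seed.

What the generator does **not** emulate: real covariate marginals and
units (fields are standardized Gaussians), meadow polygons and areas
(patches are points), multi-year survey dynamics (outcomes are already
collapsed to ever-detected), spatial variation in detection effort, and
any disease or barrier structure. Passing tests therefore establish that
the algorithms are implemented correctly and behave as designed under
realistic sampling structure — not that the fitted coefficients or maps
would match any particular field system.

## Problem sizes and determinism

The default test and acceptance runs use the full 2,558-patch landscape
with a 100-member ensemble (about 20–30 s end-to-end on one CPU);
unit-test fixtures use 500–800 patches with 3–20 members. Parameter
recovery is checked at n = 2000 with known coefficients, full survey and
perfect detection: each coefficient falls inside its 95% Wald interval
in ≥ 90% of 50 replicates. Property tests (hypothesis) run
derandomized; every stochastic routine takes an explicit seed.

## Known limitations

* The boosting recursion treats the intrinsic probability as fixed
  receptivity; it is a diffusion heuristic, not a colonization–
  extinction model, and ExpBreed over-counts relative to the
  threshold-based extrapolation when many patches sit near the MDT.
* Deletion influence scales as (component size) × (boost cost); a single
  giant component of thousands of densely connected patches would be
  slow, though clustered landscapes solve in seconds.
* The stepwise-AIC search is greedy and can settle on a local optimum;
  the exhaustive-enumeration oracle in the tests covers only small
  candidate sets.
* CV of per-watershed probabilities uses the sample standard deviation
  over the mean and is reported missing for singleton watersheds.
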