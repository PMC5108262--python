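# Methods

## The surrogate problem

Reserve-selection algorithms (Marxan, Zonation, C-Plan) need species
occurrence data for every planning unit. `prwr` addresses the planning
situation where inventories cover only q% of sites: rarity-weighted
richness (RWR) computed on the inventoried subset is regressed on
environmental covariates, and the fitted model supplies a priority score —
predicted RWR (PRWR) — for all sites. RWR is attractive as the modelled
quantity because it is a simple site score (`Σ 1/cᵢ` over the species
present, `cᵢ` = occupancy of species *i*) that in several study systems
ranks sites for species representation about as well as iterative
complementarity heuristics, while being trivially computable and shareable.

Occupancies are always counted *within the matrix being scored*: when the
q% subset is scored for model training, `cᵢ` is the subset-internal count,
because that is all a planner in this scenario could know. Sites with no
recorded species score 0 and are retained. Total RWR over any matrix
equals its occupied-species count (each species contributes `cᵢ · 1/cᵢ`),
a conservation identity used throughout the tests.

## Predictor selection

Environmental covariate pools are strongly collinear. Following standard
practice, the pool is reduced by correlation-matrix PCA: components with
eigenvalue > 1 (Kaiser rule, strict inequality, no tolerance) are
retained, and for each retained component the variable with the largest
|Pearson r| against the component scores is selected. When one variable
tops two components it keeps the component where its |r| is larger and the
runner-up takes the other — implemented as a greedy assignment over all
(variable, component) pairs in descending |r|, ties broken by variable
name, so the outcome is deterministic. Correlation-matrix (not covariance)
PCA is used because the variables mix units and the Kaiser rule assumes
unit-variance inputs; a corollary, tested as an invariant, is that
rescaling any variable by a positive constant changes nothing.

A caveat the synthetic experiments exposed: when two or more gradients are
observed with *equal* strength, their eigenvalues tie and the
corresponding components are arbitrary rotations within the tied subspace;
one-variable-per-component selection can then miss a gradient entirely.
Real covariate stacks are rarely balanced this way (energy variables
dominate), and the landscape generator mirrors that (see below). PCA runs
once on the full environment table by default — covariates are assumed
known landscape-wide — with an `ExperimentConfig(pca_sites="inventoried")`
switch that moves selection inside the replicate loop for sensitivity
analysis.

## The random-forest model

`RandomForestRegressor` (scikit-learn) with the classical recipe: 500
fully grown trees (`n_trees`), bootstrap of n draws with replacement
(≈63% unique sites per tree), `floor(p/3)` candidate predictors per split
(minimum 1, `predictors_per_split`), minimum leaf of 5 sites
(`min_leaf_size`). Out-of-bag MSE and R² are computed by regenerating each
tree's bootstrap from its recorded random state and averaging only the
votes of trees that excluded the sample — scikit-learn's own
`oob_prediction_` silently reports 0.0 for samples that were in-bag for
every tree, which corrupts small ensembles. The response is fitted
untransformed by default; `transform="log1p"` fits log(1+RWR) and
back-transforms predictions (rankings are unaffected; the option exists
because RWR is right-skewed and the log model often has better OOB R²).

**Out-of-bag prediction at training sites.** `predict_prwr` returns, for
sites the model was trained on, the mean of only the trees whose bootstrap
excluded the site; other sites get the full-ensemble mean. In-bag
predictions at training sites partially reproduce the site's own observed
RWR, which inflates apparent surrogacy wherever inventories exist — on an
environment-independent null landscape that optimism alone produced
strongly "significant" SAI. With OOB prediction a site's PRWR reflects
environment alone, and the null landscape correctly evaluates to SAI ≈ 0.

## Evaluation: the Species Accumulation Index

Sites are accumulated in descending score order (ties broken by a seeded
shuffle, then site id) and the cumulative distinct-species count S_k is
recorded against the full matrix. The index at step k is
`SAI_k = (S_k − R_k) / (O_k − R_k)`; steps where `O_k − R_k < 10⁻⁹` are
skipped; the reported value is the unweighted mean over the steps
corresponding to the top 5%, 10%, …, 50% of sites (configurable) — the
top-ranked land prioritization actually concerns.

* **O (optimal)** comes from additive greedy maximum coverage: each step
  adds the site contributing the most unrepresented species, ties broken
  by higher full-landscape RWR then site id (with a 10⁻⁹ tolerance on the
  RWR comparison so summation order cannot flip ties); once all species
  are covered, remaining sites are appended by raw richness under the same
  rule. Greedy carries the (1 − 1/e) prefix guarantee, and an exhaustive
  enumerator (`exact_optimal_curve`, feasible to 20 sites via a 2^N
  bitmask sweep) certifies it: on random small instances greedy equals the
  true optimum in well over 90% of cases. Because greedy can be slightly
  suboptimal, SAI can in principle exceed 1 against it; against the exact
  optimum SAI ≤ 1 always (asserted in tests).
* **R (random)** is the exact expectation under uniform sampling without
  replacement: `R_k = Σⱼ [1 − C(N−cⱼ, k)/C(N, k)]`, evaluated with
  `gammaln` in log space. No Monte Carlo noise enters SAI; a Monte-Carlo
  mode exists purely as a cross-check oracle.

Replicate experiment: for each q, `n_replicates` independent splits →
subset RWR → fit → PRWR for all sites → SAI against the shared O and R
curves. Per-replicate seeds derive from the master seed through
`SeedSequence(master, spawn_key=(q_index, replicate, stage))` reduced to
31 bits, so a sweep is exactly reproducible and stages never share
streams. The per-q summary is the replicate mean with a distribution-free
95% percentile interval (inverted-CDF quantiles at 2.5/97.5%, which
degrade gracefully to min/max at 2 replicates); a q level is "significant"
when the interval excludes zero. Replicate failures abort the sweep —
silently dropping replicates would bias the interval.

## The virtual-landscape generator

`LandscapeSpec` defaults describe a mid-sized atlas: 1,000 sites, 300
species, 6 latent standard-normal gradients observed through 18 noisy
covariates. Three structural choices matter, each forced by a failure mode
observed with simpler designs:

1. **Unequal gradient observability.** Variables are allocated to
   gradients by a triangular deal (5, 4, 3, 2, 2, 2 for 18/6) with
   observation noise growing with gradient index. Equal blocks produce
   tied eigenvalues, arbitrarily rotated components, and predictor sets
   that can omit a gradient; unequal blocks keep components aligned with
   gradients, as in real stacks where energy variables dominate.
2. **Rarity concentrated in scarce environments.** 70% of species
   (`restricted_fraction`) are "restricted": their niche optima sit 1.5 SD
   (`rarity_shift`) up the first gradient, where sites are genuinely
   scarce, with narrow breadth (0.7) on that axis. If instead optima
   follow the same distribution as site conditions, expected RWR is nearly
   flat — species density cancels site density — and there is nothing for
   any model to predict.
3. **Centers of endemism.** Restricted species cluster around 12 centres
   (`n_endemism_centers`) scattered across the other gradients, species
   tightly grouped (SD 0.35) around their centre with moderate breadth
   (1.1) on those axes. Distinct rarity hotspots therefore hold distinct
   species and complement one another; without clustering, top-ranked
   sites all host the same species and a score-based surrogate cannot beat
   random at small fractions.

Maximum occupancy h ~ Beta(8, 2) makes presence near-certain where the
environment is suitable, so rarity is environmental restriction rather
than Bernoulli thinning. Occupancy probability is the mixture
`p = d·h·g(x) + (1−d)·h·ḡ` with `g` the product Gaussian suitability and
`ḡ` its landscape mean: the determinism dial d moves occupancy between a
pure function of environment (d=1) and spatially uniform noise (d=0)
while holding each species' expected prevalence fixed, so rarity structure
and signal strength are independently tunable. Species that realize zero
presences are redrawn up to 10 times, then dropped with a warning.

Under the defaults the range-size distribution is right-skewed (median
occupancy ≈ 10–30 sites, mean ≈ 140–150 of 1,000) and the full pipeline
reproduces the qualitative behaviour expected of the surrogate: SAI
non-decreasing in q, roughly 0.55–0.85 at q = 20% with determinism 0.9,
and statistically indistinguishable from zero at every q with
determinism 0.

What the generator does **not** emulate: spatial autocorrelation and
dispersal limitation (two climatically identical but distant sites share
exactly the same species pool here, which makes score-based surrogates if
anything *harder* to distinguish from complementarity methods than in real
data), species interactions, abundance, and observation error in the
inventories themselves. Passing tests therefore demonstrate correct
mechanics and qualitative behaviour under a plausible macroecological
model, not performance guarantees for any particular real dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script use 1,000-site landscapes with 20
replicate splits at q ∈ {5, 10, 20, 40} — enough for stable grand means
and percentile intervals while keeping a full run to a couple of minutes.
Exhaustive optimality checks run on ≤10-site instances where the 2^N sweep
is instant. Other conventions: subset sizes round half-up; identifiers
sort lexicographically everywhere (no hidden order dependence); duplicate
occurrence records collapse silently to presence (atlas data are record
lists); missing environment values are a hard error, never imputed; the
31-bit seed reduction keeps derived seeds valid for every downstream
library.

## Known limitations

* Greedy O is a stand-in for the removal-heuristic ranking used with real
  datasets in the literature; both are near-optimal, but SAI values
  against slightly different O references are not strictly comparable.
* The averaged-fraction set (top 5–50%) is a convention; SAI magnitude
  depends on it, so comparisons should hold it fixed.
* OOB R² can be strongly negative on very noisy subsets at small q; this
  is informative (the model knows nothing), not a failure.
* Representation targets beyond one occurrence per species, cost
  weighting, and connectivity objectives are out of scope.
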