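# Methods

This note records the models implemented, the parameter choices that
matter, and what the synthetic generators do and do not emulate.

## Network representation

A community is a binary incidence matrix `A` (n consumers × m resources).
Consumers with no recorded diet are rejected at construction: the analyses
are about observed diets, and an all-zero row would silently dilute every
per-consumer statistic. Resource columns emptied by an operation
(secondary-resource filtering, species removal) are dropped before metrics
are recomputed, so the pair-count denominators shrink with the network —
the convention consistent with reporting a reduced resource richness after
removals. Duplicate interaction records collapse to a single 1; ids are
case-sensitive and whitespace-trimmed.

## Nestedness (NODF)

The strict decreasing-fill variant: a row pair contributes
`100·overlap/k_smaller` only when the totals strictly decrease and the
smaller is positive; ties contribute zero; row and column pair sums are
averaged over all pairs of both margins. This is the original formulation
and matches the convention of the standard nestedness toolchain, so values
are comparable with published NODF scores. No pre-sorting is needed — the
pairwise terms are permutation-invariant — and the implementation is
verified exactly against a from-definition brute-force oracle on hundreds
of random matrices. Zero-degree rows or columns (possible inside null
samples) contribute zero.

## Bipartite modularity

Barber's `Q = (1/F) Σ (A_ij − k_i d_j/F) δ(g_i, h_j)` over a joint
partition of consumers and resources; Q of the single-module partition is
identically 0, and k equal disjoint complete blocks give `Q = 1 − 1/k`.

Optimization is simulated annealing over joint label assignments. Per
temperature: `(n+m)²` single-node relabel proposals (target drawn from all
module slots, so moves into an empty slot create modules — this also plays
the role of split moves) and `n+m` module-merge proposals; ΔQ for
single-node moves is evaluated in O(1) from per-module running sums.
Geometric cooling (factor 0.95); the initial temperature is calibrated so
the median degrading move from the random initial state is accepted with
probability ~1/2; a run stops after 3 temperatures without improving its
best Q. The best state then receives a greedy hill-climb polish (move each
node to its best module until no improving move). Five restarts by default;
the number of module slots is capped at min(n, m). Ties keep the
first-found partition and labels are canonicalized by first occurrence. A
reduced-effort schedule (`FAST_SCHEDULE`: 1 restart, faster cooling, fewer
proposals) is used inside null ensembles where thousands of optimizations
are needed and only the ranking of null Q values against the observed Q
matters — both sides of the comparison use the same schedule.

The annealer's result is checked against exhaustive enumeration of all set
partitions (feasible to n+m ≤ 12) on batteries of small random networks;
the reported Q is always recomputed from the definition, and a partition
scoring below the single-module baseline is replaced by that baseline.

## Null model and significance

Cell (i, j) of a null matrix is filled independently with probability
`(k_i/m + d_j/n)/2` — the mean of the row and column fill proportions —
which conserves the expected number of links exactly (`Σ p_ij = F`,
algebraically). Degenerate samples with empty rows/columns are kept, not
resampled: resampling conditions on non-degeneracy and biases fill upward.
Monte-Carlo p-values use the add-one correction
`p = (1 + #extreme)/(1 + n_reps)`, so the smallest attainable p with 1,000
replicates is ≈0.001 and "0 exceedances" prints as p < .01 rather than 0.
The upper tail is the default question (is there more structure than the
null produces?); the tail is a parameter. The relative metric is
`(observed − null mean)/null mean`. Calibration is tested: when the
observed matrix is itself a draw from the null, the rejection rate at
α = 0.05 stays within 3 binomial standard errors over 200 trials.

## Removal experiments

Jackknife: `ΔN_i = N − N_i` with `N_i` the NODF after deleting row i and
any emptied columns. Targeted group removal compares the post-removal NODF
with removals of the same number of consumers drawn uniformly at random
(the target species are not excluded from the random pool by default —
uniform over all same-size subsets — with an option to exclude them); the
p-value is lower-tailed. The secondary-resource comparison counts the
resource columns lost to rank filtering and compares the NODF shift with
random removals of that many columns (two-sided on the shift magnitude).

## Regressions

Ordinary least squares of diet breadth `k_i`, and of `ΔN_i`, on
log10(body mass in grams). Base-10 logs: slopes are per order of magnitude
of body mass and would differ under natural logs. p-values are two-sided
t-tests on the slope; no multiple-testing correction is applied. A
constant response returns slope 0 with R² = 0 and p = 1 (the degenerate
limit of the fit). Family subsetting supports within-clade regressions; no
formal phylogenetic correction is attempted.

## Guild–module association

The randomization preserves both margins of the module × lifestyle table
by permuting lifestyle labels across consumers, so each cell's null is
multivariate hypergeometric (verified against the exact tail on 2×2
tables). Both tails are reported; a cell is flagged significant when
min(p_upper, p_lower) ≤ 0.025 (two-sided 0.05) and marginal at ≤ 0.05;
thresholds are parameters. Bray–Curtis dissimilarity is computed on raw
counts, not proportions — module sizes differ, and raw counts are what
make published module dissimilarities reproducible; two empty modules get
0 by convention.

## Correspondence analysis

Standard CA of the incidence matrix as a contingency table: SVD of the
standardized residuals `D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}`; total inertia is
the table's chi-square over F; symmetric scaling (both row and column
coordinates scaled by the square root of the singular values); two axes by
default, fewer returned on rank-deficient tables.

## Synthetic generators

Defaults emulate the empirical regime the package targets: 62 consumers +
5 connectors, 26 resources, ~10% connectance, right-skewed consumer
degrees, six modules, lognormal masses (log10 mean 1.8, sd 0.7 — roughly
4 orders of magnitude in grams).

- *Nested*: resources are globally ranked; consumer i takes the top
  `k_i = clamp(round(a + b·log10 mass_i), 1, m)` resources
  (a = breadth_intercept, default 0.1; b = breadth_slope, default 1.41).
  Noise relocates each link, with probability `noise_swap_rate`, to a
  random vacant cell *of its own row*: this preserves total fill and every
  consumer's diet breadth, so the noise dial degrades nestedness without
  disturbing the planted degree–mass slope. Near the breadth floor
  (k clamped at 1) the planted linear model is censored and OLS recovery
  is biased downward; slope-recovery checks therefore plant breadths in
  the interior (intercept 1.0). That floor effect is a property of any
  bounded-breadth community, not of the estimator.
- *Modular*: equal consumer and resource blocks; links Bernoulli(p_in)
  within and Bernoulli(p_out) between (defaults 0.45/0.03, chosen to give
  ~10% overall fill at the default dimensions); a consumer left empty gets
  one within-block link. Each block has a signature lifestyle; consumers
  carry it with probability `lifestyle_fidelity` (default 0.8), otherwise
  a uniform lifestyle.
- *Combined*: the modular background plus `n_connectors` consumers
  (family `ConnectorFam`) with strictly the largest masses and strictly
  the top degrees, linked into every block — the hub role of large
  generalist predators. With zero connectors the output is bit-identical
  to the modular generator on the same seed.

What the generators do **not** emulate: abundance-driven interaction
frequencies (everything is binary), phylogenetic autocorrelation of traits
(families are arbitrary labels), sampling effort gradients, and the
empirical community's specific resource-category granularity. Passing
tests on synthetic data therefore demonstrate correctness and statistical
power of the machinery under known structure, not ecological conclusions
about any real community.

## Problem sizes and determinism

Monte-Carlo depths used by the test suite and the acceptance script (e.g.
99–1,000 null replicates, 200-trial calibration batteries, 40–100
parameter-recovery replicates, ensemble modularity on ~30×15 networks with
the reduced schedule) were chosen to give stable pass/fail margins at
interactive runtimes on a single CPU; all are parameters, and field-size
analyses (1,000-replicate nulls, 5,000 resource removals) run in minutes.
Every stochastic routine takes an explicit seed; the pipeline derives one
child seed per stage from the config seed via `SeedSequence` with a stable
per-stage hash, so any single stage can be reproduced in isolation.

## Known limitations

- The annealer is stochastic; on networks with near-degenerate optima
  different seeds can return different partitions of equal Q, and module
  *count* reproducibility is only up to optimizer stochasticity.
- The exhaustive oracle is limited to 12 nodes by Bell-number growth.
- NODF and Q are recomputed from scratch inside removal loops (no
  incremental updates); adequate at field sizes, quadratic beyond.
- Weighted (quantitative) matrices, fixed-marginal swap nulls, and
  alternative modularity optimizers (label propagation, spectral) are out
  of scope.
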