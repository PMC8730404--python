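# Methods

This note documents the models, algorithms and numerical choices behind
`cpmnext`, in the order the pipeline runs.

## Genotypes and fitness landscapes

Genotypes over `G` genes are bit masks (gene 0 = leftmost character of the
printed bitstring).  Fitness is a birth rate: the wild type has fitness 1
and fitness 0 marks a non-viable genotype.  Three generators cover
increasing departures from CPM assumptions:

* **Representable** (`make_representable_landscape`): a restriction DAG
  with AND semantics plus multiplicative fitness
  `f(g) = prod(1 + s_i)` over mutated genes, with all `s_i > 0`;
  incompatible genotypes are non-viable.  This construction guarantees
  that the accessible genotypes *and* accessible mutational paths equal
  those of the DAG, with a single peak at the maximal compatible
  genotype.  Default selection coefficients are drawn uniformly from
  [0.1, 0.3] — the scale commonly attributed to cancer driver events,
  and strong enough that `N*s >> 1` at the default population sizes.
* **Local maxima** (`make_local_maxima_landscape`): the multiplicative
  baseline perturbed by genotype-wise lognormal noise
  (`noise_sd`, default 0.25), rejection-sampled until (a) the set
  accessible from the wild type equals the DAG-compatible set and (b) at
  least two fitness-graph peaks exist.  Vanishing noise cannot satisfy
  (b) and fails after `max_tries` with a clear error.
* **Rough Mount Fuji** (`make_rmf_landscape`):
  `log f(g) = -c * d(g, reference) + xi_g`, `xi_g ~ N(0, noise_sd)`,
  normalized to `f(WT) = 1`.  The log-additive form keeps fitness
  positive.  Defaults `c = 0.25`, `noise_sd = 0.25`, reference = all-ones
  were chosen once to produce the family's signature features at G = 7:
  ~9 accessible peaks on average and reciprocal sign epistasis in
  essentially every locus pair.

The **fitness graph** contains the genotypes reachable from the wild type
through viable, *strictly* fitness-increasing single-mutation steps
(ties are non-edges: no neutral steps, matching the increasing-fitness
trajectory framing; no back mutations, no multi-mutation jumps).
Landscape statistics: `gamma_statistic` is the Pearson correlation of
fitness effects of the same mutation in single-mutant neighbors (1 for
additive landscapes, ~0 under house-of-cards noise; NaN when the pair set
is empty or degenerate); `rse_fraction` is the fraction of locus pairs
with at least one reciprocal-sign-epistatic square among their viable
squares (the per-square fraction is available via `per_square=True`);
`count_peaks` counts fitness-graph sinks, i.e. *accessible* maxima —
the default reading of "number of observed peaks" (the set of all
landscape maxima is exposed separately via `landscape_peaks`).

## Evolutionary simulation

`simulate_run` advances a multitype birth–death process: genotype `g`
divides at rate `f(g)` per cell and dies at rate `log(1 + N_tot/K)` with
`K = N0/(e - 1)`, so a wild-type population equilibrates near `N0`
(density-dependent, logistic-style death; the population then grows as
fitter clones sweep, which is what the small/large detection regimes key
on).  Each division mutates each wild-type locus independently with
probability μ; double mutations in one division (order μ²) are ignored.
Non-viable mutants are purged at creation and never enter ancestries.

The process is advanced by Poisson tau-leaping (default leap 0.25 time
units, snapshots every 1.0).  Demographic time scales are of order
`1/s >= 3` time units, so leap errors are small; clone establishment at
size ~1 is still resolved because Poisson birth/death draws at small
counts approximate the exact branching process.  A run terminates when
the majority genotype is a fitness peak (no fitter viable one-mutation
superset) at frequency ≥ `fixation_threshold` (default 0.95), or is
flagged non-fixated at the time/population caps; non-fixated and extinct
runs are excluded from truth tables.

Study conditions: initial population sizes 2×10³, 5×10⁴ or 1×10⁶;
per-locus mutation rate fixed at 10⁻⁵, or per-gene log-uniform on
[0.2×10⁻⁵, 5×10⁻⁵] (`draw_mutation_rates`).

Each run records the ancestry of every clone at first creation; the Line
of Descent is the parent chain of the fixated genotype (if a genotype
arises independently more than once, the first origin is the recorded
parent — a simplification that matters only outside the SSWM regime and
leaves the one-mutation chain structure intact).  *Observable* genotypes
are the per-snapshot majorities (ties broken toward fewer mutations, then
lexicographically).  The SSWM index is the majority frequency averaged
over snapshots within a run and then over runs: 1 means hard sweeps,
lower values clonal interference.

## Cross-sectional sampling

One observation per simulated process: the majority genotype at a
snapshot drawn with weights uniform (all snapshots equal), `(1 - r)²`
("small" regime) or `r²` ("large" regime), where `r` is the within-run
percentile rank of total population size.  Quadratic rank weights are a
documented stand-in for the source study's detection-size model: they
enrich early/late sampling while keeping full support, and collapse to
uniform for constant-size runs.  No sampling error is applied.  When more
observations are requested than runs exist (reduced-scale experiments),
source runs are drawn with replacement and each draw re-samples its
snapshot independently.  `make_splits` produces k pairwise-disjoint row
subsets; `select_top_features` keeps the most frequently mutated columns
(ties by column order), mirroring the common 15-feature cap for wide real
data sets.

## True transition probabilities

For every fixated run and observed genotype `i` with `n` mutations: if
the LOD's `(n+1)`-genotype `j` contains `i`, the run credits `i -> j`; if
`i` is the fixated genotype or `nMut(i) >= nMut(fixated)`, it credits
NONE; otherwise the LOD continued through a different lineage and the run
is excluded from row `i`'s denominator (default), so that truth and
predictions share the superset-plus-NONE support.  The excluded share is
reported per row (`other_lineage_fraction`), and `unresolved="none"`
switches to counting such runs toward NONE.  Probabilities are exact
count ratios; integer counts and denominators are retained for
downstream weighting.

## Cancer progression models

All three fits consume binary matrices and share the standard
cross-sectional observation model: the chain starts at the wild type and
is observed at an Exp(1) sampling time, so the observable distribution
solves `(I - Q)^T p = e_wt` (one dense LU solve; feasible because G ≤ 15).

* **MHN** (`fit_mhn`): rate of adding event `i` to genotype `x` is
  `theta_ii * prod_{j in x} theta_ij`.  The mean log-likelihood is
  maximized over `log theta` by L-BFGS-B with *analytic* gradients via
  the adjoint of the linear system (two LU solves per gradient), plus an
  L1 penalty on off-diagonal log-effects (smoothed as
  `sqrt(x² + 1e-10)`; default weight 0.01, configurable) that shrinks
  toward independent events.  Deterministic given the data;
  initialization from marginal odds.
* **CBN** (`fit_cbn`): H-CBN-style structure search.  States are the
  poset-compatible genotypes; gene `i` fires at `lambda_i` once its
  parents are mutated; each locus of the true genotype flips with
  probability ε at observation (ε ∈ [1e-6, 0.45] during fitting,
  initialized at 0.05).  Simulated annealing (default 150 proposals,
  geometric temperature 2.0 → 0.01) toggles single edges, rejecting
  cyclic proposals; every candidate poset is scored by the observed-data
  likelihood with (log λ, ε) profiled out by a warm-started bounded
  quasi-Newton step (default 30 inner iterations; the best poset is
  refit with 200).  Scored posets are cached; the search is
  deterministic given (data, seed).
* **OT** (`fit_ot`): complete digraph over {root} ∪ genes with Desper-
  style weights `log(f_ij / ((f_i + f_j) f_j))` from marginal and joint
  frequencies; Edmonds' algorithm (networkx) returns the maximum-weight
  arborescence rooted at the wild type.  The stored edge weight is the
  conditional child-given-parent frequency; genes never observed mutated
  attach to the root with weight 0 and are flagged.

## Predicted transition distributions

From a fitted model's rate matrix, `predict_all` produces one row per
observed genotype in flavors CE (competing exponentials; NONE ≡ 0 unless
the state has no outgoing rate), TD (uniformization `P = I + Q/gamma`,
`gamma = max|q_ii|`; the diagonal becomes the NONE probability, a lower
bound on the genotype behaving as a local maximum; off-diagonal TD rows
are proportional to CE rows) and UW (equiprobable over the structure's
children; defined for CBN and OT).  For OT, the edge weight of the added
gene serves as a rate proxy (`p ∝ w` among tree-addable genes) — the
exact conversion used by the untimed OT model is not specified anywhere,
so this documented proxy keeps OT comparable with the CE family.
Genotypes a fitted structure cannot represent fall back to the uniform
distribution over all supersets with NONE = 0, flagged
`inaccessible_under_model` — maximally uninformative while keeping the JS
defined.

## Evaluation

`js_distance` is the Jensen–Shannon distance with base-2 logarithms
(exactly 0 for identical rows, exactly 1 for disjoint support; a bounded
metric).  `evaluate` returns a tidy genotype × method table with the
per-genotype minimum JS (best possible performance) and the truth-row
denominator as the default weight — weighting is on by default in the
stratified summaries.  Genotype covariates: number of mutations, fitness
rank (1 = global maximum over all 2^G genotypes), indicator of being an
accessible fitness maximum, observed proportion in the fitted sample and
its difference from the full-sample frequency; landscape/dynamics
covariates: SSWM index, gamma, reciprocal-sign-epistasis fraction, number
of observed peaks, detection regime, sample size.  `stratified_summary`
reports weighted mean/median minimal JS per covariate stratum — a
deliberately simple substitute for mixed-effects model trees; the tidy
table carries every covariate so external statistical tooling can refit
that analysis.

For real data sets (no truth), `method_agreement` compares CBN vs MHN
(CE pair), CBN_td vs MHN_td (TD pair) and each CE method against its TD
counterpart, flagging genotypes with similar CE (JS ≤ 0.0677), similar
TD, and different CE–TD (mean JS ≥ 0.7).  The 0.0677 constant is carried
as a named configuration value (it corresponds to the 20% best JS in the
simulation study and has no first-principles derivation).

## Problem sizes used by the shipped experiments

The full factorial design (enumerable via `landscape_grid` /
`dataset_grid`: 1260 landscape configurations, 56700 data sets of up to
20000 runs each) is far beyond a desk run.  The shipped end-to-end
experiment instead uses 5 replicate 7-gene landscapes per scenario
(representable vs RMF), 500 runs per landscape at N0 = 2000 and μ = 10⁻⁵,
uniform detection, sample sizes 50 and 4000 (the larger size resamples
runs with replacement), and the seven in-scope methods (MHN, MHN_td, CBN,
CBN_td, CBN_uw, OT, OT_uw).  RMF replicates are drawn conditional on the
wild type not being a fitness-graph peak, so that every simulated tumor
can progress at least one step; without this, ~8% of RMF draws make all
quantities trivially degenerate.

## What passing tests do and do not show

The synthetic data reproduce the *mechanistic* conditions of the modeled
study — clonal interference, local maxima, detection bias — but not the
messiness of real tumors: no sequencing error, no bulk-mixture
deconvolution, no copy-number events, no back mutations, one observation
per (independent) tumor.  Good performance here is therefore an upper
bound on what the same methods can deliver on real cross-sectional data.
MCCBN, CAPRI and CAPRESE are out of scope, as is reproducing the exact
H-CBN annealing schedule; the CBN and MHN optimizers are this package's
own implementations of the published model families.

## Known limitations

* The LOD uses first-origin ancestry per genotype; under extreme clonal
  interference a later independent origin could be the true ancestor.
* Tau-leaping is approximate; leap size is not adapted to per-clone rates
  (it is small relative to all rates arising under the default
  parameters, but very large fitness values would need a smaller `tau`).
* The CBN structure search is a stochastic heuristic: with few
  annealing steps on large G it can return a locally optimal poset.
* Dense linear algebra bounds models at G ≤ 15 (2^15 states).
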