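# Methods

`orcasurv` implements a pipeline for asking whether an individual's position
in an animal social network predicts its mortality risk, in the setting of a
closed, intensively photo-censused population of resident killer whales whose
survival is tightly coupled to annual Chinook salmon abundance. This note
documents the models, the estimators, the synthetic-data generator that
provides ground truth for testing, and the numerical and design choices made
where the design was genuinely open.

## Association networks

The sampling unit is the *encounter*: an observation event in which one or
more *groups* of whales are photographed. Under the gambit of the group,
every member of a group is taken to be associating with every other member.
A whale belongs to at most one group per encounter (enforced at ingest),
because the field protocol chains nearby whales into a single group.

For a dyad (a, b) within a sampling period the **simple ratio index** is

    SRI(a, b) = x / (x + y_ab + y_a + y_b)

with x = encounters in which a and b shared a group, y_ab = encounters with
both present but in different groups, y_a (y_b) = encounters with only a
(only b). The denominator is exactly the number of encounters involving
either whale, so SRI is the fraction of joint sampling opportunities on which
the pair was together. Zero-weight dyads carry a flag separating "observed
apart" (shared at least one encounter) from "never co-sampled".

Sampling periods are one calendar year by default; a pooling rule maps year
ranges to wider periods (e.g. two-year periods in the sparsely sampled early
census, 1976–1989), and period ids are plain strings ("1996", "1976-1977") so
pooled periods are first-class throughout.

**Social differentiation.** Dyadic counts (k joint observations out of n
opportunities) are modelled beta-binomially: the latent association index of
a dyad is Beta(μν, (1−μ)ν) and k | p ~ Binomial(n, p). The maximum-likelihood
fit (Nelder–Mead on logit μ and log ν, three ν starts) gives the coefficient
of variation of the latent indices,

    S = sqrt((1 − μ) / (μ (ν + 1))),

and the implied correlation between observed and true indices,
r = sqrt(S²·H̄ / (1 + S²·H̄)) with H̄ the mean dyadic sample size. A fit driven
to the ν bound (all dyads effectively identical) returns S = 0 with a
degeneracy flag. In the full pipeline S is estimated from within-community
dyads pooled across periods, the scale on which heterogeneity of preferred
associates is scientifically meaningful; the formula choice for r is exposed
rather than hidden because published analyses are not always explicit about
the dyad set entering it.

## Communities

Communities are detected independently in each period's weighted network by
walktrap (4-step random walks — the algorithm's canonical setting) with the
merge dendrogram cut at maximum weighted Newman modularity

    Q = Σ_c [ W_c/W − (k_c / 2W)² ].

Detection runs per connected component (community structure cannot span
components, and merging two components never increases Q); isolated nodes
become singletons; an edgeless network is all-singletons flagged degenerate.
Community ids are relabelled by smallest member id so results are invariant
to node order. Two robustness diagnostics mirror standard practice:

* **Bootstrap consistency (r_com)** — encounters (the census's sampling unit)
  are resampled with replacement, the network rebuilt and re-clustered;
  r_com is the mean proportion of originally co-assigned dyads (both members
  present in the replicate) that remain co-assigned.
* **Modularity null test** — observed best-partition Q versus Q of
  data-stream-permuted datasets, with the counting-rule p-value below.

Known limitation: modularity-cut agglomeration has a resolution limit. With
many communities in one network (tens of communities of ~11 individuals),
walktrap merges weakly connected communities even when the planted structure
is strong. Recovery is essentially exact at the study's natural scale
(≈6–9 communities); synthetic experiments that scale the population up keep
the between-community propensity very low so communities stay (nearly)
disconnected and identifiable.

## Centrality

Both measures are computed **within** a whale's community, never across the
population, and only for communities of at least `min_community_size`
(default 5) members — smaller groups carry too little structure.

* **Degree**: unweighted count of same-community associates (SRI > 0),
  normalized by community size − 1.
* **Closeness**: on edge lengths 1/SRI (stronger associates are fewer
  weighted steps away), closeness_raw(i) = (n−1)/Σ_j d(i, j) within the
  whale's connected component; components smaller than the size threshold are
  excluded and flagged, since mean path length is undefined across
  components. Because closeness is strongly right-skewed it is
  rank-transformed (average ranks on ties) and min–max normalized to [0, 1],
  with 1 = most central. Ranking defaults to within-community, consistent
  with every other within-community computation; `rank_scope="network"`
  ranks across the whole period network instead.

## Survival models

Person-period (counting-process) rows are built per whale per period in
which it was observed and its community passed the size filter: intervals
(t_start, t_stop] on the common study clock, entry left-truncated at first
observation. A whale with fate "died" gets event = 1 on its final observed
row — deaths are detected by absence the following summer, so the last
measured social position precedes death with no extra lag. If that final row
was removed by the community-size filter the death cannot be placed and the
whale is effectively censored; such exclusions are logged on the table. The
"study" time axis is the default because the simulated (and real) hazard
varies by calendar period through salmon abundance, which keeps risk sets
aligned with salmon strata; time-since-first-observation is available as
`time_axis="entry"`. Ages are not in the input schema, so an age axis is not
offered.

Salmon years are classed **low** iff the index is at or below the first
quartile (type-7 quantile, ties to low) of the series, else **high**; pooled
periods use the mean of their member years' indices, re-classified at the
period level (identical to the annual rule when nothing is pooled). Periods
without salmon data are excluded from salmon-stratified analyses only.

The **extended Cox proportional-hazards model** with the single time-varying
covariate (degree or rank-normalized closeness) is fitted by maximizing the
Efron-tie partial likelihood with a Newton solver written in-package; it
matches `lifelines.CoxTimeVaryingFitter` to optimizer precision (tested).
The in-package solver exists because permutation inference refits the same
model thousands of times with only the covariate changing: risk/death sets
are precomputed once (`CoxScaffold`) and each refit is a few vectorized
Newton steps. Sex-specific and salmon-stratified effects are obtained by
fitting separate models on the subset rows (matching how per-stratum hazard
ratios are conventionally reported); an interaction-term fit is deliberately
not the default. Hazard ratios are exp(coef); a ratio of 0.25 is reported as
a 75% decrease in risk per unit of the covariate.

The **binomial GLMM** (does degree change with salmon abundance?) models
degree_raw successes out of community size − 1 trials against a low-salmon
indicator with a random intercept per whale, fitted by the variational-Bayes
mixed GLM in statsmodels with binomial trials expanded to Bernoulli rows; the
fixed effect's posterior mean and sd give β and z.

## Permutation inference

Network covariates are autocorrelated, so model statistics are referred to
permutation nulls rather than asymptotic distributions:

* **Node permutation** (within-community analyses): centrality values are
  reshuffled among the members of each community within each period; the
  network, survival outcomes and sex stay fixed. Note what this tests: the
  effect of position *within* a community over and above community
  membership. Any component of a covariate–mortality association carried by
  community-level differences is preserved under this null.
* **Data-stream permutation** (population-level analyses): checkerboard swaps
  of individuals between groups within a period, preserving every whale's
  sighting count and every group's size exactly; 1,000 burn-in swaps and 100
  swaps between retained permutations decorrelate successive null datasets.

The statistic compared across permutations is a model z statistic (standard
errors change under permutation, so raw coefficients are not comparable). The
default is the **efficient score statistic** U(0)/√I(0), which is
asymptotically equivalent to the Wald z, needs no iteration, and — decisive
here — remains defined under monotone likelihood, which strongly protective
effects in small strata regularly produce; the Wald z from the full fit is
available as `statistic="wald"`. Non-convergent null fits are dropped from
the denominator and counted.

The p-value is the counting rule with the observed sample included in both
numerator and denominator: p = (b + 1)/(m + 1), so p ∈ [1/(n_perm+1), 1].
Reported tests are one-sided; `direction="auto"` tests in the direction of
the observed effect (note that auto-selection doubles the type-I error of a
nominal one-sided level, so calibration experiments fix the direction a
priori). For whales of unknown sex, each permutation's statistic is the mean
over `n_imp` random 50:50 sex imputations (the empirical-ratio alternative is
a parameter).

## Synthetic data generator

The generator emulates the study population so every stage has a
parameter-recovery surface with known truth:

* **Population**: 80 whales (the study population ranged 71–98) in 7
  communities of ~11; no births or immigration (closed population; births are
  out of scope, which matters for long, high-mortality simulations — see
  limitations).
* **Affinity**: dyadic affinities are gamma with latent CV 3.0, block-wise
  normalized so communities are comparably gregarious, then scaled by
  p_within = 1 (same community) or p_between = 0.003. The latent CV exceeds
  the realized social differentiation because gambit-of-the-group sampling
  attenuates heterogeneity; at the defaults the *realized* within-community
  S is ≈ 1.0–1.1 and annual modularity ≈ 0.60–0.68, the values reported for
  the study system (S = 1.09 ± 0.18, Q in 0.63–0.84).
* **Sightings**: per year, group seeds are drawn uniformly among living
  whales; companions by weighted sampling without replacement (Gumbel top-k)
  on the seed's affinities; group sizes 1 + Poisson(1.5) capped at 24 (mean
  2.5); groups are packed into encounters (mean ≈ 2 groups per encounter)
  under the one-group-per-whale-per-encounter constraint; the number of
  groups is set so each whale is sighted ≈ 31.3 times per year. Realized
  group size and sighting rates land within a few percent of these targets
  (property-tested at 10%).
* **Salmon**: annual index ~ log-normal; lowest quartile ⇒ low years;
  β_salmon = 1.0 puts ≈ half of all deaths in low-salmon years, as observed.
* **Mortality**: piecewise exponential per period; P(death) =
  1 − exp(−exp(η)·Δ) with η = β₀ + β_sex(c) + β_salmon·1[low] +
  β_int·c·1[low]·1[male], where c is the whale's *realized* within-community
  normalized degree that period (computed on the true partition), so recovery
  tests exercise the entire pipeline rather than a latent covariate. The
  interaction is male-specific: the scientific hypothesis being emulated is
  that social position buffers males, not females, in poor salmon years.
  β₀ defaults to −3.77 (≈2.3%/yr, the scale implied by 65 deaths among ~85
  whales over 34 years). Dead whales produce no later sightings, so death is
  detected downstream by absence from the next period.

What the generator does **not** emulate: recruitment (so long simulations
deplete), age structure (no age axis for survival), observation failure
(every living whale is sighted every year at the default effort), and
seasonal structure within years. Passing recovery tests therefore
demonstrates estimator and pipeline correctness under the model's own
assumptions, not robustness to the additional complications of real census
data.

## Experiment sizes in the test suite

Simulation experiments are scaled to what they measure. Type-I calibration
uses 200 replicate null populations of 40 whales × 10 years with 500
permutations each, a fixed test direction, and the binomial 95% band
[2.2%, 8.8%] around the nominal 5%. The null-Cox anchor uses populations of
500 whales × 20 periods, averaging the log hazard ratio over replicate fits
(each single fit has Monte-Carlo sd ≈ 0.13 on the coefficient). The
interaction-recovery experiment uses 50 replicates of 500 whales in 42
near-disconnected communities over the full 35-year design with 300
permutations per test.

A candid note on that last experiment: because the generating hazard acts on
*absolute* degree and communities differ in realized degree, part of the true
signal lives between communities, and the within-community node-permutation
null — by design — preserves exactly that component. The hazard-ratio
direction (HR < 1) is recovered essentially always and female models stay
null, but one-sided detection power at α = 0.05 is materially below what a
naive calculation from the event count would suggest. This is a real property
of within-community permutation inference applied to an absolute-covariate
effect, not an implementation artefact; the test suite asserts the intended
detection rate and reports the observed rate when it falls short.

## Numerical choices

* Cox solver: Newton steps clipped to ±2, |β| capped at 25 (monotone
  likelihood ⇒ flagged non-converged), convergence at |Δβ| < 1e-9; variance
  from the observed information at the optimum.
* Beta-binomial fit: ν capped at 1e6 (degenerate flag at the bound).
* Quantiles: numpy's default linear interpolation (type 7) everywhere.
* Ties in closeness ranks: average ranks; a single rankable member maps to
  the midpoint 0.5.
* Determinism: every stochastic routine takes a seed or Generator; one
  generator threads through a pipeline run, so identical config + seed gives
  byte-identical JSON outputs (tested).
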