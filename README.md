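# orcasurv

Does a whale's position in its social network predict its risk of dying?
`orcasurv` is a Python package for answering that question in populations
censused by grouped sightings — built around the resident (fish-eating)
killer whale system, where a closed population of ~71–98 individuals has been
photo-identified every summer since 1976 and mortality is strongly tied to
annual Chinook salmon abundance. It is aimed at behavioural ecologists and
biostatisticians who have (or can simulate) grouped-sighting records and want
the full inferential chain, not just a network metric.

The pipeline:

1. **Association networks** — per sampling period, the simple ratio index
   SRI = x / (x + y_ab + y_a + y_b) from gambit-of-the-group sightings,
   where x counts encounters with the dyad in the same group, y_ab both
   present in different groups, and y_a, y_b one present without the other.
   Two-year pooling of sparse early census years is first-class. A
   beta-binomial likelihood estimates social differentiation S (the CV of the
   latent association indices) and the observed–true index correlation r.
2. **Communities** — weighted random-walk (walktrap) clustering per period,
   cut at maximum modularity Q = Σ_c [W_c/W − (k_c/2W)²], with bootstrap
   co-assignment consistency (r_com) and a data-stream-permutation
   modularity null test.
3. **Centrality** — within-community normalized degree (direct) and
   rank-normalized closeness on edge lengths 1/SRI (indirect), computed only
   in communities of ≥ 5 whales.
4. **Survival** — counting-process person-period tables (left truncation at
   first observation; death = absence from the next summer) and extended Cox
   proportional-hazards fits of the time-varying centrality covariate, by sex
   and by low/high salmon stratum (lowest quartile of the salmon index =
   low). Hazard ratios are exp(coef): 0.25 means a 75% decrease in risk per
   unit of covariate. A binomial GLMM (whale as random intercept) asks
   whether degree itself shifts with salmon abundance.
5. **Permutation inference** — within-community node permutations and
   group/individual checkerboard (data-stream) permutations generate nulls
   for every model statistic; p = (b + 1)/(m + 1) with the observed sample
   counted; unknown-sex whales are averaged over random sex imputations.
6. **Synthetic data** — a generator that emulates the study population
   (group size 2.5, ~31 sightings/whale/year, ~7 communities of ~11, realized
   S ≈ 1.09, piecewise-exponential mortality concentrated in low-salmon
   years) with full ground truth, so every stage has parameter-recovery
   tests.

## Worked example

```python
import numpy as np
import orcasurv as o

# a synthetic 80-whale population in which male (not female) degree is
# protective: hazard ratio 0.25 per unit of within-community degree
cfg = o.SyntheticConfig(
    n_individuals=80, n_communities=7,
    years=tuple(range(1991, 2011)), pooling=((1991, 2010, 1),),
    hazard=o.HazardParams(beta0=-3.2, beta_salmon=1.0,
                          beta_centrality_male=np.log(0.25)),
    p_sex_unknown=0.0,
    seed=4,
)
model = o.SocialSurvivalModel.from_synthetic(cfg)
results = model.fit(covariates=("degree_norm",), n_perm=500, seed=1)
print(results.summary().round(3).to_string(index=False))
```

prints

```
  covariate sex salmon   coef  hazard_ratio    se      z  n_events  n_rows  p_perm direction
degree_norm   M    all -2.219         0.109 1.067 -2.081        15     582   0.032        le
degree_norm   M    low  0.931         2.538 2.369  0.393         6     154   0.667        ge
degree_norm   M   high -3.850         0.021 1.402 -2.747         9     428   0.024        le
degree_norm   F    all  1.326         3.766 1.063  1.247        30     450   0.144        ge
degree_norm   F    low  1.790         5.992 1.653  1.083        13     136   0.168        ge
degree_norm   F   high  0.970         2.637 1.393  0.696        17     314   0.214        ge
```

Each row is one Cox model: socially integrated males have roughly a tenth
the mortality risk of peripheral males per unit of normalized degree
(hazard_ratio 0.109, i.e. an ~89% decrease per unit), and the
node-permutation test rejects the null (p_perm = 0.032 over 500
permutations), while every female model is consistent with no effect —
exactly the sex-specific structure this dataset was generated with. The
low-salmon male fit illustrates small-stratum noise: only 6 events. Network
diagnostics ride along:

```python
q = results.modularity_by_period       # 0.44–0.68 across the 20 periods
results.differentiation.S              # 1.04 — strong dyadic heterogeneity
results.save("out/")                   # GraphML + CSV per period, results.json
```

The same analysis runs from CSV files
(`SocialSurvivalModel.from_csv("encounters.csv", "individuals.csv",
"salmon.csv")`) or from the shell:

```bash
orcasurv simulate --config synth.yaml --outdir data/
orcasurv networks --encounters data/encounters.csv --individuals data/individuals.csv --outdir nets/
orcasurv survival --encounters ... --individuals ... --salmon ... --covariate degree --sex M
orcasurv permtest --model cox --covariate degree --sex M --n-perm 10000
orcasurv all --config pipeline.yaml
```

See `docs/methods.md` for the statistical details, generator assumptions and
known limitations.

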