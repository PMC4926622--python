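# betascape

Species richness, compositional turnover and distance decay of assemblage
similarity across territorial faunal inventories.

Macroecologists working with country-level checklists (insects especially)
face a recurring analysis stack: regress richness on area, climate and
position; measure pairwise compositional turnover with an index that is not
fooled by richness differences; ask whether turnover is structured by
environment or by space; and test whether similarity decays faster with
distance in historically stable (southern, refugial) regions than in
recently recolonised (northern) ones. `betascape` packages that stack as
tested, reusable code, together with a synthetic-landscape generator that
plants every pattern the analyses are meant to find — so the whole pipeline
is testable end to end without any data download.

## The statistics at the core

**Turnover.** For two sites with `a` shared species and `b`, `c` species
unique to each, the Simpson turnover dissimilarity is

```
beta_sim = min(b, c) / (a + min(b, c))
```

with the Sørensen family alongside: `beta_sor = (b + c)/(2a + b + c)` and
the nestedness-resultant component `beta_sne = beta_sor − beta_sim`.
`beta_sim` is blind to nested richness differences: a fauna strictly
contained in another scores 0.

**Ordination.** Constrained analysis of principal coordinates (CAP, also
called db-RDA): embed the `beta_sim` matrix by principal coordinates,
regress the axes on predictors, and report constrained inertia as a share
of the total, with significance from permutation of the pseudo-F statistic.
Spatial predictors are the nine terms of a third-degree trend surface in
mean longitude and latitude; predictors enter in order of their marginal
contribution and are retained while significant (at most four).

**Variance partitioning.** The seven models over predictor sets A (log
area), E (environment) and S (space) — A, E, S, A+E, A+S, E+S, A+E+S — are
fitted and their R² (or constrained inertia) decomposed by
inclusion–exclusion into unique and shared fractions.

**Distance decay.** Pairwise similarity `1 − beta_sim` is fitted as
`y = a·exp(−b·x)` over great-circle centroid distances, separately for
sites above and at-or-below 48° mean latitude; the two rates are compared
through a site-level bootstrap (1000 replicates), reporting the empirical
probability that the observed slope ordering reverses.

## Worked example

```
$ python analysis/01_simulate.py --seed 11
36 units x 300 taxa (120 endemics in 3 refugia)
richness: south mean 87.2, north mean 73.6, corr with latitude -0.67
planted decay rates: south 6.02e-04/km, north 6.93e-05/km

$ python analysis/03_composition.py --seed 11
model_S: ['Long*Lat', 'Lat', 'Long^2*Lat', 'Lat^3'] -> 55.9% (pseudo-F 9.81, p 0.001)
unique(S) 51.2%  unique(E) 2.8%  shared E&S 2.5%
UPGMA cut at k=4 -> 4 groups; dendrogram in results/dendrogram.nwk

$ python analysis/04_decay.py --seed 11
north: slope -7.03e-05/km, a 0.98, r2 0.30, p 0.005 (253 pairs)
south: slope -5.15e-04/km, a 1.00, r2 0.48, p 0.005 (78 pairs)
steeper decay: south (p_diff 0.000999, 1000 bootstrap replicates)
```

Reading the output: richness falls northward (r = −0.67); the trend-surface
model explains 55.9% of compositional variation and almost all of it is
spatial rather than environmental (unique fractions 51.2% vs 2.8%); the
four-group UPGMA cut recovers the three planted refugial faunas plus the
homogeneous generalist pool; and similarity decays roughly seven times
faster among southern units (−5.2e-4 per km vs −7.0e-5), with the
bootstrap putting the probability of a reversed ordering at ~0.001. These
are the four signatures the generator plants, recovered by the pipeline.

The same pipeline runs on real data from two CSVs (a binary site × species
table and a per-site predictor table):

```
betascape all --occurrences occ.csv --sites sites.csv --seed 1 --out results/
```

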