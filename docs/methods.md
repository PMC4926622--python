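# Methods

This note documents the models and numerical choices behind `betascape`:
what each stage computes, what the synthetic-landscape generator does and
does not emulate, and where genuinely open design questions were settled.

## 1. Turnover indices

All pairwise indices are computed from the matching components of a site
pair — `a` shared species, `b`/`c` species unique to either site:

* Simpson turnover `beta_sim = min(b,c) / (a + min(b,c))`
* Sørensen `beta_sor = (b+c) / (2a + b + c)`
* nestedness-resultant `beta_sne = beta_sor − beta_sim`

Counts are exact integers and each index is formed as a rational number
before the final float conversion, so the additive partition
`beta_sor = beta_sim + beta_sne` holds to float rounding (tested at 1e-12).
A pair of two empty assemblages is an error, not a zero: the index is
undefined there, and silent zeros would corrupt downstream decay fits.
Empty sites are therefore rejected at load time (an override drops them
with a warning).

## 2. Richness models

Each predictor is screened with OLS polynomial fits of degree 1–3 (area as
its natural log). The reported "function" is the highest degree whose
top-order coefficient is significant at `alpha = 0.05`; if none qualifies
the linear fit is reported as "ns". This rule is deterministic and
reproduces the familiar "linear (−)" / "quadratic (+,−)" table layout; its
cost is mild selection inflation of the per-variable type-I rate (empirically
~8–12% rather than 5% at n = 36 — the test suite asserts it stays below
20%). Set models are pruned by backward stepwise elimination at
`alpha_stay = 0.05`, never dropping a term whose higher-degree sibling is
still in the model; ties drop the higher degree first, then break
lexicographically. Reported variance is unadjusted R² × 100 (adjusted R²
emitted alongside).

Variance partitioning fits the seven set-combination models A, E, S, A+E,
A+S, E+S, A+E+S and solves the 7×7 inclusion–exclusion system for the
disjoint fractions (unique A/E/S, three pairwise shared, one triple
shared), with `residual = 100 − R²(A+E+S)`. Fractions are exact linear
combinations of the seven R² values; shared fractions may legitimately be
negative. The same solve is reused for compositional partitioning on
constrained inertia.

## 3. Constrained ordination

`gower_pcoa` double-centres `−d²/2` and eigendecomposes; axes are scaled by
the square root of their eigenvalues. `beta_sim` is non-Euclidean, so some
eigenvalues are negative: the default policy discards those axes and
records the discarded share of total absolute inertia (typically a few
percent here); a Lingoes correction is available by flag. CAP regresses
the retained axes on predictors; constrained inertia is the sum of squares
of the fitted values,

    pseudo-F = (constrained/q) / (residual/(n − q − 1)),

and significance comes from freely permuting site identities (rows of the
embedding, equivalently simultaneous row/column permutation of the
dissimilarity matrix), `p = (hits + 1)/(n_perm + 1)` with `n_perm = 999` by
default (499 in the faster pipeline presets). For n ≤ ~7 an exhaustive mode
enumerates all n! orders and needs no seed. Per-term p-values are
sequential: terms enter in the given order and each term's extra inertia is
scaled by the full-model residual.

Model selection ranks candidates by marginal contribution (drop in
constrained inertia when the term is removed from the full model, ties
broken by name), then admits terms in that order while the sequential
permutation p stays below `alpha`, capped at `max_terms = 4` so competing
predictor sets stay comparable in size. Spatial candidates are the nine
trend-surface terms {Long, Long², Long³, Lat, Lat², Lat³, Long·Lat,
Long²·Lat, Long·Lat²} of mean-centred coordinates; centring changes the
individual columns but not the span, hence not the fitted inertia of the
full set (tested).

UPGMA clustering is average-linkage agglomeration (scipy linkage behind
the module surface); merge heights equal mean between-group dissimilarity
and are monotone. The dendrogram is exported as an ultrametric Newick
string with node depths at half the merge height.

## 4. Distance decay

Similarity `1 − beta_sim` is modelled as `y = a·exp(−b·x)` over
great-circle (haversine, R = 6371 km) centroid distances. A projected
planar distance would differ by far less than the slope's confidence width
at intra-continental scales; an equirectangular option exists for
comparison. Internally `b ≥ 0`; reports print the signed slope `−b`.

The fit is profiled least squares: for fixed `b` the optimal intercept is
`a(b) = Σ y·e^{−bx} / Σ e^{−2bx}`, clipped to (0, 1], leaving a bounded 1-D
minimisation over `b ∈ [0, 0.05]` (coarse log-spaced bracketing, then
Brent/golden-section refinement; the flat solution `b = 0` is kept when it
wins). This is deterministic and cannot fail to converge, which matters
inside the bootstrap; a grid-search oracle in the tests confirms it reaches
the least-squares optimum, and noiseless data are recovered to 1e-6.
Zero similarities participate in the fit. Fit significance uses matrix
permutation (shuffle site identities, refit, compare r²) rather than
parametric errors, since pairs sharing a site are dependent.

Bootstrap: sites are resampled with replacement (pairs are not
independent; pair-level resampling is available by flag), pairs among
distinct draws are refitted per replicate with self-pairs masked out,
1000 replicates by default, vectorised across replicates. The
slope-difference probability `p_diff` is the add-one proportion of
index-paired replicates whose ordering reverses the observed one; ~0.5
means indistinguishable rates.

**Calibration of the reversal test.** `p_diff` is an overlap probability,
not a classical p-value: if the bootstrap spread matches the sampling
spread exactly (ratio r = 1), rejection at 0.05 occurs in ~10% of
equal-rate datasets, and a strongly over-dispersed bootstrap (r ≈ 2, which
is what site resampling produces when noise is actually independent per
pair) never rejects. The site bootstrap is built for site-exchangeable
noise — each unit's checklist error propagates to all its pairs — and
under that structure its small-sample over-dispersion (r ≈ 1.3 at n ≈ 18)
puts the empirical size at ~4%, close to nominal. The acceptance suite
therefore generates equal-rate null data (and the power check at rates
5e-4 vs 1e-4 per km) with site effects plus pair noise (sd 0.025 each);
power at those magnitudes is ~100%.

## 5. The synthetic landscape

The generator plants four patterns — a negative latitudinal richness
gradient, singular southern faunal clusters, spatially (not
environmentally) structured turnover, and steeper southern distance decay —
with mechanisms chosen so that a *turnover-only* index can actually see
them:

* **Landscape.** n = 36 units scattered uniformly over 36–70°N, −10–60°E;
  lognormal areas with coordinate ranges growing as √area; annual
  temperature `T(lat36) + lapse·(Lat−36) + noise` with lapse −0.55 °C/deg;
  correlated T_max/T_min; precipitation fields independent of latitude.
* **Occupancy.** Suitability is a product of a Gaussian thermal niche and
  a *soft range disc* (logistic plateau of per-species radius, edge 100 km),
  then sharpened (`k^s/(k^s + (1−k)^s)`, s = 2.5) before a single Bernoulli
  draw. A territorial checklist is a range map: a clearly suitable unit
  holds the species almost surely. Without sharpening, mid-range
  probabilities make Bernoulli noise the dominant "turnover" everywhere and
  no planted structure survives. A smoothly decaying (exponential) spatial
  kernel fails for the same reason: its wide transition zone keeps most
  cells in the noisy middle. Mixing many disc radii and centres still
  yields a smooth, roughly exponential similarity decay.
* **Refugia and endemics.** Three refugia are anchored on actual southern
  units (farthest-point selection, so they spread out). An endemic's range
  *is* its refugium's footprint (radius 2× the 500 km refugium scale), and
  endemics never cross the 48° recolonisation latitude. Planted cluster
  labels are footprint membership; southern units outside every footprint
  belong to the generalist pool, label 0.
* **Refugial exclusion.** Each refugium shuts a random 65% of generalists
  out of its footprint: saturated old faunas resist recolonisation. This
  makes refugial faunas *substitutive* rather than additive — essential,
  because a fauna that merely adds endemics to the ubiquitous pool is
  nested, and `beta_sim` scores nested pairs as identical.
* **Northern attrition.** Generalists carry per-species northern range
  limits (uniform over ~40–82°): species drop out northward in a
  consistent order, so richness declines with latitude while northern
  assemblages remain nested and hence alike under `beta_sim`. This is how
  a richness gradient and a homogeneous north coexist.
* **Planted decay rates.** Recorded in the truth object as the exponential
  rates fitted to the noise-free plug-in similarity surface computed from
  the occupancy probabilities (expected matching components
  `a = Σ p_i p_j` etc.), separately for the southern and northern groups.
  Recovery from one Bernoulli realisation is then a well-posed sampling
  question; the median relative error across seeds is ~16%.

At the default configuration (100 seeds): richness–latitude correlation is
negative in 100, UPGMA at k = 4 recovers the planted labels with ARI ≥ 0.8
in 94, the southern fitted rate exceeds the northern in all, and typical
rates are ~5e-4 vs ~0.5–1e-4 per km with southern r² ≈ 0.5–0.6 and
northern r² ≈ 0.2.

What the generator does **not** emulate: realistic climate surfaces or
spatially autocorrelated precipitation; detection/observation error
(inventories are complete by assumption); phylogenetic structure;
abundances; island effects. Passing tests therefore demonstrate that the
pipeline recovers planted structure of this kind at checklist scale — not
that any particular empirical dataset satisfies the model.

## 6. Reproducibility and problem sizes

Every stochastic operation takes a mandatory seed; a single run seed fans
out to fixed per-stage offsets, and rerunning any stage in isolation
reproduces its numbers bit for bit. All randomised p-values are reported
with their permutation or bootstrap counts. The test suite uses reduced
problem sizes where a property is already decisive at small n (e.g. 60–100
replicate datasets for selection behaviour, 300 bootstrap replicates inside
the power/size simulations, 499 permutations in the end-to-end run);
full-size settings (999 permutations, 1000 replicates) are the library
defaults and are used by `scripts/acceptance.py`.

## 7. Known limitations

* The reversal-probability slope test is approximately, not exactly,
  calibrated; its size depends on the ratio of bootstrap to sampling
  spread (section 4). For strict error control a centred bootstrap
  difference test would be needed, but the overlap probability is the
  procedure this pipeline deliberately mirrors.
* R²-based partitioning can return small negative shared fractions; they
  are reported as computed.
* The stepwise and screen rules are significance-driven (no information
  criteria), inherit the usual selection-inference caveats, and are meant
  for the descriptive table layout they produce.
* CAP here regresses unweighted PCoA axes; negative-eigenvalue axes are
  discarded by default, so a small share of total turnover is invisible to
  the constrained models unless the Lingoes flag is set.
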