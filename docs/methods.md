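# Methods

This note documents the models, rules and numerical choices implemented in
`chromascape`, and what the synthetic-data generators do and do not emulate.

## The analysis in brief

Breeding-bird communities are summarised, per survey site, by the colour
make-up of the species present. Each species carries a fixed plumage
profile: a percentage breakdown over the ten most common bird colours
(black, blue, brown, green, grey, purple, red, rufous, white, yellow),
conventionally scored from male specimens. Light and dark variants of grey
and brown, where present in a source table, are summed into single grey and
brown classes before use. Site-level community colour percentages are

    colour_k% = (sum of colour_k over present species) * 100
                / (sum of all colours over present species),

which, because each species profile sums to 100, equals the unweighted mean
of the present species' profiles (presence/absence only; no abundance
weighting). *Colour inequality* is the Gini coefficient of the ten
community percentages: 0 when every colour is equally represented, 1 when a
single colour dominates.

The environmental side characterises each site by the land-use mosaic
inside a 200 m radius buffer (planar metric coordinates assumed): per-class
area percentages, a dominant-habitat label, *land use richness* (LUR, the
number of distinct classes present) and *weighted edge density* (WEDGE, the
summed perimeter of all patch polygons multiplied by LUR). Community
evolutionary structure is summarised by *phylogenetic species variability*
(PSV) computed on a maximum clade credibility (MCC) tree selected from a
sample of phylogenies. The association stage screens each response for
spatial autocorrelation with Mantel permutation tests, fits a
gaussian-identity GLM per colour (and for Gini) on habitat, LUR, WEDGE,
species richness, longitude and latitude (plus PSV for Gini), refits the
Gini model as a linear mixed model with a habitat random intercept, and
condenses everything into a sign table of significant associations.

## Habitat classification ruleset

The label is decided by ordered threshold rules on buffer percentages:

1. If coniferous + deciduous forest >= 60%: *deciduous forest* when
   deciduous >= 40% and coniferous <= 20%; *coniferous forest* when
   coniferous >= 40% and deciduous <= 20%; otherwise *mixed*.
2. Else, any single non-forest class >= 60% gives that class (at most one
   class can reach 60%).
3. Else, *urban* when urban >= 30% and every other class <= 60%.
4. Else *mixed*.

Three decisions here were genuinely open and are our own:

* **Threshold convention.** Descriptions of such rulesets mix ">60%" and
  "at least 60%"; we use >= 60% everywhere so the mixed-habitat rule ("none
  of the land use types occupied at least 60%") is the exact complement of
  the dominance rule.
* **Precedence.** Forest-union subdivision is evaluated first, then
  single-class dominance, then the urban rule; without an explicit order
  the rules are ambiguous for compositions satisfying several of them.
* **Forest union >= 60% with neither subtype criterion met** (e.g.
  35/30 splits) is classified *mixed*.

The classifier is total (exactly one rule fires for every valid
composition) and is tested for equivalence against an independently coded
brute-force oracle on an exhaustive 5%-step simplex grid over the five
classes the rules discriminate (deciduous, coniferous, urban, plus two
non-forest fillers; 10,626 compositions) and on randomized full 10-class
compositions.

## Buffer geometry

Percentages are normalized by **covered patch area**, not nominal disc
area, so rasterization slivers cannot break the sum-to-100 invariant.
`perimeter_sum` adds each patch polygon's own perimeter; a boundary shared
by two patches is therefore counted once per polygon (twice overall), and
the buffer's outer arc is included. This follows the literal "sum of the
perimeters of all polygons" definition; whether one should instead count
shared edges once, or exclude the clipping circle, is a genuine ambiguity
of that definition — the choice only rescales WEDGE and cannot change
sign-based conclusions. All geometry is planar (no geodesics).

## Gini coefficient

G = Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄), computed with the sorted-rank identity. By
default the small-sample correction n/(n−1) is applied, matching the
default of the widely used R implementation of this statistic, so that
full concentration on one of the ten colours yields exactly 1.0 (the
uncorrected value is 0.9). A flag disables the correction. Gini is
scale-invariant and lies in [0, 1].

## MCC tree and PSV

The MCC tree is **selected** from the input sample, never constructed: each
tree is scored by the product over its internal rooted clades of that
clade's frequency in the sample, and the highest-scoring tree wins. Scores
are compared in exact integer arithmetic (products of integer clade counts,
cross-multiplied), because distinct topologies can have mathematically
*equal* scores — floating-point log-sums and products then disagree about
which is larger, breaking the deterministic first-index tie rule. Ties
break to the lowest index. The selection agrees with
`phangorn::maxCladeCred` on cross-checked fixtures.

The phylogenetic correlation matrix is C_ij = depth(MRCA(i,j)) /
√(depth(i)·depth(j)) with unit diagonal; for an ultrametric tree this is
the standard Brownian-motion trait correlation and lies in [0, 1]. PSV of
a community of n >= 2 species is (n·tr(C) − ΣC)/(n(n−1)) on the community
submatrix — the mean pairwise distinctness 1 − C_ij. Values match
`picante::psv` on cross-checked fixtures. Species absent from the tree
raise an error by default; an opt-in prune mode drops them with a warning,
because silent dropping biases PSV. PSV is computed from the MCC tree as
returned (no re-dating or median heights).

One property worth flagging: duplicating a community member (adding a
species perfectly correlated with it) moves PSV from S/(n(n−1)) to
(S + 2·S_a)/((n+1)n), where S is the summed pairwise distinctness and S_a
the duplicated member's share. This *decreases* PSV when members are
exchangeable, but *increases* it when a lone distant member is duplicated
(S_a > S/(n−1)); intuition that duplication always lowers variability is
wrong, and the test suite asserts the exact closed form instead.

## Mantel screening

r is the Pearson correlation of the off-diagonal entries of the
variable-distance and geographic-distance matrices; the p-value is
one-sided (greater), Monte-Carlo: (1 + #{permuted r >= observed}) /
(n_perm + 1) under simultaneous row/column permutation of one matrix, with
999 permutations by default. The one-sided form matches common Monte-Carlo
practice for autocorrelation screening. Type-I calibration at α = 0.05 is
verified by simulation (500 null replicates, n = 30, 199 permutations).

## GLM, GLMM and the sign table

Responses are smooth percentages (or Gini in [0,1]); the default family is
gaussian-identity, with an optional logit-transform family
(`gaussian_logit`) for users who prefer a bounded-response link — the
reported sign table is robust to this choice. Habitat enters
treatment-coded; the default reference level is the most frequent observed
label (signs of habitat contrasts are reference-dependent, so the
reference is echoed in every result and run summary). The gaussian GLM
equals the OLS closed form, which the tests assert to 1e-8 relative. Rank
deficiency is detected on unit-normalized columns and reported with the
offending column names. No multiple-testing correction is applied across
the ten colour models (an optional Benjamini–Hochberg flag would be a
user-side addition; the primary output is sign-based).

The mixed model (Gini ~ LUR + WEDGE + richness + PSV + lon + lat, habitat
random intercept) is fit by REML via an established mixed-model solver.
For numerical stability the fixed predictors are z-scored internally and
estimates/SEs mapped back to the original scale (p-values and variance
components are invariant). Pseudo-R² follows the fixed/random variance
decomposition:

    marginal    = σ²_fixed / (σ²_fixed + σ²_group + σ²_resid)
    conditional = (σ²_fixed + σ²_group) / (σ²_fixed + σ²_group + σ²_resid)

with σ²_fixed the population variance of the fixed-effect linear
predictor. When the planted group variance is zero the estimated group
component collapses and marginal ≈ conditional, which the tests assert.

The sign table holds "+" or "−" where p < α (default 0.05) and blank
otherwise, rows ordered habitat contrasts first, then LUR, WEDGE,
richness, PSV, latitude, longitude.

## Synthetic-data generators

All randomness flows from one scenario seed through independent named
substreams, so each generator is a pure function of its seed and the
pipeline is reproducible byte-for-byte.

* **Colour table.** Species profiles are Dirichlet draws (×100) with
  concentration α = c·m/100, where m is the default mean colour-share
  vector (grey 39.2%, white 20.2%, black 17.2%, brown 13.5%, yellow 5.7%,
  rufous 2.0%, blue 1.2%, green 0.54%, red 0.37%, purple 0.12% — the
  community-level averages typical of a national breeding-bird survey) and
  c = 5 balances realistic between-species variation against degenerate
  single-colour profiles. Both m and c are configurable.
* **Phylogenies.** Ultrametric Yule (pure-birth) trees, birth rate 1;
  tree sets mix a few topologies with lognormal branch-length jitter
  (σ = 0.1) so MCC selection has real work to do.
* **Landscapes.** Each 200 m buffer disc is tiled with 25 m square cells
  clipped to the disc; cells are assigned classes by area quotas drawn for
  the site's true habitat label, and contiguous same-class cells are merged
  into patches. Quota recipes keep dominant shares 5–15 points clear of the
  rule thresholds so the true label is recoverable by the classifier with
  probability ≈ 1 (≥ 0.9 required), while filler-class counts and shares
  vary so that LUR is not a deterministic function of habitat (it must not
  be collinear with the habitat factor in the models). Sites are laid out
  on a 1 km grid in a synthetic planar CRS.
* **Communities.** Logistic habitat-affinity occupancy: each species draws
  one affinity habitat from the habitat mix; P(presence) =
  expit(b + a·match), with a the affinity strength (default 1.5) and b
  calibrated by root-finding so expected mean richness hits the target
  (default 17.7 species/site, a typical survey mean). Sites are resampled
  until they hold ≥ 2 species so PSV and Gini are defined. Presence only —
  no abundances, matching the presence/absence design of such surveys.
* **Direct inequality scenario.** For coefficient-recovery checks the site
  table is generated directly: LUR ~ 1+Binomial(9, 0.4), WEDGE ~
  Gamma(3, 1500) m, richness ~ 2+Poisson(15), PSV ~ Beta(10, 5),
  lon ~ U(6.6, 18.5), lat ~ U(36.6, 47.1) (degrees, roughly a
  Mediterranean peninsula's extent); gini = intercept + Σβ·x + habitat
  random offset (SD `group_sd`, default 0) + N(0, noise_sd = 0.05).
  Default planted signs are LUR −0.010, richness −0.005, WEDGE +2·10⁻⁵,
  PSV +0.20, lon/lat 0 — the qualitative pattern expected where
  configurational heterogeneity raises colour inequality and compositional
  heterogeneity and richness lower it.

### What the generators do not emulate

Real geography (the synthetic CRS is an abstract plane), real species
identities or taxon sampling, abundance structure, detection error,
spatially autocorrelated landscapes (sites are independent), and
phylogenetic signal in colour profiles (colours are drawn independently of
the tree). Passing tests therefore demonstrate the correctness and
calibration of the *estimators and rules*, not ecological conclusions
about any real avifauna.

## Problem sizes and numerics

The demo configuration is 500 sites × 80 species with 999 Mantel
permutations, chosen as a desk-scale stand-in for a national survey
(thousands of sites); it completes in well under five minutes on one CPU.
Simulation-based checks use n = 2000 sites × 200 seeds for sign recovery,
500 null replicates for Mantel calibration, and 10,000 random communities
for composition conservation. Geometric assertions use a 1% tolerance
against ideal-disc formulas (polygonization error at quad_segs = 64–256 is
far below that). Colour profiles are renormalized on ingest when they do
not sum to 100 (with a logged warning); the all-zero profile, empty
communities, single-species PSV, single-group mixed models and overlapping
patches are rejected with typed errors rather than silently handled.

## Known limitations

* The MCC scorer enumerates rooted clades per tree (O(n²) labels); fine
  for hundreds of tips, not for 10⁵.
* The Mantel permutation loop materialises one permuted matrix per
  iteration; with thousands of sites consider fewer permutations or a
  site subsample.
* `MixedLM` may warn about boundary estimates when the true group variance
  is zero; estimates remain valid (the variance component is clamped
  at 0).
* The per-colour GLMs assume homoscedastic gaussian errors on percentage
  responses; percentages near the 0/100 boundary (rare colours at tiny
  richness) mildly violate this, which is why the logit family is offered.
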