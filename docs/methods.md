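# Methods

This note records the models, conventions and numerical choices behind
each analysis stage, in the order the pipeline runs them.

## Diet composition

All indices are computed per consumer species over its fecal samples.
For item *i* with count c_is and volume v_is in sample *s* (sample
totals C_s, V_s, S samples overall):

* FO% = 100 · |{s : c_is > 0}| / S
* PN% = mean of 100·c_is/C_s over the samples **containing** *i*;
  N% = the same mean taken over **all** samples (absences contribute 0);
  PV%, V% analogously with volumes.
* PSIRI% = (PN% + PV%)·FO%/2/100.

With sample-averaged N% and V% (the convention of the index's source,
which we follow), the identities FO%·PN%/100 = N%, PSIRI% = (N%+V%)/2
and ΣPSIRI% = 100 hold exactly and are asserted in the test suite.  The
raw pooled totals N and V are reported alongside as columns.  Samples
whose total volume is zero (items counted but not volumetrically
quantifiable) are excluded from the volumetric averages only; when such
samples exist the volumetric identities hold within the reduced sample
set.  Duplicate (sample, taxon) rows are pooled before averaging.

Guild classification pools per-taxon volumes into broad guilds
(default: both fruit categories → fruit, the five arthropod guilds →
insect) and applies the >35% predominant / 10–35% secondary rule to the
species' share of **total pooled volume**; if no guild exceeds 35% the
species is reported as indeterminate rather than an error.

## Niche breadth and overlap

Levins' B and Pianka's O operate on a proportion vector per species.
The default basis is PSIRI%/100 per taxon — the headline composition
index, which sums to one by construction — switchable to N% or V% via
`AnalysisConfig.proportion_basis` for sensitivity analysis, because the
choice of basis is a genuine degree of freedom in fecal-diet studies.
Vectors are aligned on the union of the two species' item lists with
absences as zeros.  B̂_A is undefined (NaN) for single-item diets.

## Bayesian mixing model

The likelihood is the classic source-mixture model with TDF-shifted
source means and variances added in quadrature:

x_ij ~ N( Σ_k p_k(μ_jk+λ_jk), Σ_k p_k²(ω_jk²+τ_jk²) + σ_j² ).

Modelling choices, made where the published workflow is silent:

* prior p ~ Dirichlet(1,…,1); σ_j ~ half-Normal(0, 5 ‰) — weakly
  informative on the per-mil scale of blood isotope data;
* consumers are modelled per species, no individual random effects;
* the element set is {δ¹³C, δ¹⁵N} by default but the code is written
  for J elements.

Sampling: random-walk Metropolis on additive-log-ratio coordinates
z (K−1 of them) plus log σ_j, with the ALR Jacobian Σ_k log p_k so the
prior on p is exactly Dirichlet.  The proposal is adapted during
burn-in only: step sizes tune toward a 23% acceptance rate, and the
proposal covariance is re-estimated from the accumulated burn-in
history at ¼, ½ and ¾ of burn-in (adaptive Metropolis), then frozen, so
every retained draw comes from a fixed kernel.  Defaults: 4 chains ×
20,000 iterations, 50% burn-in, thinning 10 (4,000 retained draws);
interval summaries refuse to run on fewer than 1,000 draws.

Convergence is monitored by split-R̂ per source proportion across
chains; values above 1.1 produce a warning and a `converged=False`
flag, but results are still returned.  With 7 sources and 2 elements
the model is under-determined: the likelihood constrains two linear
combinations of p and the remaining simplex directions are prior-flat,
which is precisely where the walker mixes slowest and where flags
appear.  Parameter-recovery experiments at the default scale (n = 50
consumers) nevertheless show 93–95% coverage of true proportions by the
95% credible intervals, as expected when data are generated from the
model's own prior and likelihood.

A consequence worth knowing: in the under-determined geometry the
posterior mean is prior-dominated along unidentified directions, so
shrinking source SDs improves the posterior mean only mildly there; the
effect is clearly visible in identifiable configurations (e.g. three
well-separated sources), which is where the test suite measures it.

Credible-interval tables report lower, upper, midpoint and posterior
mean per source.  Midpoints need not sum to one across sources — each is
a marginal summary of a joint simplex posterior — and a sanity band of
[0.5, 1.5] on their sum is asserted in tests.

## Isotopic niches (SEAc)

SEA = π√det(Σ̂) with the ddof=1 sample covariance of the (δ¹³C, δ¹⁵N)
cloud; SEAc = SEA·(n−1)/(n−2).  The ellipse boundary is the 1-SD
standard ellipse (axes from the covariance eigendecomposition) scaled
radially by √((n−1)/(n−2)) so its area equals SEAc.  Overlap areas are
computed by shapely polygon intersection of boundaries sampled at 1,024
vertices — the inscribed-polygon area error is O(n⁻²), well below the
0.5% oracle tolerance checked against the closed-form circle-lens
formula.  The overlap percentage divides by the union of the two areas
(symmetric, Jaccard-style) by default; dividing by the smaller ellipse
is available via `AnalysisConfig.overlap_denominator` since published
"percentage of overlap" values rarely state their denominator.
Collinear point clouds (det ≤ 1e−12) raise a degenerate-niche error.
Bootstrap standardisation resamples individuals with replacement to a
common n (default 50) with a per-species deterministic stream.

## Bipartite networks

**Construction.**  The diet network's cells are PSIRI% values summed
into resource categories (rows therefore sum to 100); the isotope
network's cells are 95%-CI midpoints, (lower+upper)/2, with posterior
means available as a switch because "mean of the credible interval" is
ambiguous in the literature.  Zero-midpoint cells are structural zeros.
In the bundled reference table, midpoints are computed from the printed
2-decimal bounds and rounded to 3 decimals so that equal printed values
compare equal — raw IEEE midpoints of equal decimals can differ in the
last bit and would spuriously break comparison ties.

**WNODF.**  Rows and columns are ordered by decreasing fill with ties
broken by decreasing weighted marginals, matching the widely used
reference implementation (verified against vegan's weighted
`nestednodf` to 10 decimal places on random matrices).  For an ordered
pair (upper u, lower v), the pair scores 0 unless fill(u) > fill(v),
else 100 × (cells of v that are positive and strictly smaller than u's
corresponding cells) / fill(v); WNODF is the mean over all row and
column pairs.  Note that a completely filled weighted matrix scores 0
by the decreasing-fill rule — empirical matrices earn nonzero
nestedness through structural zeros.

**d′.**  With p′_j = a_ij/A_i and availabilities q_j = A_j/m,
d = Σ_j p′_j ln(p′_j/q_j) and d′ = (d − d_min)/(d_max − d_min).  Both
bounds are computed under fixed column totals, allocations capped at
A_j.  d_max: the KL objective is convex, so its maximum lies at a
vertex of the capped simplex (a set of saturated columns plus at most
one partial column); vertices are enumerated exhaustively for up to 16
resources (2^K, trivial at web scale), with a greedy rarest-first fill
as fallback beyond.  d_min: proportional-to-availability fill, exact
(d_min = 0) for continuous weights; for integer webs, largest-remainder
rounding followed by greedy single-quantum improvement sweeps.  Both
bounds agree exactly with brute-force enumeration on small integer
matrices in the test suite.  d and the bounds are computed on the raw
continuous weights; d′ is clipped to [0,1] and defined as 0 when
d_max = d_min (single usable resource).

**vaznull.**  The null model needs discrete interaction events, so
continuous matrices are quantised at 100 quanta per unit weight
(`round(w·100)`, positive cells kept at ≥1 quantum); integer matrices
are used as-is.  Each null preserves dimensions, fill and grand total
exactly: one cell per row is drawn (columns weighted by marginals),
empty columns are then covered, remaining filled-cell positions are
drawn without replacement with probability ∝ A_i·A_j, one quantum seeds
each chosen cell, and the remaining quanta are distributed
multinomially over the chosen cells.  Draws that overshoot the required
fill are rejected and redrawn.  Because every row and column must stay
covered, null marginals of skewed small matrices are flattened relative
to the originals — an inherent property of this null-model family, so
tests check rank preservation and correlation of marginals rather than
exact proportionality.  Nestedness is declared significant when the
observed WNODF strictly exceeds the 97.5th percentile of (by default)
1,000 null values; with coarsely quantised matrices the null
distribution is discrete and can tie the observed value at the upper
bound, which we read as a marginal pattern.

## Synthetic-data generator

The generator emulates the structure of the motivating field system: 3
consumer species × 7 source groups, fixed default source signatures
spread ≥ 2 ‰ apart on at least one element (C3 fruits depleted in ¹³C,
C4/CAM fruits enriched, arthropod guilds intermediate with predators
highest in ¹⁵N), true diets p* either fixed (defaults: two similar
fruit-leaning consumers and one predator-leaning consumer) or drawn
from a symmetric Dirichlet, TDF 2.2/2.6 ‰, residual σ = 1 ‰ per element
(matching the whole-blood spread reported for wild thrushes), 50
consumers per species, and fecal sampling of 26/20/4 samples with
Poisson item counts and lognormal volume noise around per-category unit
volumes (fruits bulky, arthropods small).  Blood values are drawn from
exactly the likelihood the fitting module assumes, so pipeline runs on
synthetic studies are parameter-recovery experiments by construction.

What the generator does **not** emulate: between-individual diet
variation (all conspecifics share p*), temporal/seasonal structure,
taxonomic resolution below the resource category, digestive
correlations between count and volume, and source non-normality.
Passing recovery tests therefore demonstrate correctness of the
inference machinery under the stated model, not robustness to these
real-data complications.  An optional per-category detectability
multiplier down-weights soft items in feces (but not blood) to
reproduce the classic hard-remains bias of fecal analysis.

## Problem sizes used by the test suite

Unit tests run the sampler at 2 chains × 8,000 iterations; the
recovery suite runs 20 scenarios at the full study scale (3 species ×
7 sources, n = 50) with the default 4 × 20,000 sampler, and the null
model checks use 100–1,000 randomisations.  These sizes keep the whole
suite within a few minutes on one core while leaving every assertion at
its stated tolerance.

## Known limitations

* No concentration dependence, isotope routing, or individual-level
  hierarchical structure in the mixing model.
* Source grouping is an input; the package does not cluster sources.
* WNODF of fully filled matrices is 0 by definition (see above).
* The exact d_max enumeration is exponential in the number of resources
  and falls back to a greedy bound beyond 16 columns.
* Published SEAc and ellipse-overlap values of the motivating study
  depend on its raw accession data and bootstrap seed and are not
  reproducible from the printed article alone; the ellipse machinery is
  validated against closed-form geometry instead.
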