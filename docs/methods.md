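# Methods

This note documents the statistical procedures implemented in `nemameta`,
the choices made where the methodology left room, and what the synthetic
validation does and does not demonstrate.

## The analysis in one paragraph

A soil-nematode survey produces a samples × genera count table with sample
metadata (station, land cover, replicate plot, year, coordinates), genus
trophic-group labels, and per-sample soil variables. The community is
analysed per *analysis unit*: one land cover at one station (local scale, 6
samples = 3 plots × 2 years) or one land cover pooled over all stations
(regional scale, 24 samples). For each unit the package (i) converts counts
to presence–absence, orders the matrix by reciprocal averaging, evaluates
coherence, turnover and boundary clumping against null models, and assigns
one of the idealized metacommunity structures; (ii) tests genus co-occurrence
with the C-score and its standardized effect size under a fixed-margins
null, overall and per trophic group; (iii) relates community dissimilarity
to environmental and spatial distance with Mantel tests; and (iv) ranks the
environmental and spatial variables by permutation importance for the
ordination site scores.

## Ordination

Reciprocal averaging (RA) is iterated weighted averaging between site and
genus scores; its fixed point is the first non-trivial correspondence-
analysis axis. The implementation runs the averaging iteration to a score
change below 1e-10 (at most 1000 sweeps) and falls back to the exact SVD of
the chi-square-standardized matrix when the leading axes are too close for
the iteration to separate — the two routes agree to numerical precision on
connected matrices, which the test suite checks against an independent SVD
oracle. Conventions: a single ranking axis; ties in scores broken by
original row/column index; the axis sign is fixed so the first row's score
does not exceed the last row's (in input order), and reversal provably
changes no downstream count. Block-disconnected matrices are ordered
component by component (larger components first) and flagged with a warning
rather than re-glued; an all-ones or rank-one matrix has no gradient and is
flagged degenerate.

## Elements of metacommunity structure

*Coherence* counts embedded absences: zeros lying strictly inside a genus's
range of sites in the ordered matrix, plus (default `both_axes` mode) zeros
inside a site's range of genera. `columns_only` counting is available; the
default follows the original formulation in which interruptions along both
axes count against coherence.

*Turnover* counts replacements on the range-filled matrix (each genus's
embedded absences set to 1 first, the standard convention; an unfilled
option exists for sensitivity checks): over all unordered pairs of sites and
pairs of genera, one replacement when one genus occupies only the first site
of the pair while the other occupies only the second. This equals
Σ_{a<b} D(a,b)·D(b,a) where D(a,b) is the number of filled genera present
at a but not b; the suite checks it against literal four-way enumeration.

*Boundary clumping* uses Morisita's index on the per-site counts of genus
range boundaries. Every genus contributes its first and its last occurrence
(both counted, even when they coincide): with f_i boundaries at site i and
F = Σ f_i, I = n·Σ f_i(f_i−1) / (F(F−1)). Significance is the chi-squared
dispersion statistic Σ(f_i − F/n)²/(F/n) with df = n−1; the reported p takes
the upper tail when I ≥ 1 and the lower tail when I < 1 so clumping and
hyper-dispersion are both detectable. F < 2 is degenerate.

*Null models.* Coherence and turnover are tested against `row_fixed`
randomizations: each null matrix keeps every site's richness, placing
presences in columns drawn without replacement with probability proportional
to observed genus totals (the convention of the standard EMS software);
every null matrix is re-ordinated before counting. Both statistics are
evaluated on one shared set of null matrices. The default is 1000
simulations; this package's own analyses and validation runs use 100–500 to
keep runs short, stated per report row. Significance is a Z-test:
z = (obs − mean_null)/sd_null with a two-tailed normal p (empirical
quantiles available on the null object). Note that weighted sampling without
replacement makes the *expected* null column totals flatter than exactly
proportional — an intrinsic property of that scheme, covered by the tests.

*Decision tree.* Non-significant coherence → Random; significant coherence
with more embedded absences than the null mean → Checkerboard; otherwise
turnover decides: significantly fewer replacements than null → Nested, with
the boundary test choosing the loss subtype (I significantly > 1: clumped;
significantly < 1: hyperdispersed; else stochastic); significantly more →
Clementsian (I significantly > 1), Evenly spaced (I significantly < 1) or
Gleasonian (otherwise); non-significant turnover gives the corresponding
Quasi-structure, the direction of the replacement count picking the branch.
α = 0.05 throughout, strict inequality (p = .05 is not significant),
configurable. The classifier reproduces all 15 published survey labels from
their printed statistics, including the published 93% share of Clementsian/
Gleasonian-family structures. Some published Z values are not consistent
with their own printed (obs, mean, SD) to two decimals; the package asserts
only the internally consistent triples, at ±0.02.

## Co-occurrence

The C-score is the mean of checkerboard units cu = (R_i − S)(R_j − S) over
all unordered genus pairs (the denominator is the number of pairs,
P(P−1)/2). The null is `fixed_fixed`: a sequential 2×2 checkerboard-swap
chain that preserves both margins exactly, sampled after a burn-in of 10×
the matrix fill in attempted swaps and thinned by one fill between samples.
Attempt-counted sampling with a symmetric proposal leaves the stationary
distribution uniform over the margin class. SES = (C_obs − mean_sim)/sd_sim;
|SES| > 2 flags non-random structure (≈95% of null SES values fall inside
±2). The default 10,000 simulations follow the survey protocol; calibration
runs here use 200–2000. One printed form of the SES formula divides by the
simulated C-score itself; the package follows the standard-deviations
definition, which is what the ±2 interpretation presupposes.

A structural caveat that shaped the synthetic generators: under a
fixed-margins null the total pairwise overlap Σ_{i<j} S_ij equals
Σ_sites C(richness, 2) and is therefore *invariant*. Community-level
aggregation is consequently visible to the C-score only as overlap
*homogenization* (less pair-to-pair variance in S than the margins predict);
literally identical co-placed genus pairs concentrate overlap, starve every
other pair and push SES upward — they read as segregation. The
`aggregated_pairs` generator therefore gives pair members strongly elevated
but not identical shared-site counts (k²/n + 0.3k of k occupied sites)
inside an overlap-homogenized community, which the statistic reliably
reports at SES ≤ −2; `segregated_pairs` and `checkerboard` use mutually
exclusive site sets and report SES ≥ +2.

## Distances and Mantel tests

Community dissimilarity: Bray–Curtis, Σ|x−y|/Σ(x+y), on abundances.
Environmental distance: Euclidean on z-standardized soil variables
(zero-variance variables dropped with a warning). Spatial distance:
great-circle kilometres (haversine, sphere radius 6371 km) on plot
coordinates by default — the survey names both a geodesic library and
Euclidean distance for space; both modes are implemented and the default is
the geodesic one. The Mantel statistic is the Spearman correlation of the
condensed distance entries; because a joint row/column permutation permutes
the condensed entries among themselves, ranks are computed once and the
permutation p is (1 + #{r_perm ≥ r_obs})/(1 + n_perm), one-tailed positive
by default (the distance-decay direction; two-sided available), 9999
permutations by default. Under independent matrices the p distribution is
uniform (goodness-of-fit checked in the suite).

## Variable importance

The first-axis site scores are regressed on SM, ST, pH, STC, STN, STP,
longitude and latitude with a bagged ensemble of regression trees (default
500 trees, mtry = ⌊p/3⌋, own bootstrap so out-of-bag membership is explicit
and fully seeded). Importance is the percent increase in pooled out-of-bag
squared error when the variable is permuted in the OOB predictions.
Per-variable significance comes from refitting the whole procedure on
permuted responses (default 100) and comparing importances:
p = (1 + #{imp_null ≥ imp_obs})/(1 + n_perms), starred ns/*/**/*** at
.05/.01/.001. The survey shows significance stars without naming a test;
response permutation is this package's choice of the simplest defensible
null, not a claim about the original. Collinear variables split their
importance — rankings, not absolute values, are the deliverable.

## Synthetic data

`generate_metacommunity` draws incidence with a known structure along an
explicit gradient (unit-spaced site positions, so noise parameters are in
units of inter-site spacing), then assigns abundances: per-genus log-normal
base abundance × per-cell log-normal noise, thinned multinomially to 100
identified individuals per sample (every present genus keeps at least one
individual, so incidence is preserved; totals never exceed 100).

* *clementsian*: genera split over compartments sharing range edges
  (default 3 compartments over 24 sites), each genus's two edges jittered
  N(0, sd = 0.5 spacings).
* *gleasonian*: independent range centers, widths uniform on 0.4–0.6 of the
  gradient span, ranges wholly inside the gradient. This width choice is
  deliberate: truncated or strongly width-heterogeneous ranges make the
  ordination stack range edges at the matrix margins, which the boundary
  test then reads as clumping — an artifact of range construction, not of
  the classifier.
* *nested*: occupancy depth along the site-richness order per genus, depth
  jittered by the noise sd; at zero noise every genus list is a subset of
  the next richer site's and replacements are exactly 0.
* *evenly_spaced*: equal widths, maximally separated starts.
* *checkerboard / segregated_pairs / aggregated_pairs*: as described under
  co-occurrence.
* *random*: independent Bernoulli occupancy (default fill 0.5).

`generate_study_design` emulates the survey layout: 4 stations at their
published coordinates spanning ~10° of latitude (with the published mean
annual temperature and precipitation as climate anchors), 3 land covers ×
3 replicate plots × 2 years = 72 samples; ≤ 100 identified individuals per
sample; 32 genera over the four trophic groups in realistic proportions
(bacterivores most numerous). Genus occupancy follows Gaussian niches along
latitude plus land-cover affinities; soil variables are generated around
climate-anchored means with plot noise, so ST, STC, STN, STP, pH and SM all
correlate with latitude. Validation sizes used by the packaged checks:
recovery runs use 24 sites × 30 genera × 150 null simulations × 30 seeds per
structure; SES calibration uses 24×30 Bernoulli matrices × 400 simulations ×
100 seeds; these sizes were chosen to keep full validation runs in minutes.

What the emulator does *not* model: a within-station microhabitat gradient.
Its only occupancy gradient is latitudinal, which is nearly constant inside
one station, so local-scale units of the synthetic design frequently
classify as Random, whereas the real survey found significant local
coherence (presumably from microhabitat structure). Passing tests therefore
demonstrate that the pipeline recovers known structure where structure
exists and stays calibrated where it does not — they do not certify numeric
agreement with the original survey's tables, whose raw data are not
redistributed here. The published per-unit statistics are bundled only as
desk-check inputs for the classifier and the Z-test arithmetic.

## Numerical and degenerate-input conventions

Null SDs use ddof = 1; a zero-spread null is flagged degenerate and refuses
Z/SES computation. Matrices with fewer than 2 rows or columns after pruning
are rejected; trophic subsets that prune to nothing are flagged degenerate
and reported without SES. The 2019 and 2021 samples are pooled within each
analysis unit (one result per unit, matching the published reporting);
`subset(..., year=...)` restricts to one sampling year for a per-year
analysis. Singleton genera are retained by default (no published removal
rule); `to_incidence(..., drop_singletons=True)` removes them. All
randomness flows from explicit integer seeds through counter-derived
per-simulation streams, so results are reproducible and independent of
evaluation order; reports carry the seed and settings of every row.
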