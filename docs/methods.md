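# Methods

This note documents the statistical procedures implemented in `fec`, the
choices made where the methods literature leaves room, and what the
synthetic-data generator does and does not emulate.

## Data model and curation

The central object is a taxa × samples table of non-negative integer read
counts, as produced by an amplicon denoising workflow after taxonomic
assignment. A *population* is the set of plants of one host species at
one collection site; host and site labels live in a sample-metadata
table. Taxonomy carries the seven ranks kingdom → species with an
explicit `UNASSIGNED` sentinel, constrained so that an unassigned rank
implies unassigned lower ranks.

Curation steps, in the order the pipeline applies them:

1. **Species-level agglomeration** — taxa with an identical full
   species-level assignment are summed; taxa unassigned at species rank
   are kept as separate units. Read totals are conserved.
2. **Sample filter** — samples with fewer than 1000 reads (strict) are
   dropped.
3. **Singleton/doubleton filter** — taxa with total reads ≤ 2 across the
   dataset are dropped. "Singletons and doubletons" are read-based here;
   incidence-based rarity is handled separately by the prevalence filter,
   and both thresholds are configurable so either reading is expressible.
   Alpha diversity is computed *before* this step, since rare taxa carry
   most of the information about unseen richness.
4. **Prevalence (core) filter** — taxa present in fewer than 5 samples
   are dropped ("keep if incidence ≥ 5"). The boundary case incidence = 5
   is kept; the thresholds are parameters, so the strict-greater
   convention is also available.

## Alpha diversity: incidence-based Hill numbers

For a population of `T` plants, the incidence frequency `Y_i` of taxon
`i` is the number of plants containing it; `U = Σ Y_i`,
`Q_k = #{i : Y_i = k}`. Hill numbers of order `q` are computed on relative
incidences `Y_i / U`.

Rarefaction and extrapolation to `t` sampling units:

- **q = 0, t ≤ T**: exact expected richness under subsampling without
  replacement, `S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t)`.
- **q = 0, t > T**: `S_obs + Q̂₀ · (1 − (1 − Q₁/(T·Q̂₀ + Q₁))^(t−T))`, with
  the Chao2 unseen-taxa term `Q̂₀ = ((T−1)/T)·Q₁²/(2Q₂)` when `Q₂ > 0`,
  else `((T−1)/T)·Q₁(Q₁−1)/2`.
- **q = 1, t ≤ T**: the exact expected incidence-frequency spectrum
  `E[Q_k(t)]` (hypergeometric) is plugged into the entropy form:
  `¹D(t) = exp(−Σ_k (k/U_t) ln(k/U_t) E[Q_k(t)])`, `U_t = tU/T`. At
  `t = T` this is exactly the observed `¹D`.
- **q = 1, t > T**: the Shannon entropy is moved from its observed value
  toward an asymptotic estimate in proportion to sampling effort,
  `H(t) = (T/t)·H_obs + ((t−T)/t)·H_∞`, and exponentiated. `H_∞` is a
  Chao–Jost-type debiased entropy adapted to incidence data: the digamma
  correction `Σ_{Y_i<T} (Y_i/T)(ψ(T) − ψ(Y_i))` plus the unique-taxon tail
  term, rescaled by `T/U` and shifted by `ln(U/T)` to act on normalized
  relative incidences. This estimator choice hits the observed diversity
  at `t = T`, approaches the asymptote smoothly, and preserves the Hill
  ordering in practice; it is this package's own interpolation between
  the two anchors of the incidence framework.
- **q = 2, any t**: a single closed form, exact for interpolation because
  the hypergeometric second factorial moment is linear in `t(t−1)`:
  `²D(t) = U_t² / (U_t + t(t−1)·Σ Y_i(Y_i−1)/(T(T−1)))`. Its `t → ∞`
  limit, `(U/T)²/(ΣY_i(Y_i−1)/(T(T−1)))`, is the asymptote; if every taxon
  is a unique the concentration signal vanishes and the observed richness
  is returned.

Extrapolation is capped at `2T` by default. Confidence intervals are
percentile bootstrap over plants resampled with replacement — a simple,
honest interval, deliberately *not* the estimated-assemblage bootstrap of
the iNEXT framework (which resamples from a reconstructed assemblage and
is tied to its asymptotic richness estimate). Intervals are clamped to
contain the point estimate; for a population of identical plants the
interpolated intervals have zero width. The default curve uses ~20 integer
knots and 100–200 bootstrap replicates (exact-identity properties —
estimates at `t = T`, the subset-expectation oracle for `q = 0`, and the
ordering `⁰D ≥ ¹D ≥ ²D` — are verified by the test suite).

## Beta diversity

Bray–Curtis dissimilarity `d(x,y) = Σ|x_i − y_i| / Σ(x_i + y_i)` is
computed on Hellinger-transformed abundances (`sqrt` of within-sample
relative abundance); Dice dissimilarity `1 − 2a/(2a+b+c)` on incidence.
Two all-empty samples make either metric undefined and raise an error
naming the pair.

PCoA is classical scaling: double-centering of `−½ d²`, symmetric
eigendecomposition, coordinates scaled by the square root of positive
eigenvalues; axes with non-positive eigenvalues are dropped and negative
eigenvalues reported.

PERMANOVA is one-factor: `SS_total = Σ_{i<j} d²_ij / n`, `SS_within`
summed per group analogously, pseudo-`F = (SS_b/(k−1))/(SS_w/(n−k))`,
`R² = SS_b/SS_total`; ANOSIM uses midranked distances and
`R = (r̄_between − r̄_within)/(M/2)` with `M = n(n−1)/2`. Both tests report
`p = (1 + #{stat_perm ≥ stat_obs})/(1 + B)` under seeded label
reshuffling, so p is never zero and has resolution `1/(B+1)` (default
`B = 999`). Only single-factor tests are provided; host and site are
tested separately rather than partitioned sequentially.

## Kosman dispersion and differentiation

- **KW (within-population, assignment-based)**: minimal average
  dissimilarity over fixed-point-free assignments of plants to plants,
  solved as a linear assignment problem with an infinite diagonal
  (2-cycles allowed). Equals exhaustive derangement enumeration (tested
  for all n ≤ 7).
- **KB (between populations)**: minimal average dissimilarity of an
  optimal one-to-one matching of the smaller population's plants to
  distinct plants of the larger, averaged over `min(n_a, n_b)` pairs
  (rectangular assignment). Unequal population sizes are handled by this
  partial matching; no balancing scheme is applied.
- **Effective number of populations**: from the mean pairwise KB,
  `M`, over `N` populations: `¹D(TM) = 1 + (N−1)·M`,
  `¹nD(TM) = (¹D(TM) − 1)/(N−1) = M`. Within a population the same map
  applied to `M = KW` with `N` = number of plants gives the normalized
  effective number of distinct plants, which equals KW itself.
- **Differentiation D**: default is the additive partition of
  average-based dispersion, `D = M_pooled − W`, where `M_pooled` is the
  mean pairwise distance of the pooled plant set and `W` the
  size-weighted mean of within-population mean pairwise distances. The
  original formulation is not printed in full in the sources this package
  follows, and the published numbers cannot distinguish this partition
  from the assignment-based alternative `D = mean KB − mean KW`; both are
  implemented (`variant="partition" | "assignment"`, default partition).
  Significance is a permutation test reshuffling plants among populations
  with sizes preserved (default 1000 reshuffles), `p = (1+b)/(1+B)`.
- The pooled "all locations" dispersion is computed on the pooled plant
  set, not as a weighted mean of per-site values.

## Co-occurrence networks

Counts are aggregated to genus level (taxa unassigned at genus are
removed). Within each population, Spearman correlations (midranks;
two-sided p from the t approximation) are computed between all genus
pairs on **within-sample relative abundances** — the scale matters
because Spearman is invariant to per-genus monotone maps but not to
per-sample renormalization, and raw counts would couple every pair
through library size; `raw` and `hellinger` scales are available.
Genera present in fewer than 5 plants of the population, or constant
across its plants, are skipped. Edges with `p < 0.001` (raw, no
multiple-testing correction by default; Benjamini–Hochberg available
upstream of the threshold if desired) are recorded per site.

Per host, edges seen in only one site are discarded as likely noise;
surviving edges carry the number of supporting sites and the accumulated
rho, summed separately over positive and negative site-level
coefficients (mixed-sign edges keep both accumulators). Centralities:
degree; harmonic closeness (well-defined on disconnected graphs,
normalized by `n−1`); betweenness (normalized); eigenvector centrality
per connected component (power iteration, tolerance 1e-10) scaled by the
component's vertex share. Hub candidates are ranked by the composite
rule: competition rank of descending degree + descending closeness +
ascending betweenness, ties broken by genus id — note this rule
deliberately penalizes bridge vertices (e.g. a star's center ranks below
its leaves), following the keystone heuristic of high connectivity
*within* a module. Network summaries report diameter and mean shortest
path on the largest connected component and edge density over all
vertices.

## Synthetic surveys

The generator draws, per plant, latent log-normal abundances
`exp(μ_i + h_{host,i} + s_{site,i} + ε)` for core taxa (per-taxon means
`μ_i ~ N(0, 1.5²)`, host/site effects `N(0, sd²)` per taxon, per-plant
noise sd 0.8), multiplies by Bernoulli occupancy (heterogeneous
`Beta(a, b)` per core taxon when enabled), adds sporadic taxa that occur
independently with small probability at low abundance, and host-specific
taxa structurally absent elsewhere. Counts are multinomial given a
log-normal library size (Dirichlet-multinomial overdispersion optional).
Correlated pairs/modules replace the members' noise with (equi)correlated
Gaussians at Pearson `r = 2 sin(π ρ/6)`, the monotone-invariant map that
targets Spearman `ρ` on the latent scale; count sampling attenuates the
realized correlation, so planted associations are placed on abundant,
prevalent taxa (members' occupancy is floored at 0.8) — as hub candidates
in real surveys are. A taxon may belong to at most one planted pair or
module. All randomness derives from one seed via keyed substreams, so
identical configs yield identical tables.

`preset_paper_shape()` mirrors the wheat survey's design: hosts TA/AS/TD
at 7/4/3 sites with the survey's shared-site pattern and per-population
retained sample counts (530 samples), 450 core + 1230 sporadic + 20
host-specific taxa per host (~1720 total), occupancy `Beta(0.45, 4.5)`,
sporadic occurrence 0.004, library sizes log-normal around 10⁴ reads,
host/site effect sds 0.35/0.25, and one planted 6-genus association
module plus 7 pairs (one negative). Under this preset the emulation
yields ~58 taxa per plant, per-site richness ~400–490, within-population
`¹nD(T,KW)` ≈ 0.5 and PERMANOVA host `R²` ≈ 0.04 — the same regimes as
the real survey, without attempting to reproduce its exact values.

What the generator does **not** emulate: phylogenetic structure in
abundances, spatial autocorrelation among sites, sequencing error or
chimeras, compositional interactions beyond the closure imposed by
multinomial sampling, and taxon-specific library biases. Passing
recovery tests therefore demonstrates correctness of the estimators
under a plausible community model, not robustness to all artifacts of
real amplicon data.

## Numerical choices and degenerate inputs

- Binomial coefficients in rarefaction use integer log-gamma tables;
  identities hold to ~1e-12.
- Assignment problems use the exact Jonker–Volgenant solver; the
  forbidden diagonal is `+inf`.
- Distance matrices must be symmetric to 1e-12 with zero diagonal and
  values in [0, 1]; violations raise errors naming the offending entries.
- Permutation p-values are reported as `(1+b)/(1+B)` and are therefore
  never 0; two runs with one seed are identical.
- Perfectly separated groups give infinite pseudo-F; permutations that
  reproduce the separation count as ties (≥), keeping p valid.
- Zero-total samples are rejected at transform time with their ids;
  populations of one plant are skipped (dispersion) or rejected
  (differentiation).

## Test-suite problem sizes

Calibration suites run at reduced sizes chosen once: null calibration
uses 200 replicate surveys of 2 × 12 plants with 80 taxa and 99
permutations per test (one-sided Kolmogorov excess below the 0.5%
critical value plus permutation-resolution slack); effect-recovery uses
3 host-effect levels × 20 paired replicates of 3 hosts × 2 sites × 12
plants; pair recovery uses 5 replicates of 3 sites × 40 plants with 10
planted pairs. The survey-scale determinism check runs the full pipeline
twice at the 530-sample preset.

## Known limitations

- The `q = 1` extrapolation and its entropy asymptote are this package's
  estimator choice within the incidence framework; they were not
  cross-checked against the reference R implementation and may differ in
  the far-extrapolation regime (interpolation and `q = 0`/`q = 2` are
  exact or closed-form).
- Differentiation `D` has two defensible definitions (see above); only
  their shared normalized effective-number scale is anchored to published
  worked examples.
- Spearman p-values use the t approximation, which is slightly
  anti-conservative in the extreme tail at n ≈ 40 (null edge retention
  measured at ~1.5–2 per mille at the 1-per-mille threshold); exact
  permutation p-values are not implemented.
- BIOM support is read-only and limited to the 2.1 HDF5 layout.
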