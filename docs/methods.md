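# Methods

This note documents the statistical procedures implemented in benthonet, the
parameter defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical edge-case conventions.

## Preprocessing

Replicate samples are pooled to site level by **summation** (a mean would
only rescale every taxon identically; sums keep count semantics). With a
sampled area (e.g. 0.27 m² for three 30 × 30 cm Surber grabs) pooled counts
become densities in ind/m²; the pipeline behaves identically on counts and
densities and records which was used.

Abundances are transformed as log₁₀(x + 1) before ordination/clustering.
The base is configurable (natural log, base 2); all distance-based
downstream steps are affected only through a monotone rescaling, so the
choice changes scale, never ordering, of quantization errors and distances.

Rare taxa — those occurring at fewer than 2 sites (i.e. singletons) — are
excluded before the SOM, the standard filter in community ordination.
Occurrence is counted on the pooled site-level matrix. The filter is
idempotent, and removed taxa are recorded in the run provenance.

## Community indices

The four diversity indices follow the conventions most common in Korean
benthic bioassessment: Shannon *H* with natural log, McNaughton dominance
(n₁ + n₂)/N, Margalef richness (S − 1)/ln N, Pielou evenness H/ln S. Each
formula is configurable and the report names the variant used. Degenerate
inputs are defined explicitly: an empty sample yields all-zero indices with
a warning; a single-taxon sample has H = 0 and evenness 0 (rather than 0/0).
FFG percentages are taken over trait-classified present taxa only, so taxa
with unknown guild never distort the denominators; the six-guild vocabulary
(predator, parasite, scraper, collector-filterer, collector-gatherer,
shredder) is closed.

## Co-occurrence networks

Pairwise association is Spearman rank correlation, computed as Pearson
correlation of mid-ranks (average-rank tie handling); two-sided p-values use
the t approximation on n − 2 degrees of freedom. Zero-variance taxa have
undefined correlation and can never form edges, but remain nodes — network
size should equal the observed species pool, not the statistically active
subset.

The literature this package serves rarely states its edge rule, so the rule
is explicit configuration: an edge requires p < α (default 0.05), optionally
|ρ| above a floor (default 0) and optionally positive sign only. The rule in
force is embedded in every output.

Average path length is the mean shortest-path length over connected ordered
pairs; pairs in different components are excluded (an alternative that
scores disconnected pairs as n is available). Transitivity is the global
clustering coefficient 3·triangles / connected triples. All six statistics
are validated in the tests against brute-force Floyd–Warshall and
triple-enumeration oracles.

## SOM patterning

The map size heuristic targets ceil(5·√n) output units; the rows:cols split
follows the ratio of the two leading covariance eigenvalues, and an explicit
grid override always wins (so a survey-specific choice such as 5 × 6 = 30
units for 23 sites can be reproduced exactly).

Training is the **batch** Kohonen algorithm on a hexagonal lattice: each
epoch assigns best-matching units (BMUs) by Euclidean distance, then sets
every codebook vector to the Gaussian-kernel-weighted mean of the data, the
kernel acting on lattice distance. The radius shrinks linearly from
max(grid)/4 to 1.5 over 50 rough epochs, then 1.5 → 0.5 over 100 fine
epochs; when a caller supplies a start/end pair that does not bracket the
1.5 midpoint the schedule degrades to a single linear phase. Initialization
is deterministic linear (the codebook spans the two leading principal
components, the longer lattice side carrying the first component), so runs
are reproducible without seed juggling; random initialization is available.
Units whose kernel mass is zero keep their previous vectors. In the
radius → 0 limit the batch update is exactly Lloyd's algorithm, which the
tests exploit as a 2-means oracle.

Codebook units — including units that are no sample's BMU — are clustered by
K-means (k-means++ with 100 restarts, seeded) for each K in 2..min(10,
units − 1); the K minimizing the Davies–Bouldin index
DB = (1/K)·Σᵢ maxⱼ≠ᵢ (Sᵢ + Sⱼ)/Mᵢⱼ is selected, ties toward the smaller K.
Samples inherit their BMU's cluster, and that consistency is asserted on
every run.

**Known limitation.** When within-cluster noise is large relative to the
planted separation, or when many codebook vectors are near-duplicates of
single samples, the DB curve can keep decreasing toward high K (singleton
codebook clusters have Sᵢ = 0), and model selection overshoots the true
cluster count even when the partition at the true K is essentially perfect.
This is a property of DB selection on codebooks, not of the training: in the
strongly separated regime (see below) K-recovery is exact.

## MRPP, Kruskal–Wallis, Dunn

MRPP uses group weights Cᵢ = nᵢ/N: δ = Σᵢ (nᵢ/N)·ξᵢ with ξᵢ the mean
pairwise within-group distance. Distance defaults to Euclidean (matching the
common default of the reference implementations); Bray–Curtis is exposed
because community data often warrant it. The null is 999 seeded label
permutations; p = (1 + #{δ* ≤ δ})/(n_perm + 1) and A = 1 − δ/E(δ) with E(δ)
the permutation mean. Groups with fewer than two samples are rejected (the
pipeline reports MRPP as NaN rather than failing when a tiny demo yields
singleton clusters).

The Kruskal–Wallis statistic is the tie-corrected mid-rank H with a
chi-square reference on k − 1 degrees of freedom (delegated to scipy, which
implements exactly this). Dunn's pairwise z statistics use the pooled-rank
variance with the tie term Σ(t³ − t)/(12(N − 1)); p-values are two-sided
normal, with optional Holm or Bonferroni adjustment (default none, matching
the granularity of typical published letter patterns; Holm is recommended
when many variables are screened). Compact letters are assigned per maximal
clique of the non-significance graph, which makes "shares a letter" exactly
equivalent to "not significantly different" — that equivalence is asserted
in the tests.

## Indicator species

IndVal follows the original group-equalized form: specificity
A(t,c) = mean abundance in c / Σ over clusters of mean abundances (so
unequal cluster sizes do not bias A), fidelity B(t,c) = occurrence frequency
in c, IndVal = 100·A·B on the 0–100 scale. Significance permutes sample
labels (one shared permutation per iteration across taxa) and compares each
taxon's maximum-over-clusters IndVal to its null; a taxon is selected for
its maximizing cluster when IndVal is strictly greater than 25 and p < 0.05.
Argmax ties go to the lowest cluster index. A taxon with identical abundance
everywhere is permutation-invariant and gets p = 1.

## Synthetic communities and what passing tests mean

The generator emulates the structure the analyses assume: 3 latent site
groups over 23 sites (8/8/7), 74 taxa surviving the rare-taxon filter
(56 shared core taxa + 6 cluster-exclusive indicator taxa per cluster) plus
6 planted singletons that exercise the filter. Counts are negative binomial
(mean 20, dispersion 1 by default — strongly overdispersed, as benthic
counts are), modulated by a one-dimensional latent gradient: cluster c sits
at gradient value g_c (equally spaced in [−1, 1]), taxon t has loading
λ_t ~ U(−1, 1), and expected abundance is μ·exp(γ·λ_t·g_c) with
γ = `gradient_strength`. The shared gradient induces inter-taxon Spearman
correlation that grows with γ (verified by simulation). Indicator taxa are
hard-zero outside their cluster, so their IndVal is exactly 100·B. Optional
impact profiles thin per-cluster richness and zero all scraper-guild taxa,
mimicking periphyton-grazer loss under acid mine drainage. The
`generate_mining_gradient` demo lays sites on a line with a piecewise-linear
richness profile declining from the reference pool to an interior minimum
and recovering downstream; impacted (trough) sites lose all scrapers.

The **strong-separation benchmark** (`strong_separation_spec`) is the regime
in which end-to-end recovery is expected: 12 sites per cluster, exclusive
indicators present at every own-cluster site, doubled gradient, dispersion 5
(moderate overdispersion). Under these conditions SOM → K-means → DB
recovers K = 3 with an adjusted Rand index of 1.0 essentially always, MRPP
is significant and every planted indicator is selected.

What passing these tests shows: the estimators and selection rules are
implemented correctly and recover planted structure under the stated noise
model. What they do not show: robustness to features of real survey data
that the generator omits — spatial autocorrelation between neighboring
sites, taxonomic mis-identification, detection failures correlated with
abundance, compositional closure from fixed-effort sampling, and
environment-driven covariance beyond one latent gradient.

## Problem sizes and determinism

Simulation-based checks use the sizes that make their null behavior sharp at
desk scale: 20 seeds for recovery rates, 50 null replicates at n = 40 for
MRPP's A ≈ 0 property, 1000 replicates for the Kruskal–Wallis type-I rate,
999 permutations for Monte-Carlo p-values compared against exact enumeration
on 6-sample instances. A single pipeline seed fans out to per-stage child
seeds (CRC32 of the stage name XOR the seed, kept below 2³¹), so every stage
is independently reproducible and full-bundle reruns are bit-identical.
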