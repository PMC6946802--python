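# Methods

This note documents the models, estimators, numerical conventions, and design
choices behind the package, and what the synthetic experiments do and do not
demonstrate.

## Preprocessing

Counts are rarefied per sample to a fixed depth (default 10,000 reads) by a
multivariate hypergeometric draw — subsampling without replacement, so column
sums are exact and no cell ever exceeds its input.  Samples below the depth
are dropped, not padded.  At most 5 individuals are retained per host
species (uniformly at random), then ASVs present in fewer than 10 samples
are removed; the cap→filter order is the default and both constants are
configuration.  Presence means count > 0 after rarefaction — the
presence/absence metrics (Jaccard, unweighted UniFrac) binarize implicitly
and no extra minimum-count threshold is applied.  All random steps draw from
named substreams of one root seed (CRC32-keyed `SeedSequence` spawns), so
every pipeline product is bit-reproducible from a single integer.

## Distances and alpha diversity

Jaccard and Bray-Curtis come from `scipy.spatial.distance.pdist`; matrices
are carried as `skbio.DistanceMatrix` (symmetry and zero diagonal enforced).
Unweighted UniFrac and Faith's PD are computed from an edge table (branch
length + descendant-tip mask per edge) under the **root-inclusive**
convention: every branch on the path from the root to a present tip counts.
This matches the dominant convention in 16S tooling; it matters for both
quantities whenever the root subtends lineages absent from a sample, and is
checked in the tests against both a brute-force branch-enumeration oracle
and scikit-bio's implementations.  Shannon diversity and Pielou evenness use
natural logarithms (nats); Pielou of a single-feature sample is NaN
(undefined), never 0.

## Permutation matrix statistics

Mantel r is the Pearson correlation of the vectorized upper triangles; the
test permutes object labels (rows and columns jointly) of one matrix, never
triangle entries.  p-values are one-tailed upper by default — the
phylosymbiosis hypothesis is directional — with a two-sided option, and the
observed statistic is always a member of the reference set, so the smallest
attainable p is 1/(n_perm + 1); with `exhaustive=True` all n! permutations
are enumerated and p is the exact permutation fraction.  A reported `slope`
(OLS of dy on dx triangles) accompanies r for effect-size readouts.  Ties in
the permutation count use a 1e-12 guard so the identity permutation is never
lost to rounding.

Partial Mantel follows Smouse–Long–Sokal: both triangles are regressed on
the conditioning triangle, the partial r is the correlation of residuals,
and inference permutes the labels of the residual matrix.  When the
conditioner absorbs a matrix to numerical noise (residual sd ≤ 1e-12 of the
original), the partial r is 0 by construction and reported as such rather
than as noise correlation.

MRM regresses the response triangle on predictor triangles with an
intercept; permutation of the response's object labels recomputes R²
(overall p) and |t| (per-coefficient p).  Predictor collinearity is rejected
at condition number 1e8 on the column-normalized design.  PERMANOVA uses
Anderson's pseudo-F on squared distances, F = (SS_A/(a−1)) / (SS_W/(N−a))
with SS_T = Σ_{i<j} d²/N and SS_W the within-group analogue; a matrix whose
off-diagonal entries are all equal is flagged degenerate.  The 500-replicate
null calibrations in the test suite hold both MRM and PERMANOVA to a
5% ± 2% type-I rate at α = 0.05.

## Phylosymbiosis scan

One representative sample per species (uniform, seeded) avoids zero-length
within-species branches.  Every internal node of the host tree with at least
7 descendant species is scanned once (polytomies included); matrices are
restricted to the node's species and tested against patristic distances from
the tree (subsetting a global patristic matrix — identical to recomputing on
the pruned subtree).  Per-node seeds derive from the root seed and the node
id, so adding or removing nodes does not shift other nodes' permutations.
No multiple-testing correction is applied across nodes by default
(Benjamini-Hochberg available by flag).  For plotting, between-species
sample pairs can be exported with an optional divergence cutoff (e.g.
150 Ma); within-species pairs are excluded.

## Host specificity

The evenness SES null redraws each ASV's observed occurrence count uniformly
without replacement from the class's samples, 100 times; SES uses the
population sd of those 100 statistics.  The permutation universe is the
class under analysis (mammal distributions permuted over mammal samples,
avian over avian), and the evenness denominator K counts all order-level
taxa of the class observed in the data set, not only taxa where the ASV
occurs.  A null sd of 0 yields an explicit `undefined` flag, never a silent
0.  The ≥ 10-sample filter applies to both SES and LRR scoring.  LRR uses
natural log with a configurable cap (default 3) assigned to class-exclusive
ASVs; per-sample means include capped ASVs, and samples containing no scored
ASV are flagged missing.

## BDTT

At depth t the clades are the maximal nodes whose greatest distance to any
descendant tip is ≤ t — the standard horizontal slice on ultrametric trees,
degrading gracefully on non-ultrametric ones (insertion phylogenies rarely
are ultrametric).  Clade counts are member sums; the default grid is 21
evenly spaced cuts from 0 to the 95th percentile of root-to-tip heights
(avoiding guaranteed-degenerate deepest slices), and the grid is recorded in
output headers.  The same seed feeds every depth's Mantel test, making the
depth-0 entry bit-identical to a standalone ASV-level test.  Depths where
the Jaccard triangle is constant are flagged degenerate, not dropped.  Note
that pairwise Jaccard is **not** monotone under clade merging: merging two
features exclusive to different samples lowers the distance, but merging two
shared features raises it (S/U shrinks because S < U), so the curve makes no
monotonicity assumption.

## Synthetic-data generator

Host trees are pure-birth (Yule) per class, rescaled ultrametric; order-level
taxa are the clades found by cutting each class subtree at the depth where
exactly `n_orders` lineages exist (ties broken by clade size; continuous
birth times make real ties measure-zero).  Diet is species-level: order
means from a flat Dirichlet over 5 categories, species drawn around their
order mean (concentration 8), rows summing to 100 — so diet is
phylogenetically structured at the order level, as ecological trait
databases show.  Each ASV belongs to a guild: phylogeny-tracking (70%),
diet-tracking (15%), or cosmopolitan (15%).  Occupancy probability for a
phylogeny-tracking ASV decays exponentially with patristic distance from a
uniformly drawn focal species at scale λ; diet-tracking ASVs use Bray-Curtis
distance between diet profiles at scale λ_diet (default 0.3); cosmopolitan
ASVs occupy at the focal rate everywhere.  Baseline occupancy b = 0.01 and
focal occupancy c = 0.9: the small baseline keeps restricted ASVs genuinely
restricted (a large b would scatter stray occurrences across all orders and
erase the specificity signal the generator exists to produce).  Occupied
cells get lognormal(0, 1) abundances and each sample is multinomially
resampled to exactly `reads_per_sample` reads.  Both λ and λ_diet may be set
per host class, which is how the "bird-like" regime — correlated with
neither phylogeny nor diet — is expressed.

### Experiment geometry

The recovery sweep simulates one class (32 species, 8 orders, 3
samples/species, 400 ASVs) at λ ∈ {1000, 100, 20, 5} Ma on a radiation with
a 5 Ma crown.  The crown age is a deliberate identifiability choice: an
exponential host-range kernel is only informative where the tree's pairwise
distances bracket its scale.  On a deep (say 200 Ma) tree, λ ≤ 20 Ma makes
every phylogeny-tracking ASV private to its focal species — below the
10-sample filter, and with a Jaccard signal confined to a handful of close
pairs — so Pearson-Mantel r *peaks* at intermediate λ instead of rising
monotonically with specificity.  On the 5 Ma radiation the whole ladder is
identifiable: the most-specific value equals the crown age, and the most
general (1000 Ma) is effectively flat.  The sweep statistic is the mean over
5 replicate simulations per λ (a Monte Carlo precision choice; the per-λ
generating conditions are fixed).  The two-class contrast uses the same
radiation per class (classes split at 10 Ma) with λ = 5 Ma vs 1000 Ma and
per-class λ_diet 0.3 vs 1000.  Problem sizes throughout (32 species per
class, 400 ASVs, ≤ 7 samples/species) keep any single simulation under a few
seconds while leaving all statistics well-powered.

### What the synthetic experiments show — and what they do not

Passing tests demonstrate that the estimators recover a known, tunable
host-specificity structure: monotone rank agreement of root Mantel r and
median SES with the generating λ, a left-shifted SES distribution and capped
LRRs for a specific class against a generalist one, and exact agreement of
the core statistics with independent oracles.  The generator does not
emulate real taxonomic composition, sequencing error, chimeras,
contamination, compositional count dependence beyond multinomial resampling,
or overdispersed occupancy; agreement here does not certify effect-size
estimates on real surveys, where unmodeled structure (captivity, sample
handling, uneven lineage sampling) contributes variance.

## Known limitations

* Pearson-Mantel saturates for strongly convex distance-decay relationships;
  on deep trees with small λ the scan will understate specificity that the
  SES still detects (this asymmetry is visible in the sweep design above).
* The SES permutation null conditions on occurrence counts but not on
  per-sample richness; strong richness gradients across orders could shift
  the null slightly.
* PERMANOVA here is one-way; multi-factor designs and PERMDISP-style
  dispersion checks are out of scope.
* MRM p-values permute the response matrix only, the standard scheme; they
  are approximate under strong predictor correlation.
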