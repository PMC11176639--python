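# Methods

This note documents the statistical models implemented in `ecoassembly`,
the conventions chosen where the literature admits more than one, the
design of the synthetic-data generator, and what the passing test suite
does and does not establish about real data.

## Preprocessing

**Depth filter.** Samples with total counts strictly below
`min_sample_reads` (default 1000) are removed before any beta-diversity
analysis; taxa left without observations are dropped.

**Rarefaction.** Each retained sample is subsampled *without replacement*
to an even depth — an exact multivariate-hypergeometric draw per sample
(`numpy.random.Generator.multivariate_hypergeometric`). Per-sample random
streams are derived by hashing the base seed with the sample id, so results
are invariant to sample order. Samples shallower than the target depth are
dropped with a warning.

**CSS normalization.** Cumulative-sum scaling divides each sample's counts
by the cumulative sum of its smaller counts, damping the influence of a few
dominant taxa relative to total-sum scaling. Convention: for a sample with
n nonzero counts and quantile q (default 0.5), the scaling factor sums the
smallest `ceil(q·n)` nonzero counts — a rank-based rule, so four equal
counts at q = 0.5 sum the lowest two. The factor-zero case (a sample with
no nonzero counts below the quantile rank cannot occur under this rule
unless the sample is empty) raises with the sample named. The
adaptive-quantile variant of CSS is out of scope; the quantile is
configurable.

**Collinearity pruning.** Greedy: while any pair of chemistry variables has
|Pearson r| above the cutoff (default 0.65), the worst-offending pair is
located and the member with the larger mean |r| against all remaining
variables is dropped (ties break lexicographically). The report records
every drop and its triggering correlation. Samples with missing chemistry
are excluded from the correlation computation, and downstream environmental
analyses exclude them rather than imputing.

## Diversity and ordination

Shannon diversity uses the natural logarithm and is conventionally computed
on rarefied counts (a warning is emitted otherwise). Bray–Curtis is
Σ|x−y| / Σ(x+y); Euclidean distances optionally z-score each column first.
PCoA eigendecomposes the Gower-centered matrix −½ D² double-centered;
axes are eigenvectors scaled by the square root of their eigenvalues.
Negative eigenvalues (non-Euclidean dissimilarities) are dropped, not
corrected (no Lingoes/Cailliez), and their summed magnitude is logged so
users can judge the distortion; variance proportions are over the positive
eigenvalues only.

## The two-step assembly classifier

**βMNTD.** Abundance-weighted by default (each taxon's contribution is its
within-sample relative abundance); the unweighted variant uses 1/richness
weights. Shared taxa contribute zero (a taxon's nearest neighbor in the
other community may be itself). Verified to numerical precision against an
independent brute-force implementation and against `picante::comdistnt` in
R.

**βNTI.** The null shuffles tip labels uniformly at random across all taxa
of the aligned table. One shuffle per replicate is shared by all sample
pairs — statistically equivalent to per-pair shuffles and cheaper by the
number of pairs. The z-score uses the sample standard deviation (ddof = 1)
of the null replicates. Pairs whose null SD vanishes (e.g. a star
phylogeny) are flagged undefined, excluded from percentage denominators,
and counted in the report. An explicit permutation list can be supplied,
which makes exhaustive enumeration possible for small taxon sets.

**RC on Bray–Curtis.** The stochastic null reassembles each sample with its
observed richness and total count: taxa are drawn without replacement with
probability proportional to occurrence frequency across the analyzed table
(sequential weighted sampling, implemented by the Gumbel top-k trick,
which is distributionally identical), and the individuals are then
distributed multinomially with probability proportional to the taxa's
summed within-sample relative abundances, renormalized over the drawn set.
RC = 2·[(#(null < obs) + ½·#(ties within 1e-12))/n_null] − 1. The regional
pool spans every taxon of the table passed in; restricting the pool to a
comparison group is done by subsetting the table first (the pipeline
excludes grass plots from the assembly stage by default, since the
assembly question concerns the planted plots).

**Classification.** Strict inequalities exactly as printed: βNTI < −2 →
homogeneous selection; βNTI > +2 → heterogeneous selection; otherwise
RC > +0.95 → dispersal limitation, RC < −0.95 → homogenizing dispersal,
else undominated. Values exactly on a threshold fall through to the next
test. βNTI uses relative abundances; RC uses rarefied integer counts
(its null distributes individuals). Both choices are configurable.

## Permutation statistics

All sums of squares are computed directly from the Gower-centered distance
matrix (McArdle–Anderson), so Bray–Curtis and other semi-metric
dissimilarities are handled without embedding loss. All sampled
permutation p-values use the (b+1)/(m+1) estimator, so p = 0 is
impossible; exhaustive enumeration (exact proportion, identity included)
is available for small n.

- **PERMANOVA**: sequential (Type-I) terms in the order given, matching
  the convention of fitting plot type before plot; nestedness is
  represented by term order, not by strata-restricted permutations.
  Permutation is free relabeling of samples.
- **Mantel**: Pearson r over the n(n−1)/2 off-diagonal entries; one-tailed
  (greater) by default. Distance-decay reports r between *similarity*
  (1 − dissimilarity) and distance — negative under decay — with the
  one-tailed p for turnover increasing with distance, plus the
  least-squares slope of similarity on distance for plotting.
- **Procrustes**: symmetric — both configurations centered and scaled to
  unit Frobenius norm, truncated to the common axis count; m² = 1 − (Σ
  singular values of XᵀY)²; r = √(1−m²); significance by permuting the
  rows of the second configuration.
- **DistLM**: forward selection on the distance matrix itself; at each
  step the predictor with the largest added R² enters and its pseudo-F is
  tested by free permutation; selection stops when the best candidate
  exceeds alpha. Marginal (single-variable) R² is reported for every
  predictor.

A note on reporting: R² here is always SS_term/SS_total. (Survey tables
are sometimes captioned as the square root of the component of variation;
that reading is inconsistent with per-term percentages-of-variation usage,
and this package reports plain R².)

## Spatial structure and variance partitioning

**dbMEM.** Euclidean geographic distances are truncated at the longest
minimum-spanning-tree edge t (entries beyond t replaced by 4t), the
truncated matrix is Gower-centered and eigendecomposed, and the
positive-eigenvalue eigenvectors — orthonormal, ordered broad to fine —
form the spatial basis. This reproduces the classical PCNM/dbMEM
construction (eigenvalues verified identical to `vegan::pcnm`). On a
regular transect the leading eigenvector is the broadest wave: one sign
change, rank correlation ≈ 0.79 with position (not higher: the truncated
construction flattens the extremes).

**MEM selection.** Each eigenvector is tested marginally against the
community distance matrix (single-predictor dbRDA pseudo-F, free
permutation), with Benjamini–Hochberg correction across eigenvectors;
adjusted p < alpha is retained. Marginal testing is used rather than
forward selection because the selection requirement is only that the
spatial components "significantly correlate" with community distances.
An empty selection is legal and yields zero spatial fractions.

**Variance partitioning.** dbRDA R² for environment (standardized
chemistry), space (selected MEMs), and their union; Ezekiel's adjustment
R²adj = 1 − (1 − R²)(n−1)/(n−p−1); fractions a = adj(E∪S) − adj(S),
c = adj(E∪S) − adj(E), b = adj(E) − a, d = 1 − (a+b+c). The four
fractions sum to one by construction. Pure fractions can be slightly
negative under the adjustment; values below −0.05 are flagged but
reported as computed.

## IndVal

Specificity A uses the group-equalized (Dufrêne–Legendre) form — each
group's *mean* abundance share rather than pooled sums — removing group-
size bias; the raw variant is available by flag. Fidelity B is the
fraction of the group's samples containing the feature. IndVal = max over
groups of A·B·100. Significance is by permuting group labels (p =
(b+1)/(m+1)) with BH correction across features. Inputs must be relative
or CSS-normalized abundances: specificity is only meaningful when rows
share a scale.

## The synthetic-data generator

The generator emulates the structure of a riparian restoration survey:
~60 samples in 8 plots tiling a 272 m × 30 m strip (three plot types:
monoculture, mixed, grass), thousands of taxa on a Yule phylogeny, uneven
lognormal sequencing depths (mean 6000 reads, σ = 0.5 on the log scale, a
configurable number of samples planted below 1000 reads), and a
16-variable soil-chemistry block in which 7 planted nuisance variables are
collinear (|r| ≈ 0.85) with 9 base variables and are removed exactly by
the greedy pruner.

Assembly scenarios share one mechanism set:

- **Niche trait**: early-burst Brownian motion (rate decaying as exp(−0.5
  t) from the root), giving clade-conserved niches. Plain Brownian motion
  leaves trait bands phylogenetically diffuse, and nearest-taxon metrics
  then carry no signal even under strong filtering.
- **Regional pool**: lognormal abundances (σ = 2). Under the selection
  scenarios the log abundance is a second Brownian field on the tree —
  whole clades coherently common or rare, so a taxon's close relatives
  stand a realistic chance of being sampled elsewhere. Under the neutral
  scenarios abundances are i.i.d.: phylogenetically conserved abundance is
  itself a selection signature and would contaminate them.
- **Local drift** operates in every scenario: per-sample random taxon
  extinction (p = 0.6) plus lognormal abundance fluctuation (σ = 1).
  Homogenizing dispersal suppresses both (×0.1: mass effects rescue local
  extinction); the drift scenario keeps extinction but mild fluctuation
  (×0.3), since the Raup–Crick null redistributes individuals by pool
  abundance and systematic per-sample abundance distortion would read as
  dispersal limitation rather than drift.
- **Scenario kernels**: homogeneous selection filters the pool by a
  Gaussian kernel (σ_sel = 0.15 trait SD) around one shared optimum, plus
  a 10% unfiltered-pool admixture (immigration) that spreads observed taxa
  over the whole tree — the contrast the tip-shuffling null needs.
  Heterogeneous selection uses three contrasting optima in thirds along
  the strip, anchored to the mean traits of the most trait-contrasting
  deep clades, so differently selected communities are phylogenetically
  (not merely phenotypically) distinct; no immigrant admixture, which
  would hand every taxon a close relative in the partner community.
  Dispersal limitation gives each taxon a home coordinate and decays its
  weight as exp(−d/λ), λ = 30 m. Homogenizing dispersal draws one shared
  realized metacommunity (3·n_taxa individuals from a flattened pool,
  exponent 0.5 — mass effects average abundances across sites) used by
  every site. Drift samples the pool independently per site.

Default problem size is 2000 taxa and 24 samples; at a few hundred taxa a
Yule tree's observed pool is too saturated for any βNTI signal to exist,
so smaller defaults would make the selection scenarios unrecoverable in
principle, not just noisy. These parameters were fixed during generator
design by verifying that each scenario expresses its intended process, and
then frozen.

The functional-table generator produces Dirichlet-multinomial counts
(concentration 2000) over 200 categories mapped to level-1 groups, with 30
categories per plot type enriched threefold in expectation.

**What the simulator does not emulate**: sequence-level error and chimeras,
taxonomy, compositional biases of extraction/PCR, fungal-vs-bacterial
biology beyond parameter presets, temporal dynamics, and interactions
among taxa. Passing scenario-recovery tests therefore shows the inference
machinery is correct and well calibrated on data satisfying its own
assumptions — not that real soil communities satisfy them.

## Numerical choices and degenerate inputs

- Seeds: every stochastic routine takes an integer seed; sub-streams are
  derived by hashing the seed with stable identifiers, so sample order and
  stage toggles never shift unrelated streams.
- Ties in permutation tests are counted as exceedances (≥ with 1e-12
  slack); RC ties split 50/50 within 1e-12 on the Bray–Curtis value.
- βNTI null SD below 1e-12 → undefined pair, flagged and excluded.
- PCoA/projector ranks use SVD with machine-precision thresholds; all-zero
  samples, saturated models, single-level factors, constant distance
  matrices, and missing branch lengths raise immediately with the
  offending item named.

## Known limitations

- PERMANOVA permutations are free; designs needing restricted permutation
  (repeated measures, split plots) are out of scope.
- The RC null conditions on observed richness; very shallow samples make
  it coarse.
- dbMEM assumes sampling is dense enough that the MST truncation reflects
  neighborhood structure; with few, irregular samples the basis is crude.
- Negative-eigenvalue corrections for PCoA are not implemented; for
  strongly non-Euclidean dissimilarities inspect the logged negative
  eigenvalue magnitude.
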