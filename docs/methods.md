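# Methods

This note documents the models and procedures implemented in
`pchicstats`, the parameter defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
decisions taken where the design was genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model and conventions

All genomic intervals are 0-based half-open internally; TSV formats
carry 1-based inclusive positions except BED-like tables, which stay
0-based half-open. Restriction fragments tile each chromosome without
gaps; fragment ids are gap-free integers within a chromosome, so the
ordinal distance between two fragments is their id difference — the
blockshifter's "separated by at most one fragment" rule reduces to an id
gap of at most two. An interaction is a (bait fragment, other-end
fragment) pair with one CHiCAGO score per cell type; a score ≥ 5 in at
least one cell type marks it high-confidence, and the other ends of
high-confidence interactions are the promoter-interacting regions
(PIRs). Trans pairs carry an undefined (NaN) distance and are excluded
from every distance-conditioned operation (distance-matched
randomization, TAD crossing, PIR profiles); the exclusion is logged.

## Specificity scores

For a vector *x* of per-cell-type measurements, the specificity of cell
type *c* is the weighted mean of differences
s_c = Σ_{i≠c} d_{c,i}(x_c − x_i) / Σ_{i≠c} d_{c,i}, with d the Euclidean
distances between cell-type columns of the complete dataset on the same
scale as *x*. The statistic is translation-invariant and homogeneous of
degree one in *x* (property-tested). Derived quantities:

* *Cluster specificity*: *x* = per-cell-type mean asinh CHiCAGO score
  over the cluster's interactions; weights from the full asinh score
  matrix.
* *Gene specificity (enhancer interactions)*: interactions are kept when
  the bait maps to a unique captured gene and some cell type combines
  score ≥ 5 with an active enhancer at the other end; scores are zeroed
  where the enhancer is not active, asinh-transformed and capped at 4.3
  (raw-score equivalent sinh(4.3) ≈ 36.8; the cap stops extreme scores
  from dominating the Euclidean geometry); each interaction is scored
  and a gene's n_g interaction score vectors are averaged. Genes with
  zero qualifying interactions are excluded and reported. Weights come
  from the full asinh-capped score matrix; for expression specificity
  they come from the asinh-transformed full expression matrix (the
  alternative — distances on the raw scale — changes only the weighting,
  not the zero/center structure).
* *Cluster enrichment*: e_{c,k} = p_{c,k} − q_k, where p is the cluster
  composition of the 100 genes most specifically expressed in cell type
  c and q the composition of all analyzed genes; rows of e sum to zero
  and a random gene set has expectation zero.
* *Shared specificity at baits*: each interaction inherits the maximum
  cell-type specificity of its cluster; the observed per-bait variance
  of these values (baits with ≥ 2 interactions) is compared with a null
  that permutes cluster labels across interactions; the p-value is
  one-sided for variance reduction.

Gene partitioning uses k-means (best inertia over restarts,
deterministic given seed) with k = 12 by default. Interaction clusters
in this package are also k-means — a deliberate substitution for the
Bayesian mixture clustering used historically for interaction matrices;
cluster counts are configurable and nothing downstream depends on the
clustering algorithm, only on the gene→cluster map.

## TAD calling and crossing statistics

The directionality index (DI) of a 25-kb window (stepped every 5 kb)
contrasts the contact sums A (up to 1 Mb upstream) and B (downstream):
DI = sign(B − A)·[(A−E)²/E + (B−E)²/E], E = (A+B)/2, zero when A+B = 0.
Windows are clipped at matrix edges. The track is smoothed by a ±25-kb
moving average and standardized; boundaries are called between a
negative local extremum and the following positive one when both have
|z| > 0.5, at the smoothed-DI zero crossing (midpoint if no crossing).
On a constructed two-domain matrix the boundary is recovered within one
bin, and a distance-only (featureless) matrix yields none — edge windows
produce a positive-then-negative extremum sequence, which the
negative→positive rule correctly ignores. Replicate TAD sets are merged
by best reciprocal overlap: a TAD is kept only if every replicate has a
match covering ≥ 75 % of both intervals, and matched boundaries are
averaged (overlap-based matching was chosen over nearest-boundary
matching; both are defensible, one had to be fixed).

TAD crossing: for each bait inside a TAD, the (left flank, right flank)
distances to its TAD boundaries are recorded; an interaction crosses
when its signed distance exceeds either flank. The null permutes the
flank pairs jointly across baits (joint permutation preserves the
anti-correlation of the two flanks of a single bait; independent
permutation would break TAD widths), and the p-value is one-sided for
fewer crossings than expected.

## Distance-matched PIR randomization and feature enrichment

Randomized PIR sets reassign each cis PIR to a random non-PIR fragment
whose |midpoint − bait midpoint| falls in the same log₂ distance bin
(0.25 log₂ units wide; bin width is an implementation choice, narrow
enough that the distance histogram is preserved essentially exactly).
Candidates are drawn with probability proportional to fragment length:
real PIRs arise by containing an interaction end, which is a
length-biased event, and an unweighted draw would systematically pick
shorter fragments than the observed PIRs. A bin with no candidates is
widened once to its neighbours, then errors. Feature enrichment reports
fold = obs/mean and z = (obs − mean)/sd over the draws (100 by default).

Calibration caveat: because candidates exclude observed PIR fragments, a
"feature set" generated by the randomizer itself can never overlap the
observed PIRs — observed and randomized overlaps are then not
exchangeable and z is strongly negative by construction. The calibration
test therefore uses fragment-level features assigned independently of
PIR status, for which z is empirically standard normal.

## Overdispersion-adjusted chi-square

Interactions sharing a bait are correlated, so a naive χ² on pooled
2×2 tables is anticonservative. Baits are the resampling blocks: 1000
bootstrap replicates resample baits with replacement and rebuild the
table from per-bait additive contributions. The bootstrap tables are
recentered on the independence expectation (the observed association
offset, scaled to each bootstrap total, is subtracted and counts clipped
at zero) before their χ² values are computed: the uncentered bootstrap
spread contains the observed noncentrality (variance ≈ 2 + 4z² rather
than 2) and would over-correct precisely when there is signal. The
adjusted statistic is χ²_adj = χ²_raw·√2/sd(bootstrap χ²) with a 1-df
upper-tail p; under independent baits the factor is ≈ 1 (the 1-df χ²
variance is 2), and replicating every bait's observations k-fold
multiplies χ²_raw and sd(bootstrap χ²) by the same k, leaving χ²_adj
invariant — both properties are exercised in the test suite.

Two table modes are provided: promoter×enhancer activity over every
(interacting pair, cell type) combination, and enhancer-activity ×
interaction-presence over pairs with at least one high-confidence cell
type. Poised, repressed and inactive states pool as "non-active".

## eQTLs at PIRs

A gene is an overlap hit when its lead eQTL or any LD proxy
(r² ≥ 0.8 in the haplotype panel; lead-only when the lead is absent from
the panel) falls inside a PIR fragment interacting with that gene's
bait. The enrichment null transplants each gene's complete PIR offset
profile onto another gene's bait via a random derangement
(self-assignment excluded), mirroring offsets around the bait when donor
and recipient strands differ. This preserves exactly the number of
genes, the multiset of per-gene PIR counts and the multiset of
|bait→PIR| distances. Enrichment is reported overall and per distance
bin, in gene mode (proportion of genes hit) or SNP mode (proportion of
catalog SNPs inside PIRs that are eQTLs for the connected gene), with
Benjamini–Hochberg adjustment across bins.

Two p-values are reported. The add-one rule
p = (1 + #{perm ≥ obs})/(1 + n_perm) never understates significance but
is conservative when the discrete hit-count statistic ties with its
permutation replicates (its null mean exceeds 1/2 by about half the tie
probability). The mid-p companion gives ties half weight and is the
calibrated quantity: under the null its distribution is uniform, which
is what the calibration tests check. Decisions should quote the add-one
p; calibration diagnostics use the mid-p.

## GWAS preparation, fine mapping and gene scores

QC removes genome-wide-significant SNPs (p < 5×10⁻⁸) with no supporting
SNP, where a supporter has p < 10⁻⁵ and is within 50 kb *or* in LD
(r² > 0.6) with the index — the support condition is applied to both
arms. The MHC (GRCh37 chr6:25–35 Mb, inclusive bounds) is masked. The
genome is partitioned at 0.1-cM steps of the cumulative recombination
map (linear bp interpolation; the last block may be short; for SNP
assignment the outer blocks extend to ±∞ so every mapped position
belongs to a block).

PMI ("poor man's imputation") pairs, within each block, every reference
panel SNP with MAF > 1 % that lacks a study p-value with the study SNP
of maximal r²; when r²_max > 0.6 the p-value is copied and flagged
imputed, otherwise the SNP is discarded, and study SNPs absent from the
panel are discarded so the output maps entirely onto the panel.

Fine mapping assumes at most one causal variant per block. From the
two-sided p-value, z = |Φ⁻¹(p/2)| (the sign is unrecoverable and the ABF
depends only on z²); V = 1/(2nf(1−f)) for a quantitative trait, divided
by s(1−s) for a case-control study with case proportion s; the
approximate Bayes factor is ABF = √(V/(V+W))·exp(z²W/(2(V+W))) with
prior effect variance W = 0.2² by default (configurable; the standard
weakly-informative choice for this synthesis). Posteriors normalize the
ABF within each block; mass conservation holds to 10⁻¹². An optional
null model (Bayes factor 1 in the normalizer) is provided but off by
default. p = 0 is clamped to the smallest positive float.

COGS: per gene and block, three disjoint SNP sets are scored with
precedence coding > promoter > PIR — VEP-annotated coding SNPs of the
gene; SNPs in the bait fragment(s) plus exactly one flanking fragment
per side; and SNPs in fragments with score ≥ 5 in at least one tissue of
the set (trans PIRs included, falling in whatever block covers them).
The block score is the ppi sum over the union (clipped at 1), and
genescore = 1 − Π(1 − block score) under between-block independence —
verified exactly against brute-force survival-product enumeration.
Adding a tissue to the set can only add PIR fragments, so the genescore
is monotone in the tissue set (tested). The TAD baseline score applies
the same aggregation to block∩TAD intersections with coding SNPs
removed, assigns the score to genes with TSS in the TAD, and takes the
per-gene maximum over cell types. Prioritization keeps genes with score
> 0.5, ranked with ties broken by gene id.

## Blockshifter

Fragments in both the test and control PIR sets, or carrying no GWAS
posterior mass, are discarded; survivors form blocks of consecutive
fragments separated by at most one non-PIR fragment. δ is the difference
in mean per-fragment posterior mass (sum of ppi of SNPs in the fragment)
between test and control fragments. The null re-deals the labels of
unmixed blocks across unmixed blocks (preserving the observed count of
test/control unmixed blocks) and rotates each mixed block's label
sequence by an independent uniform offset, identity included (an
exclude-identity variant is available). Z = (δ − mean δ_null)/sd δ_null;
a zero-variance null (e.g. a single mixed block of identical masses) is
reported as Z = 0 with a degenerate flag. Label swap negates δ and Z
exactly for a fixed seed. Default n_perm = 10 000; the permutation loop
is vectorized (precomputed per-rotation test sums, one gather per
permutation), so 1000-permutation runs cost milliseconds. Expectation-
preserving sampling is used for the global test-fragment proportion; an
exact-proportion constraint was considered and rejected as it would
forbid most rotations of asymmetric mixed blocks.

## Synthetic data: what it emulates, what it does not

The generator produces every input format with the statistical structure
the analyses assume. Defaults define a desk-scale study: one 3-Mb
chromosome, exponential fragment lengths with mean 4096 bp, the
17-cell-type hematopoietic panel with its myeloid/lymphoid lineage
split, 40 captured genes with on average 4 interactions at log-normal
distances (median 150 kb), interaction clusters planted as
lineage-specific, invariant or single-cell-type with scores ≥ 5 in
member cell types, enhancer and promoter activity coupled to
high-confidence interactions at strength 0.8 (1 = deterministic
co-occurrence, 0 = independence), expression additive in the number of
interacting active enhancers plus Gaussian noise, 1200 panel SNPs (one
per 2.5 kb) over 120 mosaic-copying haplotypes from 8 founders with 40
template switches per cM (LD correlation length ≈ 25 kb, so association
signals are local on the 0.1-cM block scale), GWAS z-vectors drawn per
block from N(Σλ, Σ) with Σ the ridge-regularized (ε = 10⁻³) LD
correlation matrix and λ non-zero only at the planted causal SNP
(non-centrality 6), and lead eQTLs planted inside true PIRs for a
configured fraction of genes.

Deliberate non-realism: mosaic copying is not a population-genetic
model (no coalescent, no allele-frequency spectrum realism); z-scores
are simulated directly in z-space with unit variance (no phenotypes, V
taken as 1 in simulation); expression is Gaussian, not counts; there is
a single chromosome and no trans interactions by default. Passing tests
therefore demonstrate correctness and calibration of the statistical
machinery under the stated model, not robustness to real-data artifacts
(batch effects, mappability, reference bias, population structure).

Two placements deserve note. (1) Null eQTLs (the unplanted fraction)
are placed at a distance drawn from the pooled |bait→PIR| distance
distribution, uniformly on either side of the TSS and *irrespective of
PIR status*: this makes the observed gene–eQTL pairing exchangeable with
the bait-shift null, which is the property the calibration tests verify.
Forcing null eQTLs outside PIRs (available via `avoid_pirs=True`) makes
the observed overlap identically zero and every permutation p
conservative. (2) For recovery experiments the causal variant is planted
in a PIR fragment *exclusive* to one gene's footprint: a fragment shared
by several genes' PIRs or promoter regions genuinely supports all of
them — one regulatory element may serve several promoters — and cannot
define a single-gene truth.

## Problem sizes and determinism

Every stochastic operation takes an explicit seed; generators are
reproducible bit-for-bit and the pipeline manifest (config + seed)
reproduces outputs byte-wise. The shipped statistical checks use:
1000-block posterior conservation; ≤ 20-SNP/3-block COGS oracle toys;
200 null datasets (n_perm = 1000) for blockshifter Z moments, 500 for
type-I error, 100 seeds for power; 30 replicates for the
overdispersion factor; 100 seeds for lineage recovery (25 genes, 2-Mb
chromosome); 200 seeds for eQTL p-calibration (150 genes, 8-Mb
chromosome, n_perm = 199); and 100 end-to-end seeds for causal-gene
recovery with 30 % of study SNPs hidden and re-imputed. These sizes keep
the full suite at a few minutes on one CPU while leaving the Monte-Carlo
bands far narrower than the documented tolerances.

## Known limitations

* The interaction clustering is k-means on asinh scores, not a mixture
  model; cluster counts are user choices.
* `qc_filter` is O(index × support) pairwise; adequate for per-block or
  desk-scale tables, not optimized for millions of SNPs.
* The DI caller assumes a dense contact matrix per chromosome; there is
  no sparse-matrix path.
* LD computations load the haplotype matrix densely; panels beyond
  ~10⁵ SNPs × 10³ haplotypes would need a chunked implementation.
* Case-control V uses a single study-wide case proportion; per-SNP
  sample sizes are supported but per-SNP case proportions are not.
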