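# pchicstats

Statistics for promoter capture Hi-C (PCHi-C) interactomes.

Promoter capture Hi-C measures, for nearly every annotated promoter, which
distal restriction fragments it contacts in three-dimensional nuclear
space, one interactome per cell type. `pchicstats` implements the
statistical layer that turns such interactomes — a "peak matrix" of
CHiCAGO confidence scores over a hematopoietic cell-type panel — into
biology: cell-type specificity of interactions and genes, enrichment of
promoter-interacting regions (PIRs) for regulatory chromatin and eQTLs,
TAD structure, and the integration of GWAS summary statistics that
prioritizes putative disease genes. It is written for computational
genomicists who have interaction score matrices, GWAS summary statistics
and regulatory annotation in hand and want the full analysis chain as a
tested, reusable library with a CLI.

A synthetic-data module generates every input the pipeline consumes
(fragment maps, interactomes with planted cluster structure, LD-bearing
haplotype panels, GWAS z-scores with planted causal variants, eQTLs
planted in PIRs), so the whole pipeline runs and is testable without any
external download.

## What it computes

* **Specificity scores** (`specificity`). For measurements
  *x<sub>i</sub>* over cell types *i* (CHiCAGO scores, asinh expression),
  the specificity of cell type *c* is the weighted mean of differences

  *s<sub>c</sub>* = Σ<sub>i≠c</sub> *d<sub>c,i</sub>*(*x<sub>c</sub>* −
  *x<sub>i</sub>*) / Σ<sub>i≠c</sub> *d<sub>c,i</sub>*,

  with weights *d<sub>c,i</sub>* the Euclidean distances between
  cell-type columns of the complete dataset, so near-duplicate cell
  types (three macrophage states) do not dilute each other. Built on it:
  interaction-cluster specificity, per-gene specificity from
  interactions with active enhancers (asinh-transformed CHiCAGO scores
  capped at 4.3 ≈ raw score 36.8), expression specificity, gene-cluster
  enrichment *e<sub>c,k</sub>* = *p<sub>c,k</sub>* − *q<sub>k</sub>*,
  and a permutation test for shared specificity at a bait.

* **TADs and PIR enrichment** (`chromatin`). Directionality index from
  contact matrices (25-kb window / 5-kb step / ±1 Mb flanks), boundary
  calling between negative→positive extrema with |z| > 0.5, replicate
  merging by ≥75 % reciprocal overlap, TAD-crossing statistics with a
  flank-reshuffling null; distance-matched PIR randomization (log₂ bins)
  with feature-enrichment z-scores; and overdispersion-adjusted 2×2
  χ² tests (bait-level block bootstrap, χ² rescaled by √2/sd of 1000
  bootstrap χ² values) for enhancer-activity/interaction coupling.

* **eQTLs at PIRs** (`eqtl`). Lead-eQTL overlap with LD expansion
  (r² ≥ 0.8), the bait-shift randomization (each gene's PIR profile
  transplanted to another gene's bait, strand-mirrored), and
  distance-binned permutation enrichment.

* **GWAS integration** (`gwas_cogs`). Summary-statistic QC (unsupported
  p < 5×10⁻⁸ removed), MHC masking (GRCh37 chr6:25–35 Mb), 0.1-cM
  recombination blocks, LD-proxy p-value imputation (r²<sub>max</sub> >
  0.6), Wakefield approximate Bayes factors and per-block causal
  posteriors under at most one causal variant, the COGS gene score

  genescore = 1 − Π<sub>blocks</sub>(1 − Σ ppi over the gene's coding,
  promoter and PIR SNPs),

  and a TAD-level baseline score.

* **Blockshifter** (`blockshifter`). Competitive tissue-set enrichment
  of GWAS posterior mass at PIRs: δ = mean per-fragment posterior mass
  (test) − (control), with an empirical Z from a null that rotates
  labels within mixed PIR blocks and re-deals labels across unmixed
  blocks, respecting the spatial correlation of both GWAS and
  interaction data.

## Worked example

One line simulates a full study with a causal variant planted in one
gene's PIR, hides 30 % of the study SNPs, re-imputes them from the
haplotype panel, fine-maps and scores every gene:

```python
>>> from pchicstats import cli
>>> res = cli.cogs_recovery_trial(seed=1)
>>> res["target"], res["rank"], round(res["target_genescore"], 4)
('G002', 1, 1.0)
>>> res["scores"].head(3)[["gene_id", "n_blocks", "genescore"]]
  gene_id  n_blocks  genescore
0    G002         3     1.0000
1    G007         5     0.7631
2    G011         5     0.7458
```

The planted gene G002 ranks first with genescore 1.0: the causal SNP's
posterior mass falls almost entirely inside its PIR component, while the
runners-up collect only diffuse posterior mass from unassociated blocks.
The tissue-set enrichment test on a dataset with five-fold posterior mass
planted on test-tissue PIRs:

```python
>>> from pchicstats import synthetic_data as sd, blockshifter as bs
>>> t, c, mass = sd.simulate_pir_mass_dataset(seed=1, effect=5.0)
>>> r = bs.blockshifter_z(t, c, mass, n_perm=10_000, seed=2)
>>> round(r.delta, 4), round(r.z, 2)
(3.5681, 5.22)
```

δ is the excess mean posterior mass per test fragment; Z = 5.22 says the
excess is five null standard deviations above the rotation-permutation
expectation.

The same pipeline is scriptable from the shell:

```
pchicstats simulate --seed 7 --out bundle/
pchicstats pmi --gwas bundle/gwas.tsv --legend bundle/haplotypes.legend.tsv \
    --haplotypes bundle/haplotypes.matrix.txt --recomb-map bundle/recomb_map.tsv \
    --out imputed.tsv
pchicstats run --config config.yaml --out run/
```

Subcommands: `simulate`, `specificity`, `tads`, `enrich-features`,
`enrich-eqtl`, `pmi`, `cogs`, `tadscore`, `blockshifter`, `run`,
`report`. Every stochastic stage takes an explicit `--seed`; `run`
writes a manifest from which a run reproduces byte-wise.

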