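"""GWAS preparation, single-causal-variant fine mapping and gene scores.

Pipeline stages, in order:

1. **QC**: drop genome-wide-significant SNPs (p < 5e-8) with no supporting
   SNP — a supporter has p < 1e-5 and is either in LD (r^2 > 0.6) with, or
   within 50 kb of, the index SNP.  Mask the MHC (GRCh37 chr6:25-35 Mb).
2. **Blocks**: partition the genome at 0.1-cM steps of the cumulative
   recombination map; blocks are treated as independent association units.
3. **PMI** ("poor man's imputation"): within each block, every reference
   panel SNP (MAF > 1%) lacking a study p-value inherits the p-value of
   its maximum-r^2 study partner when r^2_max > 0.6; study SNPs absent
   from the panel are discarded.
4. **Posteriors**: per SNP, the approximate Bayes factor
   ``ABF = sqrt(V/(V+W)) * exp(z^2 W / (2(V+W)))`` with ``V = 1/(2 n f(1-f))``
   (times ``1/(s(1-s))`` for case-control studies) and prior effect
   variance ``W`` (default 0.2^2); normalizing within a block under the
   at-most-one-causal-variant assumption gives each SNP's posterior
   probability of being causal (ppi).
5. **COGS**: a gene's block score sums the ppi over its coding, promoter
   (bait fragment +/- one flanking fragment) and tissue-set PIR SNPs
   (disjoint, precedence coding > promoter > PIR); block scores combine
   under between-block independence as
   ``genescore = 1 - prod(1 - genescore_block)``.
6. **TAD baseline**: same posterior aggregation over TAD-by-block
   intersections (coding SNPs removed), assigned to every gene whose TSS
   lies in the TAD, maximized over cell types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FragmentMap, GeneModel, HaplotypePanel, InteractionSet, RecombMap

__all__ = [
    "MHC_REGION",
    "qc_filter",
    "mask_region",
    "RecombBlock",
    "partition_blocks",
    "assign_blocks",
    "pmi_impute",
    "FineMapConfig",
    "wakefield_abf",
    "wakefield_posteriors",
    "gene_components",
    "CogsResult",
    "cogs_score",
    "cogs_scores",
    "tad_score",
    "prioritize",
]

MHC_REGION = ("chr6", 25_000_000, 35_000_000)  # GRCh37


# ---------------------------------------------------------------------------
# summary-statistic QC
# ---------------------------------------------------------------------------

def qc_filter(gwas: pd.DataFrame, panel: HaplotypePanel | None = None,
              p_index: float = 5e-8, p_support: float = 1e-5,
              r2_support: float = 0.6, window: int = 50_000) -> pd.DataFrame:
    """Remove SNPs with spuriously strong association.

    An index SNP (p < ``p_index``) is kept only if some other SNP with
    p < ``p_support`` either lies within ``window`` bp of it or is in LD
    with it (r^2 > ``r2_support``; LD arm active only when a panel is
    supplied and both SNPs map to it).
    """
    p = gwas["p"].to_numpy(dtype=float)
    pos = gwas["pos"].to_numpy()
    chrom = gwas["chrom"].to_numpy()
    index_rows = np.flatnonzero(p < p_index)
    support_rows = np.flatnonzero(p < p_support)

    panel_row = None
    if panel is not None:
        key = {(c, int(q)): i for i, (c, q) in
               enumerate(zip(panel.legend["chrom"], panel.legend["pos"]))}
        panel_row = [key.get((c, int(q))) for c, q in zip(chrom, pos)]

    drop = np.zeros(len(gwas), dtype=bool)
    for i in index_rows:
        others = support_rows[support_rows != i]
        if not len(others):
            drop[i] = True
            continue
        near = (chrom[others] == chrom[i]) & (np.abs(pos[others] - pos[i]) <= window)
        if near.any():
            continue
        linked = False
        if panel_row is not None and panel_row[i] is not None:
            from .core_io import r_squared_profile
            try:
                r2 = r_squared_profile(panel, panel_row[i])
            except ValueError:
                r2 = None
            if r2 is not None:
                for j in others:
                    pj = panel_row[j]
                    if pj is not None and np.isfinite(r2[pj]) and r2[pj] > r2_support:
                        linked = True
                        break
        drop[i] = not linked
    return gwas.loc[~drop].reset_index(drop=True)


def mask_region(gwas: pd.DataFrame, region: tuple[str, int, int] = MHC_REGION) -> pd.DataFrame:
    """Drop SNPs inside a region (default: the MHC, chr6:25-35 Mb)."""
    chrom, start, end = region
    inside = (gwas["chrom"] == chrom) & (gwas["pos"] >= start) & (gwas["pos"] <= end)
    return gwas.loc[~inside].reset_index(drop=True)


# ---------------------------------------------------------------------------
# recombination blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecombBlock:
    block_id: int
    start: float     # bp, inclusive
    end: float       # bp, exclusive (inf for the last block)
    cm_start: float
    cm_end: float


def partition_blocks(rmap: RecombMap, step: float = 0.1) -> list[RecombBlock]:
    """Cut the cumulative genetic map at multiples of ``step`` cM.

    Block boundaries are the bp positions where the cumulative map crosses
    k * step (linear interpolation); the last block may span less than a
    full step.  For SNP assignment the first block opens at -inf and the
    last closes at +inf, so every mapped position belongs to a block.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    total = rmap.total_cm
    cm0 = float(rmap.cum_cm[0])
    n_blocks = max(int(np.ceil(total / step - 1e-12)), 1)
    cuts_cm = cm0 + step * np.arange(1, n_blocks)
    cuts_bp = np.interp(cuts_cm, rmap.cum_cm, rmap.positions)
    edges_bp = np.concatenate([[-np.inf], cuts_bp, [np.inf]])
    edges_cm = np.concatenate([[cm0], cuts_cm, [cm0 + total]])
    return [
        RecombBlock(i, edges_bp[i], edges_bp[i + 1], edges_cm[i], edges_cm[i + 1])
        for i in range(n_blocks)
    ]


def assign_blocks(pos, blocks: list[RecombBlock]) -> np.ndarray:
    """Block id for each bp position."""
    edges = np.array([b.start for b in blocks[1:]])
    return np.searchsorted(edges, np.asarray(pos, dtype=float), side="right")


# ---------------------------------------------------------------------------
# poor man's imputation
# ---------------------------------------------------------------------------

def pmi_impute(gwas: pd.DataFrame, panel: HaplotypePanel,
               blocks: list[RecombBlock], r2_min: float = 0.6,
               maf_min: float = 0.01) -> pd.DataFrame:
    """Transfer p-values to untyped panel SNPs from their best-LD partner.

    Per block: panel SNPs with MAF > ``maf_min`` that lack a study p-value
    are paired with the study SNP of maximal r^2; the p-value is copied
    (flag ``imputed``) when r^2_max > ``r2_min``, otherwise the SNP is
    discarded.  Study SNPs absent from the panel are discarded, so the
    output maps entirely onto the reference panel.
    """
    legend = panel.legend
    maf = panel.maf()
    key = {(c, int(q)): i for i, (c, q) in enumerate(zip(legend["chrom"], legend["pos"]))}
    study_row = np.array([key.get((c, int(q)), -1)
                          for c, q in zip(gwas["chrom"], gwas["pos"])])
    typed = study_row >= 0
    typed_gwas = gwas.loc[typed].reset_index(drop=True)
    typed_panel_rows = study_row[typed]

    block_of = assign_blocks(legend["pos"].to_numpy(), blocks)
    typed_mask = np.zeros(panel.n_snps, dtype=bool)
    typed_mask[typed_panel_rows] = True
    p_of_row = np.full(panel.n_snps, np.nan)
    p_of_row[typed_panel_rows] = typed_gwas["p"].to_numpy(dtype=float)
    n_col = typed_gwas["n"] if "n" in typed_gwas.columns else pd.Series(np.nan, index=typed_gwas.index)
    n_of_row = np.full(panel.n_snps, np.nan)
    n_of_row[typed_panel_rows] = n_col.to_numpy(dtype=float)

    out_rows = [typed_gwas.assign(imputed=False,
                                  maf=maf[typed_panel_rows],
                                  snp_id=legend["snp_id"].to_numpy()[typed_panel_rows])]
    H = panel.H.astype(float)
    for block_id in np.unique(block_of):
        rows = np.flatnonzero(block_of == block_id)
        typed_here = rows[typed_mask[rows]]
        missing = rows[~typed_mask[rows] & (maf[rows] > maf_min)]
        if not len(missing) or not len(typed_here):
            continue
        A = H[missing] - H[missing].mean(axis=1, keepdims=True)
        B = H[typed_here] - H[typed_here].mean(axis=1, keepdims=True)
        na = np.sqrt((A ** 2).sum(axis=1))
        nb = np.sqrt((B ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = ((A @ B.T) / np.outer(na, nb)) ** 2
        r2 = np.nan_to_num(r2, nan=0.0)
        best = r2.argmax(axis=1)
        best_r2 = r2[np.arange(len(missing)), best]
        ok = best_r2 > r2_min
        if not ok.any():
            continue
        src = typed_here[best[ok]]
        dst = missing[ok]
        out_rows.append(pd.DataFrame({
            "chrom": legend["chrom"].to_numpy()[dst],
            "pos": legend["pos"].to_numpy()[dst],
            "a1": legend["a0"].to_numpy()[dst],
            "a2": legend["a1"].to_numpy()[dst],
            "maf": maf[dst],
            "p": p_of_row[src],
            "n": n_of_row[src],
            "imputed": True,
            "snp_id": legend["snp_id"].to_numpy()[dst],
        }))
    out = pd.concat(out_rows, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Wakefield posteriors
# ---------------------------------------------------------------------------

@dataclass
class FineMapConfig:
    """Single-causal-variant fine-mapping settings.

    ``W`` is the prior variance of the causal effect (default 0.2^2);
    ``cc_ratio`` switches V to the case-control form.  ``include_null``
    adds a no-causal-variant model with Bayes factor 1 to the normalizer
    (off by default: posteriors then sum to one over SNPs).
    """

    W: float = 0.04
    cc_ratio: float | None = None
    include_null: bool = False

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("prior variance W must be positive")


def wakefield_abf(z: np.ndarray, V: np.ndarray, W: float = 0.04) -> np.ndarray:
    """Approximate Bayes factor for association (H1 over H0)."""
    z = np.asarray(z, dtype=float)
    V = np.asarray(V, dtype=float)
    return np.sqrt(V / (V + W)) * np.exp(z * z * W / (2.0 * (V + W)))


def wakefield_posteriors(gwas: pd.DataFrame, blocks: list[RecombBlock],
                         cfg: FineMapConfig | None = None) -> pd.DataFrame:
    """Per-block causal posterior probabilities from p, MAF and n.

    z is recovered as |Phi^-1(p/2)| (the sign is unrecoverable from p and
    the ABF depends only on z^2); ``V = 1/(2 n f(1-f))`` for a
    quantitative trait or ``1/(2 n f(1-f) s(1-s))`` for a case-control
    study with case proportion s.  ppi normalizes the ABF within each
    block.  p = 0 is clamped to the smallest positive float.
    """
    cfg = cfg or FineMapConfig()
    maf = gwas["maf"].to_numpy(dtype=float)
    if np.any(~np.isfinite(maf)) or np.any(maf <= 0):
        raise ValueError("every SNP needs a positive MAF")
    p = np.clip(gwas["p"].to_numpy(dtype=float), np.finfo(float).tiny, 1.0)
    n = gwas["n"].to_numpy(dtype=float) if "n" in gwas.columns else np.full(len(gwas), np.nan)
    if np.any(~np.isfinite(n)):
        raise ValueError("every SNP needs a sample size n")
    z = np.abs(stats.norm.isf(p / 2.0))
    V = 1.0 / (2.0 * n * maf * (1.0 - maf))
    if cfg.cc_ratio is not None:
        s = cfg.cc_ratio
        V = V / (s * (1.0 - s))
    abf = wakefield_abf(z, V, cfg.W)
    block = assign_blocks(gwas["pos"].to_numpy(), blocks)
    out = gwas.copy()
    out["z_abs"] = z
    out["abf"] = abf
    out["block"] = block
    denom = out.groupby("block")["abf"].transform("sum")
    if cfg.include_null:
        denom = denom + 1.0
    out["ppi"] = out["abf"] / denom
    return out


# ---------------------------------------------------------------------------
# COGS gene scores
# ---------------------------------------------------------------------------

def gene_components(gene: GeneModel, iset: InteractionSet,
                    tissues: list[str], coding: pd.DataFrame,
                    fragment_map: FragmentMap, snp_table: pd.DataFrame,
                    threshold: float = 5.0) -> dict[str, set[str]]:
    """The three disjoint SNP sets scored for a gene.

    coding: VEP-annotated coding SNPs of the gene; promoter: SNPs in the
    bait fragment(s) plus one flanking fragment per side, minus coding;
    pir: SNPs in fragments interacting with the gene's bait at score >=
    ``threshold`` in at least one tissue of the set, minus coding and
    promoter.  ``snp_table`` needs snp_id, chrom, pos.
    """
    snp_ids = snp_table["snp_id"].to_numpy()
    coding_set = set(coding.loc[coding["gene_id"] == gene.gene_id, "snp_id"]) & set(snp_ids)

    prom_frags: set[int] = set()
    for fid in gene.bait_frag_ids:
        prom_frags.update((fid - 1, fid, fid + 1))
    valid = set(fragment_map.table["frag_id"].tolist())
    prom_frags &= valid

    tbl = iset.table
    mask = tbl["baitName"] == gene.gene_id
    if tissues:
        cols = [c for c in tissues if c in iset.cell_types]
        hc = (tbl.loc[mask, cols].to_numpy(dtype=float) >= threshold).any(axis=1) \
            if cols else np.zeros(mask.sum(), dtype=bool)
    else:
        hc = np.zeros(int(mask.sum()), dtype=bool)
    pir_frags = set(int(f) for f in tbl.loc[mask, "oeID"].to_numpy()[hc])

    def snps_in_frags(frags: set[int]) -> set[str]:
        if not frags:
            return set()
        hits = set()
        iv = fragment_map.intervals(sorted(frags))
        for chrom, grp in iv.groupby("chrom"):
            sub = snp_table[snp_table["chrom"] == chrom]
            pos = sub["pos"].to_numpy()
            ids = sub["snp_id"].to_numpy()
            for s, e in zip(grp["start"], grp["end"]):
                hits.update(ids[(pos >= s) & (pos < e)])
        return hits

    promoter_set = snps_in_frags(prom_frags) - coding_set
    pir_set = snps_in_frags(pir_frags) - coding_set - promoter_set
    return {"coding": coding_set, "promoter": promoter_set, "pir": pir_set}


@dataclass
class CogsResult:
    gene_id: str
    tissues: tuple[str, ...]
    genescore: float
    block_scores: pd.DataFrame = field(repr=False)  # block, coding, promoter, pir, score


def cogs_score(gene_id: str, posteriors: pd.DataFrame,
               components: dict[str, set[str]],
               tissues: tuple[str, ...] = ()) -> CogsResult:
    """Aggregate causal posteriors over a gene's SNP components.

    Per block, the block gene score sums ppi over the union of the three
    component sets; blocks combine under independence:
    ``genescore = 1 - prod_b (1 - score_b)``.
    """
    comp_of = {}
    for name, snps in components.items():
        for s in snps:
            comp_of[s] = name
    sub = posteriors[posteriors["snp_id"].isin(comp_of)].copy()
    if len(sub):
        sub["component"] = sub["snp_id"].map(comp_of)
        per = sub.pivot_table(index="block", columns="component", values="ppi",
                              aggfunc="sum").reindex(
            columns=["coding", "promoter", "pir"], fill_value=0.0).fillna(0.0)
    else:
        per = pd.DataFrame(columns=["coding", "promoter", "pir"])
    per["score"] = per.sum(axis=1).clip(upper=1.0)
    genescore = 1.0 - np.prod(1.0 - per["score"].to_numpy()) if len(per) else 0.0
    return CogsResult(gene_id, tuple(tissues), float(genescore),
                      per.reset_index().rename(columns={"index": "block"}))


def cogs_scores(gene_models: list[GeneModel], posteriors: pd.DataFrame,
                iset: InteractionSet, coding: pd.DataFrame,
                fragment_map: FragmentMap, tissues: list[str],
                threshold: float = 5.0) -> pd.DataFrame:
    """COGS gene scores for every captured gene under one tissue set."""
    snp_table = posteriors[["snp_id", "chrom", "pos"]]
    rows = []
    for gene in gene_models:
        comp = gene_components(gene, iset, tissues, coding, fragment_map,
                               snp_table, threshold)
        res = cogs_score(gene.gene_id, posteriors, comp, tuple(tissues))
        rows.append((gene.gene_id, ",".join(tissues) or "none",
                     len(res.block_scores), res.genescore,
                     sum(res.block_scores["coding"]) if len(res.block_scores) else 0.0,
                     sum(res.block_scores["promoter"]) if len(res.block_scores) else 0.0,
                     sum(res.block_scores["pir"]) if len(res.block_scores) else 0.0))
    return pd.DataFrame(rows, columns=["gene_id", "tissue_set", "n_blocks",
                                       "genescore", "coding", "promoter", "pir"])


# ---------------------------------------------------------------------------
# TAD-based baseline score
# ---------------------------------------------------------------------------

def tad_score(tad_sets: dict[str, pd.DataFrame], posteriors: pd.DataFrame,
              coding_snp_ids: set[str],
              gene_models: list[GeneModel]) -> pd.DataFrame:
    """TAD-level posterior aggregation as a gene-prioritization baseline.

    For each cell type's TAD set: within each TAD, posteriors of
    non-coding SNPs are summed per recombination block
    (``TADscore_block``) and combined as
    ``TAD.score = 1 - prod(1 - TADscore_block)``; every gene whose TSS
    falls inside the TAD inherits the score.  The per-gene result is the
    maximum over cell types (NaN when the TSS is in no TAD anywhere).
    """
    post = posteriors[~posteriors["snp_id"].isin(coding_snp_ids)]
    gene_best: dict[str, float] = {}
    for cell_type, tads in tad_sets.items():
        for row in tads.itertuples(index=False):
            sub = post[(post["chrom"] == row.chrom)
                       & (post["pos"] >= row.start) & (post["pos"] < row.end)]
            if len(sub):
                block_mass = sub.groupby("block")["ppi"].sum().clip(upper=1.0)
                score = 1.0 - np.prod(1.0 - block_mass.to_numpy())
            else:
                score = 0.0
            for gene in gene_models:
                if gene.chrom == row.chrom and row.start <= gene.tss < row.end:
                    gene_best[gene.gene_id] = max(gene_best.get(gene.gene_id, 0.0),
                                                  float(score))
    return pd.DataFrame({
        "gene_id": [g.gene_id for g in gene_models],
        "tad_score": [gene_best.get(g.gene_id, np.nan) for g in gene_models],
    })


def prioritize(results: pd.DataFrame, threshold: float = 0.5,
               score_col: str = "genescore") -> pd.DataFrame:
    """Genes with score above threshold, ranked (ties broken by gene id)."""
    if not len(results):
        return results
    out = results[results[score_col] > threshold]
    return out.sort_values([score_col, "gene_id"], ascending=[False, True],
                           kind="stable").reset_index(drop=True)
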