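"""Synthetic input generator for the whole pipeline.

Every analysis stage in this package was designed for promoter capture Hi-C
interactomes over a hematopoietic cell-type panel, together with GWAS
summary statistics, a haplotype reference panel and regulatory annotation.
This module generates all of those inputs with the statistical structure
the analyses assume, so the full pipeline is testable without any download:

* a restriction-fragment map emulating HindIII digestion (exponential
  fragment lengths, mean 4096 bp);
* an interactome with planted lineage-specific / invariant interaction
  clusters, distal-enhancer activity coupled to interactions, and gene
  expression additive in the number of interacting active enhancers;
* mosaic-copying haplotypes whose LD decays with genetic distance, plus a
  recombination map;
* per-block GWAS z-scores under at most one causal variant per
  recombination block (z drawn directly in z-space from N(SIGMA @ lambda,
  SIGMA));
* lead eQTLs planted inside promoter-interacting regions.

All generators are deterministic given ``SimConfig.seed``; planted truth is
returned alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    FragmentMap,
    GeneModel,
    HaplotypePanel,
    InteractionSet,
    RecombMap,
)

__all__ = [
    "SimConfig",
    "DEFAULT_CELL_TYPES",
    "DEFAULT_LINEAGES",
    "simulate_fragment_map",
    "simulate_interactome",
    "simulate_haplotype_panel",
    "simulate_gwas",
    "plant_eqtls",
    "simulate_pir_mass_dataset",
]

# The 17-cell-type hematopoietic panel used throughout, with its lineage
# assignment (megakaryocyte/erythroid/myeloid vs lymphoid; endothelial
# precursors sit outside both lineages).
DEFAULT_CELL_TYPES = [
    "MK", "Ery", "Neu", "Mon", "Mac0", "Mac1", "Mac2", "EndP",
    "nB", "tB", "FetT", "nCD4", "tCD4", "naCD4", "aCD4", "nCD8", "tCD8",
]
DEFAULT_LINEAGES = {
    "MK": "myeloid", "Ery": "myeloid", "Neu": "myeloid", "Mon": "myeloid",
    "Mac0": "myeloid", "Mac1": "myeloid", "Mac2": "myeloid",
    "EndP": "other",
    "nB": "lymphoid", "tB": "lymphoid", "FetT": "lymphoid",
    "nCD4": "lymphoid", "tCD4": "lymphoid", "naCD4": "lymphoid",
    "aCD4": "lymphoid", "nCD8": "lymphoid", "tCD8": "lymphoid",
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are desk-scale: a single 3-Mb chromosome keeps every stage
    (including 1000-fold permutation nulls) fast while preserving the
    statistical structure of the full-genome analyses.
    """

    seed: int
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 3_000_000})
    mean_fragment_len: int = 4096          # HindIII expectation
    cell_types: list[str] = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))
    lineages: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LINEAGES))
    n_genes: int = 40
    mean_interactions_per_gene: float = 4.0
    interaction_dist_scale: float = 150_000.0  # median |bait -> PIR| distance, bp
    cluster_probs: dict[str, float] = field(default_factory=lambda: {
        "invariant": 0.15, "myeloid": 0.35, "lymphoid": 0.35, "single": 0.15,
    })
    coupling: float = 0.8                  # enhancer-activity / interaction coupling
    baseline_active_prob: float = 0.3
    expr_effect: float = 1.0
    expr_noise: float = 0.5
    n_haplotypes: int = 120
    n_founders: int = 8
    n_snps: int = 1200
    switch_rate: float = 40.0              # mosaic switches per cM
    mutation_rate: float = 0.002
    cm_per_mb: float = 1.0
    ncp: float = 6.0                       # causal-SNP non-centrality
    gwas_n: int = 10_000
    eqtl_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling strength must lie in [0, 1]")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even")
        for name, value in (("n_genes", self.n_genes), ("n_snps", self.n_snps),
                            ("n_haplotypes", self.n_haplotypes),
                            ("mean_fragment_len", self.mean_fragment_len)):
            if value <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, salt)))


# ---------------------------------------------------------------------------
# fragment map
# ---------------------------------------------------------------------------

def simulate_fragment_map(cfg: SimConfig, rng: np.random.Generator | None = None) -> FragmentMap:
    """Emulate restriction digestion: cut sites with exponential spacing."""
    rng = cfg.rng(1) if rng is None else rng
    rows = []
    next_id = 0
    for chrom, length in cfg.chrom_lengths.items():
        cuts = []
        pos = 0.0
        while True:
            pos += rng.exponential(cfg.mean_fragment_len)
            if pos >= length - 1:
                break
            if int(pos) > 0:
                cuts.append(int(pos))
        bounds = np.array([0, *dict.fromkeys(cuts), length], dtype=np.int64)
        for start, end in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(start), int(end), next_id, False))
            next_id += 1
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "frag_id", "is_bait"])
    return FragmentMap(table)


# ---------------------------------------------------------------------------
# interactome + regulatory states + expression
# ---------------------------------------------------------------------------

def _cluster_members(cfg: SimConfig, kind: str, single_ct: str | None) -> np.ndarray:
    names = cfg.cell_types
    if kind == "invariant":
        return np.ones(len(names), dtype=bool)
    if kind == "single":
        return np.array([c == single_ct for c in names])
    return np.array([cfg.lineages.get(c) == kind for c in names])


def simulate_interactome(cfg: SimConfig, fragment_map: FragmentMap,
                         rng: np.random.Generator | None = None):
    """Generate an interactome with planted cell-type-specificity structure.

    Returns ``(interactions, reg_states, expression, gene_models, truth)``:

    * ``interactions`` — :class:`InteractionSet` whose CHiCAGO scores are
      high (>= 5) in the member cell types of each interaction's planted
      cluster and low elsewhere;
    * ``reg_states`` — regulatory-state table: an active promoter feature
      per bait and a distal enhancer per interacting fragment whose
      activity co-occurs with high scores at strength ``cfg.coupling``
      (coupling 1 = deterministic co-occurrence, 0 = independence);
    * ``expression`` — genes x cell types, additive in the number of
      interacting active enhancers plus Gaussian noise;
    * ``gene_models`` — one captured gene per bait;
    * ``truth`` — planted cluster kind and member mask per interaction.
    """
    rng = cfg.rng(2) if rng is None else rng
    names = cfg.cell_types
    n_ct = len(names)

    frag_table = fragment_map.table
    chrom = frag_table["chrom"].iloc[0]
    chrom_len = fragment_map.chrom_length(chrom)
    n_frags = len(frag_table)
    if cfg.n_genes >= n_frags:
        raise ValueError("more genes than fragments")
    f_start = frag_table["start"].to_numpy()
    f_end = frag_table["end"].to_numpy()
    f_id = frag_table["frag_id"].to_numpy()
    f_mid = 0.5 * (f_start + f_end)
    row_of = {int(i): r for r, i in enumerate(f_id)}

    # evenly spread bait fragments with jitter, away from chromosome ends
    anchor = np.linspace(0.05, 0.95, cfg.n_genes) * n_frags
    bait_idx = np.unique((anchor + rng.integers(-2, 3, cfg.n_genes)).clip(0, n_frags - 1).astype(int))
    while len(bait_idx) < cfg.n_genes:
        extra = rng.integers(0, n_frags, cfg.n_genes - len(bait_idx))
        bait_idx = np.unique(np.concatenate([bait_idx, extra]))
    bait_frag_ids = frag_table["frag_id"].to_numpy()[bait_idx]

    gene_models = []
    for g, fid in enumerate(bait_frag_ids):
        strand = "+" if rng.random() < 0.5 else "-"
        gene_models.append(GeneModel(f"G{g:03d}", chrom, strand,
                                     int(f_mid[row_of[int(fid)]]), (int(fid),)))

    kinds = list(cfg.cluster_probs)
    probs = np.array([cfg.cluster_probs[k] for k in kinds], dtype=float)
    probs = probs / probs.sum()

    member_masks = {k: _cluster_members(cfg, k, None) for k in kinds if k != "single"}
    rows, score_rows, truth_rows = [], [], []
    bait_set = set(int(f) for f in bait_frag_ids)
    for gene in gene_models:
        brow = row_of[gene.bait_frag_ids[0]]
        bait_mid = f_mid[brow]
        k = 1 + rng.poisson(max(cfg.mean_interactions_per_gene - 1.0, 0.0))
        used: set[int] = set(gene.bait_frag_ids)
        for _ in range(k):
            for _attempt in range(20):
                d = rng.lognormal(np.log(cfg.interaction_dist_scale), 0.8)
                d *= rng.choice([-1.0, 1.0])
                pos = int(bait_mid + d)
                if not (0 <= pos < chrom_len):
                    continue
                orow = int(np.searchsorted(f_start, pos, side="right")) - 1
                oe_id = int(f_id[orow])
                if oe_id in used:
                    continue
                used.add(oe_id)
                break
            else:
                continue
            kind = kinds[rng.choice(len(kinds), p=probs)]
            single_ct = names[rng.integers(n_ct)] if kind == "single" else None
            members = (member_masks[kind] if single_ct is None
                       else _cluster_members(cfg, kind, single_ct))
            scores = np.minimum(rng.exponential(0.8, n_ct), 4.99)
            scores[members] = 5.0 + rng.exponential(3.0, members.sum())
            rows.append((chrom, f_start[brow], f_end[brow], f_id[brow], gene.gene_id,
                         chrom, f_start[orow], f_end[orow], oe_id, ".",
                         f_mid[orow] - bait_mid))
            score_rows.append(scores)
            truth_rows.append((gene.gene_id, oe_id,
                               kind if single_ct is None else f"single:{single_ct}",
                               members.copy()))

    table = pd.DataFrame(rows, columns=[
        "baitChr", "baitStart", "baitEnd", "baitID", "baitName",
        "oeChr", "oeStart", "oeEnd", "oeID", "oeName", "dist"])
    scores = np.array(score_rows)
    for j, name in enumerate(names):
        table[name] = scores[:, j]
    interactions = InteractionSet(table, names)

    # regulatory features: one promoter per bait and one distal enhancer per
    # unique interacting fragment, both with activity coupled to the
    # fragment's high-confidence interactions at strength cfg.coupling
    def coupled_states(hi: np.ndarray) -> np.ndarray:
        p_active = np.where(
            hi, cfg.baseline_active_prob + cfg.coupling * (1 - cfg.baseline_active_prob),
            cfg.baseline_active_prob * (1 - cfg.coupling))
        active = rng.random(n_ct) < p_active
        return np.where(active, "active",
                        rng.choice(["poised", "repressed", "inactive"], n_ct))

    feat_rows = []
    bait_max = {fid: np.zeros(n_ct) for fid in sorted(bait_set)}
    oe_ids = sorted(set(table["oeID"]))
    max_scores = {fid: np.zeros(n_ct) for fid in oe_ids}
    for bid, fid, sc in zip(table["baitID"], table["oeID"], scores):
        bait_max[bid] = np.maximum(bait_max[bid], sc)
        max_scores[fid] = np.maximum(max_scores[fid], sc)
    for fid in sorted(bait_set):
        r = row_of[fid]
        feat_rows.append((chrom, f_start[r], f_end[r], f"prom_{fid}", 0, ".",
                          "promoter", *coupled_states(bait_max[fid] >= 5.0)))
    enh_active: dict[int, np.ndarray] = {}
    for fid in oe_ids:
        r = row_of[fid]
        states = coupled_states(max_scores[fid] >= 5.0)
        enh_active[fid] = states == "active"
        feat_rows.append((chrom, f_start[r], f_end[r], f"enh_{fid}", 0, ".",
                          "distal_enhancer", *states))
    reg_states = pd.DataFrame(feat_rows, columns=[
        "chrom", "start", "end", "name", "score", "strand", "feature_class", *names])

    # expression: additive in the number of interacting active enhancers
    n_active_by_gene = {g.gene_id: np.zeros(n_ct) for g in gene_models}
    for gid, fid, sc in zip(table["baitName"], table["oeID"], scores):
        n_active_by_gene[gid] += (sc >= 5.0) & enh_active[fid]
    expr = np.zeros((len(gene_models), n_ct))
    for i, gene in enumerate(gene_models):
        expr[i] = (1.0 + cfg.expr_effect * n_active_by_gene[gene.gene_id]
                   + rng.normal(0, cfg.expr_noise, n_ct))
    expression = pd.DataFrame(expr, index=[g.gene_id for g in gene_models], columns=names)

    truth = pd.DataFrame({
        "gene_id": [t[0] for t in truth_rows],
        "oe_frag": [t[1] for t in truth_rows],
        "cluster": [t[2] for t in truth_rows],
    })
    truth_members = np.array([t[3] for t in truth_rows])

    fm_table = fragment_map.table.copy()
    fm_table["is_bait"] = fm_table["frag_id"].isin(bait_set)
    return interactions, reg_states, expression, gene_models, {
        "clusters": truth,
        "members": truth_members,
        "fragment_map": FragmentMap(fm_table),
    }


# ---------------------------------------------------------------------------
# haplotypes + recombination map
# ---------------------------------------------------------------------------

def simulate_haplotype_panel(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Mosaic-copying haplotypes with LD decaying in genetic distance.

    Each haplotype copies a random founder, re-choosing its template at
    each inter-SNP interval with probability ``1 - exp(-switch_rate * dcM)``.
    This is cheap and produces r^2 decay with genetic distance; it matches
    no explicit population-genetic model.
    """
    rng = cfg.rng(3) if rng is None else rng
    chrom, length = next(iter(cfg.chrom_lengths.items()))
    pos = np.sort(rng.choice(np.arange(100, length - 100), cfg.n_snps, replace=False))

    rates = rng.exponential(cfg.cm_per_mb, cfg.n_snps - 1)  # cM/Mb per interval
    dcm = rates * np.diff(pos) / 1e6
    cum_cm = np.concatenate([[0.0], np.cumsum(dcm)])
    rmap = RecombMap(pos, cum_cm)

    freqs = rng.uniform(0.1, 0.9, cfg.n_snps)
    founders = (rng.random((cfg.n_founders, cfg.n_snps)) < freqs).astype(np.int8)

    p_switch = 1.0 - np.exp(-cfg.switch_rate * dcm)
    H = np.empty((cfg.n_snps, cfg.n_haplotypes), dtype=np.int8)
    for h in range(cfg.n_haplotypes):
        switches = rng.random(cfg.n_snps - 1) < p_switch
        template = np.empty(cfg.n_snps, dtype=np.int64)
        cur = rng.integers(cfg.n_founders)
        template[0] = cur
        for i, sw in enumerate(switches, start=1):
            if sw:
                cur = rng.integers(cfg.n_founders)
            template[i] = cur
        hap = founders[template, np.arange(cfg.n_snps)]
        if cfg.mutation_rate > 0:
            flips = rng.random(cfg.n_snps) < cfg.mutation_rate
            hap = np.where(flips, 1 - hap, hap)
        H[:, h] = hap

    legend = pd.DataFrame({
        "snp_id": [f"snp{i:05d}" for i in range(cfg.n_snps)],
        "chrom": chrom,
        "pos": pos,
        "a0": "A",
        "a1": "G",
    })
    return HaplotypePanel(legend, H), rmap


# ---------------------------------------------------------------------------
# GWAS z-scores under a single causal variant per block
# ---------------------------------------------------------------------------

def simulate_gwas(panel: HaplotypePanel, rmap: RecombMap,
                  planted: dict[int, tuple[int, float]] | None,
                  cfg: SimConfig, rng: np.random.Generator | None = None,
                  ridge: float = 1e-3) -> pd.DataFrame:
    """Draw per-block z-vectors from N(SIGMA @ lambda, SIGMA).

    ``planted`` maps block id -> (panel row index of the causal SNP,
    non-centrality); unplanted blocks have lambda = 0.  SIGMA is the LD
    correlation matrix of the block's haplotypes, ridge-regularized by
    ``ridge`` toward the identity to guarantee a valid Cholesky factor.
    Returns a GWAS summary table (internal 0-based positions) with the
    drawn z kept as an extra column.
    """
    from .gwas_cogs import assign_blocks, partition_blocks

    rng = cfg.rng(4) if rng is None else rng
    planted = planted or {}
    blocks = partition_blocks(rmap)
    pos = panel.legend["pos"].to_numpy()
    block_of = assign_blocks(pos, blocks)

    maf = panel.maf()
    z = np.zeros(panel.n_snps)
    for block in blocks:
        idx = np.flatnonzero(block_of == block.block_id)
        if not len(idx):
            continue
        poly = idx[maf[idx] > 0]
        if not len(poly):
            continue
        X = panel.H[poly].astype(float)
        if len(poly) == 1:
            sigma = np.ones((1, 1))
        else:
            sigma = np.corrcoef(X)
            sigma = (1.0 - ridge) * sigma + ridge * np.eye(len(poly))
        lam = np.zeros(len(poly))
        if block.block_id in planted:
            causal, ncp = planted[block.block_id]
            where = np.flatnonzero(poly == causal)
            if not len(where):
                raise ValueError(f"planted causal SNP {causal} not polymorphic "
                                 f"inside block {block.block_id}")
            lam[where[0]] = ncp
        L = np.linalg.cholesky(sigma)
        z[poly] = sigma @ lam + L @ rng.standard_normal(len(poly))

    keep = maf > 0
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame({
        "chrom": panel.legend["chrom"],
        "pos": pos,
        "a1": panel.legend["a0"],
        "a2": panel.legend["a1"],
        "maf": maf,
        "p": p,
        "n": cfg.gwas_n,
        "z": z,
        "snp_id": panel.legend["snp_id"],
        "imputed": False,
    })
    return out[keep].reset_index(drop=True)


def plant_causal_in_pir(iset: InteractionSet, gene_models: list[GeneModel],
                        fragment_map: FragmentMap, panel: HaplotypePanel,
                        blocks, rng: np.random.Generator,
                        ncp: float = 6.0, maf_min: float = 0.01,
                        exclusive: bool = True):
    """Choose a causal SNP inside one gene's PIR for a GWAS simulation.

    Scans genes in random order for a high-confidence cis PIR fragment
    containing at least one panel SNP above ``maf_min``.  With
    ``exclusive`` (default) the fragment must belong to a single gene's
    footprint — it is no other gene's interacting fragment and lies
    outside every other bait's promoter region — so the planted signal
    identifies one target gene unambiguously (a shared regulatory element
    legitimately supports several genes, but is useless as recovery
    truth).  Returns ``(planted, target_gene_id)`` with ``planted``
    mapping block id -> (panel row of the causal SNP, ncp).
    """
    from .gwas_cogs import assign_blocks

    hc = iset.high_confidence()
    tbl = iset.table
    pos = panel.legend["pos"].to_numpy()
    maf = panel.maf()
    footprint: dict[str, set[int]] = {}
    for g in gene_models:
        frags = set(int(f) for f in tbl.loc[(tbl["baitName"] == g.gene_id).to_numpy(), "oeID"])
        for fid in g.bait_frag_ids:
            frags.update((fid - 1, fid, fid + 1))
        footprint[g.gene_id] = frags
    order = rng.permutation(len(gene_models))
    for gi in order:
        gene = gene_models[gi]
        mask = (tbl["baitName"] == gene.gene_id).to_numpy() & hc
        for fid in tbl.loc[mask, "oeID"]:
            fid = int(fid)
            if exclusive and any(fid in footprint[g.gene_id]
                                 for g in gene_models if g.gene_id != gene.gene_id):
                continue
            frag = fragment_map.fragment(fid)
            inside = np.flatnonzero((pos >= frag.start) & (pos < frag.end)
                                    & (maf > maf_min))
            if len(inside):
                causal = int(rng.choice(inside))
                block = int(assign_blocks([pos[causal]], blocks)[0])
                return {block: (causal, ncp)}, gene.gene_id
    raise ValueError("no suitable PIR fragment with a polymorphic SNP found")


# ---------------------------------------------------------------------------
# planted eQTLs
# ---------------------------------------------------------------------------

def plant_eqtls(interactions: InteractionSet, gene_models: list[GeneModel],
                fragment_map: FragmentMap, fraction: float,
                rng: np.random.Generator, avoid_pirs: bool = False,
                score_threshold: float = 5.0):
    """Plant one lead eQTL per gene; a configured fraction inside true PIRs.

    Planted genes get their lead inside a randomly chosen high-confidence
    PIR fragment.  The remaining genes get a lead at a distance drawn from
    the pooled |bait -> PIR| distance distribution, placed uniformly at
    that distance on a random side of the TSS (with ``avoid_pirs`` the
    placement additionally rejects the gene's own PIR fragments).

    Returns ``(eqtl_table, snp_coords, planted_gene_ids)``.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    hc = interactions.high_confidence(score_threshold)
    tbl = interactions.table
    pir_by_gene = {
        g: sub.loc[hc[sub.index], "oeID"].tolist()
        for g, sub in tbl.groupby("baitName")
    }
    pooled_dist = np.abs(tbl.loc[hc, "dist"].to_numpy(dtype=float))
    pooled_dist = pooled_dist[np.isfinite(pooled_dist)]

    records, coords, planted_genes = [], [], []
    for gene in gene_models:
        pirs = pir_by_gene.get(gene.gene_id, [])
        chrom_len = fragment_map.chrom_length(gene.chrom)
        snp_id = f"eqtl_{gene.gene_id}"
        plant = rng.random() < fraction and len(pirs) > 0
        if plant:
            frag = fragment_map.fragment(int(rng.choice(pirs)))
            pos = int(rng.integers(frag.start, frag.end))
            planted_genes.append(gene.gene_id)
        else:
            pir_set = set(int(f) for f in pirs)
            for _ in range(50):
                d = float(rng.choice(pooled_dist)) * rng.choice([-1.0, 1.0])
                pos = int(np.clip(gene.tss + d, 0, chrom_len - 1))
                if not avoid_pirs:
                    break
                if fragment_map.locate(gene.chrom, pos) not in pir_set:
                    break
        records.append((gene.gene_id, snp_id, 1e-8, True, True))
        coords.append((snp_id, gene.chrom, pos))

    eqtl_table = pd.DataFrame(records, columns=["gene_id", "snp_id", "p", "fdr_pass", "lead"])
    snp_coords = pd.DataFrame(coords, columns=["snp_id", "chrom", "pos"])
    return eqtl_table, snp_coords, planted_genes


# ---------------------------------------------------------------------------
# blockshifter null / power datasets
# ---------------------------------------------------------------------------

def simulate_pir_mass_dataset(n_fragments: int = 400, n_runs: int = 60,
                              mix_prob: float = 0.4, effect: float = 1.0,
                              rng: np.random.Generator | None = None,
                              seed: int | None = None):
    """Fragment-level posterior-mass dataset for tissue-set enrichment tests.

    Lays runs of adjacent PIR fragments along a fragment ordinal axis
    (runs of length 1-4, separated by >= 2 non-PIR fragments so they form
    distinct blocks), labels each fragment test or control (a ``mix_prob``
    fraction of runs mixes labels within the run) and attaches exchangeable
    exponential posterior masses.  ``effect`` multiplies the masses of test
    fragments; 1.0 is the exchangeable null.

    Returns ``(test_ids, control_ids, mass)`` where ``mass`` is a DataFrame
    indexed by fragment ordinal with columns ``n`` and ``sum``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    frag_ids: list[int] = []
    labels: list[int] = []
    pos = int(rng.integers(0, 3))
    for _ in range(n_runs):
        run_len = int(rng.integers(1, 5))
        if pos + run_len >= n_fragments:
            break
        if rng.random() < mix_prob and run_len > 1:
            lab = (rng.random(run_len) < 0.5).astype(int)
        else:
            lab = np.full(run_len, int(rng.random() < 0.5))
        for k in range(run_len):
            frag_ids.append(pos + k)
            labels.append(int(lab[k]))
        pos += run_len + int(rng.integers(2, 6))  # gap >= 2 keeps runs separate
    frag_ids_arr = np.array(frag_ids)
    labels_arr = np.array(labels)
    masses = rng.exponential(1.0, len(frag_ids_arr))
    masses[labels_arr == 1] *= effect
    counts = rng.integers(1, 6, len(frag_ids_arr))
    mass = pd.DataFrame({"n": counts, "sum": masses}, index=frag_ids_arr)
    test_ids = frag_ids_arr[labels_arr == 1]
    control_ids = frag_ids_arr[labels_arr == 0]
    return test_ids, control_ids, mass
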