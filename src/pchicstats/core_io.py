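"""Domain types and readers/writers for the formats the pipeline touches.

Coordinate conventions
----------------------
Internally all intervals are 0-based half-open ``[start, end)``.  Text
formats follow their native dialects:

* peak matrix / GWAS / recombination map / haplotype legend / eQTL /
  coding-annotation TSVs carry 1-based inclusive positions;
* the regulatory-state table is BED-like and stays 0-based half-open.

Each reader converts into the internal convention and each writer converts
back, so ``write(read(f))`` round-trips modulo float formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MonomorphicSNPError",
    "Fragment",
    "FragmentMap",
    "CellTypePanel",
    "InteractionSet",
    "RecombMap",
    "HaplotypePanel",
    "GeneModel",
    "read_peak_matrix",
    "write_peak_matrix",
    "read_gwas_table",
    "write_gwas_table",
    "read_recomb_map",
    "write_recomb_map",
    "read_haplotypes",
    "write_haplotypes",
    "read_regulatory_states",
    "write_regulatory_states",
    "read_eqtl_table",
    "write_eqtl_table",
    "read_coding_annotation",
    "write_coding_annotation",
    "read_gene_models",
    "write_gene_models",
    "r_squared",
    "r_squared_profile",
]


class FormatError(ValueError):
    """An input file violates its declared dialect."""


class MonomorphicSNPError(ValueError):
    """LD is undefined for a monomorphic SNP."""


PEAK_MATRIX_FIXED_COLUMNS = [
    "baitChr", "baitStart", "baitEnd", "baitID", "baitName",
    "oeChr", "oeStart", "oeEnd", "oeID", "oeName", "dist",
]

HIGH_CONFIDENCE_SCORE = 5.0  # CHiCAGO score threshold for "high confidence"

REGULATORY_CLASSES = ("promoter", "proximal_enhancer", "distal_enhancer")
ACTIVITY_STATES = ("active", "poised", "repressed", "inactive")


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    frag_id: int
    is_bait: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class FragmentMap:
    """Restriction fragments tiling each chromosome without gaps or overlap.

    Fragment ids are strictly increasing and gap-free within a chromosome,
    so the ordinal distance between two fragments of the same chromosome is
    simply the id difference.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "start", "end", "frag_id"}
        if not required.issubset(table.columns):
            raise FormatError(f"fragment map needs columns {sorted(required)}")
        table = table.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if "is_bait" not in table.columns:
            table["is_bait"] = False
        for chrom, grp in table.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            ids = grp["frag_id"].to_numpy()
            if np.any(starts >= ends):
                raise FormatError(f"{chrom}: empty fragment interval")
            if np.any(starts[1:] != ends[:-1]):
                raise FormatError(f"{chrom}: fragments do not tile the chromosome")
            if np.any(np.diff(ids) != 1):
                raise FormatError(f"{chrom}: fragment ids not gap-free increasing")
        self.table = table
        self._by_chrom = {
            chrom: (grp["start"].to_numpy(), grp["end"].to_numpy(),
                    grp["frag_id"].to_numpy())
            for chrom, grp in table.groupby("chrom", sort=False)
        }
        self._by_id = table.set_index("frag_id", drop=False)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def chrom_length(self, chrom: str) -> int:
        return int(self._by_chrom[chrom][1][-1])

    def locate(self, chrom: str, pos) -> np.ndarray | int:
        """Fragment id(s) covering 0-based position(s) on a chromosome."""
        if chrom not in self._by_chrom:
            raise KeyError(f"unknown chromosome {chrom!r}")
        starts, ends, ids = self._by_chrom[chrom]
        pos_arr = np.atleast_1d(np.asarray(pos))
        if np.any((pos_arr < starts[0]) | (pos_arr >= ends[-1])):
            raise ValueError("position outside the fragment map")
        idx = np.searchsorted(starts, pos_arr, side="right") - 1
        out = ids[idx]
        return int(out[0]) if np.isscalar(pos) else out

    def fragment(self, frag_id: int) -> Fragment:
        row = self._by_id.loc[frag_id]
        return Fragment(row["chrom"], int(row["start"]), int(row["end"]),
                        int(row["frag_id"]), bool(row["is_bait"]))

    def intervals(self, frag_ids) -> pd.DataFrame:
        return self._by_id.loc[list(frag_ids), ["chrom", "start", "end", "frag_id"]].reset_index(drop=True)

    def midpoints(self, frag_ids) -> np.ndarray:
        sub = self._by_id.loc[list(frag_ids)]
        return 0.5 * (sub["start"].to_numpy() + sub["end"].to_numpy())


# ---------------------------------------------------------------------------
# cell-type panel and interactions
# ---------------------------------------------------------------------------

@dataclass
class CellTypePanel:
    """Ordered cell-type labels plus inter-cell-type distance weights."""

    names: list[str]
    dist_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dist_weights is not None:
            d = np.asarray(self.dist_weights, dtype=float)
            if d.shape != (len(self.names), len(self.names)):
                raise ValueError("dist_weights shape does not match panel size")
            if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
                raise ValueError("dist_weights must be symmetric, non-negative, zero-diagonal")
            self.dist_weights = d

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


class InteractionSet:
    """Bait/other-end fragment pairs with per-cell-type CHiCAGO scores.

    Wraps a peak-matrix-shaped DataFrame (internal 0-based coordinates).
    ``dist`` is the signed distance other-end midpoint minus bait midpoint,
    NaN for trans pairs.
    """

    def __init__(self, table: pd.DataFrame, cell_types: list[str]):
        missing = [c for c in PEAK_MATRIX_FIXED_COLUMNS + list(cell_types)
                   if c not in table.columns]
        if missing:
            raise FormatError(f"interaction table missing columns: {missing}")
        scores = table[list(cell_types)].to_numpy(dtype=float)
        if np.any(scores < 0):
            raise ValueError("negative CHiCAGO score")
        self.table = table.reset_index(drop=True)
        self.cell_types = list(cell_types)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def scores(self) -> np.ndarray:
        return self.table[self.cell_types].to_numpy(dtype=float)

    @property
    def dist(self) -> np.ndarray:
        return self.table["dist"].to_numpy(dtype=float)

    @property
    def is_cis(self) -> np.ndarray:
        return (self.table["baitChr"] == self.table["oeChr"]).to_numpy()

    def high_confidence(self, threshold: float = HIGH_CONFIDENCE_SCORE) -> np.ndarray:
        """Row mask: score >= threshold in at least one cell type."""
        return (self.scores >= threshold).any(axis=1)

    def subset(self, mask) -> "InteractionSet":
        return InteractionSet(self.table.loc[mask].reset_index(drop=True), self.cell_types)

    def panel(self) -> CellTypePanel:
        return CellTypePanel(self.cell_types)


def _recompute_dist(table: pd.DataFrame) -> np.ndarray:
    bait_mid = 0.5 * (table["baitStart"] + table["baitEnd"])
    oe_mid = 0.5 * (table["oeStart"] + table["oeEnd"])
    d = (oe_mid - bait_mid).to_numpy(dtype=float)
    d[(table["baitChr"] != table["oeChr"]).to_numpy()] = np.nan
    return d


def read_peak_matrix(path) -> InteractionSet:
    """Read a CHiCAGO-style peak matrix TSV (1-based inclusive coordinates).

    Columns after the eleven fixed ones are one CHiCAGO score column per
    cell type.  ``dist`` is re-derived for cis rows and checked against the
    file; trans rows get NaN.
    """
    table = pd.read_csv(path, sep="\t", dtype={"baitChr": str, "oeChr": str})
    missing = [c for c in PEAK_MATRIX_FIXED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"peak matrix missing columns: {missing}")
    cell_types = [c for c in table.columns if c not in PEAK_MATRIX_FIXED_COLUMNS]
    if not cell_types:
        raise FormatError("peak matrix has no score columns")
    for col in ("baitStart", "oeStart"):
        table[col] = table[col].astype(np.int64) - 1  # to 0-based
    table["dist"] = pd.to_numeric(table["dist"], errors="coerce")
    recomputed = _recompute_dist(table)
    cis = table["baitChr"] == table["oeChr"]
    got = table.loc[cis, "dist"].to_numpy(dtype=float)
    want = recomputed[cis.to_numpy()]
    if np.any(~np.isfinite(got)) or not np.allclose(got, want, atol=1.0):
        raise FormatError("cis dist column inconsistent with fragment coordinates")
    table["dist"] = recomputed
    scores = table[cell_types].to_numpy(dtype=float)
    if np.any(~np.isfinite(scores)):
        raise FormatError("non-numeric CHiCAGO score")
    if np.any(scores < 0):
        raise ValueError("negative CHiCAGO score")
    return InteractionSet(table, cell_types)


def write_peak_matrix(iset: InteractionSet, path) -> None:
    out = iset.table.copy()
    for col in ("baitStart", "oeStart"):
        out[col] = out[col].astype(np.int64) + 1
    out["dist"] = out["dist"].map(lambda d: "NA" if pd.isna(d) else f"{d:g}")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

GWAS_REQUIRED = ["chrom", "pos", "a1", "a2", "maf", "p"]
GWAS_OPTIONAL = ["beta", "se", "n", "cc_ratio", "imputed"]


def read_gwas_table(path) -> pd.DataFrame:
    """GWAS summary TSV: chrom, pos, a1, a2, maf, p [, beta, se, n, cc_ratio]."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in GWAS_REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"GWAS table missing columns: {missing}")
    if len(table):
        p = table["p"].to_numpy(dtype=float)
        present = np.isfinite(p)
        if np.any((p[present] <= 0) | (p[present] > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        maf = table["maf"].to_numpy(dtype=float)
        if np.any(np.isfinite(maf) & ((maf <= 0) | (maf > 0.5))):
            raise ValueError("MAF must lie in (0, 0.5]")
        table["pos"] = table["pos"].astype(np.int64) - 1
    else:
        table["pos"] = table.get("pos", pd.Series(dtype=np.int64))
    if "imputed" not in table.columns:
        table["imputed"] = False
    else:
        table["imputed"] = table["imputed"].astype(bool)
    return table.reset_index(drop=True)


def write_gwas_table(table: pd.DataFrame, path) -> None:
    out = table.copy()
    if len(out):
        out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# recombination map
# ---------------------------------------------------------------------------

@dataclass
class RecombMap:
    """HapMap-style genetic map: bp positions with cumulative cM values."""

    positions: np.ndarray  # 0-based bp
    cum_cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cum_cm = np.asarray(self.cum_cm, dtype=float)
        if self.positions.shape != self.cum_cm.shape:
            raise FormatError("recombination map arrays differ in length")
        if np.any(np.diff(self.positions) <= 0):
            raise FormatError("recombination map positions must increase")
        if np.any(np.diff(self.cum_cm) < 0):
            raise FormatError("cumulative cM must be non-decreasing")

    def cm_at(self, pos) -> np.ndarray:
        return np.interp(np.asarray(pos, dtype=float), self.positions, self.cum_cm)

    @property
    def total_cm(self) -> float:
        return float(self.cum_cm[-1] - self.cum_cm[0])


def read_recomb_map(path) -> RecombMap:
    """HapMap dialect: ``position rate(cM/Mb) map(cM)`` (whitespace separated)."""
    table = pd.read_csv(path, sep=r"\s+")
    if table.shape[1] < 3:
        raise FormatError("recombination map needs 3 columns: position rate map")
    pos = table.iloc[:, 0].astype(np.int64).to_numpy() - 1
    cum = table.iloc[:, 2].astype(float).to_numpy()
    return RecombMap(pos, cum)


def write_recomb_map(rmap: RecombMap, path) -> None:
    pos = rmap.positions
    cum = rmap.cum_cm
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.append(np.diff(cum) / (np.diff(pos) / 1e6), 0.0)
    pd.DataFrame({
        "position": pos + 1,
        "rate(cM/Mb)": rate,
        "map(cM)": cum,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# haplotype reference panel
# ---------------------------------------------------------------------------

class HaplotypePanel:
    """IMPUTE-style reference panel: legend rows aligned with a 0/1 matrix."""

    def __init__(self, legend: pd.DataFrame, H: np.ndarray):
        required = {"snp_id", "chrom", "pos", "a0", "a1"}
        if not required.issubset(legend.columns):
            raise FormatError(f"haplotype legend needs columns {sorted(required)}")
        H = np.asarray(H)
        if H.ndim != 2 or len(legend) != H.shape[0]:
            raise FormatError("legend and haplotype matrix row counts differ")
        if H.size and not np.isin(H, (0, 1)).all():
            raise FormatError("haplotype matrix entries must be 0/1")
        self.legend = legend.reset_index(drop=True)
        self.H = H.astype(np.int8)

    @property
    def n_snps(self) -> int:
        return self.H.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[1]

    def maf(self) -> np.ndarray:
        f = self.H.mean(axis=1)
        return np.minimum(f, 1.0 - f)

    def index_of(self, snp_id: str) -> int:
        hits = np.flatnonzero(self.legend["snp_id"].to_numpy() == snp_id)
        if not len(hits):
            raise KeyError(snp_id)
        return int(hits[0])


def read_haplotypes(legend_path, matrix_path) -> HaplotypePanel:
    legend = pd.read_csv(legend_path, sep="\t", dtype={"chrom": str, "snp_id": str})
    if "pos" in legend.columns and len(legend):
        legend["pos"] = legend["pos"].astype(np.int64) - 1
    H = np.loadtxt(matrix_path, dtype=np.int8, ndmin=2)
    return HaplotypePanel(legend, H)


def write_haplotypes(panel: HaplotypePanel, legend_path, matrix_path) -> None:
    out = panel.legend.copy()
    if len(out):
        out["pos"] = out["pos"].astype(np.int64) + 1
    out.to_csv(legend_path, sep="\t", index=False)
    np.savetxt(matrix_path, panel.H, fmt="%d")


def r_squared(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation between two haplotype columns (rows i, j)."""
    a = panel.H[i].astype(float)
    b = panel.H[j].astype(float)
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        raise MonomorphicSNPError(f"monomorphic SNP at row {i if va == 0 else j}")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def r_squared_profile(panel: HaplotypePanel, i: int, rows=None) -> np.ndarray:
    """r^2 of SNP ``i`` against a set of rows (all rows by default).

    Monomorphic partners yield NaN; a monomorphic query raises.
    """
    H = panel.H if rows is None else panel.H[np.asarray(rows)]
    a = panel.H[i].astype(float)
    if a.var() == 0:
        raise MonomorphicSNPError(f"monomorphic SNP at row {i}")
    X = H.astype(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    ac = a - a.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ ac) / denom
    return r * r


# ---------------------------------------------------------------------------
# regulatory states
# ---------------------------------------------------------------------------

def read_regulatory_states(path, cell_types: list[str] | None = None) -> pd.DataFrame:
    """BED6+ with ``feature_class`` and one activity column per cell type.

    BED columns stay 0-based half-open.  Activities must be one of
    active/poised/repressed/inactive for every (feature, cell type).
    """
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "start", "end", "name", "score", "strand", "feature_class"]
    missing = [c for c in fixed if c not in table.columns]
    if missing:
        raise FormatError(f"regulatory state table missing columns: {missing}")
    activity_cols = [c for c in table.columns if c not in fixed]
    if cell_types is not None:
        absent = [c for c in cell_types if c not in activity_cols]
        if absent:
            raise FormatError(f"no activity column for cell types: {absent}")
        activity_cols = list(cell_types)
    bad_class = set(table["feature_class"]) - set(REGULATORY_CLASSES)
    if bad_class:
        raise FormatError(f"unknown feature classes: {sorted(bad_class)}")
    for col in activity_cols:
        bad = set(table[col]) - set(ACTIVITY_STATES)
        if bad:
            raise FormatError(f"unknown activity states in {col}: {sorted(bad)}")
    return table.reset_index(drop=True)


def write_regulatory_states(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# eQTLs, coding annotation, gene models
# ---------------------------------------------------------------------------

def read_eqtl_table(path) -> pd.DataFrame:
    """eQTL TSV: gene_id, snp_id, p, fdr_pass, lead (<=1 lead per gene)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "snp_id": str})
    required = ["gene_id", "snp_id", "p", "fdr_pass", "lead"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"eQTL table missing columns: {missing}")
    table["fdr_pass"] = table["fdr_pass"].astype(bool)
    table["lead"] = table["lead"].astype(bool)
    leads = table[table["lead"]].groupby("gene_id").size()
    if (leads > 1).any():
        raise FormatError("more than one lead eQTL for a gene")
    return table.reset_index(drop=True)


def write_eqtl_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_coding_annotation(path) -> pd.DataFrame:
    """VEP-style consequence TSV: snp_id, gene_id, consequence."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "gene_id", "consequence"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"coding annotation missing columns: {missing}")
    return table.reset_index(drop=True)


def write_coding_annotation(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 0-based
    bait_frag_ids: tuple[int, ...]
    coding_snp_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.bait_frag_ids:
            raise ValueError("a captured gene needs at least one bait fragment")


def read_gene_models(path, coding: pd.DataFrame | None = None) -> list[GeneModel]:
    """Gene model TSV: gene_id, chrom, strand, tss, bait_frag_ids (comma list)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    required = ["gene_id", "chrom", "strand", "tss", "bait_frag_ids"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"gene model table missing columns: {missing}")
    coding_by_gene: dict[str, frozenset[str]] = {}
    if coding is not None:
        coding_by_gene = {
            g: frozenset(sub["snp_id"]) for g, sub in coding.groupby("gene_id")
        }
    models = []
    for row in table.itertuples(index=False):
        baits = tuple(int(x) for x in str(row.bait_frag_ids).split(","))
        models.append(GeneModel(row.gene_id, row.chrom, row.strand,
                                int(row.tss) - 1, baits,
                                coding_by_gene.get(row.gene_id, frozenset())))
    return models


def write_gene_models(models: list[GeneModel], path) -> None:
    pd.DataFrame({
        "gene_id": [m.gene_id for m in models],
        "chrom": [m.chrom for m in models],
        "strand": [m.strand for m in models],
        "tss": [m.tss + 1 for m in models],
        "bait_frag_ids": [",".join(map(str, m.bait_frag_ids)) for m in models],
    }).to_csv(path, sep="\t", index=False)
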