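"""Cell-type specificity scores and gene-cluster enrichment.

The central statistic is the weighted specificity score.  For a vector of
measurements ``x_i`` (one per cell type, e.g. a CHiCAGO interaction score
or an asinh gene-expression value) the specificity of cell type ``c`` is
the weighted mean of the differences to every other cell type::

    s_c = sum_{i != c} d_{c,i} (x_c - x_i) / sum_{i != c} d_{c,i}

where the weights ``d_{c,i}`` are Euclidean distances between the
cell-type columns of the complete dataset.  The weighting discounts
near-duplicate cell types (e.g. three macrophage states), which would
otherwise drag each other's specificity toward zero purely through
over-representation in the panel.

The module also provides the derived quantities built on this score:
per-cluster specificity, per-gene specificity from interactions with
active enhancers (with the asinh transform capped at 4.3, the value whose
raw-score equivalent is about 36.8), expression specificity, gene-cluster
enrichment scores e_{c,k} = p_{c,k} - q_k, and a permutation test for
shared specificity of interactions at the same bait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .core_io import FragmentMap, GeneModel, InteractionSet

__all__ = [
    "ASINH_CAP",
    "SCORE_THRESHOLD",
    "distance_weights",
    "specificity_score",
    "specificity_scores",
    "cluster_specificity",
    "process_scores",
    "gene_specificity_matrix",
    "GeneSpecificityMatrix",
    "expression_specificity",
    "cluster_enrichment",
    "ClusterEnrichment",
    "bait_specificity_variance_test",
    "BaitVarianceResult",
    "kmeans_partition",
]

ASINH_CAP = 4.3        # asinh-score cap; sinh(4.3) ~ 36.8 on the raw scale
SCORE_THRESHOLD = 5.0  # high-confidence CHiCAGO score
DEFAULT_K = 12         # default gene-cluster count


def distance_weights(full_data: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distances between cell-type columns.

    ``full_data`` is the complete dataset (items x cell types) on the same
    scale as the vectors later scored, e.g. asinh-capped CHiCAGO scores.
    """
    X = np.asarray(full_data, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two cell types")
    return squareform(pdist(X.T, metric="euclidean"))


def specificity_scores(x, weights: np.ndarray) -> np.ndarray:
    """Specificity score for every cell type at once.

    Vectorized form of the weighted-mean-of-differences statistic: with
    row sums ``w_c = sum_i d_{c,i}`` (the diagonal is zero),
    ``s_c = (w_c x_c - (D @ x)_c) / w_c``.
    """
    x = np.asarray(x, dtype=float)
    D = np.asarray(weights, dtype=float)
    if x.shape[0] != D.shape[0]:
        raise ValueError("x length does not match the weight matrix")
    wsum = D.sum(axis=1)
    if np.any(wsum <= 0):
        raise ValueError("all distance weights zero for some cell type; score undefined")
    return (wsum * x - D @ x) / wsum


def specificity_score(x, weights: np.ndarray, c: int) -> float:
    """Specificity of a single cell type ``c`` (index into the panel)."""
    return float(specificity_scores(x, weights)[c])


def cluster_specificity(cluster_scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Specificity of an interaction cluster.

    ``cluster_scores`` holds the raw CHiCAGO scores of the cluster's
    interactions (rows) per cell type (columns); the profile scored is the
    per-cell-type mean asinh score.
    """
    scores = np.atleast_2d(np.asarray(cluster_scores, dtype=float))
    x = np.arcsinh(scores).mean(axis=0)
    return specificity_scores(x, weights)


def process_scores(scores: np.ndarray, cap: float = ASINH_CAP) -> np.ndarray:
    """asinh-transform CHiCAGO scores and cap at ``cap``."""
    return np.minimum(np.arcsinh(np.asarray(scores, dtype=float)), cap)


# ---------------------------------------------------------------------------
# gene specificity from interactions with active enhancers
# ---------------------------------------------------------------------------

@dataclass
class GeneSpecificityMatrix:
    scores: pd.DataFrame        # gene x cell type, averaged over n_g interactions
    n_g: pd.Series              # qualifying enhancer interactions per gene
    excluded_genes: list[str]   # captured genes with zero qualifying interactions
    weights: np.ndarray


def _enhancer_activity(iset: InteractionSet, reg_states: pd.DataFrame) -> np.ndarray:
    """active/inactive matrix (interaction x cell type) for other ends.

    An other end counts as an active enhancer in a cell type if it overlaps
    at least one enhancer or promoter-proximal feature in the chromHMM
    "active" state there; poised/repressed/inactive pool as non-active.
    """
    names = iset.cell_types
    feats = reg_states[reg_states["feature_class"].isin(
        ["distal_enhancer", "proximal_enhancer", "promoter"])]
    out = np.zeros((len(iset), len(names)), dtype=bool)
    tbl = iset.table
    for chrom, sub in feats.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        act = sub[names].to_numpy() == "active"
        rows = np.flatnonzero((tbl["oeChr"] == chrom).to_numpy())
        for i in rows:
            s, e = tbl.at[i, "oeStart"], tbl.at[i, "oeEnd"]
            hit = (starts < e) & (ends > s)
            if hit.any():
                out[i] = act[hit].any(axis=0)
    return out


def gene_specificity_matrix(iset: InteractionSet, reg_states: pd.DataFrame,
                            gene_models: list[GeneModel],
                            cap: float = ASINH_CAP,
                            threshold: float = SCORE_THRESHOLD) -> GeneSpecificityMatrix:
    """Per-gene specificity of interactions with active enhancers.

    Processing chain: keep interactions whose bait maps to a unique
    captured gene and for which some cell type has both score >= threshold
    and an active enhancer; zero scores where the enhancer is not active;
    asinh-transform and cap; score each interaction; average a gene's
    ``n_g`` interaction score vectors.  Distance weights come from the full
    asinh-capped score dataset.
    """
    genes_by_bait: dict[int, list[str]] = {}
    for g in gene_models:
        for fid in g.bait_frag_ids:
            genes_by_bait.setdefault(int(fid), []).append(g.gene_id)
    unique_gene = {fid: gs[0] for fid, gs in genes_by_bait.items() if len(gs) == 1}

    weights = distance_weights(process_scores(iset.scores, cap))

    active = _enhancer_activity(iset, reg_states)
    scores = iset.scores
    bait_ids = iset.table["baitID"].to_numpy()
    qualifies = (np.array([fid in unique_gene for fid in bait_ids])
                 & ((scores >= threshold) & active).any(axis=1))

    per_gene: dict[str, list[np.ndarray]] = {}
    for i in np.flatnonzero(qualifies):
        x = process_scores(np.where(active[i], scores[i], 0.0), cap)
        s = specificity_scores(x, weights)
        per_gene.setdefault(unique_gene[int(bait_ids[i])], []).append(s)

    captured = sorted({unique_gene[int(f)] for f in bait_ids if int(f) in unique_gene})
    excluded = [g for g in captured if g not in per_gene]
    rows = {g: np.mean(v, axis=0) for g, v in per_gene.items()}
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=iset.cell_types).sort_index()
    n_g = pd.Series({g: len(v) for g, v in per_gene.items()}).sort_index()
    return GeneSpecificityMatrix(mat, n_g, excluded, weights)


def expression_specificity(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression specificity: x_i = asinh expression in cell type i.

    Distance weights are computed from the asinh-transformed full
    expression dataset.
    """
    X = np.arcsinh(expr.to_numpy(dtype=float))
    weights = distance_weights(X)
    wsum = weights.sum(axis=1)
    S = (wsum * X - X @ weights) / wsum
    return pd.DataFrame(S, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# gene-cluster enrichment
# ---------------------------------------------------------------------------

@dataclass
class ClusterEnrichment:
    e: pd.DataFrame  # cell type x cluster, e_{c,k} = p_{c,k} - q_k
    p: pd.DataFrame
    q: pd.Series


def cluster_enrichment(clusters: pd.Series, top_sets: dict[str, set]) -> ClusterEnrichment:
    """Enrichment of gene clusters for the most specifically expressed genes.

    ``clusters`` maps gene -> cluster id over all analyzed genes;
    ``top_sets`` maps cell type -> its top-specificity gene set (G_c,
    typically 100 genes).  p_{c,k} is the in-G_c cluster proportion, q_k
    the all-genes proportion, and e = p - q, so a random G_c has
    expectation 0 and rows of e sum to 0.
    """
    ks = sorted(clusters.unique())
    q = clusters.value_counts(normalize=True).reindex(ks, fill_value=0.0)
    p_rows, e_rows = {}, {}
    for c, genes in top_sets.items():
        sub = clusters.loc[clusters.index.intersection(list(genes))]
        if not len(sub):
            raise ValueError(f"top set for {c} shares no genes with the clustering")
        p = sub.value_counts(normalize=True).reindex(ks, fill_value=0.0)
        p_rows[c] = p
        e_rows[c] = p - q
    return ClusterEnrichment(
        e=pd.DataFrame(e_rows).T[ks],
        p=pd.DataFrame(p_rows).T[ks],
        q=q,
    )


# ---------------------------------------------------------------------------
# shared specificity of interactions at the same bait
# ---------------------------------------------------------------------------

@dataclass
class BaitVarianceResult:
    observed: np.ndarray      # per-bait variance of interaction specificities
    null_means: np.ndarray    # mean per-bait variance per permutation
    observed_mean: float
    p: float                  # one-sided: observed mean below the null


def bait_specificity_variance_test(bait_ids: np.ndarray, cluster_labels: np.ndarray,
                                   cluster_spec: dict | pd.DataFrame,
                                   n_perm: int = 1000, seed: int = 0) -> BaitVarianceResult:
    """Do interactions of the same bait share cell-type specificity?

    Each interaction inherits a scalar specificity: the maximum over cell
    types of its cluster's specificity scores.  The observed statistic is
    the per-bait variance of these values (baits with a single interaction
    are excluded); the null redistributes cluster labels across
    interactions ``n_perm`` times.  ``p`` is one-sided for the observed
    mean variance lying below the null mean.
    """
    bait_ids = np.asarray(bait_ids)
    labels = np.asarray(cluster_labels)
    if isinstance(cluster_spec, pd.DataFrame):
        max_spec = cluster_spec.max(axis=1)
        value_of = {k: float(max_spec.loc[k]) for k in cluster_spec.index}
    else:
        value_of = {k: float(np.max(v)) for k, v in cluster_spec.items()}
    values = np.array([value_of[k] for k in labels], dtype=float)

    order = np.argsort(bait_ids, kind="stable")
    sorted_baits = bait_ids[order]
    uniq, starts, counts = np.unique(sorted_baits, return_index=True, return_counts=True)
    keep_groups = counts >= 2

    def mean_variance(vals: np.ndarray) -> tuple[np.ndarray, float]:
        v = vals[order]
        sums = np.add.reduceat(v, starts)
        sqs = np.add.reduceat(v * v, starts)
        with np.errstate(invalid="ignore"):
            var = (sqs - sums * sums / counts) / (counts - 1)
        var = var[keep_groups]
        return var, float(var.mean())

    obs_var, obs_mean = mean_variance(values)
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    for i in range(n_perm):
        null_means[i], = (mean_variance(rng.permutation(values))[1],)
    p = (1.0 + np.sum(null_means <= obs_mean)) / (1.0 + n_perm)
    return BaitVarianceResult(obs_var, null_means, obs_mean, float(p))


def kmeans_partition(matrix: pd.DataFrame | np.ndarray, k: int = DEFAULT_K,
                     n_starts: int = 50, seed: int = 0) -> pd.Series:
    """Best-inertia k-means partition over ``n_starts`` restarts."""
    X = np.asarray(matrix, dtype=float)
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(X)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(X))
    out = pd.Series(labels, index=index, name="cluster")
    out.attrs["inertia"] = float(km.inertia_)
    return out
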