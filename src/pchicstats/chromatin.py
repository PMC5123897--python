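"""TAD calling, PIR randomization and enhancer-coupling contingency tests.

Four groups of operations:

* **Directionality index (DI) and TADs.**  The DI contrasts contact counts
  up to 1 Mb upstream (A) and downstream (B) of a 25-kb sliding window
  stepped every 5 kb: ``DI = sign(B - A) * ((A - E)^2/E + (B - E)^2/E)``
  with ``E = (A + B)/2``.  The track is smoothed with a +/- 25 kb moving
  average and standardized; boundaries are called between consecutive
  negative and positive local extrema whose standard score exceeds 0.5.

* **TAD-crossing statistics** with a null that reshuffles each bait's
  (left flank, right flank) boundary distances jointly across baits.

* **Distance-matched PIR randomization** (log2-binned bait distances) and
  feature enrichment z-scores against the randomized draws.

* **Overdispersion-adjusted chi-square.**  Interactions sharing a bait are
  correlated, so 2x2 contingency chi-squares are re-scaled by
  ``sqrt(2) / sd`` of 1000 bait-level block-bootstrap chi-square values
  before the 1-df upper tail is taken.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FragmentMap, InteractionSet

__all__ = [
    "DITrack",
    "compute_di",
    "call_tads",
    "merge_replicate_tads",
    "TadCrossingResult",
    "tad_crossing",
    "randomize_pirs_distance_matched",
    "FeatureEnrichmentResult",
    "feature_enrichment",
    "activity_coupling_table",
    "ContingencyResult",
    "overdispersed_chisq",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# directionality index and TADs
# ---------------------------------------------------------------------------

@dataclass
class DITrack:
    chrom: str
    positions: np.ndarray   # window-center bp
    di: np.ndarray
    smoothed: np.ndarray
    z: np.ndarray           # standardized smoothed DI
    step: int
    chrom_length: int


def compute_di(contacts: np.ndarray, chrom: str = "chr1", res: int = 5000,
               bin_size: int = 25_000, window: int = 1_000_000,
               smooth: int = 25_000) -> DITrack:
    """Directionality index from a symmetric contact-count matrix.

    ``contacts`` is binned at ``res`` bp.  For each ``bin_size`` window
    stepped every ``res`` bp, A and B sum the contacts between the window
    and up to ``window`` bp up-/downstream (clipped at the matrix edge).
    A window with no contacts gets DI 0.  Smoothing averages over
    +/- ``smooth`` bp; the standardized track is the z-score of the
    smoothed DI (zero when the track is flat).
    """
    C = np.asarray(contacts, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("contact matrix must be square")
    n = C.shape[0]
    half = max(bin_size // res // 2, 0)
    wbins = max(window // res, 1)
    di = np.zeros(n)
    csum = np.concatenate([np.zeros((n, 1)), np.cumsum(C, axis=1)], axis=1)
    for i in range(n):
        lo, hi = max(i - half, 0), min(i + half + 1, n)
        rows = slice(lo, hi)
        a0, a1 = max(lo - wbins, 0), lo
        b0, b1 = hi, min(hi + wbins, n)
        seg = csum[rows]
        A = float((seg[:, a1] - seg[:, a0]).sum())
        B = float((seg[:, b1] - seg[:, b0]).sum())
        if A + B == 0:
            continue
        E = 0.5 * (A + B)
        di[i] = np.sign(B - A) * ((A - E) ** 2 / E + (B - E) ** 2 / E)
    k = max(smooth // res, 0)
    kernel = np.ones(2 * k + 1)
    smoothed = np.convolve(di, kernel, mode="same") / np.convolve(
        np.ones(n), kernel, mode="same")
    sd = smoothed.std()
    z = (smoothed - smoothed.mean()) / sd if sd > 0 else np.zeros(n)
    positions = (np.arange(n) + 0.5) * res
    return DITrack(chrom, positions, di, smoothed, z, res, n * res)


def _local_extrema(y: np.ndarray) -> list[tuple[int, int]]:
    """(index, sign) of local extrema; sign +1 maxima, -1 minima.

    Plateaus are collapsed to their midpoint; monotone ends are not
    extrema.
    """
    d = np.sign(np.diff(y))
    # propagate the previous non-zero slope through plateaus
    trend = d.copy()
    for i in range(1, len(trend)):
        if trend[i] == 0:
            trend[i] = trend[i - 1]
    out = []
    for i in range(1, len(trend)):
        if trend[i - 1] > 0 and trend[i] < 0:
            out.append((i, +1))
        elif trend[i - 1] < 0 and trend[i] > 0:
            out.append((i, -1))
    return out


def call_tads(track: DITrack, z_threshold: float = 0.5) -> pd.DataFrame:
    """Call TADs between qualifying negative -> positive DI extrema.

    A qualifying extremum has |standardized smoothed DI| above
    ``z_threshold``; the boundary between a negative extremum and the next
    positive one is placed at the smoothed-DI zero crossing (midpoint when
    the sign never crosses).  Returns BED-like intervals (0-based
    half-open) spanning the chromosome between successive boundaries.
    """
    y = track.smoothed
    extrema = [(i, s) for i, s in _local_extrema(y)
               if abs(track.z[i]) > z_threshold
               and ((s > 0 and y[i] > 0) or (s < 0 and y[i] < 0))]
    boundaries = []
    for (i0, s0), (i1, s1) in zip(extrema[:-1], extrema[1:]):
        if s0 == -1 and s1 == +1:
            cross = None
            for j in range(i0, i1):
                if y[j] <= 0 < y[j + 1]:
                    cross = track.positions[j] + (track.positions[j + 1] - track.positions[j]) \
                        * (-y[j]) / (y[j + 1] - y[j])
                    break
            if cross is None:
                cross = 0.5 * (track.positions[i0] + track.positions[i1])
            boundaries.append(float(cross))
    edges = [0.0, *boundaries, float(track.chrom_length)]
    return pd.DataFrame({
        "chrom": track.chrom,
        "start": np.asarray(edges[:-1], dtype=np.int64),
        "end": np.asarray(edges[1:], dtype=np.int64),
    })


def merge_replicate_tads(tad_sets: list[pd.DataFrame],
                         min_overlap: float = 0.75) -> pd.DataFrame:
    """Merge replicate TAD calls by reciprocal-overlap matching.

    A TAD of the first replicate is matched to its best-overlapping TAD in
    each further replicate; any pair below ``min_overlap`` reciprocal
    overlap (of both intervals) drops the TAD.  Matched boundaries are
    averaged across replicates.
    """
    if not tad_sets:
        raise ValueError("need at least one TAD set")
    if len(tad_sets) == 1:
        return tad_sets[0].reset_index(drop=True)
    rows = []
    base = tad_sets[0]
    for row in base.itertuples(index=False):
        starts, ends = [row.start], [row.end]
        ok = True
        for other in tad_sets[1:]:
            sub = other[other["chrom"] == row.chrom]
            if not len(sub):
                ok = False
                break
            ov = (np.minimum(sub["end"].to_numpy(), row.end)
                  - np.maximum(sub["start"].to_numpy(), row.start)).clip(min=0)
            j = int(np.argmax(ov))
            len_a = row.end - row.start
            len_b = int(sub["end"].iloc[j] - sub["start"].iloc[j])
            if ov[j] < min_overlap * len_a or ov[j] < min_overlap * len_b:
                ok = False
                break
            starts.append(int(sub["start"].iloc[j]))
            ends.append(int(sub["end"].iloc[j]))
        if ok:
            rows.append((row.chrom, int(np.mean(starts)), int(np.mean(ends))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# TAD crossing
# ---------------------------------------------------------------------------

@dataclass
class TadCrossingResult:
    observed: float                 # global crossing proportion
    per_bait: pd.Series             # crossing fraction per bait
    null: np.ndarray                # permuted global proportions
    null_mean: float
    null_sd: float
    p: float                        # one-sided: observed below the null


def tad_crossing(iset: InteractionSet, tads: pd.DataFrame,
                 n_perm: int = 1000, seed: int = 0) -> TadCrossingResult:
    """Proportion of cis interactions leaving their bait's TAD.

    Baits whose midpoint falls outside every TAD are excluded.  The null
    reshuffles the (left flank, right flank) boundary-distance pairs
    jointly across baits and recomputes the proportion from the observed
    signed bait->other-end distances.
    """
    tbl = iset.table
    cis = iset.is_cis
    bait_mid = 0.5 * (tbl["baitStart"] + tbl["baitEnd"]).to_numpy()
    dist = iset.dist

    flanks: dict[int, tuple[float, float]] = {}
    for bid, sub_idx in tbl.groupby("baitID").groups.items():
        i0 = sub_idx[0]
        chrom = tbl.at[i0, "baitChr"]
        mid = bait_mid[tbl.index.get_loc(i0)]
        sub = tads[(tads["chrom"] == chrom)
                   & (tads["start"] <= mid) & (mid < tads["end"])]
        if len(sub):
            flanks[bid] = (mid - float(sub["start"].iloc[0]),
                           float(sub["end"].iloc[0]) - mid)

    keep = cis & tbl["baitID"].isin(flanks).to_numpy()
    if not keep.any():
        raise ValueError("no cis interactions with baits inside TADs")
    sub = tbl.loc[keep]
    d = dist[keep]
    baits = sub["baitID"].to_numpy()
    uniq_baits = np.unique(baits)
    bait_pos = {b: i for i, b in enumerate(uniq_baits)}
    bait_idx = np.array([bait_pos[b] for b in baits])
    dl = np.array([flanks[b][0] for b in uniq_baits])
    dr = np.array([flanks[b][1] for b in uniq_baits])

    def crossing(dl_b, dr_b) -> np.ndarray:
        return (d < -dl_b[bait_idx]) | (d > dr_b[bait_idx])

    obs_mask = crossing(dl, dr)
    observed = float(obs_mask.mean())
    per_bait = pd.Series(obs_mask).groupby(baits).mean()

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(uniq_baits))
        null[i] = crossing(dl[perm], dr[perm]).mean()
    p = (1.0 + np.sum(null <= observed)) / (1.0 + n_perm)
    return TadCrossingResult(observed, per_bait, null,
                             float(null.mean()), float(null.std(ddof=1)), float(p))


# ---------------------------------------------------------------------------
# distance-matched PIR randomization + feature enrichment
# ---------------------------------------------------------------------------

def randomize_pirs_distance_matched(iset: InteractionSet, fragment_map: FragmentMap,
                                    n_draws: int = 100, seed: int = 0,
                                    bin_width: float = 0.25) -> list[np.ndarray]:
    """Random non-PIR fragments matching the binned PIR distance profile.

    Each draw reassigns every cis PIR to a random non-PIR fragment whose
    |midpoint - bait midpoint| falls in the same log2 distance bin
    (``bin_width`` log2 units wide), so every draw reproduces the observed
    binned distance histogram exactly.  Candidates are drawn with
    probability proportional to fragment length, matching the
    length-biased way real PIRs arise (a fragment's chance of containing
    an interaction end grows with its size).  Trans PIRs are excluded
    (and logged).  A bin with no candidates is widened once to its
    neighbours; if still empty an error is raised.

    Returns one fragment-id array per draw, aligned with the cis PIRs.
    """
    tbl = iset.table
    cis = iset.is_cis & (np.abs(iset.dist) > 0)
    n_trans = int((~iset.is_cis).sum())
    if n_trans:
        log.info("randomize_pirs: excluding %d trans PIRs", n_trans)
    sub = tbl.loc[cis]
    pir_ids = set(tbl["oeID"].tolist()) | set(tbl["baitID"].tolist())

    mids_by_chrom, ids_by_chrom, lens_by_chrom = {}, {}, {}
    for chrom, grp in fragment_map.table.groupby("chrom", sort=False):
        mid = 0.5 * (grp["start"].to_numpy() + grp["end"].to_numpy())
        fid = grp["frag_id"].to_numpy()
        flen = (grp["end"] - grp["start"]).to_numpy(dtype=float)
        non_pir = ~np.isin(fid, list(pir_ids))
        mids_by_chrom[chrom] = mid[non_pir]
        ids_by_chrom[chrom] = fid[non_pir]
        lens_by_chrom[chrom] = flen[non_pir]

    def candidates(chrom: str, bait_mid: float, lo: float, hi: float):
        mids = mids_by_chrom[chrom]
        dist = np.abs(mids - bait_mid)
        sel = (dist >= lo) & (dist < hi)
        return ids_by_chrom[chrom][sel], lens_by_chrom[chrom][sel]

    rng = np.random.default_rng(seed)
    cand_per_pir = []
    for row in sub.itertuples(index=False):
        bait_mid = 0.5 * (row.baitStart + row.baitEnd)
        k = np.floor(np.log2(abs(row.dist)) / bin_width)
        lo, hi = 2 ** (k * bin_width), 2 ** ((k + 1) * bin_width)
        cand, w = candidates(row.baitChr, bait_mid, lo, hi)
        if not len(cand):  # widen once to the neighbouring bins
            cand, w = candidates(row.baitChr, bait_mid,
                                 2 ** ((k - 1) * bin_width), 2 ** ((k + 2) * bin_width))
        if not len(cand):
            raise ValueError(f"no candidate fragments near distance {row.dist:g}")
        cand_per_pir.append((cand, w / w.sum()))
    return [np.array([rng.choice(c, p=w) for c, w in cand_per_pir])
            for _ in range(n_draws)]


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    keep_s, keep_e = [], []
    for s, e in zip(starts, ends):
        if keep_e and s <= keep_e[-1]:
            keep_e[-1] = max(keep_e[-1], e)
        else:
            keep_s.append(s)
            keep_e.append(e)
    return np.asarray(keep_s), np.asarray(keep_e)


def _count_overlapping(intervals: pd.DataFrame, features: pd.DataFrame) -> int:
    """Number of query intervals overlapping >= 1 feature interval."""
    total = 0
    merged = {chrom: _merge_intervals(grp["start"].to_numpy(), grp["end"].to_numpy())
              for chrom, grp in features.groupby("chrom")}
    for chrom, grp in intervals.groupby("chrom"):
        if chrom not in merged:
            continue
        fs, fe = merged[chrom]
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        idx = np.searchsorted(fs, e, side="left") - 1
        hit = (idx >= 0) & (fe[np.clip(idx, 0, None)] > s)
        total += int(hit.sum())
    return total


@dataclass
class FeatureEnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    fold: float
    z: float
    null: np.ndarray


def feature_enrichment(pir_frag_ids, features: pd.DataFrame,
                       randomized_sets: list[np.ndarray],
                       fragment_map: FragmentMap) -> FeatureEnrichmentResult:
    """Observed vs randomized PIR-feature overlap, as fold change and z.

    ``z = (obs - mean_null) / sd_null`` and ``fold = obs / mean_null`` over
    the randomized draws.
    """
    obs = _count_overlapping(fragment_map.intervals(pir_frag_ids), features)
    null = np.array([
        _count_overlapping(fragment_map.intervals(ids), features)
        for ids in randomized_sets
    ], dtype=float)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd > 0:
        z = (obs - mean) / sd
    else:
        z = 0.0 if obs == mean else float(np.inf) * np.sign(obs - mean)
    fold = obs / mean if mean > 0 else np.inf
    return FeatureEnrichmentResult(obs, mean, sd, float(fold), float(z), null)


# ---------------------------------------------------------------------------
# activity coupling + overdispersion-adjusted chi-square
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    observed: np.ndarray      # 2x2 counts
    expected: np.ndarray
    ratio: np.ndarray         # observed / expected
    chi2_raw: float
    sd_boot: float | None = None
    chi2_adj: float | None = None
    p: float | None = None
    boot: np.ndarray | None = None


def _chi2_2x2(table: np.ndarray) -> tuple[float, np.ndarray]:
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    n = table.sum()
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return 0.0, np.full((2, 2), np.nan)
    expected = rows @ cols / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, expected


def _feature_active_matrix(intervals: pd.DataFrame, feats: pd.DataFrame,
                           cell_types: list[str]) -> np.ndarray:
    out = np.zeros((len(intervals), len(cell_types)), dtype=bool)
    for chrom, sub in feats.groupby("chrom"):
        fs = sub["start"].to_numpy()
        fe = sub["end"].to_numpy()
        act = sub[cell_types].to_numpy() == "active"
        rows = np.flatnonzero((intervals["chrom"] == chrom).to_numpy())
        s = intervals["start"].to_numpy()
        e = intervals["end"].to_numpy()
        for i in rows:
            hit = (fs < e[i]) & (fe > s[i])
            if hit.any():
                out[i] = act[hit].any(axis=0)
    return out


def activity_coupling_table(iset: InteractionSet, reg_states: pd.DataFrame,
                            mode: str = "promoter_enhancer",
                            threshold: float = 5.0):
    """2x2 coupling table between regulatory activity and interactions.

    ``promoter_enhancer``: over every (interacting pair, cell type)
    combination, cross-tabulate bait-promoter activity against other-end
    enhancer activity.  ``enhancer_interaction``: over fragment pairs with
    >= 1 high-confidence cell type, cross-tabulate enhancer activity
    against interaction presence per cell type.  The non-active cell pools
    the poised, repressed and inactive states.

    Returns ``(result, bait_tables)`` where ``bait_tables`` holds each
    bait's additive 2x2 contribution (rows for the bait block bootstrap).
    """
    if mode not in ("promoter_enhancer", "enhancer_interaction"):
        raise ValueError(f"unknown mode {mode!r}")
    names = iset.cell_types
    tbl = iset.table
    proms = reg_states[reg_states["feature_class"] == "promoter"]
    enhs = reg_states[reg_states["feature_class"].isin(
        ["distal_enhancer", "proximal_enhancer"])]
    bait_iv = tbl[["baitChr", "baitStart", "baitEnd"]].rename(
        columns={"baitChr": "chrom", "baitStart": "start", "baitEnd": "end"})
    oe_iv = tbl[["oeChr", "oeStart", "oeEnd"]].rename(
        columns={"oeChr": "chrom", "oeStart": "start", "oeEnd": "end"})
    bait_active = _feature_active_matrix(bait_iv, proms, names)
    enh_active = _feature_active_matrix(oe_iv, enhs, names)
    hc = iset.scores >= threshold

    per_bait: dict[int, np.ndarray] = {}
    bait_ids = tbl["baitID"].to_numpy()
    for i in range(len(tbl)):
        t = per_bait.setdefault(int(bait_ids[i]), np.zeros((2, 2)))
        if mode == "promoter_enhancer":
            for c in range(len(names)):
                t[int(~bait_active[i, c]), int(~enh_active[i, c])] += 1
        else:
            if not hc[i].any():
                continue
            for c in range(len(names)):
                t[int(~enh_active[i, c]), int(~hc[i, c])] += 1

    baits = sorted(per_bait)
    bait_tables = pd.DataFrame(
        [per_bait[b].ravel() for b in baits], index=baits,
        columns=["a11", "a10", "a01", "a00"])
    observed = bait_tables.to_numpy().sum(axis=0).reshape(2, 2)
    chi2_raw, expected = _chi2_2x2(observed)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = observed / expected
    return ContingencyResult(observed, expected, ratio, chi2_raw), bait_tables


def overdispersed_chisq(bait_tables: pd.DataFrame | np.ndarray,
                        n_boot: int = 1000, seed: int = 0) -> ContingencyResult:
    """Bait-level block-bootstrap overdispersion adjustment of the chi-square.

    Baits are resampled with replacement ``n_boot`` times; each bootstrap
    table is the weighted sum of per-bait contributions and yields a
    chi-square value.  The bootstrap tables are recentered on the
    independence expectation (the observed association offset is
    subtracted, scaled to each bootstrap total) so that the spread of the
    bootstrap chi-squares estimates the *null* variance of the statistic
    under bait-level dependence, not its noncentral spread.  The adjusted
    statistic is ``chi2_raw * sqrt(2) / sd(boot chi2)`` — an independent,
    well-calibrated null, whose 1-df chi-square has variance 2, is left
    unscaled — and the p-value is its 1-df upper tail.
    """
    contrib = np.asarray(bait_tables, dtype=float)
    if contrib.ndim != 2 or contrib.shape[1] != 4:
        raise ValueError("bait_tables must be (n_baits, 4)")
    n_baits = contrib.shape[0]
    observed = contrib.sum(axis=0).reshape(2, 2)
    chi2_raw, expected = _chi2_2x2(observed)
    rng = np.random.default_rng(seed)
    weights = rng.multinomial(n_baits, np.full(n_baits, 1.0 / n_baits), size=n_boot)
    boot_tables = weights @ contrib  # (n_boot, 4)
    if np.all(np.isfinite(expected)):
        offset = (observed - expected).ravel()
        total_obs = observed.sum()
        scale = boot_tables.sum(axis=1, keepdims=True) / total_obs
        boot_tables = np.clip(boot_tables - scale * offset, 0.0, None)
    rows0 = boot_tables[:, 0] + boot_tables[:, 1]
    rows1 = boot_tables[:, 2] + boot_tables[:, 3]
    cols0 = boot_tables[:, 0] + boot_tables[:, 2]
    cols1 = boot_tables[:, 1] + boot_tables[:, 3]
    n = boot_tables.sum(axis=1)
    ok = (rows0 > 0) & (rows1 > 0) & (cols0 > 0) & (cols1 > 0)
    chi2_boot = np.zeros(n_boot)
    e = np.stack([rows0 * cols0, rows0 * cols1, rows1 * cols0, rows1 * cols1],
                 axis=1) / n[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = ((boot_tables - e) ** 2 / e).sum(axis=1)
    chi2_boot[ok] = vals[ok]
    sd_boot = float(chi2_boot.std(ddof=1))
    if sd_boot == 0:
        chi2_adj = chi2_raw
    else:
        chi2_adj = chi2_raw * np.sqrt(2.0) / sd_boot
    p = float(stats.chi2.sf(chi2_adj, df=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = observed / expected
    return ContingencyResult(observed, expected, ratio, chi2_raw,
                             sd_boot, float(chi2_adj), p, chi2_boot)
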