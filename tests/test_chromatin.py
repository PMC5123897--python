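import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pchicstats import chromatin as ch
from pchicstats import core_io as io
from conftest import make_peak_table


def two_domain_matrix(n=200, boundary=100, inside=20.0, background=1.0):
    C = np.full((n, n), background)
    C[:boundary, :boundary] += inside
    C[boundary:, boundary:] += inside
    return C


class TestDirectionalityIndex:
    def test_distance_only_matrix_has_zero_interior_di(self):
        n = 300
        D = 20.0 / (1 + np.abs(np.subtract.outer(np.arange(n), np.arange(n))))
        track = ch.compute_di(D)
        interior = slice(210, n - 210)  # complete 1-Mb windows on both sides
        np.testing.assert_allclose(track.di[interior], 0, atol=1e-9)

    def test_downstream_bias_is_positive(self):
        n = 100
        C = np.zeros((n, n))
        C[40, 60] = C[60, 40] = 10.0  # contact downstream of bin 40
        track = ch.compute_di(C)
        assert track.di[40] > 0
        assert track.di[60] < 0

    def test_checkerboard_sign_flip_across_boundary(self):
        track = ch.compute_di(two_domain_matrix())
        assert track.smoothed[95] < 0  # end of domain 1: upstream-biased
        assert track.smoothed[105] > 0  # start of domain 2: downstream-biased

    def test_empty_window_gets_zero(self):
        track = ch.compute_di(np.zeros((50, 50)))
        np.testing.assert_array_equal(track.di, 0)
        np.testing.assert_array_equal(track.z, 0)


class TestCallTads:
    def test_flat_track_no_boundaries(self):
        track = ch.compute_di(np.ones((100, 100)))
        tads = ch.call_tads(track)
        assert len(tads) == 1  # whole chromosome, no internal boundary

    def test_planted_boundary_within_one_bin(self):
        track = ch.compute_di(two_domain_matrix())
        tads = ch.call_tads(track)
        assert len(tads) == 2
        boundary = tads["end"].iloc[0]
        assert abs(boundary - 100 * 5000) <= 25_000

    def test_infinite_threshold_silences_everything(self):
        track = ch.compute_di(two_domain_matrix())
        tads = ch.call_tads(track, z_threshold=np.inf)
        assert len(tads) == 1


class TestMergeReplicates:
    def test_identical_replicates_identity(self):
        tads = pd.DataFrame({"chrom": "chr1", "start": [0, 1_000_000],
                             "end": [1_000_000, 2_000_000]})
        merged = ch.merge_replicate_tads([tads, tads.copy()])
        pd.testing.assert_frame_equal(merged, tads)

    def test_shifted_boundaries_averaged(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [1_000_000], "end": [2_000_000]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [1_100_000], "end": [2_100_000]})
        merged = ch.merge_replicate_tads([a, b])
        assert merged["start"].iloc[0] == 1_050_000
        assert merged["end"].iloc[0] == 2_050_000

    def test_half_overlap_pair_removed(self):
        a = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
        b = pd.DataFrame({"chrom": ["chr1"], "start": [500_000], "end": [1_500_000]})
        assert len(ch.merge_replicate_tads([a, b])) == 0


def interaction_row(bait_mid, oe_mid, score, bait_id=1, oe_id=5, width=1000):
    return ("chr1", bait_mid - width // 2, bait_mid + width // 2, bait_id, f"G{bait_id}",
            "chr1", oe_mid - width // 2, oe_mid + width // 2, oe_id, ".",
            float(oe_mid - bait_mid), score)


class TestTadCrossing:
    def test_all_inside_gives_zero(self):
        rows = [interaction_row(500_000, 600_000, 6.0, bait_id=1, oe_id=5),
                interaction_row(500_000, 400_000, 6.0, bait_id=1, oe_id=6)]
        iset = io.InteractionSet(make_peak_table(rows, ["Mon"]), ["Mon"])
        tads = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
        res = ch.tad_crossing(iset, tads, n_perm=100, seed=0)
        assert res.observed == 0.0

    def test_baits_outside_tads_excluded(self):
        rows = [interaction_row(500_000, 600_000, 6.0, bait_id=1, oe_id=5),
                interaction_row(5_000_000, 5_100_000, 6.0, bait_id=2, oe_id=9)]
        iset = io.InteractionSet(make_peak_table(rows, ["Mon"]), ["Mon"])
        tads = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000]})
        res = ch.tad_crossing(iset, tads, n_perm=100, seed=0)
        assert len(res.per_bait) == 1

    def test_random_placement_matches_null(self):
        rng = np.random.default_rng(0)
        rows = []
        tads = pd.DataFrame({"chrom": "chr1",
                             "start": np.arange(0, 5_000_000, 500_000),
                             "end": np.arange(500_000, 5_500_000, 500_000)})
        for b in range(60):
            bait_mid = int(rng.integers(100_000, 4_900_000))
            for j in range(3):
                d = int(rng.choice([-1, 1]) * rng.integers(10_000, 400_000))
                oe = int(np.clip(bait_mid + d, 5000, 5_495_000))
                rows.append(interaction_row(bait_mid, oe, 6.0, bait_id=b,
                                            oe_id=1000 + 10 * b + j))
        iset = io.InteractionSet(make_peak_table(rows, ["Mon"]), ["Mon"])
        res = ch.tad_crossing(iset, tads, n_perm=500, seed=1)
        assert abs(res.observed - res.null_mean) < 4 * res.null_sd


class TestRandomizedPirs:
    def test_distance_histogram_preserved(self, interactome):
        iset, _, _, _, truth = interactome
        hc = iset.subset(iset.high_confidence() & iset.is_cis)
        fmap = truth["fragment_map"]
        draws = ch.randomize_pirs_distance_matched(hc, fmap, n_draws=3, seed=0)
        bin_width = 0.25
        obs_d = np.abs(hc.dist[np.abs(hc.dist) > 0])
        obs_bins = np.floor(np.log2(obs_d) / bin_width)
        bait_mid = 0.5 * (hc.table["baitStart"] + hc.table["baitEnd"]).to_numpy()
        for ids in draws:
            mids = fmap.midpoints(ids)
            d = np.abs(mids - bait_mid)
            got_bins = np.floor(np.log2(d) / bin_width)
            # identical binned histogram up to the single allowed widening
            assert np.mean(got_bins == obs_bins) > 0.9
            assert len(ids) == len(obs_bins)

    def test_draws_avoid_observed_pirs(self, interactome):
        iset, _, _, _, truth = interactome
        hc = iset.subset(iset.high_confidence() & iset.is_cis)
        pirs = set(iset.table["oeID"]) | set(iset.table["baitID"])
        draws = ch.randomize_pirs_distance_matched(hc, truth["fragment_map"],
                                                   n_draws=2, seed=1)
        for ids in draws:
            assert not (set(ids.tolist()) & pirs)


class TestFeatureEnrichment:
    def test_self_features_maximal_signal(self, interactome):
        iset, _, _, _, truth = interactome
        fmap = truth["fragment_map"]
        hc = iset.subset(iset.high_confidence() & iset.is_cis)
        pir_ids = hc.table["oeID"].to_numpy()
        feats = fmap.intervals(pir_ids)
        draws = ch.randomize_pirs_distance_matched(hc, fmap, n_draws=30, seed=2)
        res = ch.feature_enrichment(pir_ids, feats, draws, fmap)
        assert res.z > 3
        assert res.observed == len(pir_ids)

    def test_zero_features(self, interactome):
        iset, _, _, _, truth = interactome
        fmap = truth["fragment_map"]
        hc = iset.subset(iset.high_confidence() & iset.is_cis)
        pir_ids = hc.table["oeID"].to_numpy()
        feats = pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [10]})
        draws = ch.randomize_pirs_distance_matched(hc, fmap, n_draws=10, seed=3)
        res = ch.feature_enrichment(pir_ids, feats, draws, fmap)
        assert res.observed == 0

    def test_pir_independent_features_calibrated(self, interactome):
        # fragment-level features assigned independently of PIR status:
        # observed and randomized overlaps are exchangeable, z ~ N(0,1)
        iset, _, _, _, truth = interactome
        fmap = truth["fragment_map"]
        hc = iset.subset(iset.high_confidence() & iset.is_cis)
        pir_ids = hc.table["oeID"].to_numpy()
        all_frags = fmap.table
        zs = []
        for rep in range(60):
            rng = np.random.default_rng(1000 + rep)
            chosen = all_frags.sample(frac=0.25, random_state=rng.integers(2 ** 31))
            feats = chosen[["chrom", "start", "end"]]
            draws = ch.randomize_pirs_distance_matched(hc, fmap, n_draws=50,
                                                       seed=2000 + rep)
            res = ch.feature_enrichment(pir_ids, feats, draws, fmap)
            zs.append(res.z)
        assert abs(np.mean(zs)) < 0.5
        assert 0.5 < np.std(zs) < 2.0


class TestOverdispersedChisq:
    def test_identical_row_proportions(self):
        bait_tables = pd.DataFrame(np.tile([10, 10, 10, 10], (30, 1)),
                                   columns=["a11", "a10", "a01", "a00"])
        res = ch.overdispersed_chisq(bait_tables, n_boot=200, seed=0)
        assert res.chi2_raw == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.99

    def test_independent_baits_leave_chi2_unscaled(self):
        # one observation per bait under independence: sd_boot near sqrt(2)
        rng = np.random.default_rng(1)
        factors = []
        for rep in range(30):
            cells = rng.multinomial(1, [0.25] * 4, size=400)
            res = ch.overdispersed_chisq(cells, n_boot=1000, seed=rep)
            factors.append(np.sqrt(2.0) / res.sd_boot)
        assert np.mean(factors) == pytest.approx(1.0, abs=0.1)

    def test_duplicated_baits_adjusted_out(self):
        rng = np.random.default_rng(2)
        cells = rng.multinomial(1, [0.3, 0.2, 0.3, 0.2], size=300).astype(float)
        base = ch.overdispersed_chisq(cells, n_boot=1000, seed=0)
        dup = ch.overdispersed_chisq(np.vstack([c * 4 for c in cells]),
                                     n_boot=1000, seed=0)
        assert dup.chi2_raw == pytest.approx(4 * base.chi2_raw, rel=1e-9)
        assert dup.chi2_adj == pytest.approx(base.chi2_adj, rel=0.15)

    def test_null_p_calibrated(self):
        rng = np.random.default_rng(3)
        ps = []
        for rep in range(200):
            cells = rng.multinomial(1, [0.25] * 4, size=200)
            res = ch.overdispersed_chisq(cells, n_boot=200, seed=rep)
            ps.append(res.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestActivityCoupling:
    def test_coupled_simulation_enriches_active_active(self, interactome):
        iset, reg, _, _, _ = interactome
        res, bait_tables = ch.activity_coupling_table(iset, reg,
                                                      mode="promoter_enhancer")
        assert res.ratio[0, 0] > 1.0  # active promoter x active enhancer
        full = ch.overdispersed_chisq(bait_tables, n_boot=500, seed=0)
        assert full.p < 0.05

    def test_independent_states_ratio_near_one(self):
        import pchicstats.synthetic_data as sd
        cfg = sd.SimConfig(seed=42, coupling=0.0, n_genes=120,
                           chrom_lengths={"chr1": 8_000_000})
        fmap = sd.simulate_fragment_map(cfg)
        iset, reg, _, _, _ = sd.simulate_interactome(cfg, fmap)
        res, _ = ch.activity_coupling_table(iset, reg, mode="enhancer_interaction")
        assert res.ratio[0, 0] == pytest.approx(1.0, abs=0.15)

    def test_unknown_mode_rejected(self, interactome):
        iset, reg, _, _, _ = interactome
        with pytest.raises(ValueError):
            ch.activity_coupling_table(iset, reg, mode="bogus")
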