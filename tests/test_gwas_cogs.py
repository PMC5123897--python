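import numpy as np
import pandas as pd
import pytest

from pchicstats import core_io as io
from pchicstats import gwas_cogs as gc
from pchicstats import synthetic_data as sd
from conftest import make_peak_table


def gwas_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "a1", "a2", "maf", "p"])


class TestQcFilter:
    def test_isolated_strong_snp_dropped(self):
        gwas = gwas_frame([("chr1", 1_000_000, "A", "G", 0.2, 1e-9),
                           ("chr1", 3_000_000, "A", "G", 0.2, 0.5)])
        out = gc.qc_filter(gwas)
        assert len(out) == 1
        assert out["p"].iloc[0] == 0.5

    def test_supported_snp_kept(self):
        gwas = gwas_frame([("chr1", 1_000_000, "A", "G", 0.2, 1e-9),
                           ("chr1", 1_010_000, "A", "G", 0.2, 1e-6)])
        out = gc.qc_filter(gwas)
        assert len(out) == 2

    def test_sub_threshold_snp_never_dropped(self):
        gwas = gwas_frame([("chr1", 1_000_000, "A", "G", 0.2, 1e-7),
                           ("chr1", 9_000_000, "A", "G", 0.2, 0.9)])
        out = gc.qc_filter(gwas)
        assert len(out) == 2

    def test_ld_arm_supports_distant_snp(self):
        # supporter is 60 kb away (outside the window) but in perfect LD
        H = np.array([[0, 1, 0, 1, 0, 1], [0, 1, 0, 1, 0, 1]])
        legend = pd.DataFrame({"snp_id": ["a", "b"], "chrom": "chr1",
                               "pos": [1_000_000, 1_060_000], "a0": "A", "a1": "G"})
        panel = io.HaplotypePanel(legend, H)
        gwas = gwas_frame([("chr1", 1_000_000, "A", "G", 0.2, 1e-9),
                           ("chr1", 1_060_000, "A", "G", 0.2, 1e-6)])
        assert len(gc.qc_filter(gwas, panel)) == 2
        assert len(gc.qc_filter(gwas, panel=None)) == 1


class TestMaskRegion:
    def test_mhc_interval(self):
        gwas = gwas_frame([("chr6", 30_000_000, "A", "G", 0.2, 0.5),
                           ("chr6", 24_999_999, "A", "G", 0.2, 0.5),
                           ("chr1", 30_000_000, "A", "G", 0.2, 0.5)])
        out = gc.mask_region(gwas)
        assert len(out) == 2
        assert 30_000_000 not in out.loc[out["chrom"] == "chr6", "pos"].tolist()


class TestPartitionBlocks:
    def test_constant_rate_arithmetic(self):
        # 1 cM/Mb over 1 Mb: ten 100-kb blocks
        rmap = io.RecombMap([0, 1_000_000], [0.0, 1.0])
        blocks = gc.partition_blocks(rmap, step=0.1)
        assert len(blocks) == 10
        widths = [b.end - b.start for b in blocks[1:-1]]
        np.testing.assert_allclose(widths, 100_000)

    def test_ceiling_rule(self):
        rmap = io.RecombMap([0, 1_000_000], [0.0, 0.35])
        assert len(gc.partition_blocks(rmap, step=0.1)) == 4

    def test_single_block_when_step_spans_map(self):
        rmap = io.RecombMap([0, 1_000_000], [0.0, 0.35])
        assert len(gc.partition_blocks(rmap, step=0.35)) == 1

    def test_assignment_covers_every_position(self):
        rmap = io.RecombMap([0, 1_000_000], [0.0, 1.0])
        blocks = gc.partition_blocks(rmap)
        ids = gc.assign_blocks([0, 50_000, 550_000, 999_999], blocks)
        assert ids.tolist() == [0, 0, 5, 9]


def simple_panel(pos, H):
    legend = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(pos))], "chrom": "chr1",
        "pos": pos, "a0": "A", "a1": "G",
    })
    return io.HaplotypePanel(legend, np.asarray(H))


class TestPmi:
    def setup_case(self, h_missing):
        # s0 typed in study; s1 untyped, LD with s0 controlled by h_missing
        pos = [100, 200]
        H = np.array([[0, 1, 0, 1, 0, 1, 0, 1], h_missing])
        panel = simple_panel(pos, H)
        rmap = io.RecombMap([0, 1000], [0.0, 0.05])
        blocks = gc.partition_blocks(rmap)
        gwas = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "a1": "A",
                             "a2": "G", "maf": [0.5], "p": [3e-6], "n": 5000})
        return gc.pmi_impute(gwas, panel, blocks)

    def test_perfect_ld_copies_p(self):
        out = self.setup_case([0, 1, 0, 1, 0, 1, 0, 1])
        imputed = out[out["imputed"]]
        assert len(imputed) == 1
        assert imputed["p"].iloc[0] == pytest.approx(3e-6)

    def test_weak_ld_discarded(self):
        # r^2 = 0.25 < 0.6: the untyped SNP does not appear
        out = self.setup_case([0, 1, 1, 0, 0, 1, 1, 1])
        assert not out["imputed"].any()
        assert len(out) == 1

    def test_study_snp_not_in_panel_discarded(self):
        pos = [100]
        panel = simple_panel(pos, [[0, 1, 0, 1]])
        rmap = io.RecombMap([0, 1000], [0.0, 0.05])
        gwas = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 999],
                             "a1": "A", "a2": "G", "maf": 0.5,
                             "p": [0.5, 1e-4], "n": 5000})
        out = gc.pmi_impute(gwas, panel, gc.partition_blocks(rmap))
        assert out["pos"].tolist() == [100]

    def test_low_maf_panel_snps_skipped(self):
        pos = [100, 200]
        H = np.zeros((2, 200), dtype=int)
        H[0, :100] = 1
        H[1, 0] = 1  # MAF 0.5%
        panel = simple_panel(pos, H)
        rmap = io.RecombMap([0, 1000], [0.0, 0.05])
        gwas = pd.DataFrame({"chrom": ["chr1"], "pos": [100], "a1": "A",
                             "a2": "G", "maf": [0.5], "p": [1e-6], "n": 5000})
        out = gc.pmi_impute(gwas, panel, gc.partition_blocks(rmap))
        assert not out["imputed"].any()


class TestWakefield:
    def test_abf_formula_value(self):
        # z=3, V=0.02, W=0.04: ABF = sqrt(1/3) * e^3
        want = np.sqrt(1.0 / 3.0) * np.exp(3.0)
        assert gc.wakefield_abf(np.array([3.0]), np.array([0.02]), 0.04)[0] == \
            pytest.approx(want, rel=1e-12)
        assert want == pytest.approx(11.60, abs=0.005)

    def test_identical_snps_share_posterior(self):
        gwas = pd.DataFrame({
            "chrom": "chr1", "pos": [10, 20, 30], "maf": 0.2, "p": 1e-4,
            "n": 10_000, "snp_id": ["a", "b", "c"],
        })
        rmap = io.RecombMap([0, 100], [0.0, 0.05])
        post = gc.wakefield_posteriors(gwas, gc.partition_blocks(rmap))
        np.testing.assert_allclose(post["ppi"], 1 / 3)

    def test_posterior_mass_conserved(self, haplotypes):
        panel, rmap = haplotypes
        cfg = sd.SimConfig(seed=31)
        gwas = sd.simulate_gwas(panel, rmap, None, cfg)
        blocks = gc.partition_blocks(rmap)
        post = gc.wakefield_posteriors(gwas, blocks)
        sums = post.groupby("block")["ppi"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_zero_maf_rejected(self):
        gwas = pd.DataFrame({"chrom": ["chr1"], "pos": [10], "maf": [0.0],
                             "p": [0.5], "n": 1000})
        rmap = io.RecombMap([0, 100], [0.0, 0.05])
        with pytest.raises(ValueError):
            gc.wakefield_posteriors(gwas, gc.partition_blocks(rmap))

    def test_include_null_shrinks_ppi(self):
        gwas = pd.DataFrame({"chrom": "chr1", "pos": [10, 20], "maf": 0.2,
                             "p": [0.5, 0.5], "n": 1000})
        rmap = io.RecombMap([0, 100], [0.0, 0.05])
        blocks = gc.partition_blocks(rmap)
        a = gc.wakefield_posteriors(gwas, blocks)
        b = gc.wakefield_posteriors(gwas, blocks,
                                    gc.FineMapConfig(include_null=True))
        assert (b["ppi"] < a["ppi"]).all()


class TestGeneComponents:
    def toy(self):
        # six 1-kb fragments; bait = fragment 2; PIR = fragment 5
        fmap = io.FragmentMap(pd.DataFrame({
            "chrom": "chr1", "start": np.arange(6) * 1000,
            "end": (np.arange(6) + 1) * 1000, "frag_id": np.arange(6),
        }))
        gene = io.GeneModel("G1", "chr1", "+", 2500, (2,))
        rows = [("chr1", 2000, 3000, 2, "G1", "chr1", 5000, 6000, 5, ".",
                 3000.0, 6.0)]
        iset = io.InteractionSet(make_peak_table(rows, ["Mon"]), ["Mon"])
        snps = pd.DataFrame({
            "snp_id": [f"r{i}" for i in range(6)], "chrom": "chr1",
            "pos": [500, 1500, 2500, 3500, 4500, 5500],
        })
        coding = pd.DataFrame({"snp_id": ["r5"], "gene_id": ["G1"],
                               "consequence": ["missense"]})
        return gene, iset, coding, fmap, snps

    def test_manual_assignment(self):
        gene, iset, coding, fmap, snps = self.toy()
        comp = gc.gene_components(gene, iset, ["Mon"], coding, fmap, snps)
        assert comp["promoter"] == {"r1", "r2", "r3"}  # bait +/- one fragment
        assert comp["coding"] == {"r5"}
        assert comp["pir"] == set()  # r5 is coding, precedence wins

    def test_coding_precedence_over_pir(self):
        gene, iset, coding, fmap, snps = self.toy()
        comp = gc.gene_components(gene, iset, ["Mon"], coding, fmap, snps)
        assert "r5" not in comp["pir"] and "r5" in comp["coding"]

    def test_empty_tissue_set_empty_pir(self):
        gene, iset, coding, fmap, snps = self.toy()
        comp = gc.gene_components(gene, iset, [], coding, fmap, snps)
        assert comp["pir"] == set()


def brute_force_genescore(posteriors, component_snps):
    """Survival-product enumeration over blocks."""
    survive = 1.0
    for block, sub in posteriors.groupby("block"):
        mass = sub.loc[sub["snp_id"].isin(component_snps), "ppi"].sum()
        survive *= (1.0 - min(mass, 1.0))
    return 1.0 - survive


class TestCogsScore:
    def test_two_block_arithmetic(self):
        post = pd.DataFrame({
            "snp_id": ["a", "b", "c", "d"], "block": [0, 0, 1, 1],
            "ppi": [0.5, 0.5, 0.5, 0.5],
            "chrom": "chr1", "pos": [1, 2, 3, 4],
        })
        res = gc.cogs_score("G", post, {"coding": set(), "promoter": set(),
                                        "pir": {"a", "c"}})
        assert res.genescore == pytest.approx(0.75)

    def test_single_block_equals_block_score(self):
        post = pd.DataFrame({"snp_id": ["a", "b"], "block": 0,
                             "ppi": [0.3, 0.7], "chrom": "chr1", "pos": [1, 2]})
        res = gc.cogs_score("G", post, {"coding": {"a"}, "promoter": set(),
                                        "pir": set()})
        assert res.genescore == pytest.approx(0.3)

    def test_full_coverage_gives_one(self):
        post = pd.DataFrame({"snp_id": ["a", "b"], "block": 0,
                             "ppi": [0.4, 0.6], "chrom": "chr1", "pos": [1, 2]})
        res = gc.cogs_score("G", post, {"coding": set(), "promoter": {"a", "b"},
                                        "pir": set()})
        assert res.genescore == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n_snps = rng.integers(3, 21)
            blocks = rng.integers(0, 3, n_snps)
            raw = rng.exponential(1, n_snps)
            ppi = np.concatenate([
                raw[blocks == b] / raw[blocks == b].sum()
                for b in range(3) if (blocks == b).any()])
            ids = np.concatenate([
                np.array([f"s{i}" for i in range(n_snps)])[blocks == b]
                for b in range(3) if (blocks == b).any()])
            post = pd.DataFrame({"snp_id": ids, "block": np.sort(blocks),
                                 "ppi": ppi, "chrom": "chr1",
                                 "pos": np.arange(n_snps)})
            chosen = set(rng.choice([f"s{i}" for i in range(n_snps)],
                                    rng.integers(1, n_snps), replace=False))
            res = gc.cogs_score("G", post, {"coding": chosen,
                                            "promoter": set(), "pir": set()})
            assert res.genescore == pytest.approx(
                brute_force_genescore(post, chosen), abs=1e-12)

    def test_monotone_in_tissue_set(self, interactome, haplotypes):
        iset, _, _, genes, truth = interactome
        panel, rmap = haplotypes
        cfg = sd.SimConfig(seed=37)
        gwas = sd.simulate_gwas(panel, rmap, None, cfg)
        blocks = gc.partition_blocks(rmap)
        post = gc.wakefield_posteriors(gwas, blocks)
        coding = pd.DataFrame(columns=["snp_id", "gene_id", "consequence"])
        small = gc.cogs_scores(genes[:10], post, iset, coding,
                               truth["fragment_map"], ["Mon"])
        big = gc.cogs_scores(genes[:10], post, iset, coding,
                             truth["fragment_map"], iset.cell_types)
        assert (big["genescore"].to_numpy() >=
                small["genescore"].to_numpy() - 1e-12).all()


class TestTadScore:
    def test_two_block_arithmetic(self):
        post = pd.DataFrame({
            "snp_id": ["a", "b"], "block": [0, 1], "ppi": [0.2, 0.3],
            "chrom": "chr1", "pos": [100, 900],
        })
        tads = {"Mon": pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                     "end": [1000]})}
        genes = [io.GeneModel("G1", "chr1", "+", 500, (0,))]
        out = gc.tad_score(tads, post, set(), genes)
        assert out["tad_score"].iloc[0] == pytest.approx(1 - 0.8 * 0.7)

    def test_full_block_in_tad_scores_one(self):
        post = pd.DataFrame({"snp_id": ["a"], "block": [0], "ppi": [1.0],
                             "chrom": "chr1", "pos": [100]})
        tads = {"Mon": pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                     "end": [1000]})}
        genes = [io.GeneModel("G1", "chr1", "+", 500, (0,))]
        out = gc.tad_score(tads, post, set(), genes)
        assert out["tad_score"].iloc[0] == pytest.approx(1.0)

    def test_gene_outside_tads_missing(self):
        post = pd.DataFrame({"snp_id": ["a"], "block": [0], "ppi": [1.0],
                             "chrom": "chr1", "pos": [100]})
        tads = {"Mon": pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                     "end": [1000]})}
        genes = [io.GeneModel("G1", "chr1", "+", 5000, (0,))]
        out = gc.tad_score(tads, post, set(), genes)
        assert np.isnan(out["tad_score"].iloc[0])

    def test_coding_snps_removed(self):
        post = pd.DataFrame({"snp_id": ["a", "b"], "block": [0, 0],
                             "ppi": [0.6, 0.4], "chrom": "chr1",
                             "pos": [100, 200]})
        tads = {"Mon": pd.DataFrame({"chrom": ["chr1"], "start": [0],
                                     "end": [1000]})}
        genes = [io.GeneModel("G1", "chr1", "+", 500, (0,))]
        out = gc.tad_score(tads, post, {"a"}, genes)
        assert out["tad_score"].iloc[0] == pytest.approx(0.4)


class TestPrioritize:
    def test_threshold_boundary(self):
        df = pd.DataFrame({"gene_id": ["a", "b"], "genescore": [0.51, 0.49]})
        out = gc.prioritize(df)
        assert out["gene_id"].tolist() == ["a"]

    def test_tie_break_by_gene_id(self):
        df = pd.DataFrame({"gene_id": ["z", "a"], "genescore": [0.9, 0.9]})
        out = gc.prioritize(df)
        assert out["gene_id"].tolist() == ["a", "z"]

    def test_empty_input(self):
        df = pd.DataFrame({"gene_id": [], "genescore": []})
        assert len(gc.prioritize(df)) == 0
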