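import numpy as np
import pytest

from cnscan import cnscall, conscore
from cnscan.alnio import ConfigError, GenomeDict
from cnscan.cnscall import (CDS, INTERGENIC, INTRON, UTR3, UTR5, CNSInterval,
                            LABEL_NAMES, RegionIndex, build_region_index,
                            call_cns, categorize, constrained_fraction,
                            feature_overlap, bigfoot_genes,
                            genes_downstream_of_cns, summarize)

from conftest import make_track, write_gff
from oracles import call_cns_oracle


def regions_of(labels):
    return RegionIndex({"chr1": np.asarray(labels, dtype=np.uint8)})


def intervals(cns):
    return [(c.start, c.end) for c in cns]


class TestRegionIndex:
    def test_no_genes_all_intergenic(self, two_exon_models):
        from cnscan.alnio import GeneModels
        genome = GenomeDict({"chr1": 100}, "ref")
        idx = build_region_index(GeneModels([]), genome)
        assert (idx.labels["chr1"] == INTERGENIC).all()

    def test_two_exon_toy_label_counts(self, two_exon_models):
        models, genome = two_exon_models("+")
        idx = build_region_index(models, genome)
        counts = idx.counts()
        assert counts["CDS"] == 100  # [50,100) + [200,250)
        assert counts["UTR5"] == 50
        assert counts["UTR3"] == 50
        assert counts["intron"] == 100
        assert counts["intergenic"] == 1000 - 300

    def test_minus_strand_swaps_utr_positions(self, two_exon_models):
        models, genome = two_exon_models("-")
        idx = build_region_index(models, genome)
        assert (idx.labels["chr1"][0:50] == UTR3).all()
        assert (idx.labels["chr1"][250:300] == UTR5).all()

    def test_cds_wins_over_other_isoforms_intron(self, tmp_path):
        from cnscan import alnio
        gff = write_gff(tmp_path / "iso.gff3", [
            "chr1\t.\tgene\t1\t300\t.\t+\t.\tID=g1",
            # isoform A: intron over [100,200)
            "chr1\t.\tmRNA\t1\t300\t.\t+\t.\tID=tA;Parent=g1",
            "chr1\t.\texon\t1\t100\t.\t+\t.\tID=eA1;Parent=tA",
            "chr1\t.\texon\t201\t300\t.\t+\t.\tID=eA2;Parent=tA",
            "chr1\t.\tCDS\t1\t100\t.\t+\t0\tID=cA1;Parent=tA",
            "chr1\t.\tCDS\t201\t300\t.\t+\t0\tID=cA2;Parent=tA",
            # isoform B: CDS covering [100,200)
            "chr1\t.\tmRNA\t1\t300\t.\t+\t.\tID=tB;Parent=g1",
            "chr1\t.\texon\t1\t300\t.\t+\t.\tID=eB1;Parent=tB",
            "chr1\t.\tCDS\t1\t300\t.\t+\t0\tID=cB1;Parent=tB",
        ])
        genome = GenomeDict({"chr1": 400}, "ref")
        models = alnio.read_gff3(gff, genome)
        idx = build_region_index(models, genome)
        assert (idx.labels["chr1"][100:200] == CDS).all()


class TestCallCns:
    def test_merge_example(self):
        # scores: 0-3 = 0.8, 4-5 = 0.5, 6-9 = 0.9, rest 0; no CDS
        matched = [8] * 4 + [5] * 2 + [9] * 4 + [0] * 10
        track = make_track({"chr1": matched}, n_species=10)
        cns = call_cns(track, regions_of([INTERGENIC] * 20))
        assert intervals(cns) == [(0, 10)]
        # mean over ALL 10 bases including the sub-threshold gap:
        # (4*0.8 + 2*0.5 + 4*0.9) / 10, confirmed by the naive oracle
        assert cns[0].mean_score == pytest.approx(0.78)
        assert call_cns_oracle(matched, 10, [False] * 20, 0.7, 3, 6) == [(0, 10)]

    def test_no_merge_beyond_gap(self):
        matched = [8] * 4 + [0] * 5 + [8] * 5 + [0] * 6
        track = make_track({"chr1": matched}, n_species=10)
        cns = call_cns(track, regions_of([INTERGENIC] * 20))
        assert cns == []  # gap 5 > 3, both runs < 6 bp

    def test_cds_truncation_drops_short_candidate(self):
        matched = [8] * 10 + [0] * 10
        labels = [CDS] * 5 + [INTERGENIC] * 15
        track = make_track({"chr1": matched}, n_species=10)
        cns = call_cns(track, regions_of(labels))
        assert cns == []  # candidate [5,10) has length 5 < 6

    def test_merge_never_bridges_cds(self):
        matched = [8] * 6 + [0, 0] + [8] * 6
        labels = [INTERGENIC] * 6 + [CDS, CDS] + [INTERGENIC] * 6
        track = make_track({"chr1": matched}, n_species=10)
        cns = call_cns(track, regions_of(labels))
        assert intervals(cns) == [(0, 6), (8, 14)]

    def test_threshold_out_of_range(self):
        track = make_track({"chr1": [0]}, n_species=1)
        with pytest.raises(ConfigError):
            call_cns(track, regions_of([0]), threshold=1.5)

    def test_output_sorted_disjoint_no_cds(self, sim_track, sim_bundle):
        cfg, paths, truth, objects = sim_bundle
        regions = build_region_index(objects["models"], cfg.genome())
        cns = call_cns(sim_track, regions)
        prev_end = -1
        for c in cns:
            assert c.start >= prev_end
            assert c.length >= 6
            assert not (regions.labels[c.chrom][c.start:c.end] == CDS).any()
            prev_end = c.end

    @pytest.mark.parametrize("seed", range(20))
    def test_against_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        L = 60
        matched = rng.integers(0, 11, size=L)
        cds_mask = rng.random(L) < 0.15
        labels = np.where(cds_mask, CDS, INTERGENIC)
        thr = rng.choice([0.5, 0.7, 0.9])
        gap = int(rng.integers(0, 5))
        min_len = int(rng.integers(1, 9))
        track = make_track({"chr1": matched}, n_species=10)
        got = intervals(call_cns(track, regions_of(labels), thr, gap, min_len))
        want = call_cns_oracle(matched.tolist(), 10, cds_mask.tolist(), thr,
                               gap, min_len)
        assert got == want

    def test_total_bp_monotonicity(self):
        rng = np.random.default_rng(99)
        matched = rng.integers(0, 11, size=500)
        labels = np.where(rng.random(500) < 0.1, CDS, INTERGENIC)
        track = make_track({"chr1": matched}, n_species=10)
        regions = regions_of(labels)

        def bp(thr=0.7, gap=3, ml=6):
            return sum(c.length for c in call_cns(track, regions, thr, gap, ml))

        assert bp(thr=0.5) >= bp(thr=0.7) >= bp(thr=0.9)  # thr: non-increasing
        assert bp(gap=0) <= bp(gap=3) <= bp(gap=6)        # gap: non-decreasing
        assert bp(ml=1) >= bp(ml=6) >= bp(ml=12)          # min_len: non-incr.


class TestCategorize:
    def test_majority(self):
        labels = np.array([INTRON] * 7 + [INTERGENIC] * 3, dtype=np.uint8)
        assert categorize((0, 10), labels) == "intron"

    def test_all_intergenic(self):
        labels = np.full(10, INTERGENIC, dtype=np.uint8)
        assert categorize((0, 10), labels) == "intergenic"

    def test_tie_prefers_utr3_over_intron(self):
        labels = np.array([UTR3] * 5 + [INTRON] * 5, dtype=np.uint8)
        assert categorize((0, 10), labels) == "UTR3"

    def test_tie_prefers_utr5_over_utr3(self):
        labels = np.array([UTR5] * 5 + [UTR3] * 5, dtype=np.uint8)
        assert categorize((0, 10), labels) == "UTR5"


class TestSummarize:
    def test_single_cns(self):
        cns = [CNSInterval("chr1", 0, 8, 0.8, "intron")]
        s = summarize(cns, "all")
        assert s.total_number == 1 and s.total_length == 8
        assert s.mean_length == 8 and s.median_length == 8
        assert s.pct_by_category["intron"] == 100.0

    def test_percentages_partition(self, sim_track, sim_bundle):
        cfg, paths, truth, objects = sim_bundle
        regions = build_region_index(objects["models"], cfg.genome())
        cns = call_cns(sim_track, regions)
        s = summarize(cns, "all")
        assert s.total_length == sum(c.length for c in cns)
        assert sum(s.pct_by_category.values()) == pytest.approx(100.0, abs=0.2)

    def test_median_lower_middle_for_even_counts(self):
        cns = [CNSInterval("chr1", 0, n, 1.0, "intergenic")
               for n in (6, 7, 10, 20)]
        assert summarize(cns, "x").median_length == 7

    def test_empty(self):
        s = summarize([], "x")
        assert s.total_number == 0 and s.total_length == 0


class TestConstrainedFraction:
    def test_all_zero(self):
        track = make_track({"chr1": [0] * 10}, n_species=5)
        frac, per = constrained_fraction(track, regions_of([INTERGENIC] * 10))
        assert frac == 0.0 and sum(per.values()) == 0

    def test_all_ones(self):
        track = make_track({"chr1": [5] * 10}, n_species=5)
        frac, per = constrained_fraction(track, regions_of([INTERGENIC] * 10))
        assert frac == 1.0 and per["intergenic"] == 10

    def test_planted_bp_exact(self):
        # constrained bases are exactly the positions given matched >= 0.7*n
        rng = np.random.default_rng(4)
        matched = rng.integers(0, 11, size=200)
        labels = rng.integers(0, 5, size=200)
        track = make_track({"chr1": matched}, n_species=10)
        frac, per = constrained_fraction(track, regions_of(labels))
        want = int((matched >= 7).sum())
        assert sum(per.values()) == want
        assert frac == want / 200


def _gene(gid, start, end, strand="+", chrom="chr1"):
    from cnscan.alnio import Gene, GeneModels, Transcript
    t = Transcript(f"{gid}.t", chrom, strand, start, end, [(start, end)],
                   [(start, end)])
    return Gene(gid, chrom, strand, [t])


def _models(*genes):
    from cnscan.alnio import GeneModels
    return GeneModels(list(genes))


class TestGeneAssociation:
    def test_no_cns_empty(self):
        models = _models(_gene("g1", 100, 200))
        assert genes_downstream_of_cns([], models) == set()
        assert bigfoot_genes(models, []) == set()
        frac, by_class = feature_overlap([], [("chr1", 0, 10, "repeat")])
        assert frac is None

    def test_downstream_plus_strand(self):
        models = _models(_gene("g1", 1500, 2000, "+"))
        cns = [CNSInterval("chr1", 400, 600, 1.0, "intergenic")]
        assert genes_downstream_of_cns(cns, models, window=1000) == {"g1"}
        assert genes_downstream_of_cns(cns, models, window=800) == set()

    def test_downstream_minus_strand(self):
        # for a minus gene the upstream side is the higher-coordinate side
        models = _models(_gene("g1", 100, 500, "-"))
        cns = [CNSInterval("chr1", 700, 800, 1.0, "intergenic")]
        assert genes_downstream_of_cns(cns, models, window=1000) == {"g1"}
        cns_wrong_side = [CNSInterval("chr1", 0, 50, 1.0, "intergenic")]
        assert genes_downstream_of_cns(cns_wrong_side, models) == set()

    def test_cns_downstream_mode_flips_direction(self):
        models = _models(_gene("g1", 1500, 2000, "+"))
        cns = [CNSInterval("chr1", 1600, 1700, 1.0, "intron")]
        assert genes_downstream_of_cns(cns, models,
                                       mode="cns_downstream") == {"g1"}

    def test_bigfoot_thresholds_as_printed(self):
        gene = _gene("g1", 1000, 6000)  # span 5 kb > 4 kb
        cns = [CNSInterval("chr1", 1000 + 100 * i, 1050 + 100 * i, 1.0,
                           "intron") for i in range(6)]
        assert bigfoot_genes(_models(gene), cns) == {"g1"}
        assert bigfoot_genes(_models(gene), cns[:5]) == set()
        small = _gene("g2", 0, 3999)
        assert bigfoot_genes(_models(small), cns) == set()

    def test_feature_overlap_planted_fraction(self):
        cns = [CNSInterval("chr1", i * 100, i * 100 + 50, 1.0, "intergenic")
               for i in range(10)]
        # repeats overlapping exactly the first 2 CNSs
        feats = [("chr1", 0, 10, "repeat"), ("chr1", 149, 151, "repeat"),
                 ("chr1", 5000, 5100, "repeat")]
        frac, by_class = feature_overlap(cns, feats)
        assert frac == pytest.approx(0.2)
        assert by_class["repeat"] == pytest.approx(0.2)

    def test_feature_overlap_touching_does_not_count(self):
        cns = [CNSInterval("chr1", 100, 150, 1.0, "intergenic")]
        assert feature_overlap(cns, [("chr1", 150, 200, "r")])[0] == 0.0
        assert feature_overlap(cns, [("chr1", 149, 200, "r")])[0] == 1.0


class TestBedExport:
    def test_bed6_fields(self):
        cns = [CNSInterval("chr1", 0, 10, 0.789, "intron")]
        rows = cnscall.cns_to_bed(cns)
        assert rows == [("chr1", 0, 10, "intron", 789, "+")]
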