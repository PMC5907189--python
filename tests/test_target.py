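"""HPR/OPR construction: filter boundaries, best-hit choice, assembly."""

import numpy as np
import pytest

import panelift as pl
from panelift.io_formats import Transcript
from conftest import occupancy


def aln(query="p1", subject="chr1", identity=95.0, evalue=1e-30, bitscore=200.0,
        sstart=1001, send=1120, length=120):
    return pl.AlignmentRecord(query, subject, identity, length, 0, 0, 1, length,
                              sstart, send, evalue, bitscore)


class TestFilterAlignments:
    def test_inclusive_boundaries(self):
        assert pl.filter_alignments([aln(identity=85.0, evalue=1e-10)]) != []
        assert pl.filter_alignments([aln(identity=84.9, evalue=1e-30)]) == []
        assert pl.filter_alignments([aln(identity=99.0, evalue=1e-5)]) == []

    def test_predicate_rowwise(self):
        records = [
            aln("p1", identity=90, evalue=1e-20),   # pass
            aln("p2", identity=80, evalue=1e-20),   # fail identity
            aln("p3", identity=90, evalue=1e-8),    # fail evalue
            aln("p4", identity=85.0, evalue=1e-10), # boundary pass
            aln("p5", identity=84.99, evalue=1e-10),
            aln("p6", identity=100.0, evalue=0.0),  # pass
        ]
        expect = [r for r in records if r.identity >= 85.0 and r.evalue <= 1e-10]
        assert pl.filter_alignments(records, mode="all") == expect

    def test_best_hit_by_bitscore_then_evalue(self):
        records = [
            aln("p1", bitscore=100, evalue=1e-20, sstart=1001, send=1120),
            aln("p1", bitscore=300, evalue=1e-15, sstart=5001, send=5120),
            aln("p1", bitscore=300, evalue=1e-25, sstart=9001, send=9120),
        ]
        (best,) = pl.filter_alignments(records, mode="best")
        assert best.sstart == 9001  # highest bitscore, then lowest e-value

    def test_mode_all_keeps_multiple_loci(self):
        records = [aln("p1", sstart=1001, send=1120), aln("p1", sstart=9001, send=9120)]
        assert len(pl.filter_alignments(records, mode="all")) == 2
        assert len(pl.filter_alignments(records, mode="best")) == 1

    def test_probe_mapping_rate(self):
        records = [aln("p1"), aln("p2", identity=80.0)]
        passing = pl.filter_alignments(records, mode="all")
        assert pl.probe_mapping_rate(["p1", "p2", "p3"], passing) == pytest.approx(1 / 3)


class TestBuildHpr:
    def test_merge_of_subject_intervals(self):
        records = [aln("p1", sstart=101, send=220), aln("p2", sstart=201, send=300)]
        hpr = pl.build_hpr(records)
        assert {(i.start, i.end) for i in hpr} == {(100, 300)}
        assert hpr.total_length == 200

    def test_strand_ignored(self):
        records = [aln("p1", sstart=220, send=101)]
        assert {(i.start, i.end) for i in pl.build_hpr(records)} == {(100, 220)}

    def test_occupancy_matches_oracle(self):
        rng = np.random.default_rng(5)
        records = []
        for i in range(200):
            s = int(rng.integers(0, 9000))
            records.append(aln(f"p{i}", sstart=s + 1, send=s + 120))
        hpr = pl.build_hpr(records)
        occ = occupancy(hpr, 10_000, ["chr1"])["chr1"]
        expect = np.zeros(10_000, bool)
        for r in records:
            iv = r.subject_interval()
            expect[iv.start : iv.end] = True
        np.testing.assert_array_equal(occ, expect)


class TestCoveredSymbols:
    def promoters(self):
        return {"A": pl.GenomicInterval("src1", 0, 2000, name="A")}

    def test_strictly_above_60pct_included(self):
        probes = pl.RegionSet.from_tuples([("src1", 0, 1201)])
        assert pl.covered_gene_symbols(self.promoters(), probes) == {"A"}

    def test_exactly_60pct_excluded(self):
        probes = pl.RegionSet.from_tuples([("src1", 0, 1200)])
        assert pl.covered_gene_symbols(self.promoters(), probes) == set()

    def test_fully_covered_included(self):
        probes = pl.RegionSet.from_tuples([("src1", 0, 5000)])
        assert pl.covered_gene_symbols(self.promoters(), probes) == {"A"}


class TestBuildOpr:
    def genes(self, symbols):
        out = []
        for i, s in enumerate(symbols):
            t = Transcript(f"{s}.t1", "chr1", "+", 10_000 + 8000 * i, 14_000 + 8000 * i,
                           exons=[(10_000 + 8000 * i, 14_000 + 8000 * i)])
            out.append(pl.GeneModel(s, [t]))
        return out

    def test_symbol_intersection(self):
        opr = pl.build_opr({"A", "B", "C", "D", "E"}, self.genes(["A", "C", "E"]),
                           chrom_lengths={"chr1": 100_000})
        assert len(opr) == 3 and opr.total_length == 6000

    def test_empty_when_no_match(self):
        opr = pl.build_opr({"X"}, self.genes(["A"]), chrom_lengths={"chr1": 100_000})
        assert opr.total_length == 0

    def test_case_insensitive_flag(self):
        opr = pl.build_opr({"a"}, self.genes(["A"]), chrom_lengths={"chr1": 100_000},
                           case_insensitive=True)
        assert opr.total_length == 2000


class TestAssembleTarget:
    def test_absorption_and_additivity(self):
        hpr = pl.RegionSet.from_tuples([("chr1", 0, 1000)], label="HPR")
        opr_in = pl.RegionSet.from_tuples([("chr1", 200, 500)], label="OPR")
        td = pl.assemble_target(hpr, opr_in)
        assert td.redefined.total_length == 1000 and td.opr_added_bases == 0
        opr_out = pl.RegionSet.from_tuples([("chr1", 5000, 6000)], label="OPR")
        td2 = pl.assemble_target(hpr, opr_out)
        assert td2.redefined.total_length == 2000 and td2.opr_added_bases == 1000

    def test_added_cg_sites_equal_subtract_then_count(self):
        genome = {"chr1": "ACGT" * 2500}
        hpr = pl.RegionSet.from_tuples([("chr1", 0, 4000)])
        opr = pl.RegionSet.from_tuples([("chr1", 3000, 6000)])
        td = pl.assemble_target(hpr, opr, genome=genome)
        only = pl.subtract(opr, hpr)
        assert td.opr_added_cg_sites == pl.count_cpg_in_regions(only, genome)
        assert td.opr_raw_cg_sites == pl.count_cpg_in_regions(opr, genome)

    def test_genome_mismatch_rejected(self):
        hpr = pl.RegionSet("HPR", "g1", [pl.GenomicInterval("c", 0, 10)])
        opr = pl.RegionSet("OPR", "g2", [pl.GenomicInterval("c", 0, 10)])
        with pytest.raises(ValueError, match="genome"):
            pl.assemble_target(hpr, opr)


def test_hpr_length_monotone_in_identity_threshold(bundle):
    """Tightening the identity cutoff never grows the HPR."""
    prev = None
    for ident in np.arange(80.0, 95.5, 2.5):
        params = pl.PipelineParams(hpr_min_identity=float(ident))
        hpr = pl.build_hpr(pl.filter_alignments(bundle.alignments, params, mode="all"))
        if prev is not None:
            assert hpr.total_length <= prev
        prev = hpr.total_length


def test_filter_recovers_planted_truth_labels(bundle):
    """Generator-labelled pass records are exactly what the filter keeps."""
    truth = [r for r, lab in zip(bundle.alignments, bundle.alignment_truth) if lab]
    assert pl.filter_alignments(bundle.alignments, mode="all") == truth
    best = pl.filter_alignments(bundle.alignments, mode="best")
    assert {r.query_id for r in best} == {q for q, ok in bundle.probe_truth.items() if ok}
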