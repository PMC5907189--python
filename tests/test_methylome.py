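"""Strand merging, on-target filtering, depth statistics, class methylation."""

import numpy as np
import pandas as pd
import pytest

import panelift as pl
from panelift.io_formats import CytosineRecord
from panelift.regions import RegionClass


def rec(chrom, pos, strand, m, u, context="CpG"):
    return CytosineRecord(chrom, pos, strand, m, u, context)


SITES = {"chr1": np.array([100, 300])}


class TestMergeStrands:
    def test_count_conservation_two_strands(self):
        df = pl.merge_strands(
            [rec("chr1", 100, "+", 3, 1), rec("chr1", 101, "-", 2, 2)], SITES
        )
        row = df.iloc[0]
        assert (row["meth"], row["unmeth"], row["depth"]) == (5, 3, 8)
        assert row["level"] == pytest.approx(0.625)

    def test_single_strand_site(self):
        df = pl.merge_strands([rec("chr1", 100, "+", 4, 0)], SITES)
        assert df.iloc[0]["depth"] == 4 and df.iloc[0]["level"] == 1.0

    def test_non_cpg_context_ignored(self):
        df = pl.merge_strands([rec("chr1", 100, "+", 3, 1, context="CHH")], SITES)
        assert df.empty

    def test_orphan_records_excluded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            df = pl.merge_strands([rec("chr1", 250, "+", 3, 1)], SITES)
        assert df.empty
        assert "did not match" in caplog.text

    def test_global_sum_oracle_on_fixture(self, bundle):
        """Total meth/unmeth counts are invariant under strand merging."""
        cx = bundle.cx_report
        sites = pl.genome_cpg_sites(bundle.genome)
        records = (
            CytosineRecord(r.chrom, r.pos - 1, r.strand, r.meth, r.unmeth, "CpG")
            for r in cx.itertuples()
        )
        df = pl.merge_strands(records, sites)
        assert df["meth"].sum() == cx["meth"].sum()
        assert df["unmeth"].sum() == cx["unmeth"].sum()


class TestOnTarget:
    def test_half_open_boundary(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [100, 150], "meth": [1, 1],
             "unmeth": [0, 0], "depth": [1, 1], "level": [1.0, 1.0]}
        )
        target = pl.RegionSet.from_tuples([("chr1", 50, 150)])
        kept = pl.on_target_sites(sites, target)
        assert list(kept["pos"]) == [100]

    def test_read_rate(self):
        target = pl.RegionSet.from_tuples([("chr1", 1000, 2000)])
        reads = [pl.GenomicInterval("chr1", 900, 1001)] * 6 + [
            pl.GenomicInterval("chr1", 2000, 2101)  # abuts: zero overlap
        ] * 4
        assert pl.on_target_read_rate(reads, target) == pytest.approx(0.6)
        assert np.isnan(pl.on_target_read_rate([], target))

    def test_all_reads_inside(self):
        target = pl.RegionSet.from_tuples([("chr1", 0, 10_000)])
        reads = [pl.GenomicInterval("chr1", i, i + 101) for i in range(0, 1000, 100)]
        assert pl.on_target_read_rate(reads, target) == 1.0


class TestDepthProfile:
    def test_direct_counts(self):
        sites = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [10, 20, 30], "meth": [1, 5, 10],
             "unmeth": [0, 0, 0], "depth": [1, 5, 10], "level": [1.0] * 3}
        )
        prof = pl.depth_profile(sites, {"chr1": np.array([10, 20, 30])}, [1, 5, 10])
        assert prof.cumulative_coverage[5] == pytest.approx(200 / 3)
        assert prof.mean_depth == pytest.approx(16 / 3)

    def test_uncalled_sites_have_zero_depth(self):
        prof = pl.depth_profile(
            pl.methylome._empty_sites(), {"chr1": np.array([10, 20])}, [1, 5]
        )
        assert prof.cumulative_coverage[1] == 0.0 and prof.mean_depth == 0.0

    def test_monotone_nonincreasing(self, pipeline_result):
        cov = list(pipeline_result.depth.cumulative_coverage.values())
        assert all(a >= b for a, b in zip(cov, cov[1:]))


class TestClassMethylation:
    def make_sites(self, levels, depth=10):
        n = len(levels)
        return pd.DataFrame(
            {"chrom": ["chr1"] * n, "pos": np.arange(0, 2 * n, 2),
             "meth": [int(round(l * depth)) for l in levels],
             "unmeth": [depth - int(round(l * depth)) for l in levels],
             "depth": [depth] * n, "level": levels}
        )

    def everything(self):
        return pl.RegionSet.from_tuples([("chr1", 0, 10_000)], label="CGI")

    def test_two_point_mean_sd(self):
        sites = self.make_sites([0.2, 0.4])
        out = pl.class_methylation(sites, {RegionClass.CGI: self.everything()},
                                   self.everything())
        row = out.iloc[0]
        assert row["mean_level"] == pytest.approx(0.30)
        assert row["sd_level"] == pytest.approx(0.1414, abs=1e-4)

    def test_single_site_sd_na(self):
        out = pl.class_methylation(self.make_sites([0.7]),
                                   {RegionClass.CGI: self.everything()}, self.everything())
        assert out.iloc[0]["mean_level"] == pytest.approx(0.7)
        assert np.isnan(out.iloc[0]["sd_level"])

    def test_depth_filter_applied(self):
        sites = self.make_sites([0.2, 0.8], depth=10)
        sites.loc[1, ["depth"]] = 3  # below the default cutoff of 5
        out = pl.class_methylation(sites, {RegionClass.CGI: self.everything()},
                                   self.everything())
        assert out.iloc[0]["n_sites"] == 1

    def test_empty_class_is_na_row(self):
        out = pl.class_methylation(
            self.make_sites([0.2]),
            {RegionClass.SHELF: pl.RegionSet.from_tuples([("chr2", 0, 10)], label="SHELF")},
            self.everything(),
        )
        assert out.iloc[0]["n_sites"] == 0 and np.isnan(out.iloc[0]["mean_level"])

    def test_depth_weighted_pooling_flag(self):
        sites = self.make_sites([0.0, 1.0], depth=10)
        sites.loc[1, ["meth", "unmeth", "depth"]] = [30, 0, 30]
        out = pl.class_methylation(sites, {RegionClass.CGI: self.everything()},
                                   self.everything(), depth_weighted=True)
        assert out.iloc[0]["mean_level"] == pytest.approx(30 / 40)

    def test_matches_two_pass_oracle(self, bundle, pipeline_result):
        """Per-class means agree with an independent pandas recomputation."""
        res = pipeline_result
        sites = res.sites_on_target
        ok = sites[sites["depth"] >= 5]
        for _, row in res.class_summary.iterrows():
            cls = RegionClass(row["region_class"])
            region = pl.intersect(res.class_map[cls], res.target_def.redefined)
            mask = []
            for chrom, grp in ok.groupby("chrom"):
                mask.append(pd.Series(
                    region.contains_positions(str(chrom), grp["pos"].to_numpy()),
                    index=grp.index))
            sel = ok.loc[pd.concat(mask).sort_index()] if mask else ok.iloc[:0]
            assert row["n_sites"] == len(sel)
            if len(sel):
                assert row["mean_level"] == pytest.approx(sel["level"].mean())
                if len(sel) > 1:
                    assert row["sd_level"] == pytest.approx(sel["level"].std(ddof=1))


def test_planted_gradient_ordering(pipeline_result):
    """Estimated class means reproduce CGI < promoter < shore < shelf < exon < intergenic."""
    means = dict(zip(pipeline_result.class_summary["region_class"],
                     pipeline_result.class_summary["mean_level"]))
    order = ["CGI", "PROMOTER", "SHORE", "SHELF", "EXON", "INTERGENIC"]
    values = [means[c] for c in order]
    assert values == sorted(values)
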