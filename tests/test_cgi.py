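"""Island calling vs the independent positional oracle; shore/shelf geometry."""

import numpy as np
import pytest

import panelift as pl
from conftest import cgi_oracle, occupancy


def calls_as_tuples(calls):
    return [(c.interval.start, c.interval.end, c.peak_score) for c in calls]


class TestFindCgis:
    def test_no_cg_no_islands(self):
        assert pl.find_cgis("ATATATATATAT") == []

    def test_cgcg_single_island(self):
        (call,) = pl.find_cgis("CGCG")
        assert (call.interval.start, call.interval.end) == (0, 4)
        assert call.peak_score == 17 - 1 + 17 == 33
        assert call.cg_count == 2

    def test_isolated_cg_is_minimal_island(self):
        # a lone CG reaches the default peak threshold of 17 on its own
        (call,) = pl.find_cgis("AAAACGAAAA")
        assert (call.interval.start, call.interval.end, call.peak_score) == (4, 6, 17)

    def test_island_is_cg_bounded(self):
        for call in pl.find_cgis("TTCGATCGATATATTTTTTTTTTTTTTTTCGTT"):
            iv = call.interval
            s = "TTCGATCGATATATTTTTTTTTTTTTTTTCGTT"
            assert s[iv.start : iv.start + 2] == "CG"
            assert s[iv.end - 2 : iv.end] == "CG"

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid sequence character"):
            pl.find_cgis("ACGTX")

    def test_n_breaks_cg(self):
        assert pl.find_cgis("AACNGAA") == []

    @pytest.mark.parametrize("seed", range(20))
    def test_random_sequences_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # CG-enriched alphabet so islands actually form
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=2000))
        got = calls_as_tuples(pl.find_cgis(seq))
        assert got == cgi_oracle(seq)

    def test_custom_params_match_oracle(self):
        rng = np.random.default_rng(99)
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=3000))
        params = pl.CgiParams(cg_reward=10, non_cg_penalty=2, min_peak_score=40)
        got = calls_as_tuples(pl.find_cgis(seq, params))
        assert got == cgi_oracle(seq, reward=10, penalty=2, min_peak=40)

    def test_appending_cg_never_splits_or_lowers_peak(self):
        seq = "CGCGCGTATA"
        (before,) = pl.find_cgis(seq)
        (after,) = pl.find_cgis(seq[:6] + "CG" + seq[6:])
        assert after.peak_score >= before.peak_score
        assert after.interval.start == before.interval.start

    def test_determinism(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=1000))
        assert calls_as_tuples(pl.find_cgis(seq)) == calls_as_tuples(pl.find_cgis(seq))


class TestShoresShelves:
    def make(self, ivs, length=1_000_000):
        cgis = pl.RegionSet.from_tuples([("chr1", s, e) for s, e in ivs], label="CGI")
        return pl.derive_shores_shelves(cgis, {"chr1": length})

    def test_canonical_geometry(self):
        shores, shelves = self.make([(10000, 10800)])
        assert {(i.start, i.end) for i in shores} == {(8000, 10000), (10800, 12800)}
        assert {(i.start, i.end) for i in shelves} == {(6000, 8000), (12800, 14800)}

    def test_boundary_clipping(self):
        shores, shelves = self.make([(500, 700)])
        assert {(i.start, i.end) for i in shores} == {(0, 500), (700, 2700)}
        assert {(i.start, i.end) for i in shelves} == {(2700, 4700)}

    def test_adjacent_cgis_share_shore_no_shelf_between(self):
        # two CGIs 1 kb apart: the gap is all shore, never shelf
        shores, shelves = self.make([(10000, 10500), (11500, 12000)])
        occ_shore = occupancy(shores, 20000, ["chr1"])["chr1"]
        occ_shelf = occupancy(shelves, 20000, ["chr1"])["chr1"]
        assert occ_shore[10500:11500].all()
        assert not occ_shelf[10500:11500].any()

    def test_cgi_beyond_chromosome_rejected(self):
        with pytest.raises(ValueError, match="beyond chromosome"):
            self.make([(900, 1200)], length=1000)

    @pytest.mark.parametrize("seed", range(5))
    def test_per_base_class_map_oracle(self, seed):
        """Precedence CGI > shore > shelf reproduced against a painted array."""
        rng = np.random.default_rng(seed)
        length = 100_000
        starts = np.sort(rng.choice(np.arange(2000, length - 2000, 100), 8, replace=False))
        ivs = [(int(s), int(s + rng.integers(200, 1500))) for s in starts]
        cgis = pl.merge(pl.RegionSet.from_tuples([("chr1", s, e) for s, e in ivs]))
        shores, shelves = pl.derive_shores_shelves(cgis, {"chr1": length})
        # paint with precedence: shelf first, then shore, then CGI wins
        paint = np.zeros(length, dtype=np.int8)
        for iv in cgis:
            paint[max(iv.start - 4000, 0) : min(iv.end + 4000, length)] = 1  # shelf
        for iv in cgis:
            paint[max(iv.start - 2000, 0) : min(iv.end + 2000, length)] = 2  # shore
        for iv in cgis:
            paint[iv.start : iv.end] = 3
        got_shore = occupancy(shores, length, ["chr1"])["chr1"]
        got_shelf = occupancy(shelves, length, ["chr1"])["chr1"]
        np.testing.assert_array_equal(got_shore, paint == 2)
        np.testing.assert_array_equal(got_shelf, paint == 1)
        # pairwise disjoint
        occ_cgi = occupancy(cgis, length, ["chr1"])["chr1"]
        assert not (occ_cgi & got_shore).any()
        assert not (occ_cgi & got_shelf).any()
        assert not (got_shore & got_shelf).any()
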