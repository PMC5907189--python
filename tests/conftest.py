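"""Shared fixtures: one default synthetic study per session, plus oracles."""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np
import pytest

import panelift as pl


# ---------------------------------------------------------------------------
# independent per-base boolean oracle for interval algebra
# ---------------------------------------------------------------------------

def occupancy(
    intervals: Iterable[pl.GenomicInterval], chrom_len: int, chroms: List[str]
) -> Dict[str, np.ndarray]:
    """Per-base boolean coverage arrays, built by direct slicing."""
    arr = {c: np.zeros(chrom_len, dtype=bool) for c in chroms}
    for iv in intervals:
        arr[iv.chrom][iv.start : iv.end] = True
    return arr


def random_region_set(
    rng: np.random.Generator, n: int, chroms: List[str], chrom_len: int,
    label: str = "", genome_id: str = "",
) -> pl.RegionSet:
    ivs = []
    for _ in range(n):
        c = chroms[int(rng.integers(len(chroms)))]
        s = int(rng.integers(0, chrom_len - 1))
        e = s + 1 + int(rng.integers(0, min(chrom_len - s - 1, 500) + 1))
        ivs.append(pl.GenomicInterval(c, s, e))
    return pl.RegionSet(label, genome_id, ivs)


# ---------------------------------------------------------------------------
# independent positional simulation of the island-calling rule
# ---------------------------------------------------------------------------

def cgi_oracle(
    seq: str, reward: int = 17, penalty: int = 1, min_peak: int = 17
) -> List[Tuple[int, int, int]]:
    """Scalar open/close walk over dinucleotide positions -> (start, end, peak)."""
    calls = []
    s = 0
    is_open = False
    start = peak = peak_pos = 0
    for i in range(len(seq) - 1):
        if seq[i : i + 2] == "CG":
            s += reward
        else:
            s = max(s - penalty, 0)
        if not is_open:
            if s > 0:
                is_open = True
                start, peak, peak_pos = i, s, i
        else:
            if s >= peak:  # rightmost maximum on ties
                peak, peak_pos = s, i
            if s == 0:
                if peak >= min_peak:
                    calls.append((start, peak_pos + 2, peak))
                is_open = False
    if is_open and peak >= min_peak:
        calls.append((start, peak_pos + 2, peak))
    return calls


# ---------------------------------------------------------------------------
# the default synthetic study, generated once per session
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def bundle() -> pl.FixtureBundle:
    return pl.generate_fixture(pl.SynthConfig())


@pytest.fixture(scope="session")
def fixture_paths(bundle, tmp_path_factory):
    return bundle.write(tmp_path_factory.mktemp("fixture"))


@pytest.fixture(scope="session")
def pipeline_result(bundle, fixture_paths) -> pl.PipelineResult:
    """Full pipeline run on the default fixture, planted islands as CGI class."""
    return pl.run_pipeline(
        fixture_paths["genome"],
        fixture_paths["source_gtf"],
        fixture_paths["target_gtf"],
        fixture_paths["probes"],
        fixture_paths["blast8"],
        fixture_paths["cx_report"],
        reads_bed=fixture_paths["reads"],
        cgi_bed=fixture_paths["truth_islands"],
        seed=bundle.config.seed,
    )
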