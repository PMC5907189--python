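"""CpG-island prediction and shore/shelf geometry.

Islands are called with the classic running-score maximal-segment scheme
(the cpgreport scoring): scanning dinucleotide positions left to right, a
score S starts at 0, gains ``cg_reward`` (default 17) at each CG and loses
``non_cg_penalty`` (default 1) otherwise, clamped at 0. A candidate segment
opens when S rises from 0 and closes when S returns to 0 (or at the sequence
end); the reported island runs from the segment's first CG through both
bases of the CG at which S attained its maximum (rightmost on ties), and is
reported iff the peak score reaches ``min_peak_score`` (default 17). Under
these defaults even an isolated CG dinucleotide reaches the threshold and is
reported as a 2-bp island — an inherent property of the scoring.

N (and any assembly-gap base) never forms a CG and incurs the non-CG
penalty, which is conservative toward gaps.

Shores are the 2-kb windows flanking each island and shelves the 2-kb
windows beyond each shore (2-4 kb from the island), both clipped to the
chromosome and precedence-trimmed so CGI > shore > shelf are pairwise
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .intervals import GenomicInterval, RegionSet, merge, subtract, union

__all__ = ["CgiParams", "CgiCall", "find_cgis", "derive_shores_shelves"]

_ALLOWED = frozenset(b"ACGTN")


@dataclass(frozen=True)
class CgiParams:
    """Scoring constants for island calling (cpgreport defaults)."""

    cg_reward: int = 17
    non_cg_penalty: int = 1
    min_peak_score: int = 17

    def __post_init__(self) -> None:
        if self.cg_reward <= 0 or self.non_cg_penalty <= 0 or self.min_peak_score <= 0:
            raise ValueError("all scoring constants must be positive")


@dataclass(frozen=True)
class CgiCall:
    """A called island: CG-bounded interval with its peak score and CG count."""

    interval: GenomicInterval
    peak_score: int
    cg_count: int


def find_cgis(seq: str, params: CgiParams = CgiParams(), chrom: str = "chr") -> List[CgiCall]:
    """Call CpG islands on one chromosome sequence.

    Returns non-overlapping calls sorted by start. Raises on characters
    outside {A,C,G,T,N} (case-insensitive).
    """
    raw = seq.upper().encode("ascii", errors="replace")
    arr = np.frombuffer(raw, dtype=np.uint8)
    if arr.size and not np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8)).all():
        bad = arr[~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))][0]
        raise ValueError(f"invalid sequence character {chr(bad)!r}")
    if arr.size < 2:
        return []

    is_cg = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    scores = np.where(is_cg, params.cg_reward, -params.non_cg_penalty).astype(np.int64)
    csum = np.cumsum(scores)
    # clamp-at-0 running score: S_i = csum_i - min(0, running_min(csum)_i)
    running_min = np.minimum(np.minimum.accumulate(csum), 0)
    s = csum - running_min

    positive = s > 0
    if not positive.any():
        return []
    # maximal runs of positive score = candidate segments
    edges = np.flatnonzero(np.diff(positive.astype(np.int8)))
    seg_starts = ([0] if positive[0] else []) + [int(i) + 1 for i in edges if not positive[i]]
    seg_ends = [int(i) + 1 for i in edges if positive[i]] + ([len(s)] if positive[-1] else [])

    calls: List[CgiCall] = []
    for a, b in zip(seg_starts, seg_ends):
        seg = s[a:b]
        peak = int(seg.max())
        if peak < params.min_peak_score:
            continue
        # rightmost position attaining the peak; always a CG position
        j = a + int(len(seg) - 1 - np.argmax(seg[::-1]))
        iv = GenomicInterval(chrom, a, j + 2)
        cg_count = int(is_cg[a : j + 1].sum())
        calls.append(CgiCall(iv, peak, cg_count))
    return calls


def derive_shores_shelves(
    cgis: RegionSet, chrom_lengths: Dict[str, int]
) -> Tuple[RegionSet, RegionSet]:
    """Derive shore (0-2 kb) and shelf (2-4 kb) flanks of each island.

    Windows are clipped to [0, chromosome length); shores then have all CGI
    bases subtracted and shelves have CGI and shore bases subtracted, giving
    the precedence CGI > shore > shelf.
    """
    cgis = merge(cgis)
    width = 2000
    shore_iv: List[GenomicInterval] = []
    shelf_iv: List[GenomicInterval] = []
    for iv in cgis:
        length = chrom_lengths.get(iv.chrom)
        if length is None:
            raise ValueError(f"no chromosome length for {iv.chrom!r}")
        if iv.end > length:
            raise ValueError(
                f"CGI {iv.chrom}:{iv.start}-{iv.end} beyond chromosome length {length}"
            )
        for lo, hi in (
            (iv.start - width, iv.start),          # left shore
            (iv.end, iv.end + width),              # right shore
        ):
            lo, hi = max(lo, 0), min(hi, length)
            if lo < hi:
                shore_iv.append(GenomicInterval(iv.chrom, lo, hi))
        for lo, hi in (
            (iv.start - 2 * width, iv.start - width),  # left shelf
            (iv.end + width, iv.end + 2 * width),      # right shelf
        ):
            lo, hi = max(lo, 0), min(hi, length)
            if lo < hi:
                shelf_iv.append(GenomicInterval(iv.chrom, lo, hi))

    gid = cgis.genome_id
    shores = subtract(
        merge(RegionSet("shore", gid, shore_iv)), cgis, label="shore"
    )
    shelves = subtract(
        subtract(merge(RegionSet("shelf", gid, shelf_iv)), cgis), shores, label="shelf"
    )
    return shores, shelves
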