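"""Genomic interval data model and set algebra.

All coordinates are 0-based half-open throughout the package; 1-based formats
(GTF, blast8) are converted on read. Set algebra is strand-agnostic: capture
and methylation coverage are summarized over covered bases, so strand is
carried on :class:`GenomicInterval` but ignored by merge/intersect/subtract.
Book-ended intervals (``end == next.start``) coalesce on merge, because region
sets here represent covered spans, not discrete features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "merge",
    "intersect",
    "subtract",
    "union",
    "overlap_fraction",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


# Per-chromosome coordinate table: (starts, ends) as sorted int64 arrays.
_ChromArrays = Dict[str, Tuple[np.ndarray, np.ndarray]]


@dataclass
class RegionSet:
    """A labelled collection of intervals on one genome assembly.

    ``normalized()`` returns an equivalent set whose intervals are sorted by
    (chrom, start) and pairwise disjoint (overlapping/book-ended intervals
    coalesced). Most algebra requires/produces normalized sets.
    """

    label: str = ""
    genome_id: str = ""
    intervals: List[GenomicInterval] = field(default_factory=list)

    @classmethod
    def from_tuples(
        cls,
        tuples: Iterable[Tuple[str, int, int]],
        label: str = "",
        genome_id: str = "",
    ) -> "RegionSet":
        return cls(label, genome_id, [GenomicInterval(c, s, e) for c, s, e in tuples])

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_length(self) -> int:
        """Total covered bases of the normalized set."""
        return sum(len(iv) for iv in self.normalized().intervals)

    def normalized(self) -> "RegionSet":
        return merge(self)

    def _arrays(self) -> _ChromArrays:
        """Sorted, coalesced per-chromosome start/end arrays."""
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        out: _ChromArrays = {}
        for chrom in sorted(by_chrom):
            pairs = sorted(by_chrom[chrom])
            starts: List[int] = []
            ends: List[int] = []
            for s, e in pairs:
                if ends and s <= ends[-1]:
                    if e > ends[-1]:
                        ends[-1] = e
                else:
                    starts.append(s)
                    ends.append(e)
            out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
        return out

    def contains_positions(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean membership mask for 0-based positions (vectorized)."""
        arrays = self._arrays()
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in arrays or positions.size == 0:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = arrays[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        mask = np.zeros(positions.shape, dtype=bool)
        mask[ok] = positions[ok] < ends[idx[ok]]
        return mask


def _check_same_genome(a: RegionSet, b: RegionSet) -> None:
    if a.genome_id and b.genome_id and a.genome_id != b.genome_id:
        raise ValueError(
            f"genome_id mismatch: {a.genome_id!r} vs {b.genome_id!r}"
        )


def _from_arrays(arrays: _ChromArrays, label: str, genome_id: str) -> RegionSet:
    ivs = [
        GenomicInterval(chrom, int(s), int(e))
        for chrom in sorted(arrays)
        for s, e in zip(*arrays[chrom])
    ]
    return RegionSet(label, genome_id, ivs)


def merge(a: RegionSet) -> RegionSet:
    """Minimal sorted disjoint set covering the same bases (book-ended coalesce)."""
    return _from_arrays(a._arrays(), a.label, a.genome_id)


def union(a: RegionSet, b: RegionSet, label: str = "") -> RegionSet:
    _check_same_genome(a, b)
    combined = RegionSet(
        label or a.label, a.genome_id or b.genome_id, list(a.intervals) + list(b.intervals)
    )
    return merge(combined)


def intersect(a: RegionSet, b: RegionSet, label: str = "") -> RegionSet:
    """Bases present in both sets; commutative."""
    _check_same_genome(a, b)
    aa, bb = a._arrays(), b._arrays()
    out: _ChromArrays = {}
    for chrom in sorted(set(aa) & set(bb)):
        s1, e1 = aa[chrom]
        s2, e2 = bb[chrom]
        starts, ends = [], []
        i = j = 0
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if lo < hi:
                starts.append(lo)
                ends.append(hi)
            if e1[i] <= e2[j]:
                i += 1
            else:
                j += 1
        out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return _from_arrays(out, label or a.label, a.genome_id or b.genome_id)


def subtract(a: RegionSet, b: RegionSet, label: str = "") -> RegionSet:
    """Bases in ``a`` and not in ``b``."""
    _check_same_genome(a, b)
    aa, bb = a._arrays(), b._arrays()
    out: _ChromArrays = {}
    for chrom in sorted(aa):
        s1, e1 = aa[chrom]
        if chrom not in bb:
            out[chrom] = (s1, e1)
            continue
        s2, e2 = bb[chrom]
        starts, ends = [], []
        j = 0
        for s, e in zip(s1, e1):
            cur = s
            while j < len(s2) and e2[j] <= cur:
                j += 1
            k = j
            while k < len(s2) and s2[k] < e:
                if s2[k] > cur:
                    starts.append(cur)
                    ends.append(int(s2[k]))
                cur = max(cur, int(e2[k]))
                if e2[k] >= e:
                    break
                k += 1
            if cur < e:
                starts.append(int(cur))
                ends.append(int(e))
        out[chrom] = (np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64))
    return _from_arrays(out, label or a.label, a.genome_id)


def overlap_fraction(query: GenomicInterval, regions: RegionSet) -> float:
    """Fraction of ``query`` bases covered by ``regions``, in [0, 1]."""
    arrays = regions._arrays()
    if query.chrom not in arrays:
        return 0.0
    starts, ends = arrays[query.chrom]
    lo = np.maximum(starts, query.start)
    hi = np.minimum(ends, query.end)
    covered = int(np.clip(hi - lo, 0, None).sum())
    return covered / len(query)


# ---------------------------------------------------------------------------
# BED I/O (BED3/BED6; tab-separated, 0-based half-open — native convention)
# ---------------------------------------------------------------------------

def read_bed(path, label: str = "", genome_id: str = "") -> RegionSet:
    """Read a BED3/BED6 file into a RegionSet (comment/track lines skipped)."""
    intervals: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            chrom, start, end = fields[0], fields[1], fields[2]
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            try:
                intervals.append(GenomicInterval(chrom, s, e, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(label, genome_id, intervals)


def write_bed(regions: RegionSet, path, scores: Optional[Dict[GenomicInterval, int]] = None) -> None:
    """Write BED3 (or BED5 when per-interval scores are supplied)."""
    with open(path, "w") as fh:
        for iv in sorted(regions.intervals, key=lambda x: (x.chrom, x.start, x.end)):
            if scores is not None:
                name = iv.name or "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{scores.get(iv, 0)}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
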