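"""Readers and writers for the standard formats the pipeline consumes.

Dialects handled:

* FASTA (via Biopython) — sequences uppercased; soft-masked lowercase bases
  are treated as ordinary sequence.
* blast8 — the 12-column tabular alignment format (query, subject, %identity,
  alignment length, mismatches, gap opens, qstart, qend, sstart, send,
  e-value, bitscore); 1-based inclusive coordinates, ``sstart > send``
  denotes a minus-strand hit.
* GTF — ``key "value";`` attributes; exon/CDS rows grouped into gene models
  keyed by gene symbol (``gene_name``, falling back to ``gene_id``).
* Bismark cytosine report — 7 columns: chrom, 1-based position, strand,
  methylated count, unmethylated count, context (CpG/CHG/CHH), trinucleotide.

Everything is converted to 0-based half-open coordinates on read. Parsers
fail on the first offending line and report its number; no rows are silently
dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

from Bio import SeqIO

from .intervals import GenomicInterval

__all__ = [
    "AlignmentRecord",
    "CytosineRecord",
    "Transcript",
    "GeneModel",
    "read_fasta",
    "write_fasta",
    "read_blast8",
    "read_gtf",
    "read_cytosine_report",
]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Dict[str, str]:
    """Load a FASTA file as ``{name: uppercase sequence}``.

    Duplicate headers and empty sequences are rejected.
    """
    genome: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"{path}: duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty sequence for {record.id!r}")
        genome[record.id] = seq
    return genome


def write_fasta(genome: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# blast8 tabular alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentRecord:
    """One row of 12-column tabular (blast8) output: a probe-to-genome hit."""

    query_id: str
    subject: str
    identity: float          # percent, 0-100
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int              # 1-based inclusive
    qend: int
    sstart: int              # 1-based inclusive; sstart > send == minus strand
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"identity {self.identity} outside [0,100]")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if self.aln_length < 1:
            raise ValueError(f"alignment length {self.aln_length} < 1")

    @property
    def minus_strand(self) -> bool:
        return self.sstart > self.send

    def subject_interval(self) -> GenomicInterval:
        """Subject hit as a forward 0-based half-open interval.

        1-based inclusive [sstart, send] (possibly reversed) maps to
        [min-1, max).
        """
        lo, hi = sorted((self.sstart, self.send))
        return GenomicInterval(
            self.subject, lo - 1, hi,
            strand="-" if self.minus_strand else "+",
            name=self.query_id,
        )


def read_blast8(path) -> List[AlignmentRecord]:
    """Parse a blast8 file; ``#`` comment lines are skipped (and counted)."""
    records: List[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=fields[0],
                    subject=fields[1],
                    identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int = 0            # 0-based half-open span
    tx_end: int = 0
    exons: List[Tuple[int, int]] = field(default_factory=list)
    cds: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start


@dataclass
class GeneModel:
    """All transcripts sharing one gene symbol on one chromosome."""

    gene_symbol: str
    transcripts: List[Transcript] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path) -> List[GeneModel]:
    """Read exon/CDS features from a GTF into gene models.

    Transcripts are grouped under the gene symbol (``gene_name`` if present,
    else ``gene_id``); 1-based closed coordinates become 0-based half-open.
    Transcript bounds come from the transcript feature when present,
    otherwise from the exon envelope.
    """
    transcripts: Dict[str, Transcript] = {}
    tx_symbol: Dict[str, str] = {}
    explicit_bounds: Dict[str, Tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS", "transcript"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            s0, e0 = int(start) - 1, int(end)  # 1-based closed -> 0-based half-open
            if not (0 <= s0 < e0):
                raise ValueError(f"{path}:{lineno}: invalid span {start}-{end}")
            a = _parse_attributes(attrs)
            tid = a.get("transcript_id")
            if not tid:
                raise ValueError(f"{path}:{lineno}: {feature} without transcript_id")
            symbol = a.get("gene_name") or a.get("gene_id")
            if not symbol:
                raise ValueError(f"{path}:{lineno}: no gene_name/gene_id attribute")
            tx = transcripts.get(tid)
            if tx is None:
                tx = transcripts[tid] = Transcript(tid, chrom, strand)
                tx_symbol[tid] = symbol
            if tx.chrom != chrom:
                raise ValueError(f"{path}:{lineno}: transcript {tid} spans chromosomes")
            if feature == "exon":
                tx.exons.append((s0, e0))
            elif feature == "CDS":
                tx.cds.append((s0, e0))
            else:
                explicit_bounds[tid] = (s0, e0)

    genes: Dict[Tuple[str, str], GeneModel] = {}
    for tid, tx in transcripts.items():
        if not tx.exons:
            raise ValueError(f"{path}: transcript {tid} has no exons")
        if tid in explicit_bounds:
            tx.tx_start, tx.tx_end = explicit_bounds[tid]
        else:
            tx.tx_start = min(s for s, _ in tx.exons)
            tx.tx_end = max(e for _, e in tx.exons)
        key = (tx_symbol[tid], tx.chrom)
        genes.setdefault(key, GeneModel(tx_symbol[tid])).transcripts.append(tx)
    # deterministic ordering
    out = []
    for (_sym, _chrom), gm in sorted(genes.items()):
        gm.transcripts.sort(key=lambda t: t.transcript_id)
        out.append(gm)
    return out


# ---------------------------------------------------------------------------
# Bismark cytosine report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineRecord:
    """One per-strand cytosine call; ``pos`` is 0-based internally."""

    chrom: str
    pos: int
    strand: str
    count_methylated: int
    count_unmethylated: int
    context: str             # CpG / CHG / CHH
    tricontext: str = ""

    @property
    def depth(self) -> int:
        return self.count_methylated + self.count_unmethylated

    @property
    def is_cpg(self) -> bool:
        return self.context in ("CpG", "CG")


def read_cytosine_report(path) -> Iterator[CytosineRecord]:
    """Stream a 7-column Bismark-style cytosine report.

    Positions are converted from 1-based to 0-based. Zero-depth rows are
    retained (depth filtering happens downstream); CHG/CHH rows pass through
    flagged non-CpG via :attr:`CytosineRecord.is_cpg`.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            chrom, pos, strand, meth, unmeth, context, tri = fields
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                pos1 = int(pos)
                m = int(meth)
                u = int(unmeth)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field") from exc
            if m < 0 or u < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            if pos1 < 1:
                raise ValueError(f"{path}:{lineno}: position must be >= 1")
            yield CytosineRecord(chrom, pos1 - 1, strand, m, u, context, tri)
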