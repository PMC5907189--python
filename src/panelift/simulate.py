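"""Deterministic synthetic methyl-capture study generator.

Emits everything the pipeline consumes — target genome FASTA with planted
CpG islands, source/target GTF annotations with a controllable shared
gene-symbol fraction, a probe panel BED on the source genome, blast8
probe-to-target alignments with planted pass/fail filter labels, a
Bismark-style cytosine report with a planted per-class methylation gradient,
and de-duplicated read intervals — plus the truth tables needed to score
every stage. The same seed reproduces the bundle byte for byte.

Geometry: each chromosome is tiled with fixed-stride "gene units". A unit
carries (relative to its start, mirrored for minus-strand genes)

* an intergenic margin, then the 2-kb promoter and the TSS,
* a first exon, then a long intron hosting the planted CpG island with its
  2-kb shores and 2-kb shelves fully inside the intron,
* the remaining exons, then an intergenic tail.

This placement makes the gradient classes (CGI, shore, shelf, promoter,
exon, intergenic) pairwise disjoint, so each CpG site has one unambiguous
planted class truth; where classes would still overlap the precedence
CGI > shore > shelf > promoter > exon > intergenic assigns the truth level
(a generator-side convention only — the analysis never sees it).

Emulated data regime: ~30x mean calling depth on target (split per strand),
101-bp reads, beta-binomial per-site methylation around planted class
means. Not emulated: read-level sequence, bisulfite conversion errors, PCR
duplicates, mapping bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .cgi import derive_shores_shelves
from .intervals import GenomicInterval, RegionSet, merge, union, write_bed
from .io_formats import AlignmentRecord, GeneModel, Transcript, write_fasta
from .regions import PipelineParams, RegionClass, build_region_map, promoters_of

__all__ = ["SynthConfig", "FixtureBundle", "generate_fixture"]

_GRADIENT = (
    RegionClass.CGI,
    RegionClass.SHORE,
    RegionClass.SHELF,
    RegionClass.PROMOTER,
    RegionClass.EXON,
    RegionClass.INTERGENIC,
)


def _default_class_means() -> Dict[RegionClass, float]:
    return {
        RegionClass.CGI: 0.10,
        RegionClass.PROMOTER: 0.20,
        RegionClass.SHORE: 0.40,
        RegionClass.SHELF: 0.60,
        RegionClass.EXON: 0.75,
        RegionClass.INTERGENIC: 0.80,
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic study (defaults = the tested conditions)."""

    seed: int = 17
    n_chroms: int = 2
    chrom_length: int = 500_000
    background_gc: float = 0.40
    n_genes: int = 40                  # total, spread evenly over chromosomes
    n_islands: Optional[int] = None    # None -> one intronic island per gene
    island_length: int = 1000
    island_cg_density: float = 0.15    # probability a CG starts at an island position
    exons_per_gene: int = 4
    exon_length: int = 500
    probe_length: int = 120
    # planted alignment-filter mixture (pass / fail-identity / fail-evalue)
    pass_prob: float = 0.60
    fail_identity_prob: float = 0.25
    extra_hit_probs: Tuple[float, ...] = (0.08, 0.62, 0.20, 0.10)  # 0..3 hits
    exon_tile_fraction: float = 0.5
    n_intergenic_probes: int = 60
    shared_symbol_fraction: float = 0.8
    class_means: Dict[RegionClass, float] = dc_field(default_factory=_default_class_means)
    dispersion: float = 0.02           # beta-binomial rho; 0 -> degenerate at the mean
    depth_mean: float = 30.0           # on-target per-site depth (both strands)
    off_target_depth: float = 1.0
    full_depth: bool = False           # capture-free variant: depth_mean everywhere
    read_length: int = 101
    n_reads: int = 4000
    read_on_target_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not all(0.0 <= m <= 1.0 for m in self.class_means.values()):
            raise ValueError("class means must lie in [0,1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not (0 <= self.dispersion < 1):
            raise ValueError("dispersion (rho) must lie in [0,1)")

    # -- derived unit geometry (relative offsets inside one gene unit) -----
    @property
    def _rel(self) -> Dict[str, Tuple[int, int]]:
        li = self.island_length
        prom = (2000, 4000)
        exon1 = (4000, 4000 + self.exon_length)
        shelf_l = (6500, 8500)
        shore_l = (8500, 10500)
        island = (10500, 10500 + li)
        shore_r = (island[1], island[1] + 2000)
        shelf_r = (shore_r[1], shore_r[1] + 2000)
        return {
            "prom": prom, "exon1": exon1, "shelf_l": shelf_l, "shore_l": shore_l,
            "island": island, "shore_r": shore_r, "shelf_r": shelf_r,
        }

    @property
    def _rel_exons(self) -> List[Tuple[int, int]]:
        rel = self._rel
        exons = [rel["exon1"]]
        start = rel["shelf_r"][1] + 500
        for _ in range(self.exons_per_gene - 1):
            exons.append((start, start + self.exon_length))
            start += self.exon_length + 500
        return exons

    @property
    def unit_stride(self) -> int:
        tail = 5500
        return self._rel_exons[-1][1] + tail

    @property
    def genes_per_chrom(self) -> int:
        per = self.n_genes // self.n_chroms
        if per * self.unit_stride > self.chrom_length:
            raise ValueError(
                f"{per} gene units of {self.unit_stride} bp exceed chromosome "
                f"length {self.chrom_length}"
            )
        return per


@dataclass
class FixtureBundle:
    """Everything one synthetic study comprises, in memory."""

    config: SynthConfig
    genome: Dict[str, str]                      # target genome
    chrom_lengths: Dict[str, int]
    truth_islands: RegionSet                    # planted islands (target genome)
    target_genes: List[GeneModel]
    source_genes: List[GeneModel]
    source_chrom_lengths: Dict[str, int]
    probes: RegionSet                           # source-genome probe panel
    alignments: List[AlignmentRecord]
    alignment_truth: List[bool]                 # planted pass/fail per record
    probe_truth: Dict[str, bool]                # probe -> has a planted-pass hit
    covered_symbol_truth: Set[str]              # source symbols > 60% probe-covered
    class_map: Dict[RegionClass, RegionSet]     # truth-island based, target genome
    redefined_truth: RegionSet                  # union of planted-pass subjects + OPR truth
    cx_report: pd.DataFrame
    truth_class_levels: pd.DataFrame            # planted vs realized class means
    reads: List[GenomicInterval]

    def write(self, outdir) -> Dict[str, Path]:
        """Write the bundle as plain-text files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "truth_islands": outdir / "truth" / "islands.bed",
            "source_gtf": outdir / "source.gtf",
            "target_gtf": outdir / "target.gtf",
            "probes": outdir / "probes.bed",
            "blast8": outdir / "alignments.blast8",
            "cx_report": outdir / "calls.CX_report.txt",
            "reads": outdir / "reads.bed",
            "truth_levels": outdir / "truth" / "class_levels.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        write_bed(self.truth_islands, paths["truth_islands"])
        _write_gtf(self.source_genes, paths["source_gtf"])
        _write_gtf(self.target_genes, paths["target_gtf"])
        with open(paths["probes"], "w") as fh:
            for iv in self.probes:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
        with open(paths["blast8"], "w") as fh:
            for rec in self.alignments:
                fh.write(
                    f"{rec.query_id}\t{rec.subject}\t{rec.identity:.2f}\t"
                    f"{rec.aln_length}\t{rec.mismatches}\t{rec.gap_opens}\t"
                    f"{rec.qstart}\t{rec.qend}\t{rec.sstart}\t{rec.send}\t"
                    f"{rec.evalue:.2e}\t{rec.bitscore:.1f}\n"
                )
        self.cx_report.to_csv(paths["cx_report"], sep="\t", header=False, index=False)
        with open(paths["reads"], "w") as fh:
            for iv in self.reads:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        self.truth_class_levels.to_csv(paths["truth_levels"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _background_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _island_sequence(rng: np.random.Generator, n: int, cg_density: float, gc: float) -> np.ndarray:
    """CG-dense segment: at each position, start a CG with prob cg_density."""
    bg = _background_sequence(rng, n, gc)
    coin = rng.random(n)
    out = np.empty(n, dtype=np.uint8)
    i = 0
    while i < n:
        if i + 1 < n and coin[i] < cg_density:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            out[i] = bg[i]
            i += 1
    return out


def _mirror(rel: Tuple[int, int], stride: int) -> Tuple[int, int]:
    return (stride - rel[1], stride - rel[0])


@dataclass
class _Unit:
    chrom: str
    start: int
    strand: str
    symbol: str
    has_island: bool
    rel: Dict[str, Tuple[int, int]]
    exons: List[Tuple[int, int]]

    def abs_iv(self, rel: Tuple[int, int]) -> Tuple[int, int]:
        return (self.start + rel[0], self.start + rel[1])


def _layout_units(
    cfg: SynthConfig, chrom_prefix: str, symbols: Sequence[str], n_islands: int
) -> List[_Unit]:
    units: List[_Unit] = []
    per = cfg.genes_per_chrom
    stride = cfg.unit_stride
    rel = cfg._rel
    rel_exons = cfg._rel_exons
    idx = 0
    for c in range(cfg.n_chroms):
        chrom = f"{chrom_prefix}{c + 1}"
        for g in range(per):
            if idx >= len(symbols):
                break
            strand = "+" if idx % 2 == 0 else "-"
            if strand == "+":
                urel, uex = dict(rel), list(rel_exons)
            else:
                urel = {k: _mirror(v, stride) for k, v in rel.items()}
                uex = sorted(_mirror(e, stride) for e in rel_exons)
            units.append(
                _Unit(chrom, g * stride, strand, symbols[idx], idx < n_islands, urel, uex)
            )
            idx += 1
    return units


def _units_to_genes(units: List[_Unit], two_tx_every: int = 3) -> List[GeneModel]:
    """Gene models from units; every ``two_tx_every``-th gene gets a second,
    shorter transcript so the longest-transcript TSS rule is exercised."""
    genes = []
    for i, u in enumerate(units):
        exons_abs = [u.abs_iv(e) for e in u.exons]
        tx_start = min(s for s, _ in exons_abs)
        tx_end = max(e for _, e in exons_abs)
        # CDS: middle exons, full extent
        cds_abs = exons_abs[1:-1] if len(exons_abs) > 2 else []
        tx1 = Transcript(f"{u.symbol}.t1", u.chrom, u.strand, tx_start, tx_end,
                         exons=exons_abs, cds=cds_abs)
        transcripts = [tx1]
        if two_tx_every and i % two_tx_every == 0 and len(exons_abs) >= 2:
            # shorter transcript dropping the outermost exon on the TSS side
            sub = exons_abs[1:] if u.strand == "+" else exons_abs[:-1]
            ts, te = min(s for s, _ in sub), max(e for _, e in sub)
            transcripts.append(
                Transcript(f"{u.symbol}.t2", u.chrom, u.strand, ts, te, exons=sub)
            )
        genes.append(GeneModel(u.symbol, transcripts))
    return genes


def _write_gtf(genes: List[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gm in genes:
            for tx in gm.transcripts:
                attrs = (
                    f'gene_id "{gm.gene_symbol}"; transcript_id "{tx.transcript_id}"; '
                    f'gene_name "{gm.gene_symbol}";'
                )
                fh.write(
                    f"{tx.chrom}\tsynth\ttranscript\t{tx.tx_start + 1}\t{tx.tx_end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
                for s, e in sorted(tx.exons):
                    fh.write(
                        f"{tx.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                    )
                for s, e in sorted(tx.cds):
                    fh.write(
                        f"{tx.chrom}\tsynth\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# probes and alignments
# ---------------------------------------------------------------------------

def _revcomp_flip(rng: np.random.Generator) -> bool:
    return bool(rng.random() < 0.5)


def _draw_alignment(
    rng: np.random.Generator,
    cfg: SynthConfig,
    probe_id: str,
    subject: str,
    s0: int,
    s1: int,
    category: str,
) -> Tuple[AlignmentRecord, bool]:
    """One blast8 record with a planted filter category.

    Categories: ``pass`` (identity >= 85, e-value <= 1e-10),
    ``fail_identity``, ``fail_evalue``; the returned label is True iff the
    record passes the inclusive (85, 1e-10) filter.
    """
    length = s1 - s0
    if category == "pass":
        identity = round(float(rng.uniform(85.0, 99.5)), 2)
        evalue = float(10.0 ** -rng.uniform(12, 40))
    elif category == "fail_identity":
        identity = round(float(rng.uniform(70.0, 84.9)), 2)
        evalue = float(10.0 ** -rng.uniform(12, 40))
    else:  # fail_evalue
        identity = round(float(rng.uniform(85.0, 99.5)), 2)
        evalue = float(10.0 ** -rng.uniform(2.0, 9.9))
    mism = int(round(length * (100 - identity) / 100))
    bitscore = round(2.0 * length * identity / 100.0 - 20 * math.log10(max(evalue, 1e-300)) / 100, 1)
    minus = _revcomp_flip(rng)
    sstart, send = (s1, s0 + 1) if minus else (s0 + 1, s1)
    rec = AlignmentRecord(
        query_id=probe_id, subject=subject, identity=identity, aln_length=length,
        mismatches=mism, gap_opens=0, qstart=1, qend=length,
        sstart=sstart, send=send, evalue=evalue, bitscore=float(bitscore),
    )
    label = identity >= 85.0 and evalue <= 1.0e-10
    return rec, label


def _tile(lo: int, hi: int, length: int, limit: Optional[int] = None) -> List[Tuple[int, int]]:
    """Non-overlapping tiles of ``length`` covering [lo, hi) from the left."""
    tiles = []
    p = lo
    while p + length <= hi and (limit is None or len(tiles) < limit):
        tiles.append((p, p + length))
        p += length
    return tiles


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

def _truth_class_of_sites(
    class_map: Dict[RegionClass, RegionSet], chrom: str, pos: np.ndarray
) -> np.ndarray:
    """Index into _GRADIENT per site by precedence; -1 = no class (introns)."""
    out = np.full(len(pos), -1, dtype=np.int8)
    for rank, cls in enumerate(_GRADIENT):
        mask = class_map[cls].contains_positions(chrom, pos)
        out[(out == -1) & mask] = rank
    return out


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_fixture(cfg: SynthConfig = SynthConfig()) -> FixtureBundle:
    """Generate the complete synthetic study for one configuration."""
    root = np.random.SeedSequence(cfg.seed)
    rng_genome, rng_aln, rng_meth, rng_reads = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    n_islands = cfg.n_genes if cfg.n_islands is None else cfg.n_islands

    # --- symbols: target G0001.., source shares a leading fraction ---------
    target_symbols = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    n_shared = int(round(cfg.shared_symbol_fraction * cfg.n_genes))
    source_symbols = target_symbols[:n_shared] + [
        f"SRC{i + 1:04d}" for i in range(cfg.n_genes - n_shared)
    ]

    units = _layout_units(cfg, "chr", target_symbols, n_islands)
    src_units = _layout_units(cfg, "src", source_symbols, n_islands)
    chrom_lengths = {f"chr{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)}
    src_chrom_lengths = {f"src{c + 1}": cfg.chrom_length for c in range(cfg.n_chroms)}

    # --- target genome sequence with planted islands ----------------------
    genome: Dict[str, str] = {}
    island_ivs: List[GenomicInterval] = []
    for chrom in sorted(chrom_lengths):
        seq = _background_sequence(rng_genome, cfg.chrom_length, cfg.background_gc)
        for u in units:
            if u.chrom != chrom or not u.has_island:
                continue
            a, b = u.abs_iv(u.rel["island"])
            seq[a:b] = _island_sequence(rng_genome, b - a, cfg.island_cg_density,
                                        cfg.background_gc)
            island_ivs.append(GenomicInterval(chrom, a, b))
        genome[chrom] = seq.tobytes().decode("ascii")
    truth_islands = merge(RegionSet("CGI", "target", island_ivs))

    target_genes = _units_to_genes(units)
    source_genes = _units_to_genes(src_units)

    params = PipelineParams()
    src_promoters = promoters_of(source_genes, params, src_chrom_lengths)

    # --- probe panel on the source genome + alignments to the target ------
    probes: List[GenomicInterval] = []
    alignments: List[AlignmentRecord] = []
    truth_labels: List[bool] = []
    probe_truth: Dict[str, bool] = {}
    covered_truth: Set[str] = set()
    pid = 0
    cat_p = [cfg.pass_prob, cfg.fail_identity_prob,
             1.0 - cfg.pass_prob - cfg.fail_identity_prob]
    unit_by_symbol = {u.symbol: u for u in units}

    def add_probe(src_iv: GenomicInterval, tgt: Optional[Tuple[str, int, int]]) -> None:
        nonlocal pid
        pid += 1
        probe_id = f"probe{pid:05d}"
        probes.append(GenomicInterval(src_iv.chrom, src_iv.start, src_iv.end,
                                      name=probe_id))
        n_hits = int(rng_aln.choice(4, p=list(cfg.extra_hit_probs)))
        any_pass = False
        for h in range(n_hits):
            cat = ["pass", "fail_identity", "fail_evalue"][int(rng_aln.choice(3, p=cat_p))]
            if h == 0 and tgt is not None:
                subject, s0, s1 = tgt
            else:
                chrom = sorted(chrom_lengths)[int(rng_aln.integers(cfg.n_chroms))]
                s0 = int(rng_aln.integers(0, cfg.chrom_length - cfg.probe_length))
                s1 = s0 + cfg.probe_length
                subject = chrom
            rec, label = _draw_alignment(rng_aln, cfg, probe_id, subject, s0, s1, cat)
            alignments.append(rec)
            truth_labels.append(label)
            any_pass = any_pass or label
        probe_truth[probe_id] = any_pass

    for su in src_units:
        prom = src_promoters.get(su.symbol)
        tu = unit_by_symbol.get(su.symbol)
        # promoter tiling: 4..17 tiles of probe_length from the promoter start;
        # realized covered fraction straddles the 60% orthology cutoff
        if prom is not None:
            n_tiles = int(rng_aln.integers(4, 18))
            tiles = _tile(prom.start, prom.end, cfg.probe_length, limit=n_tiles)
            covered = sum(e - s for s, e in tiles)
            if covered / len(prom) > params.opr_min_overlap:
                covered_truth.add(su.symbol)
            tprom_rel = tu.rel["prom"] if tu is not None else None
            for k, (s, e) in enumerate(tiles):
                tgt = None
                if tu is not None:
                    off = s - prom.start
                    a = tu.abs_iv(tprom_rel)[0] + off
                    tgt = (tu.chrom, a, a + (e - s))
                add_probe(GenomicInterval(prom.chrom, s, e), tgt)
        # island +/- 3 kb tiling (covers shores fully, half of each shelf)
        if su.has_island:
            ia, ib = su.abs_iv(su.rel["island"])
            for s, e in _tile(ia - 3000, ib + 3000, cfg.probe_length):
                tgt = None
                if tu is not None:
                    ta, _tb = tu.abs_iv(tu.rel["island"])
                    off = s - ia
                    tgt = (tu.chrom, ta + off, ta + off + (e - s))
                add_probe(GenomicInterval(su.chrom, max(s, 0), e), tgt)
        # exon tiling for a fraction of genes
        if rng_aln.random() < cfg.exon_tile_fraction:
            for ex in su.exons[1:]:
                (sa, sb) = su.abs_iv(ex)
                for s, e in _tile(sa, sb, cfg.probe_length):
                    tgt = None
                    if tu is not None:
                        ta = tu.abs_iv(ex)[0] + (s - sa)
                        tgt = (tu.chrom, ta, ta + (e - s))
                    add_probe(GenomicInterval(su.chrom, s, e), tgt)
    # intergenic probes: subjects in the unit tail gaps of the target genome
    # (strand-aware: the mirrored layout of minus-strand units puts the
    # promoter near the unit end, so the free gap flips side)
    stride = cfg.unit_stride
    for _ in range(cfg.n_intergenic_probes):
        u = units[int(rng_aln.integers(len(units)))]
        lo = u.start + (stride - 5000 if u.strand == "+" else 500)
        s0 = lo + int(rng_aln.integers(0, 4500 - cfg.probe_length))
        src_chrom = "src" + u.chrom[3:]
        add_probe(
            GenomicInterval(src_chrom, s0, s0 + cfg.probe_length),
            (u.chrom, s0, s0 + cfg.probe_length),
        )
    # deterministic boundary records on the first probe: inclusive pass at
    # exactly (85.0, 1e-10); fails on one criterion each
    first = probes[0]
    for identity, evalue, label in (
        (85.0, 1.0e-10, True), (84.9, 1.0e-30, False), (99.0, 1.0e-5, False),
    ):
        alignments.append(AlignmentRecord(
            query_id=first.name, subject="chr1", identity=identity,
            aln_length=cfg.probe_length, mismatches=0, gap_opens=0,
            qstart=1, qend=cfg.probe_length, sstart=1001,
            send=1000 + cfg.probe_length, evalue=evalue, bitscore=200.0,
        ))
        truth_labels.append(label)
        if label:
            probe_truth[first.name] = True

    probe_set = RegionSet("probes", "source", probes)

    # --- truth-based class map on the target genome -----------------------
    shores, shelves = derive_shores_shelves(truth_islands, chrom_lengths)
    tgt_promoters = promoters_of(target_genes, params, chrom_lengths)
    prom_set = merge(RegionSet("PROMOTER", "target",
                               [GenomicInterval(p.chrom, p.start, p.end)
                                for p in tgt_promoters.values()]))
    class_map = build_region_map(
        truth_islands, shores, shelves, prom_set, target_genes, chrom_lengths,
        genome_id="target",
    )

    # truth redefined region: planted-pass subject intervals + OPR promoters
    pass_ivs = [
        rec.subject_interval() for rec, lab in zip(alignments, truth_labels) if lab
    ]
    opr_truth_ivs = [
        GenomicInterval(tgt_promoters[s].chrom, tgt_promoters[s].start,
                        tgt_promoters[s].end)
        for s in sorted(covered_truth) if s in tgt_promoters
    ]
    redefined_truth = union(
        merge(RegionSet("hpr", "target",
                        [GenomicInterval(i.chrom, i.start, i.end) for i in pass_ivs])),
        merge(RegionSet("opr", "target", opr_truth_ivs)),
        label="redefined",
    )

    # --- cytosine report with the planted class gradient ------------------
    rho = cfg.dispersion
    kappa = (1 - rho) / rho if rho > 0 else None
    rows: List[pd.DataFrame] = []
    truth_acc: Dict[str, Tuple[float, int]] = {}
    realized: Dict[str, List[np.ndarray]] = {str(c): [] for c in _GRADIENT}
    for chrom in sorted(genome):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pos = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
        cls_idx = _truth_class_of_sites(class_map, chrom, pos)
        means = np.full(len(pos), cfg.class_means[RegionClass.INTERGENIC])
        for rank, cls in enumerate(_GRADIENT):
            means[cls_idx == rank] = cfg.class_means[cls]
        if kappa is None:
            levels = means.copy()
        else:
            levels = rng_meth.beta(np.maximum(means * kappa, 1e-9),
                                   np.maximum((1 - means) * kappa, 1e-9))
        if cfg.full_depth:
            lam = np.full(len(pos), cfg.depth_mean / 2.0)
        else:
            on = redefined_truth.contains_positions(chrom, pos)
            lam = np.where(on, cfg.depth_mean / 2.0, cfg.off_target_depth / 2.0)
        d_plus = rng_meth.poisson(lam)
        d_minus = rng_meth.poisson(lam)
        m_plus = rng_meth.binomial(d_plus, levels)
        m_minus = rng_meth.binomial(d_minus, levels)
        tri_plus = [seq[p : p + 3].ljust(3, "N") for p in pos]
        tri_minus = [
            _revcomp(("N" + seq)[p : p + 3]) for p in pos  # seq[p-1:p+2] with left pad
        ]
        plus = pd.DataFrame({
            "chrom": chrom, "pos": pos + 1, "strand": "+",
            "meth": m_plus, "unmeth": d_plus - m_plus,
            "context": "CpG", "tri": tri_plus,
        })
        minus = pd.DataFrame({
            "chrom": chrom, "pos": pos + 2, "strand": "-",
            "meth": m_minus, "unmeth": d_minus - m_minus,
            "context": "CpG", "tri": tri_minus,
        })
        both = pd.concat([plus, minus]).sort_values(
            ["pos", "strand"], kind="mergesort"
        )
        rows.append(both)
        for rank, cls in enumerate(_GRADIENT):
            realized[str(cls)].append(levels[cls_idx == rank])
    cx = pd.concat(rows, ignore_index=True)
    truth_levels = pd.DataFrame(
        {
            "region_class": [str(c) for c in _GRADIENT],
            "planted_mean": [cfg.class_means[c] for c in _GRADIENT],
            "realized_mean": [
                float(np.concatenate(realized[str(c)]).mean())
                if sum(len(a) for a in realized[str(c)]) else float("nan")
                for c in _GRADIENT
            ],
            "n_sites": [
                int(sum(len(a) for a in realized[str(c)])) for c in _GRADIENT
            ],
        }
    )

    # --- de-duplicated read intervals --------------------------------------
    reads: List[GenomicInterval] = []
    tgt_arrays = redefined_truth._arrays()
    flat: List[Tuple[str, int, int]] = [
        (c, int(s), int(e)) for c in sorted(tgt_arrays) for s, e in zip(*tgt_arrays[c])
    ]
    weights = np.array([e - s for _, s, e in flat], dtype=float)
    weights = weights / weights.sum() if len(flat) else weights
    for _ in range(cfg.n_reads):
        if flat and rng_reads.random() < cfg.read_on_target_fraction:
            i = int(rng_reads.choice(len(flat), p=weights))
            c, s, e = flat[i]
            a = int(rng_reads.integers(max(s - cfg.read_length + 1, 0), e))
        else:
            c = sorted(chrom_lengths)[int(rng_reads.integers(cfg.n_chroms))]
            a = int(rng_reads.integers(0, cfg.chrom_length - cfg.read_length))
        b = min(a + cfg.read_length, chrom_lengths[c])
        reads.append(GenomicInterval(c, a, b))

    return FixtureBundle(
        config=cfg,
        genome=genome,
        chrom_lengths=chrom_lengths,
        truth_islands=truth_islands,
        target_genes=target_genes,
        source_genes=source_genes,
        source_chrom_lengths=src_chrom_lengths,
        probes=probe_set,
        alignments=alignments,
        alignment_truth=truth_labels,
        probe_truth=probe_truth,
        covered_symbol_truth=covered_truth,
        class_map=class_map,
        redefined_truth=redefined_truth,
        cx_report=cx,
        truth_class_levels=truth_levels,
        reads=reads,
    )
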