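"""Cross-species target redefinition: HPR, OPR, and their union.

The homologous probe region (HPR) is built from probe-to-genome local
alignments: records passing identity >= 85% and e-value <= 1e-10 (inclusive
boundaries, configurable) have their subject intervals merged, strand
ignored. With multiple hits per probe the default keeps the single best hit
(highest bitscore, ties by lowest e-value, then highest identity, then
smallest subject coordinate) to avoid paralogous inflation; ``mode="all"``
keeps every passing hit for sensitivity analysis.

The orthologous promoter region (OPR) recovers promoters the probe panel
only partially reaches: source-genome gene symbols whose promoters are
covered by the probe region strictly more than 60% are matched by symbol to
the target annotation, and the target-genome promoters (2 kb upstream of the
TSS) of the matched symbols are merged. The redefined target region is the
union HPR + OPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .intervals import GenomicInterval, RegionSet, merge, overlap_fraction, subtract, union
from .io_formats import AlignmentRecord, GeneModel
from .regions import PipelineParams, promoter_of

__all__ = [
    "TargetDefinition",
    "filter_alignments",
    "build_hpr",
    "covered_gene_symbols",
    "build_opr",
    "assemble_target",
    "probe_mapping_rate",
]

logger = logging.getLogger(__name__)


@dataclass
class TargetDefinition:
    """The redefined target region and its provenance."""

    hpr: RegionSet
    opr: RegionSet
    redefined: RegionSet
    probe_mapping_rate: Optional[float] = None
    per_probe_best: Dict[str, AlignmentRecord] = field(default_factory=dict)
    opr_added_bases: int = 0
    opr_added_cg_sites: Optional[int] = None
    opr_raw_cg_sites: Optional[int] = None


def _passes(rec: AlignmentRecord, params: PipelineParams) -> bool:
    return rec.identity >= params.hpr_min_identity and rec.evalue <= params.hpr_max_evalue


def filter_alignments(
    records: Sequence[AlignmentRecord],
    params: PipelineParams = PipelineParams(),
    mode: str = "best",
) -> List[AlignmentRecord]:
    """Apply the identity/e-value filter; optionally keep one best hit per probe.

    Probes with no passing record are logged (drop report), never silently
    lost from the mapping-rate denominator.
    """
    if mode not in ("best", "all"):
        raise ValueError(f"mode must be 'best' or 'all', got {mode!r}")
    passing = [r for r in records if _passes(r, params)]
    if mode == "all":
        return passing
    best: Dict[str, AlignmentRecord] = {}
    for rec in passing:
        cur = best.get(rec.query_id)
        if cur is None or _best_key(rec) < _best_key(cur):
            best[rec.query_id] = rec
    dropped = {r.query_id for r in records} - set(best)
    if dropped:
        logger.info("%d probes with no passing alignment", len(dropped))
    return [best[q] for q in sorted(best)]


def _best_key(rec: AlignmentRecord) -> Tuple:
    iv = rec.subject_interval()
    return (-rec.bitscore, rec.evalue, -rec.identity, iv.chrom, iv.start)


def probe_mapping_rate(all_probe_ids: Iterable[str], passing: Sequence[AlignmentRecord]) -> float:
    """Fraction of probes with at least one passing alignment."""
    total = len(set(all_probe_ids))
    if total == 0:
        raise ValueError("no probes supplied")
    return len({r.query_id for r in passing}) / total


def build_hpr(passing: Sequence[AlignmentRecord], genome_id: str = "") -> RegionSet:
    """Merge passing subject intervals (strand-ignored) into the HPR."""
    ivs = [r.subject_interval() for r in passing]
    return merge(RegionSet("HPR", genome_id, [GenomicInterval(i.chrom, i.start, i.end) for i in ivs]))


def covered_gene_symbols(
    source_promoters: Dict[str, GenomicInterval],
    probe_regions: RegionSet,
    params: PipelineParams = PipelineParams(),
) -> Set[str]:
    """Symbols whose source promoter is probe-covered strictly above the cutoff."""
    probe_regions = merge(probe_regions)
    return {
        sym
        for sym, prom in source_promoters.items()
        if overlap_fraction(prom, probe_regions) > params.opr_min_overlap
    }


def build_opr(
    symbols: Set[str],
    target_gene_models: Sequence[GeneModel],
    params: PipelineParams = PipelineParams(),
    chrom_lengths: Optional[Dict[str, int]] = None,
    genome_id: str = "",
    case_insensitive: bool = False,
) -> RegionSet:
    """Target-genome promoters of the matched symbols, merged.

    Symbol matching is exact by default (optionally case-folded); unmatched
    symbols are logged.
    """
    def fold(s: str) -> str:
        return s.casefold() if case_insensitive else s

    wanted = {fold(s) for s in symbols}
    promoters: List[GenomicInterval] = []
    matched: Set[str] = set()
    for gm in target_gene_models:
        if fold(gm.gene_symbol) in wanted:
            iv = promoter_of(gm, params, chrom_lengths)
            if iv is not None:
                promoters.append(GenomicInterval(iv.chrom, iv.start, iv.end))
                matched.add(fold(gm.gene_symbol))
    unmatched = wanted - matched
    if unmatched:
        logger.info("%d covered symbols absent from target annotation", len(unmatched))
    return merge(RegionSet("OPR", genome_id, promoters))


def assemble_target(
    hpr: RegionSet,
    opr: RegionSet,
    genome: Optional[Dict[str, str]] = None,
    probe_rate: Optional[float] = None,
    per_probe_best: Optional[Dict[str, AlignmentRecord]] = None,
) -> TargetDefinition:
    """Union HPR and OPR into the redefined target region.

    Reports the bases the OPR adds beyond the HPR, and (when the genome
    sequence is supplied) both the raw OPR CG-site count and the CG sites
    added by the OPR-only bases.
    """
    if hpr.genome_id and opr.genome_id and hpr.genome_id != opr.genome_id:
        raise ValueError(f"genome mismatch: {hpr.genome_id!r} vs {opr.genome_id!r}")
    redefined = union(hpr, opr, label="redefined")
    opr_only = subtract(opr, hpr)
    td = TargetDefinition(
        hpr=merge(hpr),
        opr=merge(opr),
        redefined=redefined,
        probe_mapping_rate=probe_rate,
        per_probe_best=per_probe_best or {},
        opr_added_bases=opr_only.total_length,
    )
    if genome is not None:
        from .census import count_cpg_in_regions  # local import: avoid cycle

        td.opr_added_cg_sites = count_cpg_in_regions(opr_only, genome)
        td.opr_raw_cg_sites = count_cpg_in_regions(td.opr, genome)
    return td
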