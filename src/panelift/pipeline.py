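"""End-to-end orchestration: CGI -> regions -> HPR -> OPR -> target -> census -> summary.

`run_pipeline` consumes the on-disk inputs (FASTA genome, source/target GTF,
probe BED, blast8 alignments, cytosine report, optional read BED, optional
precomputed CGI BED) and returns a :class:`PipelineResult`; `write_outputs`
serializes every stage product as TSV/BED with a parameter-echo header so a
rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .census import CensusTable, census, count_cpg_in_regions, genome_cpg_sites
from .cgi import CgiParams, derive_shores_shelves, find_cgis
from .intervals import GenomicInterval, RegionSet, merge, read_bed, write_bed
from .io_formats import read_blast8, read_cytosine_report, read_fasta, read_gtf
from .methylome import (
    DepthProfile,
    class_methylation,
    depth_profile,
    merge_strands,
    on_target_read_rate,
    on_target_sites,
)
from .regions import PipelineParams, RegionClass, build_region_map, promoters_of
from .target import (
    TargetDefinition,
    assemble_target,
    build_hpr,
    build_opr,
    covered_gene_symbols,
    filter_alignments,
    probe_mapping_rate,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    params: PipelineParams
    chrom_lengths: Dict[str, int]
    cgis: RegionSet
    class_map: Dict[RegionClass, RegionSet]
    target_def: TargetDefinition
    census_table: CensusTable
    sites_on_target: pd.DataFrame
    depth: DepthProfile
    class_summary: pd.DataFrame
    on_target_rate: Optional[float] = None
    n_covered_symbols: int = 0
    seed: Optional[int] = None

    def summary_dict(self) -> Dict[str, object]:
        td = self.target_def
        return {
            "version": __version__,
            "probe_mapping_rate_pct": None if td.probe_mapping_rate is None
            else round(100 * td.probe_mapping_rate, 1),
            "hpr_length_bp": td.hpr.total_length,
            "opr_length_bp": td.opr.total_length,
            "redefined_length_bp": td.redefined.total_length,
            "opr_added_bases": td.opr_added_bases,
            "opr_added_cg_sites": td.opr_added_cg_sites,
            "redefined_cg_sites": self.census_table.rows["TOTAL"]["cg_sites_in_target"],
            "n_covered_symbols": self.n_covered_symbols,
            "mean_depth": round(self.depth.mean_depth, 2),
            "coverage_ge5_pct": round(self.depth.cumulative_coverage.get(5, float("nan")), 1),
            "on_target_read_rate_pct": None if self.on_target_rate is None
            else round(100 * self.on_target_rate, 1),
        }


def _progress(stage: str, t0: float) -> float:
    t = time.monotonic()
    logger.info("stage %-10s %.2fs", stage, t - t0)
    return t


def run_pipeline(
    genome_fa,
    source_gtf,
    target_gtf,
    probes_bed,
    blast8,
    cx_report,
    reads_bed=None,
    cgi_bed=None,
    params: PipelineParams = PipelineParams(),
    cgi_params: CgiParams = CgiParams(),
    mode: str = "best",
    seed: Optional[int] = None,
) -> PipelineResult:
    """Run every stage of the target-redefinition and summarization pipeline.

    When ``cgi_bed`` is given, its intervals are used as the CGI class
    (e.g. a previous ``cgi`` stage output, or planted truth islands when
    evaluating on synthetic data); otherwise islands are predicted from the
    genome sequence.
    """
    t0 = time.monotonic()
    genome = read_fasta(genome_fa)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    t0 = _progress("load", t0)

    if cgi_bed is not None:
        cgis = read_bed(cgi_bed, label="CGI", genome_id="target")
    else:
        calls = []
        for chrom in sorted(genome):
            calls.extend(find_cgis(genome[chrom], cgi_params, chrom=chrom))
        cgis = RegionSet("CGI", "target", [c.interval for c in calls])
    cgis = merge(cgis)
    t0 = _progress("cgi", t0)

    shores, shelves = derive_shores_shelves(cgis, chrom_lengths)
    target_genes = read_gtf(target_gtf)
    tgt_promoters = promoters_of(target_genes, params, chrom_lengths)
    prom_set = merge(RegionSet("PROMOTER", "target",
                               [GenomicInterval(p.chrom, p.start, p.end)
                                for p in tgt_promoters.values()]))
    class_map = build_region_map(cgis, shores, shelves, prom_set, target_genes,
                                 chrom_lengths, genome_id="target")
    t0 = _progress("regions", t0)

    source_genes = read_gtf(source_gtf)
    probes = read_bed(probes_bed, label="probes", genome_id="source")
    src_promoters = promoters_of(source_genes, params)
    symbols = covered_gene_symbols(src_promoters, probes, params)

    records = read_blast8(blast8)
    passing = filter_alignments(records, params, mode=mode)
    rate = probe_mapping_rate(
        [iv.name or "" for iv in probes], filter_alignments(records, params, mode="all")
    )
    hpr = build_hpr(passing, genome_id="target")
    opr = build_opr(symbols, target_genes, params, chrom_lengths, genome_id="target")
    target_def = assemble_target(hpr, opr, genome=genome, probe_rate=rate)
    t0 = _progress("target", t0)

    reference = {
        str(cls): count_cpg_in_regions(rs, genome) for cls, rs in class_map.items()
    }
    reference["TOTAL"] = sum(len(p) for p in genome_cpg_sites(genome).values())
    census_table = census(target_def.redefined, class_map, genome, reference)
    t0 = _progress("census", t0)

    cpg_sites = genome_cpg_sites(genome)
    sites = merge_strands(read_cytosine_report(cx_report), cpg_sites)
    on_sites = on_target_sites(sites, target_def.redefined)
    target_positions = {
        chrom: pos[target_def.redefined.contains_positions(chrom, pos)]
        for chrom, pos in cpg_sites.items()
    }
    depth = depth_profile(on_sites, target_positions)
    class_summary = class_methylation(on_sites, class_map, target_def.redefined, params)
    rate_reads = None
    if reads_bed is not None:
        reads = read_bed(reads_bed, label="reads", genome_id="target")
        rate_reads = on_target_read_rate(list(reads), target_def.redefined)
    t0 = _progress("summarize", t0)

    return PipelineResult(
        params=params,
        chrom_lengths=chrom_lengths,
        cgis=cgis,
        class_map=class_map,
        target_def=target_def,
        census_table=census_table,
        sites_on_target=on_sites,
        depth=depth,
        class_summary=class_summary,
        on_target_rate=rate_reads,
        n_covered_symbols=len(symbols),
        seed=seed,
    )


def _header(seed: Optional[int], params: PipelineParams) -> str:
    echo = " ".join(f"{k}={v}" for k, v in sorted(vars(params).items()))
    return f"# panelift {__version__} seed={seed} {echo}\n"


def write_outputs(result: PipelineResult, outdir) -> List[Path]:
    """Write every stage product under ``outdir`` (deterministic bytes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    head = _header(result.seed, result.params)
    written: List[Path] = []

    def tsv(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        with open(p, "w") as fh:
            fh.write(head)
            df.to_csv(fh, sep="\t", index=False, na_rep="NA")
        written.append(p)

    for name, rs in [
        ("cgi.bed", result.cgis),
        ("hpr.bed", result.target_def.hpr),
        ("opr.bed", result.target_def.opr),
        ("redefined.bed", result.target_def.redefined),
    ]:
        write_bed(rs, outdir / name)
        written.append(outdir / name)
    for cls, rs in result.class_map.items():
        write_bed(rs, outdir / f"regions_{cls}.bed")
        written.append(outdir / f"regions_{cls}.bed")
    tsv("census.tsv", result.census_table.to_frame().reset_index())
    tsv("class_methylation.tsv", result.class_summary)
    depth_df = pd.DataFrame(
        {
            "depth_threshold": list(result.depth.cumulative_coverage),
            "pct_sites_ge_depth": [
                round(v, 3) for v in result.depth.cumulative_coverage.values()
            ],
        }
    )
    tsv("depth_profile.tsv", depth_df)
    summary = result.summary_dict()
    summary["mean_depth"] = summary["mean_depth"]
    p = outdir / "run_summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(p)
    return written
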