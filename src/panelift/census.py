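"""CpG-site enumeration and the per-region-class census of a target.

A CpG site is identified by the 0-based plus-strand coordinate of its C;
region membership uses that coordinate alone (even when the G falls just
outside a region boundary) so no site is double-counted at class edges.
The census counts, for every region class, the CG sites inside the class
and inside class-intersect-target, and optionally expresses the latter as a
percentage of a reference (e.g. source-panel) per-class census.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .intervals import RegionSet, intersect, merge
from .regions import RegionClass

__all__ = ["enumerate_cpg_sites", "count_cpg_in_regions", "census", "CensusTable"]

TOTAL = "TOTAL"


def enumerate_cpg_sites(seq: str) -> np.ndarray:
    """Sorted 0-based positions of the C of each CG dinucleotide."""
    arr = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)


def genome_cpg_sites(genome: Mapping[str, str]) -> Dict[str, np.ndarray]:
    """Per-chromosome CpG positions for a whole genome map."""
    return {chrom: enumerate_cpg_sites(seq) for chrom, seq in genome.items()}


def count_cpg_in_regions(
    regions: RegionSet,
    genome: Mapping[str, str],
    sites: Optional[Dict[str, np.ndarray]] = None,
) -> int:
    """Number of CpG sites whose C position lies inside ``regions``."""
    if sites is None:
        sites = genome_cpg_sites(genome)
    regions = merge(regions)
    return int(
        sum(regions.contains_positions(chrom, pos).sum() for chrom, pos in sites.items())
    )


@dataclass
class CensusTable:
    """Per-class CG-site counts of a target region set.

    ``rows`` maps class label (plus ``TOTAL``) to a dict with
    ``cg_sites_in_class``, ``cg_sites_in_target`` and, when a reference
    census was supplied, ``coverage_vs_reference`` as a percentage (NA when
    the reference count is zero). Classes overlap, so per-class in-target
    counts need not sum to TOTAL; TOTAL is the count over the merged target.
    """

    rows: Dict[str, Dict[str, object]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.rows, orient="index")
        df.index.name = "region_class"
        return df


def census(
    target: RegionSet,
    classes: Mapping[RegionClass, RegionSet],
    genome: Mapping[str, str],
    reference_census: Optional[Mapping[str, int]] = None,
) -> CensusTable:
    """Count CG sites per region class inside the target.

    A site is "in class and target" if its C position lies in
    intersect(class, target). Coverage percentages are reported at 0.1%
    precision relative to the reference per-class counts.
    """
    sites = genome_cpg_sites(genome)
    target = merge(target)
    table = CensusTable()
    for cls, regions in classes.items():
        if (
            target.genome_id
            and regions.genome_id
            and target.genome_id != regions.genome_id
        ):
            raise ValueError("census: class map and target on different genomes")
        in_class = count_cpg_in_regions(regions, genome, sites)
        in_both = count_cpg_in_regions(intersect(merge(regions), target), genome, sites)
        row: Dict[str, object] = {
            "cg_sites_in_class": in_class,
            "cg_sites_in_target": in_both,
        }
        if reference_census is not None:
            ref = reference_census.get(str(cls), 0)
            row["coverage_vs_reference"] = (
                round(100.0 * in_both / ref, 1) if ref else float("nan")
            )
        table.rows[str(cls)] = row
    total_row: Dict[str, object] = {
        "cg_sites_in_class": sum(len(p) for p in sites.values()),
        "cg_sites_in_target": count_cpg_in_regions(target, genome, sites),
    }
    if reference_census is not None:
        ref = reference_census.get(TOTAL, 0)
        total_row["coverage_vs_reference"] = (
            round(100.0 * total_row["cg_sites_in_target"] / ref, 1) if ref else float("nan")
        )
    table.rows[TOTAL] = total_row
    return table
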