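"""Methylome summarization from per-cytosine bisulfite calls.

Per-strand cytosine calls are merged into strand-combined CpG-site calls
(the plus-strand C at position p absorbs the minus-strand C at p+1), then
filtered to the redefined target and summarized: on-target read rate, depth
statistics with cumulative coverage, and per-region-class methylation means
with standard deviations.

Site calls are carried as a pandas DataFrame with columns
``chrom, pos, meth, unmeth, depth, level`` — one row per strand-merged CpG
site with at least one covering read; enumerated sites absent from the
calls have depth 0 and enter the depth statistics through the enumerated
site list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet, intersect, merge
from .io_formats import CytosineRecord
from .regions import PipelineParams, RegionClass

__all__ = [
    "merge_strands",
    "on_target_sites",
    "on_target_read_rate",
    "depth_profile",
    "class_methylation",
    "DepthProfile",
]

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "meth", "unmeth", "depth", "level"]
DEFAULT_DEPTH_THRESHOLDS = (1, 5, 10, 20, 30, 40)


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "meth": pd.Series(dtype=np.int64),
            "unmeth": pd.Series(dtype=np.int64),
            "depth": pd.Series(dtype=np.int64),
            "level": pd.Series(dtype=float),
        }
    )


def merge_strands(
    records: Iterable[CytosineRecord],
    cpg_sites: Mapping[str, np.ndarray],
) -> pd.DataFrame:
    """Merge per-strand CpG-context calls into strand-combined site calls.

    For a site at plus-strand position p, counts from (+, p) and (-, p+1)
    are summed; a missing strand contributes zero. Total methylated and
    unmethylated counts are conserved. CpG-context records at positions
    not explained by any enumerated site signal an annotation/genome
    mismatch: they are excluded and reported via a warning.
    """
    acc: Dict[Tuple[str, int], List[int]] = {}
    orphans = 0
    site_lookup = {
        chrom: frozenset(int(p) for p in pos) for chrom, pos in cpg_sites.items()
    }
    for rec in records:
        if not rec.is_cpg:
            continue
        sites = site_lookup.get(rec.chrom, frozenset())
        if rec.strand == "+":
            p = rec.pos
        else:
            p = rec.pos - 1
        if p not in sites:
            orphans += 1
            continue
        cur = acc.setdefault((rec.chrom, p), [0, 0])
        cur[0] += rec.count_methylated
        cur[1] += rec.count_unmethylated
    if orphans:
        logger.warning(
            "%d CpG-context records did not match any enumerated CpG site "
            "(possible annotation/genome mismatch); excluded", orphans,
        )
    if not acc:
        return _empty_sites()
    keys = sorted(acc)
    df = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "pos": np.array([k[1] for k in keys], dtype=np.int64),
            "meth": np.array([acc[k][0] for k in keys], dtype=np.int64),
            "unmeth": np.array([acc[k][1] for k in keys], dtype=np.int64),
        }
    )
    df["depth"] = df["meth"] + df["unmeth"]
    with np.errstate(invalid="ignore"):
        df["level"] = np.where(df["depth"] > 0, df["meth"] / df["depth"], np.nan)
    return df


def on_target_sites(sites: pd.DataFrame, target: RegionSet) -> pd.DataFrame:
    """Sites whose C position lies inside the (half-open) target."""
    if sites.empty:
        return sites.copy()
    target = merge(target)
    keep = np.zeros(len(sites), dtype=bool)
    for chrom, grp in sites.groupby("chrom", sort=False):
        keep[grp.index.to_numpy()] = target.contains_positions(
            str(chrom), grp["pos"].to_numpy()
        )
    return sites.loc[keep].reset_index(drop=True)


def on_target_read_rate(reads: Sequence[GenomicInterval], target: RegionSet) -> float:
    """Fraction of read intervals overlapping the target by >= 1 bp.

    NaN for an empty read set. Reads merely abutting the target (half-open,
    zero overlapping bases) count as off-target.
    """
    if not reads:
        return float("nan")
    arrays = merge(target)._arrays()
    n_on = 0
    for r in reads:
        if r.chrom not in arrays:
            continue
        starts, ends = arrays[r.chrom]
        i = np.searchsorted(ends, r.start, side="right")
        if i < len(starts) and starts[i] < r.end:
            n_on += 1
    return n_on / len(reads)


@dataclass
class DepthProfile:
    """Mean calling depth and cumulative coverage over target CpG sites."""

    n_target_sites: int
    mean_depth: float
    cumulative_coverage: Dict[int, float] = field(default_factory=dict)  # d -> %


def depth_profile(
    sites: pd.DataFrame,
    target_cpg_positions: Mapping[str, np.ndarray],
    thresholds: Sequence[int] = DEFAULT_DEPTH_THRESHOLDS,
) -> DepthProfile:
    """Depth statistics over the enumerated target CpG sites.

    Sites absent from the calls count with depth 0; coverage(d) is the
    percentage of target sites with depth >= d and is non-increasing in d.
    """
    thresholds = sorted(thresholds)
    n_total = int(sum(len(p) for p in target_cpg_positions.values()))
    if n_total == 0:
        return DepthProfile(0, float("nan"), {d: float("nan") for d in thresholds})
    depths = np.zeros(n_total, dtype=np.int64)
    offset = 0
    for chrom in sorted(target_cpg_positions):
        pos = np.asarray(target_cpg_positions[chrom], dtype=np.int64)
        sub = sites[sites["chrom"] == chrom]
        if len(sub):
            idx = np.searchsorted(pos, sub["pos"].to_numpy())
            ok = (idx < len(pos)) & (pos[np.minimum(idx, len(pos) - 1)] == sub["pos"].to_numpy())
            depths[offset + idx[ok]] = sub["depth"].to_numpy()[ok]
        offset += len(pos)
    coverage = {
        int(d): 100.0 * float((depths >= d).sum()) / n_total for d in thresholds
    }
    return DepthProfile(n_total, float(depths.mean()), coverage)


def class_methylation(
    sites: pd.DataFrame,
    classes: Mapping[RegionClass, RegionSet],
    target: RegionSet,
    params: PipelineParams = PipelineParams(),
    depth_weighted: bool = False,
) -> pd.DataFrame:
    """Per-class methylation summary over qualifying sites.

    For each class, sites with depth >= ``params.min_call_depth`` lying in
    intersect(class, target) contribute. The default estimator is the
    unweighted mean of per-site levels with the sample SD (n-1 denominator);
    ``depth_weighted=True`` instead pools counts (sum meth / sum depth).
    Classes with no qualifying site yield NA rows. A 95% CI half-width
    (1.96 * sd / sqrt(n)) is included for reporting.
    """
    target = merge(target)
    qualified = sites[sites["depth"] >= params.min_call_depth]
    rows = []
    for cls, regions in classes.items():
        region_target = intersect(merge(regions), target)
        if qualified.empty:
            sel = qualified
        else:
            keep = np.zeros(len(qualified), dtype=bool)
            arr_idx = qualified.index.to_numpy()
            pos_of = {i: j for j, i in enumerate(arr_idx)}
            for chrom, grp in qualified.groupby("chrom", sort=False):
                mask = region_target.contains_positions(str(chrom), grp["pos"].to_numpy())
                keep[[pos_of[i] for i in grp.index]] = mask
            sel = qualified.iloc[keep]
        n = len(sel)
        if n == 0:
            rows.append((str(cls), 0, float("nan"), float("nan"), float("nan")))
            continue
        levels = sel["level"].to_numpy()
        if depth_weighted:
            mean = float(sel["meth"].sum() / sel["depth"].sum())
        else:
            mean = float(levels.mean())
        sd = float(levels.std(ddof=1)) if n > 1 else float("nan")
        ci = 1.96 * sd / math.sqrt(n) if n > 1 else float("nan")
        rows.append((str(cls), n, mean, sd, ci))
    return pd.DataFrame(
        rows, columns=["region_class", "n_sites", "mean_level", "sd_level", "ci95_halfwidth"]
    )
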