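# Methods

## Coordinate model

All coordinates are 0-based half-open internally. BED is native; GTF
(1-based closed) and blast8 (1-based inclusive, `sstart > send` meaning a
minus-strand hit) are converted on read. Set algebra (merge/intersect/
subtract/union) operates on covered bases: strand is carried on intervals
but ignored, and book-ended intervals coalesce, because capture targets and
methylation coverage are span concepts, not stranded features. Only
promoter construction is strand-aware.

## CpG island calling

Islands are called with the classic running-score maximal-segment scheme:
scanning dinucleotide start positions left to right, a score S (starting at
0, clamped below at 0) gains `cg_reward` = 17 at each CG and loses
`non_cg_penalty` = 1 otherwise. A segment opens when S rises from 0 and
closes when S returns to 0 or the sequence ends; the island runs from the
segment's first CG through both bases of the CG where S peaked, and is
reported iff the peak reaches `min_peak_score` = 17. All three constants are
configurable.

Numerical/tie choices: the island end uses the *rightmost* position
attaining the peak (a fixed, span-maximizing tie-break); `N` never forms a
CG and incurs the non-CG penalty, which is conservative toward assembly
gaps; characters outside `{A,C,G,T,N}` are rejected. The implementation is
vectorized (clamped running score as cumulative sum minus its running
minimum); tests compare it against an independent scalar open/close walk.

A consequence of the default constants is that a single isolated CG attains
peak 17 and is reported as a 2-bp island. This is inherent to the scoring,
not a defect; on random background sequence it produces many tiny calls.
For synthetic-data evaluation we therefore score the detector against the
planted islands (base recovery), and build the analysis region classes from
the planted islands rather than from detector output, so that the island
class does not absorb every background CG (see "Synthetic study" below).
On real genomes, users supply whichever island track they trust via
`--cgi`.

## Region taxonomy

Shores are the 2-kb windows flanking each island; shelves the next 2-kb
windows (2–4 kb from the island). Both are clipped to the chromosome, then
precedence-trimmed (CGI > shore > shelf) so the three classes are pairwise
disjoint. The shelf width is fixed at 2 kb, following the 450K-array
shore/shelf convention.

Promoters span the 2 kb upstream of the TSS. The TSS comes from the longest
transcript of a gene symbol, where "longest" means largest genomic span
(tx_end − tx_start) — the TSS is a genomic-coordinate concept — with ties
broken by lexicographically smallest transcript id for determinism. Gene
symbols are `gene_name` with `gene_id` fallback; a symbol appearing on
multiple loci keeps its first model and is logged.

Exon and CDS classes are merged unions over all transcripts; introns are
excluded and get no class. Intergenic is the genome minus merged gene spans
and promoters. Classes from different groups may overlap (a base can be
both CGI and promoter); per-class summaries are computed independently, so
no exclusivity is forced across groups. CDS bases outside exons indicate a
malformed annotation and are reported, never silently repaired.

## Target redefinition

Alignment filter: identity ≥ `hpr_min_identity` (85.0) AND e-value ≤
`hpr_max_evalue` (1e−10). Boundaries are inclusive — the published cut-off
values are themselves selected — and both thresholds are configuration.
With multiple hits per probe, mode `best` (default) keeps the single best
record per probe (highest bitscore, then lowest e-value, then highest
identity, then smallest subject coordinate), preventing paralogous hits
from inflating the target; mode `all` keeps every passing record for
sensitivity analysis. The probe mapping rate is the fraction of *probes*
with ≥ 1 passing alignment (not the fraction of alignment records).

The OPR cutoff is strict: a source promoter must be probe-covered by
*more than* 60% (`opr_min_overlap` = 0.60). Symbol matching against the
target annotation is exact by default with an optional case-folded flag; no
ortholog database is consulted. Because OPR promoters may overlap the HPR,
the assembly reports both the raw OPR CpG-site count and the count over
OPR-minus-HPR bases (the sites the OPR genuinely adds).

## Methylome summarization

A CpG site is the 0-based plus-strand position of the C of a CG
dinucleotide; membership of a site in any region uses that single
coordinate, so boundary sites are never double-counted. Strand merging sums
the plus-strand C at p with the minus-strand C at p+1; missing strands
contribute zero, and total methylated/unmethylated counts are conserved.
CpG-context records not explained by any enumerated site (annotation/genome
mismatch) are excluded with a warning, never silently dropped.

Depth statistics: coverage(d) = percentage of enumerated target CpG sites
with strand-merged depth ≥ d (uncalled sites count as depth 0), over the
default thresholds {1, 5, 10, 20, 30, 40}; the mean depth is over all
target sites. Per-class methylation uses sites at calling depth ≥
`min_call_depth` (default 5) inside class ∩ target, averaging per-site
levels unweighted with the sample SD (n−1); depth-weighted count pooling is
available behind a flag. The 95% interval reported alongside is
mean ± 1.96·sd/√n over sites. The 30× target-depth and 40× de-duplicated
depth figures are data-acquisition goals surfaced only in QC reporting,
not per-site filters. On-target read rate counts reads overlapping the
target by ≥ 1 bp; an abutting read (half-open, zero shared bases) is
off-target.

## Synthetic study

The generator emits a complete study under one seed (byte-identical
reruns). Defaults — chosen once as a realistic desk-scale regime — are:
2 chromosomes × 500 kb, background GC 0.40, 40 genes in fixed-stride units,
one 1-kb planted island (CG start probability 0.15 per position) inside
each gene's long intron, 4 exons × 500 bp per gene, 120-bp probes, 101-bp
reads, ~30× on-target calling depth split Poisson per strand (off-target
~1×), beta-binomial methylation with ρ = 0.02 around the planted gradient
CGI 0.10 < promoter 0.20 < shore 0.40 < shelf 0.60 < exon 0.75 <
intergenic 0.80, and 80% of source gene symbols shared with the target
annotation.

Placing each island (with its shores and shelves) inside an intron keeps
the six gradient classes pairwise disjoint, so every CpG site has an
unambiguous planted truth level; where classes could still overlap, the
generator assigns truth by the precedence CGI > shore > shelf > promoter >
exon > intergenic — a generator-side convention the analysis never sees.
Probe tiling covers source promoters to a varying extent (tile counts
straddle the 60% orthology cutoff, including the exact-60% boundary),
islands ± 3 kb, half of the genes' non-first exons, and some intergenic
tail positions; each probe receives 0–3 alignment records whose
identity/e-value category (pass / fail-identity / fail-evalue) is planted
and recorded as a truth label, including exact boundary records at
(85.0, 1e−10). Strand depths are independent Poisson halves, so count
conservation under strand merging is a non-trivial check.

`full_depth=True` switches off the capture effect (full depth genome-wide);
it is the configuration used for estimator-recovery evaluation, where each
gradient class needs ≥ 2000 qualifying sites. At that size the planted
class means are recovered within ±0.02 (sampling error alone is an order of
magnitude smaller).

What the generator does not emulate — and what passing tests therefore do
not demonstrate about real data: read-level sequences and mapping bias,
bisulfite-conversion errors, PCR duplicates, CpG-density autocorrelation of
real genomes, bimodal per-site methylation, annotation incompleteness
beyond the shared-symbol fraction, and assembly gaps.

## Problem sizes and determinism

The default test/evaluation study is 1 Mb; the end-to-end throughput check
runs a 5-Mb genome (10 chromosomes, 200 genes) through the whole chain,
which completes in well under a minute on one CPU. All randomness flows
from a single seed through named per-stage generators; outputs carry a
version/seed/parameter header and contain no timestamps, so reruns are
byte-identical.

## Known limitations

- The island caller is the running-score scheme with the stated defaults;
  exact call-for-call parity with any particular external implementation's
  edge-case reporting is not asserted.
- Orthology is by gene-symbol string match only; paralogs sharing a symbol
  across loci and symbol drift between annotation releases are the user's
  responsibility.
- No differential methylation, DMR calling, conversion-rate estimation, or
  duplicate removal; inputs are assumed de-duplicated.
- Reads arrive as BED intervals; BAM/SAM and FASTQ are out of scope.
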