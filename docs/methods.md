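# Methods

This note records the models and procedures implemented in `asmqc`, the
parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the numerical conventions used throughout.

## Coordinate convention

All in-memory coordinates are 0-based half-open. Conversions happen only
at file boundaries (`asmqc.io`): VCF positions, BUSCO full-table
coordinates and RepeatMasker query positions are 1-based inclusive on
disk; BED and PAF are already 0-based half-open. A 1-based inclusive
interval `[s, e]` becomes `[s−1, e)`, preserving its length `e−s+1`.
Keeping a single internal convention removes the entire class of
off-by-one errors that mixed-convention pipelines are prone to.

## Contiguity

N50/NGx use the standard cumulative rule: sort contigs in descending
length, accumulate, and report the length of the first contig at which
the cumulative sum reaches (≥) x% of the target — the assembly total for
Nx, an independent genome-size estimate for NGx. When the genome-size
estimate exceeds the assembled total, NGx is undefined (reported absent)
for x beyond the covered fraction. auN = Σ Lᵢ²/Σ Lⱼ is computed directly
from the definition; it equals the length of a single-contig assembly and
strictly decreases whenever a contig is split, which is why it is the
preferred statistic for comparing versions of the same assembly. Contigs
of equal length are ordered stably by name; this affects no statistic and
makes outputs deterministic.

## Completeness and the purge rule

A marker with two or more placements counts once as duplicated; the
denominator of every percentage is the number of distinct markers
searched (the convention BUSCO itself reports). Haplotig purging is
recommended when the duplication rate *strictly exceeds* the threshold
(default 1%); at exactly 1.0% the decision is negative.

## Genome size

Mean (not median) read depth is taken over the merged intervals of
complete single-copy markers — duplicated and fragmented markers are
excluded because they cannot be trusted as single-copy anchors.
Overlapping marker intervals are merged before averaging so each genomic
position contributes once. Positions inside marker intervals that are
absent from the depth file are treated as true zero-coverage sites
(`zero_fill=True` default), since depth profiles conventionally omit zero
rows; passing `zero_fill=False` restricts the average to recorded
positions. A median option exists for robustness checks but is off by
default because the estimator is defined in terms of the mean. The
estimate is `total read bases × (1 − removed fraction) / mean depth`,
where the removed fraction accounts for contaminant sequence dropped
from the assembly after the reads were counted.

## Heterozygosity and variant-based QV

Filters are inclusive minimums (depth ≥ 10, site quality ≥ 30, genotype
quality ≥ 30 by default); a record missing its depth field fails the
depth filter (depth is required evidence), while a missing genotype
quality passes (the field is optional in callers that do not emit it).
Banded gVCF intervals are filtered on whichever of their MIN_DP/quality
fields are present; bands often lack QUAL, and only present fields are
required to meet thresholds. Callable sites = summed lengths of passing
bands (merged, with a warning, if a caller emits overlapping bands) +
the number of distinct passing variant sites. Heterozygosity uses het
SNPs only in the numerator; indel and homozygous counts are reported
separately. The QV estimator deliberately counts *every* site with a
non-reference variant (SNP or indel, het or hom) as an error — on a
heterozygous sample it therefore reports a lower bound driven by residual
diversity rather than by consensus error, which is the intended reading.
An optional exclusion set (e.g. repeat-masked regions) is subtracted from
both variants and bands before any counting. Zero observed errors are
reported at the cap (default QV 60) with an explicit `capped` flag.

## Reference-based windowed accuracy

Differences are consumed from PAF `cs` strings (short form; long-form
`=SEQ` matches accepted) with substitution runs decomposed into unit
SNVs. Windows are fixed, non-overlapping, aligned to multiples of the
window size (default 100 kb). For each window × element-class cell the
denominator is aligned bp ∩ window ∩ class — aligned length, not window
length, because unaligned reference carries no evidence. Insertions
occupy no reference span, so each contributes its full inserted length
at its anchor coordinate (no proration); deletions are prorated by bp
across windows and classes. Windows with zero denominator are omitted
rather than reported as undefined values.

Element classes: introns are the within-gene complement of exons,
intergenic the complement of genic regions, so {exon, intron, intergenic}
partition each contig exactly; repeats overlap genes and are handled as
an independent overlay, not part of the partition. An exon outside every
gene is treated as an annotation error and rejected loudly.

Aggregation offers three views: the pooled rate (Phred of
Σ errors / Σ aligned), the median of per-window QVs, and the QV value
below which a stated percentage of windows fall (default the bottom 10th
percentile, linear interpolation between order statistics). A handful of
bad windows in an otherwise clean genome drives the pooled value far
below the median — both are reported so that the discrepancy itself is
visible.

The coding-indel summary counts an indel toward a gene when its anchor
(insertions) or span (deletions) intersects the gene's coding intervals;
"small" is < 50 bp and "large" ≥ 100 bp by default, and the share of
total coding difference bp contributed by large insertions is reported
because a few kb-scale insertions can dominate an otherwise nearly
identical coding genome.

## Synteny graph

Only complete single-copy markers anchor adjacencies; a marker appearing
twice as complete-single within one assembly is a status inconsistency
and an error. Within a contig, markers are ordered by start (ties by
end, then id). Only immediate neighbors form edges; chains of three or
more markers contribute no transitive (long-range) pairs. The
alternative reading — discarding contigs with three or more markers —
is available as `pair_mode="drop_long_contigs"` but would destroy most
of the signal and is not the default. Marker strand is stored by the
readers but ignored here: the graph is undirected.

Clustering uses connected components above a minimum edge weight
(default 1); component labels are the smallest member id, so assignments
are deterministic. The layout implements the ForceAtlas2 force model —
linear attraction along edges scaled by weight, (deg+1)(deg+1)/d
repulsion, mass-scaled gravity toward the origin, adaptive step sizes
via the swinging/traction heuristic (defaults tolerance 1, gravity 1,
3000 iterations) — with exact pairwise repulsion, which is adequate at
the few-thousand-node scale of a marker universe. All clustering claims
in the tests are made against `components()`, never against layout
geometry, which is for visualization only.

## Repeats, reads, downsampling

Repeat classes are the `.out` class field truncated at "/" (family
folded into class); unknown strings are kept verbatim. Within-class
intervals are merged before summing and the repetitive total is the
union across classes, so `repetitive + non_repetitive == assembly` holds
even when classes overlap. "Bases in reads longer than L" uses strict >
by default, matching the usual phrasing of the statistic; a flag flips
it to ≥. Downsampling takes reads in a seeded uniform permutation until
the cumulative length first reaches `depth × genome size`: inclusion
probability is independent of read length, so the downsampled read N50
is an unbiased image of the full set's, and overshoot is bounded by one
read length.

## Synthetic data

Generators are pure functions of their parameters plus one integer seed;
per-component streams are spawned via `numpy.random.SeedSequence`, so
reruns are bitwise identical. Defaults describe a drosophilid-like
regime: 6 chromosome arms × 300 markers (≈ the 1800–3300 marker range of
dipteran ortholog sets), 20 species, 5 within-arm inversions per species,
geometric fragmentation with mean 20 markers per contig, residual
heterozygosity around 10⁻³ (the generators accept the full
3.5×10⁻⁶–10⁻² range observed across real fly lines), read N50 targets of
20–30 kb with lognormal shape σ = 0.6, and Poisson per-position depth.
Inversion blocks are chosen uniformly over within-arm intervals of at
least two markers — the simplest model that preserves arm content, which
is the property the synteny analysis depends on.

The generators emulate the *statistical structure* the analyses consume,
not sequence: there are no base-level read errors, no assembly graph, no
misassembly, and marker coordinates are synthetic (fixed spacing). The
alignment-difference generator enforces non-overlapping differences
(a real alignment cannot report a SNV inside a deleted span) and keeps
deletions within their element block, so per-class truth is exact.
Passing tests therefore demonstrate correctness of the computations
under known truth — coordinate handling, counting rules, estimator
calibration — not robustness to alignment artifacts, miscalled variants
or annotation noise in real data.

## Problem sizes and numeric choices

The test and acceptance workloads use 10⁵–2×10⁶ site/bp scales and
20-species marker simulations, chosen so sampling error is comfortably
inside each estimator's stated recovery band (e.g. QV recovery is
checked at snv rate 10⁻³ over 2 Mb, where the binomial SD of the pooled
QV is ≈ 0.1). Phred values are computed in double precision directly
from counts; the only tolerance anywhere is the zero-error cap. Interval
arithmetic is integer-exact.

## Known limitations

* Multi-sample VCFs: FORMAT fields are read from the first sample only.
* Whole-file streaming I/O; no indexed random access (desk-scale inputs).
* The layout is exact-repulsion O(n²) per iteration — fine for marker
  universes, not for graphs of 10⁵+ nodes.
* The QV-from-variants estimator conflates residual heterozygosity with
  consensus error by construction; for inbred samples this is small, for
  diverse samples it is a lower bound.
* Reference-based accuracy cannot distinguish assembly error from true
  strain difference between the query and the reference.
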