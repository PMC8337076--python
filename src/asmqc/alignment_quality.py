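"""Reference-based accuracy: windowed QV by element and error type, and
coding-indel impact accounting.

A query assembly aligned to a trusted reference yields SNV, insertion
and deletion differences in reference coordinates. Accuracy is assessed
in non-overlapping windows (default 100 kb): for each window and each
genomic element class (exon, intron, intergenic, repeat, or the whole
sequence), the number of affected base pairs is divided by the aligned
length, and the ratio is Phred-scaled with a zero-error cap (default 60).
Insertions affect no reference span, so each insertion contributes its
full inserted length at its reference anchor; deletions are prorated by
base pair across windows and classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._intervals import (
    contains_point,
    intersect,
    merge,
    subtract,
    total_length,
)
from .models import DiffRecord
from .variant_quality import phred

Intervals = List[Tuple[int, int]]

ELEMENT_CLASSES = ("exon", "intron", "intergenic", "repeat")


@dataclass
class ElementAnnotation:
    """Merged per-contig interval sets for each genomic element class.

    Introns are the within-gene complement of exons; intergenic regions
    are the complement of genic regions, so {exon, intron, intergenic}
    partition every contig exactly. Repeats overlap the others and are
    tracked as an independent overlay.
    """

    contig_lengths: Dict[str, int]
    classes: Dict[str, Dict[str, Intervals]]

    def intervals(self, element_class: str, contig: str) -> Intervals:
        return self.classes.get(element_class, {}).get(contig, [])


def _by_contig(rows: Iterable[Tuple[str, int, int]]) -> Dict[str, Intervals]:
    out: Dict[str, Intervals] = {}
    for contig, s, e in rows:
        out.setdefault(contig, []).append((s, e))
    return {c: merge(ivs) for c, ivs in out.items()}


def derive_elements(
    genes: Iterable[Tuple[str, int, int]],
    exons: Iterable[Tuple[str, int, int]],
    repeats: Iterable[Tuple[str, int, int]],
    contig_lengths: Dict[str, int],
) -> ElementAnnotation:
    """Derive the exon/intron/intergenic partition plus the repeat overlay."""
    genes_m = _by_contig(genes)
    exons_m = _by_contig(exons)
    repeats_m = _by_contig(repeats)

    offenders = []
    for contig, ex in exons_m.items():
        outside = subtract(ex, genes_m.get(contig, []))
        offenders.extend((contig, s, e) for s, e in outside)
    if offenders:
        raise ValueError(
            "exon intervals outside any gene: "
            + ", ".join(f"{c}:{s}-{e}" for c, s, e in offenders[:10])
        )

    introns = {
        c: subtract(gm, exons_m.get(c, [])) for c, gm in genes_m.items()
    }
    intergenic = {
        c: subtract([(0, length)], genes_m.get(c, []))
        for c, length in contig_lengths.items()
    }
    return ElementAnnotation(
        contig_lengths=dict(contig_lengths),
        classes={
            "exon": exons_m,
            "intron": {c: iv for c, iv in introns.items() if iv},
            "intergenic": {c: iv for c, iv in intergenic.items() if iv},
            "repeat": repeats_m,
        },
    )


@dataclass
class WindowQV:
    contig: str
    window_start: int
    element_class: str  # one of ELEMENT_CLASSES or "whole"
    aligned_bp: int
    snv_bp: int
    ins_bp: int
    del_bp: int
    qv_total: float
    qv_snv: float
    qv_ins: float
    qv_del: float
    cap: float = 60.0

    @property
    def error_bp(self) -> int:
        return self.snv_bp + self.ins_bp + self.del_bp


def _split_by_windows(s: int, e: int, window_bp: int):
    """Split [s, e) at multiples of window_bp -> (window_start, bp) pieces."""
    while s < e:
        w = (s // window_bp) * window_bp
        cut = min(e, w + window_bp)
        yield w, cut - s
        s = cut


def window_qv(
    diffs: Sequence[DiffRecord],
    aligned: Dict[str, Intervals],
    elements: ElementAnnotation,
    window_bp: int = 100_000,
    cap: float = 60.0,
    classes: Optional[Sequence[str]] = None,
) -> List[WindowQV]:
    """Per-window, per-element-class error counts and Phred qualities.

    The denominator of each window/class cell is the aligned bp falling
    in that window and class; windows with zero denominator are omitted.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    class_list = ["whole"] + list(classes if classes is not None else ELEMENT_CLASSES)

    diffs_by_contig: Dict[str, List[DiffRecord]] = {}
    for d in diffs:
        diffs_by_contig.setdefault(d.contig, []).append(d)

    out: List[WindowQV] = []
    for contig, aln in sorted(aligned.items()):
        aln = merge(aln)
        contig_diffs = diffs_by_contig.get(contig, [])
        for cls in class_list:
            cls_ivs = aln if cls == "whole" else intersect(
                aln, elements.intervals(cls, contig)
            )
            if not cls_ivs:
                continue
            # denominators per window
            den: Dict[int, int] = {}
            for s, e in cls_ivs:
                for w, bp in _split_by_windows(s, e, window_bp):
                    den[w] = den.get(w, 0) + bp
            num: Dict[int, List[int]] = {w: [0, 0, 0] for w in den}  # snv, ins, del

            for d in contig_diffs:
                if d.kind == "del":
                    for s, e in intersect([(d.ref_start, d.ref_start + d.length)], cls_ivs):
                        for w, bp in _split_by_windows(s, e, window_bp):
                            if w in num:
                                num[w][2] += bp
                else:
                    if not contains_point(cls_ivs, d.ref_start):
                        continue
                    w = (d.ref_start // window_bp) * window_bp
                    if w not in num:
                        continue
                    if d.kind == "snv":
                        num[w][0] += 1
                    else:  # insertion: full inserted length at its anchor
                        num[w][1] += d.length

            for w in sorted(den):
                snv_bp, ins_bp, del_bp = num[w]
                aligned_bp = den[w]
                qv = lambda n: phred(n / aligned_bp, cap)[0]
                out.append(
                    WindowQV(
                        contig=contig,
                        window_start=w,
                        element_class=cls,
                        aligned_bp=aligned_bp,
                        snv_bp=snv_bp,
                        ins_bp=ins_bp,
                        del_bp=del_bp,
                        qv_total=qv(snv_bp + ins_bp + del_bp),
                        qv_snv=qv(snv_bp),
                        qv_ins=qv(ins_bp),
                        qv_del=qv(del_bp),
                        cap=cap,
                    )
                )
    return out


@dataclass
class QVSummary:
    n_windows: int
    pooled_qv: float
    median_qv: float
    percentile: float
    percentile_cutoff_qv: float
    total_aligned_bp: int
    total_error_bp: int


def aggregate_qv(windows: Sequence[WindowQV], percentile: float = 10.0) -> QVSummary:
    """Pooled, median and lower-percentile QV over a set of windows.

    The pooled value Phred-scales the overall error rate
    (sum errors / sum aligned); the percentile cutoff is the QV below
    which ``percentile`` percent of windows fall.
    """
    if not windows:
        raise ValueError("at least one window is required")
    cap = windows[0].cap
    total_err = sum(w.error_bp for w in windows)
    total_aln = sum(w.aligned_bp for w in windows)
    qvs = np.array([w.qv_total for w in windows], dtype=float)
    return QVSummary(
        n_windows=len(windows),
        pooled_qv=phred(total_err / total_aln, cap)[0],
        median_qv=float(np.median(qvs)),
        percentile=percentile,
        percentile_cutoff_qv=float(np.percentile(qvs, percentile)),
        total_aligned_bp=total_aln,
        total_error_bp=total_err,
    )


@dataclass
class IndelImpactSummary:
    n_genes_queried: int
    n_genes_with_indel: int
    pct_genes_with_indel: float
    n_insertions: int
    n_deletions: int
    inserted_bp: int
    deleted_bp: int
    n_small_insertions: int
    n_large_insertions: int
    n_small_deletions: int
    n_large_deletions: int
    pct_diff_bp_from_large_insertions: float


def indel_impact(
    diffs: Sequence[DiffRecord],
    coding: Dict[str, List[Tuple[str, int, int]]],
    small_cutoff: int = 50,
    large_cutoff: int = 100,
) -> IndelImpactSummary:
    """Account for insertions/deletions hitting coding sequence.

    ``coding`` maps gene id -> list of (contig, start, end) coding
    intervals. An indel counts toward a gene when its reference anchor
    (insertions) or span (deletions) intersects the gene's coding
    intervals. "Small" is < ``small_cutoff`` bp, "large" >= ``large_cutoff``.
    """
    if not coding:
        raise ValueError("no genes queried")

    # contig -> sorted (start, end, gene) for interval stabbing
    index: Dict[str, List[Tuple[int, int, str]]] = {}
    for gene, ivs in coding.items():
        for contig, s, e in ivs:
            index.setdefault(contig, []).append((s, e, gene))
    for contig in index:
        index[contig].sort()

    def _hit_genes(contig: str, s: int, e: int) -> List[str]:
        hits = []
        for gs, ge, gene in index.get(contig, []):
            if gs >= e:
                break
            if ge > s:
                hits.append(gene)
        return hits

    genes_hit = set()
    n_ins = n_del = ins_bp = del_bp = 0
    small_ins = large_ins = small_del = large_del = 0
    large_ins_bp = 0
    for d in diffs:
        if d.kind == "snv":
            continue
        span = (d.ref_start, d.ref_start + 1) if d.kind == "ins" else (
            d.ref_start, d.ref_start + d.length
        )
        hits = _hit_genes(d.contig, *span)
        if not hits:
            continue
        genes_hit.update(hits)
        if d.kind == "ins":
            n_ins += 1
            ins_bp += d.length
            small_ins += d.length < small_cutoff
            if d.length >= large_cutoff:
                large_ins += 1
                large_ins_bp += d.length
        else:
            n_del += 1
            del_bp += d.length
            small_del += d.length < small_cutoff
            large_del += d.length >= large_cutoff

    total_diff_bp = ins_bp + del_bp
    return IndelImpactSummary(
        n_genes_queried=len(coding),
        n_genes_with_indel=len(genes_hit),
        pct_genes_with_indel=100.0 * len(genes_hit) / len(coding),
        n_insertions=n_ins,
        n_deletions=n_del,
        inserted_bp=ins_bp,
        deleted_bp=del_bp,
        n_small_insertions=small_ins,
        n_large_insertions=large_ins,
        n_small_deletions=small_del,
        n_large_deletions=large_del,
        pct_diff_bp_from_large_insertions=(
            100.0 * large_ins_bp / total_diff_bp if total_diff_bp else 0.0
        ),
    )
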