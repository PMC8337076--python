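"""Variant filtering, callable-site accounting, heterozygosity and QV.

Residual sample diversity is estimated as the number of heterozygous
SNPs divided by the number of callable sites, where callable sites are
counted as the summed lengths of invariant-site intervals passing the
depth/quality filters plus the number of variant sites that pass the
same filters.

Consensus quality treats every site carrying a non-reference variant
(SNP or indel, het or hom) as an error:

    P_error = n_error_sites / n_callable_sites
    QV      = -10 * log10(P_error)

with a reporting cap (default 60) applied when no errors are observed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from ._intervals import contains_point, merge, subtract, total_length
from .models import CallableInterval, VariantRecord


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive minimums: a record passes at exactly the threshold value."""

    min_depth: int = 10
    min_site_quality: float = 30.0
    min_genotype_quality: Optional[float] = 30.0

    def __post_init__(self) -> None:
        if self.min_depth < 0 or self.min_site_quality < 0:
            raise ValueError("thresholds must be non-negative")
        if self.min_genotype_quality is not None and self.min_genotype_quality < 0:
            raise ValueError("thresholds must be non-negative")


def _variant_passes(v: VariantRecord, t: FilterThresholds) -> bool:
    if v.depth is None or v.depth < t.min_depth:
        return False
    if v.site_quality < t.min_site_quality:
        return False
    if (
        t.min_genotype_quality is not None
        and v.genotype_quality is not None
        and v.genotype_quality < t.min_genotype_quality
    ):
        return False
    return True


def _interval_passes(iv: CallableInterval, t: FilterThresholds) -> bool:
    # fields absent from the file cannot be filtered on; only present
    # fields are required to meet their thresholds
    if iv.min_depth is not None and iv.min_depth < t.min_depth:
        return False
    if iv.quality is not None and iv.quality < t.min_site_quality:
        return False
    return True


def filter_calls(
    variants: Sequence[VariantRecord],
    callable_intervals: Sequence[CallableInterval],
    thresholds: FilterThresholds = FilterThresholds(),
    exclude: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> Tuple[List[VariantRecord], int]:
    """Apply depth/quality filters; count callable sites.

    ``exclude`` optionally maps contig -> intervals (e.g. repeat-masked
    regions) removed from both the variants and the callable intervals
    before any counting.

    Returns ``(kept_variants, n_callable_sites)`` where the callable-site
    count is the summed length of passing invariant intervals plus the
    number of distinct passing variant sites.
    """
    excl = {c: merge(ivs) for c, ivs in (exclude or {}).items()}

    kept = [
        v
        for v in variants
        if _variant_passes(v, thresholds)
        and not (v.contig in excl and contains_point(excl[v.contig], v.pos))
    ]

    passing_by_contig: Dict[str, List[Tuple[int, int]]] = {}
    for iv in callable_intervals:
        if _interval_passes(iv, thresholds):
            passing_by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))

    n_band_sites = 0
    for contig, ivs in passing_by_contig.items():
        merged = merge(ivs)
        if total_length(merged) < total_length(ivs):
            warnings.warn(
                f"overlapping callable intervals on {contig}; normalized by merging"
            )
        if contig in excl:
            merged = subtract(merged, excl[contig])
        n_band_sites += total_length(merged)

    n_variant_sites = len({(v.contig, v.pos) for v in kept})
    return kept, n_band_sites + n_variant_sites


@dataclass
class DiversityStats:
    n_het_snps: int
    n_hom_snps: int
    n_het_indels: int
    n_hom_indels: int
    n_callable_sites: int
    het_per_site: float
    het_pct: float


def heterozygosity(
    kept_variants: Sequence[VariantRecord], n_callable_sites: int
) -> DiversityStats:
    """Per-site SNP heterozygosity: het SNPs / callable sites."""
    if n_callable_sites <= 0:
        raise ValueError("n_callable_sites must be positive")
    counts = {("snp", "het"): 0, ("snp", "hom_alt"): 0,
              ("indel", "het"): 0, ("indel", "hom_alt"): 0}
    for v in kept_variants:
        counts[(v.kind, v.genotype)] += 1
    het = counts[("snp", "het")] / n_callable_sites
    return DiversityStats(
        n_het_snps=counts[("snp", "het")],
        n_hom_snps=counts[("snp", "hom_alt")],
        n_het_indels=counts[("indel", "het")],
        n_hom_indels=counts[("indel", "hom_alt")],
        n_callable_sites=n_callable_sites,
        het_per_site=het,
        het_pct=100.0 * het,
    )


@dataclass
class QVEstimate:
    n_error_sites: int
    n_callable_sites: int
    p_error: float
    qv: float
    cap: float = 60.0
    capped: bool = False


def phred(p_error: float, cap: float = 60.0) -> Tuple[float, bool]:
    """Phred scale with zero-error cap: (-10*log10(p), capped?)."""
    if p_error < 0:
        raise ValueError("error probability must be non-negative")
    if p_error == 0:
        return cap, True
    return min(-10.0 * math.log10(p_error), cap), False


def variant_qv(
    kept_variants: Sequence[VariantRecord],
    n_callable_sites: int,
    cap: float = 60.0,
) -> QVEstimate:
    """Consensus QV assuming every site with a non-reference variant is an error."""
    if n_callable_sites <= 0:
        raise ValueError("n_callable_sites must be positive")
    n_error_sites = len({(v.contig, v.pos) for v in kept_variants})
    p = n_error_sites / n_callable_sites
    qv, capped = phred(p, cap)
    return QVEstimate(
        n_error_sites=n_error_sites,
        n_callable_sites=n_callable_sites,
        p_error=p,
        qv=qv,
        cap=cap,
        capped=capped,
    )
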