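"""Assembly contiguity statistics: Nx/NGx curves, N50/NG50, L50 and auN.

The Nx statistic is the length of the contig at which the cumulative
length, with contigs sorted in descending size order, first reaches x%
of the assembly total (or of an independent genome-size estimate for the
NGx variant). auN is the area under the Nx curve,

    auN = sum_i L_i * (L_i / sum_j L_j),

which, unlike any single Nx point, decreases for every break introduced
into an assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

from .models import ContigSet

Lengths = Union[ContigSet, Sequence[int]]


def _sorted_lengths(contigs: Lengths) -> List[int]:
    if isinstance(contigs, ContigSet):
        # equal lengths ordered stably by name: deterministic, statistic-neutral
        pairs = sorted(((c.length, c.name) for c in contigs.contigs),
                       key=lambda p: (-p[0], p[1]))
        lengths = [l for l, _ in pairs]
    else:
        lengths = sorted((int(l) for l in contigs), reverse=True)
    if not lengths:
        raise ValueError("at least one contig is required")
    if min(lengths) < 1:
        raise ValueError("contig lengths must be >= 1")
    return lengths


@dataclass
class NxCurve:
    """Step function x (percent) -> Nx length, optionally the NG variant."""

    lengths: List[int]  # descending
    total_bp: int
    genome_size_bp: Optional[int] = None

    @property
    def is_ng(self) -> bool:
        return self.genome_size_bp is not None

    @property
    def target_bp(self) -> int:
        return self.genome_size_bp if self.genome_size_bp is not None else self.total_bp

    def value(self, x: float) -> Optional[int]:
        """Nx (or NGx) at x in (0, 100]; None where undefined (NGx beyond coverage)."""
        if not 0 < x <= 100:
            raise ValueError("x must be in (0, 100]")
        need = x / 100.0 * self.target_bp
        cum = 0
        for length in self.lengths:
            cum += length
            if cum >= need:
                return length
        return None  # genome_size exceeds assembled total at this x

    def values(self, xs: Sequence[float]) -> List[Optional[int]]:
        return [self.value(x) for x in xs]


def nx_curve(contigs: Lengths, genome_size: Optional[int] = None) -> NxCurve:
    lengths = _sorted_lengths(contigs)
    if genome_size is not None and genome_size <= 0:
        raise ValueError("genome_size must be positive")
    return NxCurve(lengths, sum(lengths), genome_size)


@dataclass
class ContiguityStats:
    total_bp: int
    n_contigs: int
    largest_bp: int
    N50_bp: int
    L50: int
    auN_bp: float
    fraction_bp_in_contigs_ge_10kb: float
    NG50_bp: Optional[int] = None
    genome_size_bp: Optional[int] = None


def auN(contigs: Lengths) -> float:
    """Area under the Nx curve: sum_i L_i^2 / sum_j L_j."""
    lengths = _sorted_lengths(contigs)
    total = sum(lengths)
    return sum(l * l for l in lengths) / total


def contiguity_stats(
    contigs: Lengths,
    genome_size: Optional[int] = None,
    small_contig_threshold: int = 10_000,
) -> ContiguityStats:
    """All contiguity summary statistics of one assembly."""
    lengths = _sorted_lengths(contigs)
    total = sum(lengths)
    need = total / 2.0
    cum = 0
    n50 = lengths[0]
    l50 = 1
    for i, length in enumerate(lengths):
        cum += length
        if cum >= need:
            n50, l50 = length, i + 1
            break
    ng50 = None
    if genome_size is not None:
        ng50 = nx_curve(lengths, genome_size).value(50)
    big_bp = sum(l for l in lengths if l >= small_contig_threshold)
    return ContiguityStats(
        total_bp=total,
        n_contigs=len(lengths),
        largest_bp=lengths[0],
        N50_bp=n50,
        L50=l50,
        auN_bp=sum(l * l for l in lengths) / total,
        fraction_bp_in_contigs_ge_10kb=big_bp / total,
        NG50_bp=ng50,
        genome_size_bp=genome_size,
    )
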