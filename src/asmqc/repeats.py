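"""Repeat-content summaries, read-set statistics and seeded downsampling."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._intervals import merge, total_length
from .models import ContigSet, RepeatRecord


@dataclass
class RepeatSummary:
    assembly_bp: int
    class_bp: Dict[str, int]
    class_fraction: Dict[str, float]
    repetitive_bp: int  # union across classes
    non_repetitive_bp: int
    repetitive_fraction: float


def repeat_summary(records: Sequence[RepeatRecord], contigs: ContigSet) -> RepeatSummary:
    """Masked bp and genome fraction per repeat class, plus the overall union.

    Within-class intervals are merged before summing; the total
    repetitive span is the union across all classes, so overlapping
    classes never double-count toward the repetitive/non-repetitive split.
    """
    known = {c.name: c.length for c in contigs.contigs}
    by_class: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    all_ivs: Dict[str, List[Tuple[int, int]]] = {}
    for r in records:
        if r.contig not in known:
            raise ValueError(f"repeat record on unknown contig {r.contig!r}")
        if r.end > known[r.contig]:
            raise ValueError(
                f"repeat interval [{r.start},{r.end}) exceeds contig "
                f"{r.contig!r} length {known[r.contig]}"
            )
        by_class.setdefault(r.repeat_class, {}).setdefault(r.contig, []).append(
            (r.start, r.end)
        )
        all_ivs.setdefault(r.contig, []).append((r.start, r.end))

    total = contigs.total_bp
    class_bp = {
        cls: sum(total_length(merge(ivs)) for ivs in per_contig.values())
        for cls, per_contig in by_class.items()
    }
    union_bp = sum(total_length(merge(ivs)) for ivs in all_ivs.values())
    return RepeatSummary(
        assembly_bp=total,
        class_bp=class_bp,
        class_fraction={cls: bp / total for cls, bp in class_bp.items()},
        repetitive_bp=union_bp,
        non_repetitive_bp=total - union_bp,
        repetitive_fraction=union_bp / total,
    )


@dataclass
class ReadSetStats:
    n_reads: int
    total_bp: int
    read_N50_bp: int
    fraction_bp_in_reads_longer_than: Dict[int, float]


def read_stats(
    lengths: Sequence[int],
    thresholds: Sequence[int] = (25_000, 50_000, 100_000),
    strict: bool = True,
) -> ReadSetStats:
    """Read-length summary: N50 and fraction of bases in long reads.

    ``strict`` counts bases in reads strictly longer than each threshold
    ("reads longer than L"); set False for >=.
    """
    if not len(lengths):
        raise ValueError("at least one read is required")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    total = int(arr.sum())
    cum = np.cumsum(arr)
    n50 = int(arr[np.searchsorted(cum, total / 2.0)])
    fractions = {}
    for t in thresholds:
        mask = arr > t if strict else arr >= t
        fractions[int(t)] = float(arr[mask].sum()) / total
    return ReadSetStats(
        n_reads=len(arr),
        total_bp=total,
        read_N50_bp=n50,
        fraction_bp_in_reads_longer_than=fractions,
    )


def downsample(
    read_ids: Sequence[str],
    lengths: Sequence[int],
    target_depth: float,
    genome_size: int,
    seed: int,
) -> Tuple[List[str], int, float]:
    """Select a random read subset reaching the target depth of coverage.

    Reads are taken in a seeded uniform random permutation until the
    cumulative length first reaches ``target_depth * genome_size``;
    inclusion probability is therefore independent of read length.

    Returns ``(selected_ids, achieved_bp, achieved_depth)``.
    """
    if len(read_ids) != len(lengths):
        raise ValueError("read_ids and lengths differ in length")
    lengths = np.asarray(lengths, dtype=np.int64)
    target_bp = target_depth * genome_size
    total = int(lengths.sum())
    if total < target_bp:
        raise ValueError(
            f"insufficient data: maximum achievable depth is "
            f"{total / genome_size:.2f}x"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(lengths))
    cum = np.cumsum(lengths[perm])
    k = int(np.searchsorted(cum, target_bp)) + 1
    chosen = perm[:k]
    achieved = int(cum[k - 1])
    return [read_ids[i] for i in chosen], achieved, achieved / genome_size
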