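"""Genome-size estimation from long-read throughput and marker-region depth.

Because raw long reads are too error-prone for k-mer based genome-size
estimation, size is estimated from sequencing depth over regions that
can be trusted to be single-copy: complete, non-duplicated orthologous
markers. With B total read bases, d the mean depth over those regions,
and f the fraction of the draft assembly removed as contaminant,

    genome_size = B * (1 - f) / d.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from ._intervals import merge
from .models import DepthTrack, MarkerTable


def mean_depth_over_markers(
    track: DepthTrack,
    markers: MarkerTable,
    zero_fill: bool = True,
    statistic: str = "mean",
) -> Tuple[float, int]:
    """Depth summarized over complete single-copy marker intervals.

    Overlapping marker intervals are merged first so each position counts
    once. With ``zero_fill`` (default), positions inside marker intervals
    that are absent from the track count as depth 0; otherwise they are
    excluded. ``statistic`` may be ``"mean"`` (the estimator's definition)
    or ``"median"``.

    Returns ``(depth_statistic, n_positions_used)``.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    by_contig = {}
    for r in markers.by_status("complete_single"):
        if r.start is None or r.end is None:
            continue
        by_contig.setdefault(r.contig, []).append((r.start, r.end))
    if not by_contig:
        raise ValueError("no complete single-copy markers with coordinates")

    total_depth = 0
    n_positions = 0
    medians = [] if statistic == "median" else None
    for contig, ivs in by_contig.items():
        for s, e in merge(ivs):
            pos, depth = track.window(contig, s, e)
            total_depth += int(depth.sum())
            n_here = (e - s) if zero_fill else len(pos)
            n_positions += n_here
            if medians is not None and n_here:
                d = depth.astype(float)
                if zero_fill and len(pos) < e - s:
                    d = np.concatenate([d, np.zeros((e - s) - len(pos))])
                medians.append(d)
    if n_positions == 0:
        raise ValueError("no usable positions inside marker intervals")
    if statistic == "median":
        value = float(np.median(np.concatenate(medians)))
    else:
        value = total_depth / n_positions
    if value == 0:
        raise ValueError("depth over marker regions is zero")
    return value, n_positions


@dataclass
class GenomeSizeEstimate:
    total_read_bases: int
    mean_depth: float
    removed_fraction: float
    genome_size_bp: float
    n_positions_used: int = 0


def estimate_genome_size(
    total_read_bases: int,
    mean_depth: float,
    removed_fraction: float = 0.0,
    n_positions_used: int = 0,
) -> GenomeSizeEstimate:
    """genome_size = total_read_bases * (1 - removed_fraction) / mean_depth."""
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= removed_fraction < 1:
        raise ValueError("removed_fraction must be in [0, 1)")
    size = total_read_bases * (1.0 - removed_fraction) / mean_depth
    return GenomeSizeEstimate(
        total_read_bases=total_read_bases,
        mean_depth=mean_depth,
        removed_fraction=removed_fraction,
        genome_size_bp=size,
        n_positions_used=n_positions_used,
    )
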