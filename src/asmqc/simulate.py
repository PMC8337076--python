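"""Synthetic-data generators with retained ground truth.

Every analysis in the toolkit can be exercised on data generated here:
multi-chromosome marker genomes with conserved per-arm content and
intra-arm rearrangement, fragmentation into contigs, variant calls with
known heterozygosity over callable-site bands, reference-alignment
differences at known per-element error rates, long-read length
distributions with a target read N50, depth tracks, and repeat
annotations with known class proportions.

Each generator is a pure function of its arguments plus one integer
seed. Internally, per-component random streams are derived from the
master seed with ``numpy.random.SeedSequence(seed).spawn``, so reruns
are bitwise identical and the streams of different components never
interact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import (
    CallableInterval,
    DepthTrack,
    DiffRecord,
    MarkerRecord,
    MarkerTable,
    RepeatRecord,
    VariantRecord,
)

MARKER_SPACING_BP = 10_000  # synthetic coordinates: one marker per 10 kb slot
MARKER_LEN_BP = 5_000


@dataclass
class SimTruth:
    """Ground truth recorded alongside each generated dataset."""

    arm_of_marker: Optional[Dict[str, int]] = None
    genome_size_bp: Optional[int] = None
    heterozygosity: Optional[float] = None
    hom_rate: Optional[float] = None
    n_callable_sites: Optional[int] = None
    error_rates: Optional[Dict[str, Dict[str, float]]] = None
    class_bp: Optional[Dict[str, int]] = None
    repeat_proportions: Optional[Dict[str, float]] = None
    read_n50_bp: Optional[int] = None
    mean_depth: Optional[float] = None
    total_read_bases: Optional[int] = None
    extras: Dict = field(default_factory=dict)


def _streams(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# marker genomes


@dataclass(frozen=True)
class MarkerGenomeSpec:
    """Conditions for the multi-species marker-genome simulation.

    Defaults mirror a drosophilid-like regime: six chromosome arms whose
    marker content is conserved while within-arm order is shuffled by
    inversions, and assemblies fragmented into multi-marker contigs.
    """

    n_species: int = 20
    n_arms: int = 6
    markers_per_arm: int = 300
    inversions_per_species: int = 5
    translocation_rate: float = 0.0
    contig_markers_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.markers_per_arm < 2:
            raise ValueError("markers_per_arm must be >= 2")
        if self.n_species < 1 or self.n_arms < 1:
            raise ValueError("n_species and n_arms must be >= 1")
        if not 0 <= self.translocation_rate <= 1:
            raise ValueError("translocation_rate must be a probability")
        if self.contig_markers_mean < 1:
            raise ValueError("contig_markers_mean must be >= 1")


def marker_id(arm: int, index: int) -> str:
    return f"m{arm:02d}_{index:04d}"


def sim_marker_assemblies(
    spec: MarkerGenomeSpec,
) -> Tuple[List[MarkerTable], SimTruth]:
    """Simulate per-species single-copy marker tables.

    Ancestral marker order per arm; each species receives
    ``inversions_per_species`` random block reversals within randomly
    chosen arms and, with probability ``translocation_rate``, one
    cross-arm marker move; each arm is then fragmented into contigs by a
    geometric process with mean ``contig_markers_mean`` markers. Contigs
    never span arms when ``translocation_rate`` is 0. All markers are
    emitted as complete single-copy with synthetic coordinates.
    """
    ancestral = [
        [marker_id(a, i) for i in range(spec.markers_per_arm)]
        for a in range(spec.n_arms)
    ]
    arm_of = {m: a for a, arm in enumerate(ancestral) for m in arm}
    streams = _streams(spec.seed, spec.n_species)

    tables: List[MarkerTable] = []
    for s in range(spec.n_species):
        rng = streams[s]
        arms = [list(arm) for arm in ancestral]
        for _ in range(spec.inversions_per_species):
            a = int(rng.integers(spec.n_arms))
            arm = arms[a]
            if len(arm) < 2:
                continue
            i = int(rng.integers(0, len(arm) - 1))
            j = int(rng.integers(i + 1, len(arm)))
            arm[i : j + 1] = arm[i : j + 1][::-1]
        if rng.random() < spec.translocation_rate and spec.n_arms > 1:
            src = int(rng.integers(spec.n_arms))
            while len(arms[src]) < 3:
                src = int(rng.integers(spec.n_arms))
            dst = int(rng.integers(spec.n_arms))
            while dst == src:
                dst = int(rng.integers(spec.n_arms))
            m = arms[src].pop(int(rng.integers(len(arms[src]))))
            arms[dst].insert(int(rng.integers(len(arms[dst]) + 1)), m)

        records: List[MarkerRecord] = []
        ctg = 0
        p_break = 1.0 / spec.contig_markers_mean
        for arm in arms:
            k = 0
            while k < len(arm):
                size = int(rng.geometric(p_break))
                chunk = arm[k : k + size]
                k += size
                name = f"sp{s:03d}_ctg{ctg:05d}"
                ctg += 1
                for t, m in enumerate(chunk):
                    start = t * MARKER_SPACING_BP + 1000
                    records.append(
                        MarkerRecord(
                            m,
                            "complete_single",
                            name,
                            start,
                            start + MARKER_LEN_BP,
                            "+" if rng.random() < 0.5 else "-",
                        )
                    )
        tables.append(MarkerTable(f"species_{s:03d}", records))
    return tables, SimTruth(arm_of_marker=arm_of, extras={"spec": spec})


# ---------------------------------------------------------------------------
# variant calls


def sim_variant_calls(
    n_callable: int,
    het_rate: float,
    hom_rate: float,
    seed: int,
    contamination: float = 0.0,
    contig: str = "sim1",
) -> Tuple[List[VariantRecord], List[CallableInterval], SimTruth]:
    """Simulate filtered variant calls over ``n_callable`` callable sites.

    Each site is independently a heterozygous SNP with probability
    ``het_rate`` or a homozygous non-reference SNP with probability
    ``hom_rate``; all emitted records carry DP=30, QUAL=50, GQ=50 and so
    pass the default filters. A ``contamination`` fraction of sites
    instead receives a sub-threshold record (DP=5, QUAL=10) that default
    filtering must remove. Invariant runs are emitted as callable
    intervals with passing band metrics.
    """
    if het_rate + hom_rate + contamination > 1:
        raise ValueError("rates sum to more than 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n_callable)
    het_pos = np.flatnonzero(u < het_rate)
    hom_pos = np.flatnonzero((u >= het_rate) & (u < het_rate + hom_rate))
    sub_pos = np.flatnonzero(
        (u >= het_rate + hom_rate) & (u < het_rate + hom_rate + contamination)
    )

    variants: List[VariantRecord] = []
    for pos in het_pos:
        variants.append(VariantRecord(contig, int(pos), "snp", "het", 50.0, 30, 50.0))
    for pos in hom_pos:
        variants.append(
            VariantRecord(contig, int(pos), "snp", "hom_alt", 50.0, 30, 50.0)
        )
    for pos in sub_pos:
        variants.append(VariantRecord(contig, int(pos), "snp", "het", 10.0, 5, 10.0))
    variants.sort(key=lambda v: v.pos)

    special = np.sort(np.concatenate([het_pos, hom_pos, sub_pos]))
    intervals: List[CallableInterval] = []
    prev = -1
    for p in special.tolist() + [n_callable]:
        if p > prev + 1:
            intervals.append(
                CallableInterval(contig, prev + 1, p, min_depth=30, quality=50.0)
            )
        prev = p

    truth = SimTruth(
        heterozygosity=het_rate,
        hom_rate=hom_rate,
        n_callable_sites=n_callable - len(sub_pos),
        extras={
            "n_het": len(het_pos),
            "n_hom": len(hom_pos),
            "n_subthreshold": len(sub_pos),
        },
    )
    return variants, intervals, truth


# ---------------------------------------------------------------------------
# alignment differences


def sim_alignment_diffs(
    aligned_bp: Dict[str, int],
    error_rates: Dict[str, Dict[str, float]],
    window: int = 100_000,
    seed: int = 0,
    block_bp: int = 10_000,
    contig: str = "simref",
) -> Tuple[List[DiffRecord], Dict[str, List[Tuple[str, int, int]]], SimTruth]:
    """Simulate reference-alignment differences at known per-class rates.

    ``aligned_bp`` maps element class -> total bp of that class;
    ``error_rates`` maps class -> {"snv": r, "ins": r, "del": r} per-bp
    rates. The reference is laid out as interleaved ``block_bp`` blocks
    cycling through the classes (so windows mix classes); differences
    are Poisson-placed within each class and never cross a block
    boundary. Indel lengths follow a mixture: 90% uniform on 1-3 bp,
    10% a geometric tail.

    Returns ``(diffs, class_beds, truth)`` where ``class_beds`` maps
    class -> list of (contig, start, end).
    """
    rng = np.random.default_rng(seed)
    remaining = {cls: int(bp) for cls, bp in aligned_bp.items()}
    beds: Dict[str, List[Tuple[str, int, int]]] = {cls: [] for cls in aligned_bp}
    cursor = 0
    while any(v > 0 for v in remaining.values()):
        for cls in aligned_bp:
            if remaining[cls] <= 0:
                continue
            b = min(block_bp, remaining[cls])
            beds[cls].append((contig, cursor, cursor + b))
            cursor += b
            remaining[cls] -= b

    def _indel_len() -> int:
        if rng.random() < 0.9:
            return int(rng.integers(1, 4))
        return 3 + int(rng.geometric(0.2))

    diffs: List[DiffRecord] = []
    realized_bp = {cls: sum(e - s for _, s, e in ivs) for cls, ivs in beds.items()}
    for cls, rates in error_rates.items():
        ivs = beds.get(cls, [])
        bp = realized_bp.get(cls, 0)
        if bp == 0:
            continue
        offsets = np.cumsum([0] + [e - s for _, s, e in ivs])
        for kind, rate in rates.items():
            n = int(rng.poisson(rate * bp))
            offs = rng.integers(0, bp, size=n)
            for off in offs.tolist():
                i = int(np.searchsorted(offsets, off, side="right")) - 1
                _, s, e = ivs[i]
                pos = s + (off - int(offsets[i]))
                if kind == "snv":
                    diffs.append(DiffRecord(contig, pos, "snv", 1, "a", "c"))
                elif kind == "ins":
                    diffs.append(DiffRecord(contig, pos, "ins", _indel_len()))
                else:
                    length = min(_indel_len(), e - pos)  # stay inside the block
                    diffs.append(DiffRecord(contig, pos, "del", length))
    # a real alignment cannot carry overlapping differences: keep the first
    # event at each reference locus and drop any event inside a prior span
    diffs.sort(key=lambda d: (d.contig, d.ref_start))
    kept: List[DiffRecord] = []
    next_free = 0
    for d in diffs:
        if d.ref_start < next_free:
            continue
        kept.append(d)
        next_free = d.ref_start + max(1, d.ref_span)
    diffs = kept
    truth = SimTruth(
        error_rates={c: dict(r) for c, r in error_rates.items()},
        class_bp=realized_bp,
        extras={"contig_length": cursor, "window": window},
    )
    return diffs, beds, truth


# ---------------------------------------------------------------------------
# reads and depth


def sim_reads_and_depth(
    genome_size: int,
    mean_depth: float,
    length_n50_target: int = 25_000,
    seed: int = 0,
    depth_mode: str = "poisson",
    n_track_positions: Optional[int] = None,
    sigma: float = 0.6,
    contig: str = "simdepth",
) -> Tuple[np.ndarray, DepthTrack, SimTruth]:
    """Simulate a long-read length set and a depth track.

    Read lengths are lognormal (shape ``sigma``) rescaled so the realized
    read N50 matches ``length_n50_target``; reads are emitted until total
    bases first reach ``genome_size * mean_depth``. The depth track
    covers ``n_track_positions`` positions (default: min(genome size,
    200000)) with per-position depth drawn Poisson(``mean_depth``), or
    exactly ``mean_depth`` everywhere in ``depth_mode="uniform"``.
    """
    if depth_mode not in ("poisson", "uniform"):
        raise ValueError("depth_mode must be 'poisson' or 'uniform'")
    rng_reads, rng_depth = _streams(seed, 2)
    target_total = int(genome_size * mean_depth)

    # draw a batch, rescale so realized N50 hits the target exactly
    mean_len = length_n50_target / 1.8  # lognormal N50 sits above the mean
    n0 = max(500, int(target_total / mean_len) + 200)
    raw = rng_reads.lognormal(mean=np.log(mean_len) - sigma**2 / 2, sigma=sigma, size=n0)
    order = np.sort(raw)[::-1]
    cum = np.cumsum(order)
    realized_n50 = order[np.searchsorted(cum, cum[-1] / 2.0)]
    lengths = np.maximum(1, np.round(raw * length_n50_target / realized_n50)).astype(
        np.int64
    )
    cum = np.cumsum(lengths)
    while cum[-1] < target_total:
        extra = np.maximum(
            1,
            np.round(
                rng_reads.lognormal(np.log(mean_len) - sigma**2 / 2, sigma, n0)
                * length_n50_target
                / realized_n50
            ),
        ).astype(np.int64)
        lengths = np.concatenate([lengths, extra])
        cum = np.cumsum(lengths)
    k = int(np.searchsorted(cum, target_total)) + 1
    lengths = lengths[:k]
    total = int(lengths.sum())

    n_pos = (
        int(n_track_positions)
        if n_track_positions is not None
        else min(int(genome_size), 200_000)
    )
    pos = np.arange(n_pos, dtype=np.int64)
    if depth_mode == "uniform":
        depth = np.full(n_pos, int(round(mean_depth)), dtype=np.int64)
    else:
        depth = rng_depth.poisson(mean_depth, n_pos).astype(np.int64)
    track = DepthTrack({contig: (pos, depth)})

    srt = np.sort(lengths)[::-1]
    cum = np.cumsum(srt)
    truth = SimTruth(
        genome_size_bp=int(genome_size),
        mean_depth=float(mean_depth),
        total_read_bases=total,
        read_n50_bp=int(srt[np.searchsorted(cum, total / 2.0)]),
        extras={"n_reads": len(lengths), "n_track_positions": n_pos},
    )
    return lengths, track, truth


def markers_spanning_track(track: DepthTrack, assembly_id: str = "sim") -> MarkerTable:
    """One complete single-copy marker covering each contig of a depth track
    (convenience for feeding a simulated track to the genome-size estimator)."""
    records = []
    for i, contig in enumerate(track.contigs):
        pos = track.positions(contig)
        records.append(
            MarkerRecord(
                f"span_{i:04d}", "complete_single", contig, 0, int(pos[-1]) + 1, "+"
            )
        )
    return MarkerTable(assembly_id, records)


# ---------------------------------------------------------------------------
# repeat annotation


def sim_repeat_annotation(
    contig_lengths: Dict[str, int],
    class_proportions: Dict[str, float],
    seed: int = 0,
) -> List[RepeatRecord]:
    """Simulate non-overlapping repeat intervals at stated class proportions.

    Per contig, each class receives a bp quota of proportion x length
    (exact to rounding, hence well within 1%), split into randomly sized
    pieces that are shuffled and laid out left to right with random gaps
    consuming the non-repetitive remainder.
    """
    if sum(class_proportions.values()) > 1:
        raise ValueError("class proportions sum to more than 1")
    rng = np.random.default_rng(seed)
    records: List[RepeatRecord] = []
    for contig, length in contig_lengths.items():
        pieces: List[Tuple[str, int]] = []
        for cls, prop in class_proportions.items():
            quota = int(round(prop * length))
            lo = max(1, length // 500)
            hi = max(lo + 1, length // 100)
            while quota > 0:
                piece = min(quota, int(rng.integers(lo, hi)))
                pieces.append((cls, piece))
                quota -= piece
        rng.shuffle(pieces)
        free = length - sum(p for _, p in pieces)
        if free < 0:
            raise ValueError(f"contig {contig}: quotas exceed contig length")
        gaps = rng.multinomial(free, [1.0 / (len(pieces) + 1)] * (len(pieces) + 1))
        cursor = 0
        for i, (cls, piece) in enumerate(pieces):
            cursor += int(gaps[i])
            records.append(
                RepeatRecord(contig, cursor, cursor + piece, f"{cls}_el{i}", cls)
            )
            cursor += piece
    return records
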