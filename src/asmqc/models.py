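"""Core domain containers shared across the toolkit.

All coordinates held by these types are 0-based half-open. Conversion
from 1-based inclusive file conventions (VCF, BUSCO full tables,
RepeatMasker ``.out``) happens in :mod:`asmqc.io` at the file boundary
and nowhere else, so downstream arithmetic never sees mixed conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

MARKER_STATUSES = ("complete_single", "duplicated", "fragmented", "missing")


@dataclass(frozen=True)
class Contig:
    name: str
    length: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.name!r}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class ContigSet:
    """Named contig lengths (optionally sequences) of one assembly."""

    assembly_id: str
    contigs: List[Contig]

    def __post_init__(self) -> None:
        seen = set()
        for c in self.contigs:
            if c.name in seen:
                raise ValueError(f"duplicate contig name: {c.name}")
            seen.add(c.name)

    @property
    def lengths(self) -> List[int]:
        return [c.length for c in self.contigs]

    @property
    def total_bp(self) -> int:
        return sum(c.length for c in self.contigs)

    def length_of(self, name: str) -> int:
        for c in self.contigs:
            if c.name == name:
                return c.length
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass(frozen=True)
class MarkerRecord:
    """One placement of a single-copy orthologous marker (BUSCO)."""

    marker_id: str
    status: str
    contig: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in MARKER_STATUSES:
            raise ValueError(f"unknown marker status: {self.status!r}")
        if self.status == "missing" and self.contig is not None:
            raise ValueError(f"missing marker {self.marker_id} has a placement")
        if self.status != "missing" and self.contig is None:
            raise ValueError(f"placed marker {self.marker_id} lacks a contig")
        if self.start is not None and self.end is not None and self.end <= self.start:
            raise ValueError(
                f"marker {self.marker_id}: end {self.end} <= start {self.start}"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class MarkerTable:
    assembly_id: str
    records: List[MarkerRecord]

    def by_status(self, status: str) -> List[MarkerRecord]:
        return [r for r in self.records if r.status == status]

    def marker_ids(self) -> set:
        return {r.marker_id for r in self.records}


@dataclass(frozen=True)
class VariantRecord:
    """One filtered-call candidate site with a non-reference genotype."""

    contig: str
    pos: int  # 0-based
    kind: str  # "snp" | "indel"
    genotype: str  # "het" | "hom_alt"
    site_quality: float
    depth: Optional[int] = None
    genotype_quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "indel"):
            raise ValueError(f"bad variant kind {self.kind!r}")
        if self.genotype not in ("het", "hom_alt"):
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.site_quality < 0:
            raise ValueError("site_quality must be non-negative")


@dataclass(frozen=True)
class CallableInterval:
    """A run of invariant sites at which a variant could have been called."""

    contig: str
    start: int
    end: int
    min_depth: Optional[int] = None
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty callable interval [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DiffRecord:
    """One difference between a query assembly and a reference.

    ``snv`` records are always unit length (substitution runs are split);
    insertions consume zero reference bp and are anchored at ``ref_start``;
    deletions consume ``length`` reference bp.
    """

    contig: str
    ref_start: int
    kind: str  # "snv" | "ins" | "del"
    length: int
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("snv", "ins", "del"):
            raise ValueError(f"bad diff kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("diff length must be positive")
        if self.kind == "snv" and self.length != 1:
            raise ValueError("snv records must have length 1")

    @property
    def ref_span(self) -> int:
        """Reference bp consumed by this record."""
        if self.kind == "ins":
            return 0
        if self.kind == "snv":
            return 1
        return self.length


@dataclass(frozen=True)
class RepeatRecord:
    contig: str
    start: int
    end: int
    repeat_name: str
    repeat_class: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty repeat interval [{self.start},{self.end})")


class DepthTrack:
    """Per-contig sorted (position, depth) pairs from a depth profile.

    Positions are 0-based and strictly increasing within each contig;
    positions absent from the track are interpreted as depth 0 by callers
    that enable zero-fill.
    """

    def __init__(self, data: Dict[str, Tuple[np.ndarray, np.ndarray]]):
        self._data = {}
        for contig, (pos, depth) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            depth = np.asarray(depth, dtype=np.int64)
            if pos.shape != depth.shape:
                raise ValueError("position/depth arrays differ in length")
            order = np.argsort(pos, kind="stable")
            pos, depth = pos[order], depth[order]
            if len(pos) > 1 and np.any(np.diff(pos) == 0):
                raise ValueError(f"duplicate positions on contig {contig!r}")
            if np.any(depth < 0):
                raise ValueError("negative depth")
            self._data[contig] = (pos, depth)

    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, int, int]]) -> "DepthTrack":
        by_contig: Dict[str, List[Tuple[int, int]]] = {}
        for contig, pos, depth in records:
            by_contig.setdefault(contig, []).append((pos, depth))
        data = {}
        for contig, pairs in by_contig.items():
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            depth = np.array([d for _, d in pairs], dtype=np.int64)
            data[contig] = (pos, depth)
        return cls(data)

    @property
    def contigs(self) -> List[str]:
        return list(self._data)

    def __len__(self) -> int:
        return sum(len(p) for p, _ in self._data.values())

    def positions(self, contig: str) -> np.ndarray:
        return self._data[contig][0]

    def depths(self, contig: str) -> np.ndarray:
        return self._data[contig][1]

    def window(self, contig: str, start: int, end: int) -> Tuple[np.ndarray, np.ndarray]:
        """Recorded (positions, depths) with start <= position < end."""
        if contig not in self._data:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        pos, depth = self._data[contig]
        lo, hi = np.searchsorted(pos, [start, end])
        return pos[lo:hi], depth[lo:hi]

    def iter_records(self):
        for contig in self._data:
            pos, depth = self._data[contig]
            for p, d in zip(pos.tolist(), depth.tolist()):
                yield contig, p, d
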