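"""Readers and writers for every external format the pipeline touches.

All conversions between file conventions and the internal 0-based
half-open convention live here:

========================  =====================  =======================
format                    file convention        reader
========================  =====================  =======================
FASTA                     n/a (sequences)        :func:`read_fasta_lengths`
BUSCO v4 full table TSV   1-based inclusive      :func:`read_busco_table`
VCF 4.x (+ banded gVCF)   1-based, END 1-based   :func:`read_vcf_with_bands`
PAF + cs tag              0-based half-open      :func:`read_paf_cs`
RepeatMasker .out         1-based inclusive      :func:`read_repeatmasker_out`
depth TSV                 1-based positions      :func:`read_depth_tsv`
BED                       0-based half-open      :func:`read_bed`
========================  =====================  =======================
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .models import (
    CallableInterval,
    Contig,
    ContigSet,
    DepthTrack,
    DiffRecord,
    MarkerRecord,
    MarkerTable,
    RepeatRecord,
    VariantRecord,
)

IUPAC = set("ACGTURYSWKMBDHVNacgturyswkmbdhvn-")

_BUSCO_STATUS = {
    "Complete": "complete_single",
    "Duplicated": "duplicated",
    "Fragmented": "fragmented",
    "Missing": "missing",
}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_lengths(path: str, keep_sequences: bool = False) -> ContigSet:
    """Read a FASTA file into a :class:`ContigSet`.

    The contig name is the header token before the first whitespace.
    Non-IUPAC characters are counted (toward the length) with a warning.
    """
    contigs: List[Contig] = []
    name: Optional[str] = None
    chunks: List[str] = []
    n_bad = 0
    seen = set()

    def _flush():
        nonlocal n_bad
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ValueError(f"contig {name!r}: empty sequence")
        bad = sum(1 for ch in seq if ch not in IUPAC)
        n_bad += bad
        contigs.append(
            Contig(name, len(seq), sequence=seq if keep_sequences else None)
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ValueError("FASTA header with empty name")
                if name in seen:
                    raise ValueError(f"duplicate contig name: {name}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line.strip())
        _flush()
    if not contigs:
        raise ValueError(f"empty FASTA file: {path}")
    if n_bad:
        warnings.warn(f"{path}: {n_bad} non-IUPAC characters in sequences")
    import os

    return ContigSet(os.path.basename(path), contigs)


def write_fasta(contigs: ContigSet, path: str, line_width: int = 60) -> None:
    """Write a ContigSet; contigs without sequence are written as runs of N."""
    with open(path, "w") as fh:
        for c in contigs.contigs:
            fh.write(f">{c.name}\n")
            seq = c.sequence if c.sequence is not None else "N" * c.length
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BUSCO full table


def read_busco_table(path: str, assembly_id: Optional[str] = None) -> MarkerTable:
    """Parse a BUSCO v4 ``full_table.tsv``.

    File coordinates are 1-based inclusive and converted here; duplicated
    markers contribute one record per placement.
    """
    records: List[MarkerRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            marker_id, status_token = fields[0], fields[1]
            if status_token not in _BUSCO_STATUS:
                raise ValueError(
                    f"{path}:{lineno}: unknown status token {status_token!r}"
                )
            status = _BUSCO_STATUS[status_token]
            if status == "missing":
                records.append(MarkerRecord(marker_id, "missing"))
                continue
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: placed marker lacks contig/coordinates"
                )
            contig = fields[2]
            start1, end1 = int(fields[3]), int(fields[4])
            start, end = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
            if end <= start:
                raise ValueError(
                    f"{path}:{lineno}: non-positive interval after conversion "
                    f"({start1}..{end1})"
                )
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            records.append(MarkerRecord(marker_id, status, contig, start, end, strand))
    if assembly_id is None:
        import os

        assembly_id = os.path.basename(path)
    return MarkerTable(assembly_id, records)


def write_busco_table(table: MarkerTable, path: str) -> None:
    status_out = {v: k for k, v in _BUSCO_STATUS.items()}
    with open(path, "w") as fh:
        fh.write("# Busco id\tStatus\tSequence\tGene Start\tGene End\tStrand\n")
        for r in table.records:
            if r.status == "missing":
                fh.write(f"{r.marker_id}\tMissing\n")
            else:
                fh.write(
                    f"{r.marker_id}\t{status_out[r.status]}\t{r.contig}\t"
                    f"{r.start + 1}\t{r.end}\t{r.strand or '+'}\n"
                )


# ---------------------------------------------------------------------------
# VCF (with banded gVCF records)


def _fmt_scalar(variant, key: str) -> Optional[float]:
    try:
        arr = variant.format(key)
    except KeyError:
        return None
    if arr is None:
        return None
    v = arr[0]
    try:
        v = v[0]
    except (TypeError, IndexError):
        pass
    v = float(v)
    if v < 0:  # cyvcf2 encodes missing integers as large negatives
        return None
    return v


def read_vcf_with_bands(
    path: str,
) -> Tuple[List[VariantRecord], List[CallableInterval]]:
    """Read a VCF/gVCF into variant records plus callable intervals.

    Banded records (INFO END and/or only symbolic ALT) become
    :class:`CallableInterval` spans; non-banded reference-call rows become
    length-1 intervals; rows with a called non-reference genotype become
    :class:`VariantRecord`. DP/GQ are taken from the first sample.
    """
    from cyvcf2 import VCF

    variants: List[VariantRecord] = []
    intervals: List[CallableInterval] = []
    vcf = VCF(path)
    try:
        for v in vcf:
            real_alts = [a for a in (v.ALT or []) if not a.startswith("<")]
            end_info = v.INFO.get("END")
            depth = _fmt_scalar(v, "DP")
            min_dp = _fmt_scalar(v, "MIN_DP")
            gq = _fmt_scalar(v, "GQ")
            qual = float(v.QUAL) if v.QUAL is not None else None

            if v.genotypes:
                alleles = [a for a in v.genotypes[0][:-1] if a >= 0]
            else:
                alleles = []
            non_ref = [a for a in alleles if a > 0]

            if not real_alts or not non_ref:
                # reference call: banded or single-site
                if end_info is not None:
                    end1 = int(end_info)
                    if end1 < v.POS:
                        raise ValueError(
                            f"{path}: END={end1} < POS={v.POS} at {v.CHROM}"
                        )
                    start, end = v.POS - 1, end1
                else:
                    start, end = v.POS - 1, v.POS
                md = min_dp if min_dp is not None else depth
                q = qual if qual is not None else gq
                intervals.append(
                    CallableInterval(
                        v.CHROM,
                        start,
                        end,
                        min_depth=int(md) if md is not None else None,
                        quality=q,
                    )
                )
                continue

            kind = (
                "indel"
                if any(len(a) != len(v.REF) for a in real_alts)
                else "snp"
            )
            genotype = "het" if len(set(alleles)) > 1 else "hom_alt"
            variants.append(
                VariantRecord(
                    v.CHROM,
                    v.POS - 1,
                    kind,
                    genotype,
                    site_quality=qual if qual is not None else 0.0,
                    depth=int(depth) if depth is not None else None,
                    genotype_quality=gq,
                )
            )
    finally:
        vcf.close()
    return variants, intervals


def write_vcf(
    variants: Sequence[VariantRecord],
    intervals: Sequence[CallableInterval],
    contig_lengths: Dict[str, int],
    path: str,
    sample: str = "sample1",
) -> None:
    """Write variants and banded invariant intervals as a single gVCF-style file."""
    rows = []
    for var in variants:
        ref, alt = ("A", "T") if var.kind == "snp" else ("AT", "A")
        gt = "0/1" if var.genotype == "het" else "1/1"
        dp = str(var.depth) if var.depth is not None else "."
        gq = (
            str(int(var.genotype_quality))
            if var.genotype_quality is not None
            else "."
        )
        rows.append(
            (
                var.contig,
                var.pos + 1,
                f"{var.contig}\t{var.pos + 1}\t.\t{ref}\t{alt}\t"
                f"{var.site_quality:g}\tPASS\t.\tGT:DP:GQ\t{gt}:{dp}:{gq}",
            )
        )
    for iv in intervals:
        md = str(iv.min_depth) if iv.min_depth is not None else "."
        qual = f"{iv.quality:g}" if iv.quality is not None else "."
        rows.append(
            (
                iv.contig,
                iv.start + 1,
                f"{iv.contig}\t{iv.start + 1}\t.\tA\t<NON_REF>\t{qual}\tPASS\t"
                f"END={iv.end}\tGT:DP:MIN_DP\t0/0:{md}:{md}",
            )
        )
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="Band end">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=MIN_DP,Number=1,Type=Integer,Description="Min depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GQ">\n')
        fh.write('##ALT=<ID=NON_REF,Description="Non-ref placeholder">\n')
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for _, _, row in rows:
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# PAF cs-tag differences

_CS_TOKEN = re.compile(r"(:\d+|=[A-Za-z]+|\*[A-Za-z]{2}|\+[A-Za-z]+|-[A-Za-z]+)")


def _cs_tokens(cs: str):
    pos = 0
    while pos < len(cs):
        m = _CS_TOKEN.match(cs, pos)
        if m is None:
            raise ValueError(f"malformed cs string at byte offset {pos}: {cs[pos:pos+10]!r}")
        yield m.group(0)
        pos = m.end()


def parse_cs_diffs(contig: str, ref_start: int, cs: str) -> List[DiffRecord]:
    """Extract difference records from a minimap2 ``cs`` string.

    Short form (``:N`` match, ``*xy`` substitution, ``+seq`` insertion,
    ``-seq`` deletion) and long-form matches (``=SEQ``) are accepted.
    Matches, substitutions and deletions advance the reference cursor;
    insertions are anchored at the current reference coordinate.
    """
    diffs: List[DiffRecord] = []
    cursor = ref_start
    for tok in _cs_tokens(cs):
        op = tok[0]
        if op == ":":
            cursor += int(tok[1:])
        elif op == "=":
            cursor += len(tok) - 1
        elif op == "*":
            diffs.append(
                DiffRecord(contig, cursor, "snv", 1, ref_allele=tok[1], alt_allele=tok[2])
            )
            cursor += 1
        elif op == "+":
            diffs.append(
                DiffRecord(contig, cursor, "ins", len(tok) - 1, alt_allele=tok[1:])
            )
        elif op == "-":
            diffs.append(
                DiffRecord(contig, cursor, "del", len(tok) - 1, ref_allele=tok[1:])
            )
            cursor += len(tok) - 1
    diffs.sort(key=lambda d: d.ref_start)
    return diffs


def cs_reference_span(cs: str) -> int:
    """Reference bp consumed by a cs string (matches + substitutions + deletions)."""
    span = 0
    for tok in _cs_tokens(cs):
        op = tok[0]
        if op == ":":
            span += int(tok[1:])
        elif op == "=":
            span += len(tok) - 1
        elif op == "*":
            span += 1
        elif op == "-":
            span += len(tok) - 1
    return span


def diffs_to_cs(diffs: Sequence[DiffRecord], ref_start: int, ref_end: int) -> str:
    """Inverse of :func:`parse_cs_diffs` over reference span [ref_start, ref_end)."""
    parts: List[str] = []
    cursor = ref_start
    for d in sorted(diffs, key=lambda d: d.ref_start):
        if d.ref_start < cursor:
            raise ValueError("overlapping diff records cannot be encoded")
        if d.ref_start > cursor:
            parts.append(f":{d.ref_start - cursor}")
            cursor = d.ref_start
        if d.kind == "snv":
            parts.append(f"*{(d.ref_allele or 'a')}{(d.alt_allele or 'c')}")
            cursor += 1
        elif d.kind == "ins":
            parts.append("+" + (d.alt_allele or "a" * d.length))
        else:
            parts.append("-" + (d.ref_allele or "a" * d.length))
            cursor += d.length
    if cursor < ref_end:
        parts.append(f":{ref_end - cursor}")
    return "".join(parts)


def read_paf_cs(
    path: str,
) -> Tuple[List[DiffRecord], Dict[str, List[Tuple[int, int]]], Dict[str, int]]:
    """Read PAF alignments carrying cs tags, in target (reference) coordinates.

    Returns ``(diffs, aligned_intervals_by_contig, contig_lengths)``.
    """
    diffs: List[DiffRecord] = []
    aligned: Dict[str, List[Tuple[int, int]]] = {}
    lengths: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: expected >=12 PAF columns")
            target, tlen, tstart, tend = (
                fields[5],
                int(fields[6]),
                int(fields[7]),
                int(fields[8]),
            )
            lengths[target] = tlen
            aligned.setdefault(target, []).append((tstart, tend))
            cs = None
            for tag in fields[12:]:
                if tag.startswith("cs:Z:"):
                    cs = tag[5:]
                    break
            if cs is None:
                continue
            recs = parse_cs_diffs(target, tstart, cs)
            span = cs_reference_span(cs)
            if tstart + span != tend:
                raise ValueError(
                    f"{path}:{lineno}: cs span {span} inconsistent with "
                    f"target interval [{tstart},{tend})"
                )
            diffs.extend(recs)
    diffs.sort(key=lambda d: (d.contig, d.ref_start))
    return diffs, aligned, lengths


def write_paf_cs(
    diffs: Sequence[DiffRecord],
    aligned: Dict[str, List[Tuple[int, int]]],
    contig_lengths: Dict[str, int],
    path: str,
    query_prefix: str = "qry",
) -> None:
    """Write one PAF row (with cs tag) per aligned reference interval."""
    by_contig: Dict[str, List[DiffRecord]] = {}
    for d in diffs:
        by_contig.setdefault(d.contig, []).append(d)
    with open(path, "w") as fh:
        k = 0
        for contig, ivs in aligned.items():
            for s, e in ivs:
                sub = [
                    d
                    for d in by_contig.get(contig, [])
                    if s <= d.ref_start < e
                ]
                cs = diffs_to_cs(sub, s, e)
                ins_bp = sum(d.length for d in sub if d.kind == "ins")
                del_bp = sum(d.length for d in sub if d.kind == "del")
                qlen = (e - s) + ins_bp - del_bp
                fh.write(
                    f"{query_prefix}{k}\t{qlen}\t0\t{qlen}\t+\t{contig}\t"
                    f"{contig_lengths[contig]}\t{s}\t{e}\t{qlen}\t{e - s}\t60\t"
                    f"cs:Z:{cs}\n"
                )
                k += 1


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker_out(path: str) -> List[RepeatRecord]:
    """Parse a RepeatMasker ``.out`` table (3 header lines, whitespace columns).

    The class/family column is split at "/" and the class part kept.
    """
    records: List[RepeatRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            # header lines start with the column banner or are blank
            if stripped.startswith(("SW", "score", "There were no")):
                continue
            fields = stripped.split()
            if not fields[0].replace(".", "").isdigit():
                continue
            if len(fields) < 15:
                raise ValueError(f"{path}:{lineno}: expected >=15 columns")
            contig = fields[4]
            begin1, end1 = int(fields[5]), int(fields[6])
            name = fields[9]
            rclass = fields[10].split("/")[0]
            records.append(RepeatRecord(contig, begin1 - 1, end1, name, rclass))
    return records


def write_repeatmasker_out(records: Sequence[RepeatRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "   SW   perc perc perc  query     position in query    matching"
            "  repeat       position in repeat\n"
        )
        fh.write(
            "score   div. del. ins.  sequence  begin end   (left)   repeat"
            "  class/family  begin end (left) ID\n\n"
        )
        for i, r in enumerate(records, 1):
            fh.write(
                f"  100   1.0  0.0  0.0  {r.contig}  {r.start + 1} {r.end} (0)"
                f"  +  {r.repeat_name}  {r.repeat_class}  1 {r.end - r.start} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# depth TSV


def read_depth_tsv(path: str) -> DepthTrack:
    """Read a three-column depth table (contig, 1-based position, depth)."""
    import pandas as pd

    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "pos", "depth"],
            dtype={"contig": str, "pos": int, "depth": int},
        )
    except pd.errors.EmptyDataError:
        return DepthTrack({})
    if (df["depth"] < 0).any():
        raise ValueError(f"{path}: negative depth")
    data = {}
    for contig, sub in df.groupby("contig", sort=False):
        data[str(contig)] = (sub["pos"].to_numpy() - 1, sub["depth"].to_numpy())
    return DepthTrack(data)


def write_depth_tsv(track: DepthTrack, path: str) -> None:
    with open(path, "w") as fh:
        for contig, pos, depth in track.iter_records():
            fh.write(f"{contig}\t{pos + 1}\t{depth}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> List[Tuple[str, int, int, Optional[str]]]:
    """Read BED3/BED4 rows as (contig, start, end, name-or-None)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty BED interval")
            rows.append((fields[0], start, end, fields[3] if len(fields) > 3 else None))
    return rows


def write_bed(rows: Iterable[Tuple], path: str) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row if x is not None) + "\n")
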