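"""Readers and writers for the formats the pipeline consumes and emits.

GFF3 (1-based inclusive) is converted to the internal 0-based half-open
convention on read; PAF is already 0-based half-open. Spliced alignment
block structure travels in the standard ``cg:Z`` CIGAR tag (M/N/D consume
reference, M/I consume read); a PAF line without a CIGAR is treated as a
single gap-free block.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd

from .models import AlignmentRecord, GeneModel, HomeologGroup, TruthRecord

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


# ---------------------------------------------------------------------------
# GFF3


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise ParseError(f"{path}: line {lineno}: invalid interval {start}-{end}")


def read_gff3(path) -> List[GeneModel]:
    """Read gene/mRNA/exon features into one :class:`GeneModel` per mRNA.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    0-based half-open. mRNAs with no exon children are skipped with a
    warning. Malformed lines raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: List[GeneModel] = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")
        )
        if not exons:
            warnings.warn(f"mRNA {mrna.id} has no exons; skipped")
            continue
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.attributes.get("Parent", [mrna.id])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
            )
        )
    return models


def write_gff3(genes: Sequence[GeneModel], path, chrom_lengths: Optional[Dict[str, int]] = None) -> None:
    """Write gene/mRNA/exon features, converting back to 1-based inclusive."""
    by_gene: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_gene.setdefault(g.gene_id, []).append(g)
    lines = ["##gff-version 3"]
    if chrom_lengths:
        for chrom in sorted(chrom_lengths):
            lines.append(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}")
    order = sorted(by_gene.items(), key=lambda kv: (kv[1][0].chrom, kv[1][0].span[0], kv[0]))
    for gene_id, transcripts in order:
        gstart = min(t.span[0] for t in transcripts)
        gend = max(t.span[1] for t in transcripts)
        t0 = transcripts[0]
        lines.append(
            "\t".join(
                [t0.chrom, "flreads", "gene", str(gstart + 1), str(gend), ".",
                 t0.strand, ".", f"ID={gene_id}"]
            )
        )
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            s, e = t.span
            lines.append(
                "\t".join(
                    [t.chrom, "flreads", "mRNA", str(s + 1), str(e), ".", t.strand,
                     ".", f"ID={t.transcript_id};Parent={gene_id}"]
                )
            )
            for i, (es, ee) in enumerate(t.exons, start=1):
                lines.append(
                    "\t".join(
                        [t.chrom, "flreads", "exon", str(es + 1), str(ee), ".",
                         t.strand, ".",
                         f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PAF

_CIGAR_RE = re.compile(r"(\d+)([MIDN=X])")


def _blocks_from_cigar(tstart: int, cigar: str, where: str) -> Tuple[Tuple[int, int], ...]:
    blocks = []
    pos = tstart
    block_start = tstart
    open_block = False
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op in "M=XD":
            if not open_block:
                block_start = pos
                open_block = True
            pos += n
        elif op == "N":
            if open_block:
                blocks.append((block_start, pos))
                open_block = False
            pos += n
        # I consumes read only
    if open_block:
        blocks.append((block_start, pos))
    if not blocks:
        raise ParseError(f"{where}: CIGAR {cigar!r} aligns no reference bases")
    return tuple(blocks)


def _cigar_from_blocks(blocks: Sequence[Tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def read_paf(path) -> List[AlignmentRecord]:
    """Read a PAF file into :class:`AlignmentRecord` objects, in file order.

    Identity is matches / alignment block length (columns 10/11). Lines with
    fewer than 12 columns raise :class:`ParseError`; lines with a zero block
    length are rejected with a warning. Multiple lines sharing a read_id are
    preserved as separate records.
    """
    path = Path(path)
    records: List[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: PAF needs >= 12 columns, got {len(fields)}"
                )
            read_id = fields[0]
            read_length = int(fields[1])
            strand = fields[4]
            chrom = fields[5]
            tstart = int(fields[7])
            tend = int(fields[8])
            matches = int(fields[9])
            aln_length = int(fields[10])
            if aln_length <= 0:
                warnings.warn(f"{path}: line {lineno}: zero alignment length; rejected")
                continue
            tags = dict(
                (f.split(":", 2)[0], f.split(":", 2)[2]) for f in fields[12:] if f.count(":") >= 2
            )
            if "cg" in tags:
                blocks = _blocks_from_cigar(tstart, tags["cg"], f"{path}: line {lineno}")
            else:
                blocks = ((tstart, tend),)
            is_primary = tags.get("tp", "P") == "P"
            records.append(
                AlignmentRecord(
                    read_id=read_id,
                    read_length=read_length,
                    chrom=chrom,
                    strand=strand,
                    blocks=blocks,
                    matches=matches,
                    aln_length=aln_length,
                    is_primary=is_primary,
                )
            )
    return records


def write_paf(records: Sequence[AlignmentRecord], path, chrom_lengths: Optional[Dict[str, int]] = None) -> None:
    chrom_lengths = chrom_lengths or {}
    lines = []
    for r in records:
        tstart, tend = r.span
        lines.append(
            "\t".join(
                [
                    r.read_id,
                    str(r.read_length),
                    "0",
                    str(r.aln_length),
                    r.strand,
                    r.chrom,
                    str(chrom_lengths.get(r.chrom, tend)),
                    str(tstart),
                    str(tend),
                    str(r.matches),
                    str(r.aln_length),
                    "60" if r.is_primary else "0",
                    f"tp:A:{'P' if r.is_primary else 'S'}",
                    f"cg:Z:{_cigar_from_blocks(r.blocks)}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bam(path) -> List[AlignmentRecord]:
    """Adapter for SAM/BAM input: CIGAR-walked into :class:`AlignmentRecord`.

    PAF is the reference format; this converts coordinate-sorted or
    unsorted SAM/BAM with the same semantics: blocks split at N (introns),
    ``aln_length`` counts aligned read bases (M/=/X plus I), and matches
    are derived from the NM tag when present (``aln_length - NM``).
    Unmapped reads are skipped.
    """
    import pysam

    records: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            blocks: List[Tuple[int, int]] = []
            pos = seg.reference_start
            block_start = pos
            open_block = False
            read_bases = 0
            for op, n in seg.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    if not open_block:
                        block_start, open_block = pos, True
                    pos += n
                    read_bases += n
                elif op == 2:  # D consumes reference only
                    if not open_block:
                        block_start, open_block = pos, True
                    pos += n
                elif op == 3:  # N closes the block
                    if open_block:
                        blocks.append((block_start, pos))
                        open_block = False
                    pos += n
                elif op == 1:  # I consumes read only
                    read_bases += n
            if open_block:
                blocks.append((block_start, pos))
            if not blocks or read_bases == 0:
                warnings.warn(f"{path}: {seg.query_name}: no aligned bases; rejected")
                continue
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            read_length = seg.infer_read_length() or read_bases
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    read_length=read_length,
                    chrom=seg.reference_name,
                    strand="-" if seg.is_reverse else "+",
                    blocks=tuple(blocks),
                    matches=max(0, read_bases - int(nm)),
                    aln_length=read_bases,
                    is_primary=not (seg.is_secondary or seg.is_supplementary),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Homeolog table


def read_homeolog_table(path, known_gene_ids: Optional[Iterable[str]] = None) -> List[HomeologGroup]:
    """Read a TSV of homeologous groups, one group per row, gene IDs in columns.

    Rows with fewer than 2 IDs are skipped with a warning. If
    ``known_gene_ids`` is given, member IDs absent from it are reported
    (warning) but the group is kept.
    """
    path = Path(path)
    known = set(known_gene_ids) if known_gene_ids is not None else None
    groups: List[HomeologGroup] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids = [f for f in line.split("\t") if f]
            if len(ids) < 2:
                warnings.warn(f"{path}: line {lineno}: fewer than 2 gene ids; skipped")
                continue
            if known is not None:
                missing = [g for g in ids if g not in known]
                if missing:
                    warnings.warn(
                        f"{path}: line {lineno}: gene ids absent from annotation: "
                        + ",".join(missing)
                    )
            groups.append(HomeologGroup(group_id=f"HG{len(groups) + 1:03d}", gene_ids=frozenset(ids)))
    return groups


def write_homeolog_table(groups: Sequence[HomeologGroup], path) -> None:
    lines = ["\t".join(sorted(g.gene_ids)) for g in sorted(groups, key=lambda g: g.group_id)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Truth and report tables

TRUTH_COLUMNS = [
    "read_id", "gene_id", "protocol", "capped", "bases_lost_5p",
    "bases_lost_3p", "bases_gained_3p", "size_fraction", "read_length",
]


def write_truth(truths: Sequence[TruthRecord], path) -> None:
    df = pd.DataFrame([t.__dict__ for t in truths], columns=TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"read_id": str, "gene_id": str})


def write_table(df: pd.DataFrame, path) -> None:
    """Write a report table as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)


def write_json_summary(summary: dict, path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
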