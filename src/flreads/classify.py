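"""Read classification: identity filtering, multiplicity partition, target
assignment, strand-aware 5'/3' end offsets, full-length calls and size
fractions.

A read is full length (FL) when its length is equal to or larger than the
spliced (mRNA) length of its assigned target — cDNA reads are spliced, so
comparing against genomic span would make FL unreachable for any
intron-containing gene.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .models import AlignmentRecord, GeneModel, ReadAssignment

IDENTITY_THRESHOLD = 0.90  # inclusive, as in "aligning with >= 90% identity"


def filter_identity(
    records: Sequence[AlignmentRecord], threshold: float = IDENTITY_THRESHOLD
) -> Tuple[List[AlignmentRecord], List[AlignmentRecord]]:
    """Split records into (kept, rejected) by nucleotide identity.

    The threshold is inclusive: identity exactly at the threshold is kept.
    """
    kept, rejected = [], []
    for r in records:
        (kept if r.identity >= threshold else rejected).append(r)
    return kept, rejected


def partition_multiplicity(
    kept: Sequence[AlignmentRecord],
    manifest: Optional[Iterable[str]] = None,
    prefilter_read_ids: Optional[Iterable[str]] = None,
) -> Dict[str, str]:
    """Map each read to its uniqueness class.

    A read with exactly one surviving record is ``unique``; with two or more,
    ``multi`` (multiplicity is counted per read, across all its alignment
    lines). Reads listed in ``prefilter_read_ids`` that lost every record to
    the identity filter are ``filtered``; manifest reads never seen in the
    alignments are ``unaligned``.
    """
    counts: Dict[str, int] = defaultdict(int)
    for r in kept:
        counts[r.read_id] += 1
    out = {rid: ("unique" if n == 1 else "multi") for rid, n in counts.items()}
    if prefilter_read_ids is not None:
        for rid in prefilter_read_ids:
            if rid not in out:
                out[rid] = "filtered"
    if manifest is not None:
        for rid in manifest:
            if rid not in out:
                out[rid] = "unaligned"
    return out


def assign_size_fraction(read_length: int) -> str:
    """Label a read by cDNA size fraction (gel fractionation bins).

    Boundaries are half-open, low-inclusive: [1000,2000) -> 1-2kb,
    [2000,3000) -> 2-3kb, [3000,6000] -> 3-6kb; shorter reads are sub1k and
    longer ones over6k.
    """
    if read_length <= 0:
        raise ValueError(f"non-positive read length {read_length}")
    if read_length < 1000:
        return "sub1k"
    if read_length < 2000:
        return "1-2kb"
    if read_length < 3000:
        return "2-3kb"
    if read_length <= 6000:
        return "3-6kb"
    return "over6k"


class AnnotationIndex:
    """Interval-indexed gene models for overlap queries and target assignment."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes: Tuple[GeneModel, ...] = tuple(genes)
        self.by_transcript: Dict[str, GeneModel] = {g.transcript_id: g for g in genes}
        self.by_gene: Dict[str, List[GeneModel]] = defaultdict(list)
        for g in genes:
            self.by_gene[g.gene_id].append(g)
        self._trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g in genes:
            s, e = g.span
            self._trees[g.chrom].addi(s, e, g)

    def overlapping(
        self, chrom: str, span: Tuple[int, int], strand: Optional[str] = None
    ) -> List[GeneModel]:
        hits = [iv.data for iv in self._trees[chrom].overlap(*span)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.gene_id, g.transcript_id))

    @staticmethod
    def exonic_overlap(record: AlignmentRecord, gene: GeneModel) -> int:
        """Overlap in bases between alignment blocks and gene exons."""
        total = 0
        for bs, be in record.blocks:
            for es, ee in gene.exons:
                lo, hi = max(bs, es), min(be, ee)
                if hi > lo:
                    total += hi - lo
        return total

    def assign_target(self, record: AlignmentRecord) -> Tuple[Optional[str], bool]:
        """Assign a unique read to the gene maximizing exonic overlap.

        Candidates must be same-chromosome, same-strand models overlapping
        the alignment span with at least one exonic base. Returns
        ``(transcript_id, tie_flag)``; ``(None, False)`` when no candidate
        exists (the read is 'not annotated'). Ties on overlap go to the
        lexicographically smaller gene id, with the tie flagged.
        """
        best: List[Tuple[int, GeneModel]] = []
        for g in self.overlapping(record.chrom, record.span, strand=record.strand):
            ov = self.exonic_overlap(record, g)
            if ov > 0:
                best.append((ov, g))
        if not best:
            return None, False
        best.sort(key=lambda t: (-t[0], t[1].gene_id, t[1].transcript_id))
        top_ov = best[0][0]
        tie = sum(1 for ov, g in best if ov == top_ov and g.gene_id != best[0][1].gene_id) > 0
        return best[0][1].transcript_id, tie


def classify_read(record: AlignmentRecord, gene: GeneModel, tie_flag: bool = False) -> ReadAssignment:
    """Compute offsets and the FL flag for a unique read against its target.

    5' offset is the signed distance from the read's transcript-orientation
    5' alignment end to the annotated TSS (negative = upstream); 3' offset
    is analogous against the TES (positive = downstream).
    """
    if record.strand != gene.strand:
        raise ValueError(
            f"{record.read_id}: strand mismatch with target {gene.transcript_id}"
        )
    if gene.strand == "+":
        off5 = record.end5() - gene.tss
        off3 = record.end3() - gene.tes
    else:
        off5 = gene.tss - record.end5()
        off3 = gene.tes - record.end3()
    return ReadAssignment(
        read_id=record.read_id,
        uniqueness="unique",
        gene_id=gene.gene_id,
        five_prime_offset=off5,
        three_prime_offset=off3,
        read_length=record.read_length,
        target_spliced_length=gene.spliced_length,
        is_full_length=record.read_length >= gene.spliced_length,
        size_fraction=assign_size_fraction(record.read_length),
        tie_flag=tie_flag,
        chrom=record.chrom,
        strand=record.strand,
        end5=record.end5(),
        end3=record.end3(),
    )


def classify_alignments(
    records: Sequence[AlignmentRecord],
    index: AnnotationIndex,
    manifest: Optional[Iterable[str]] = None,
    identity_threshold: float = IDENTITY_THRESHOLD,
) -> List[ReadAssignment]:
    """Full classification pass: filter, partition, assign, compute offsets.

    Returns one :class:`ReadAssignment` per read (not per alignment line).
    Multi-mapped, filtered and unaligned reads get a row with their
    uniqueness class and no offsets. Output is sorted by read_id.
    """
    kept, _rejected = filter_identity(records, identity_threshold)
    uniqueness = partition_multiplicity(
        kept,
        manifest=manifest,
        prefilter_read_ids=[r.read_id for r in records],
    )
    by_read: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    for r in kept:
        by_read[r.read_id].append(r)

    out: List[ReadAssignment] = []
    for rid in sorted(uniqueness):
        klass = uniqueness[rid]
        if klass != "unique":
            rl = by_read[rid][0].read_length if by_read.get(rid) else None
            out.append(
                ReadAssignment(
                    read_id=rid,
                    uniqueness=klass,
                    read_length=rl,
                    size_fraction=assign_size_fraction(rl) if rl else None,
                )
            )
            continue
        rec = by_read[rid][0]
        tid, tie = index.assign_target(rec)
        if tid is None:
            out.append(
                ReadAssignment(
                    read_id=rid,
                    uniqueness="unique",
                    gene_id=None,
                    read_length=rec.read_length,
                    size_fraction=assign_size_fraction(rec.read_length),
                    chrom=rec.chrom,
                    strand=rec.strand,
                    end5=rec.end5(),
                    end3=rec.end3(),
                )
            )
            continue
        out.append(classify_read(rec, index.by_transcript[tid], tie_flag=tie))
    return out


ASSIGNMENT_COLUMNS = [
    "read_id", "uniqueness", "gene_id", "five_prime_offset", "three_prime_offset",
    "read_length", "target_spliced_length", "is_full_length", "size_fraction",
    "tie_flag", "chrom", "strand", "end5", "end3",
]


def assignments_to_frame(assignments: Sequence[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame([a.to_row() for a in assignments], columns=ASSIGNMENT_COLUMNS)


def full_length_percentage(assignments: Sequence[ReadAssignment]) -> float:
    """FL% over unique reads with an assigned target."""
    assigned = [a for a in assignments if a.uniqueness == "unique" and a.gene_id is not None]
    if not assigned:
        raise ValueError("no assigned unique reads")
    return 100.0 * sum(a.is_full_length for a in assigned) / len(assigned)
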