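"""Intron-chain isoform classification.

Each uniquely aligned read is compared against the annotation by its
intron chain (the ordered intron intervals of the spliced alignment):

* ``known`` — multi-exon read whose chain exactly equals a same-strand
  annotated transcript's chain (junction fuzz configurable, default 0);
* ``novel_isoform`` — shares at least one splice junction with an
  overlapping same-strand transcript but the chains differ (5'-truncated
  reads whose chain is a contiguous sub-chain are flagged ``contained``);
* ``mono_exon_contained`` — single-exon read fully inside one annotated
  exon;
* ``other`` — exonic overlap with an annotated gene but no shared
  junction;
* ``novel_locus`` — no exonic overlap with any annotated gene.

The classes are exhaustive and mutually exclusive.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .classify import AnnotationIndex
from .models import AlignmentRecord

Interval = Tuple[int, int]

ISOFORM_CLASSES = ("known", "novel_isoform", "mono_exon_contained", "other", "novel_locus")


def intron_chain(record: AlignmentRecord) -> Tuple[Interval, ...]:
    """Intron intervals of a spliced alignment (gaps between blocks)."""
    return tuple(
        (record.blocks[i][1], record.blocks[i + 1][0])
        for i in range(len(record.blocks) - 1)
    )


def _chains_equal(a: Sequence[Interval], b: Sequence[Interval], fuzz: int) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(x[0] - y[0]) <= fuzz and abs(x[1] - y[1]) <= fuzz for x, y in zip(a, b)
    )


def _junction_matches(j: Interval, chain: Sequence[Interval], fuzz: int) -> bool:
    return any(abs(j[0] - c[0]) <= fuzz and abs(j[1] - c[1]) <= fuzz for c in chain)


def _is_contiguous_subchain(sub: Sequence[Interval], chain: Sequence[Interval], fuzz: int) -> bool:
    if not sub or len(sub) > len(chain):
        return False
    for i in range(len(chain) - len(sub) + 1):
        if _chains_equal(sub, chain[i : i + len(sub)], fuzz):
            return True
    return False


@dataclass
class IsoformCall:
    read_id: str
    klass: str
    matched_transcript: Optional[str] = None
    shared_junctions: int = 0
    contained: bool = False
    gene_id: Optional[str] = None  # best overlapping gene, for per-gene tallies
    chrom: str = ""
    strand: str = ""
    span: Tuple[int, int] = (0, 0)


def classify_isoform(
    record: AlignmentRecord, index: AnnotationIndex, fuzz: int = 0
) -> IsoformCall:
    """Classify one uniquely aligned read by intron chain (see module docs)."""
    chain = intron_chain(record)
    same_strand = index.overlapping(record.chrom, record.span, strand=record.strand)
    any_strand = index.overlapping(record.chrom, record.span, strand=None)
    call = IsoformCall(
        read_id=record.read_id,
        klass="other",
        chrom=record.chrom,
        strand=record.strand,
        span=record.span,
    )
    exonic_genes = [
        g for g in any_strand if AnnotationIndex.exonic_overlap(record, g) > 0
    ]
    if chain:  # multi-exon read
        shared_best = 0
        for g in same_strand:
            gchain = g.introns()
            if _chains_equal(chain, gchain, fuzz):
                call.klass = "known"
                call.matched_transcript = g.transcript_id
                call.shared_junctions = len(chain)
                call.gene_id = g.gene_id
                return call
        for g in same_strand:
            gchain = g.introns()
            shared = sum(1 for j in chain if _junction_matches(j, gchain, fuzz))
            if shared > shared_best:
                shared_best = shared
                call.matched_transcript = g.transcript_id
                call.gene_id = g.gene_id
                call.contained = _is_contiguous_subchain(chain, gchain, fuzz)
        if shared_best > 0:
            call.klass = "novel_isoform"
            call.shared_junctions = shared_best
            return call
        if exonic_genes:
            call.klass = "other"
            call.gene_id = min(g.gene_id for g in exonic_genes)
            return call
        call.klass = "novel_locus"
        call.gene_id = None
        call.matched_transcript = None
        return call
    # mono-exon read
    block = record.blocks[0]
    for g in sorted(any_strand, key=lambda g: (g.gene_id, g.transcript_id)):
        for es, ee in g.exons:
            if es <= block[0] and block[1] <= ee:
                call.klass = "mono_exon_contained"
                call.matched_transcript = g.transcript_id
                call.gene_id = g.gene_id
                return call
    if exonic_genes:
        call.klass = "other"
        call.gene_id = min(g.gene_id for g in exonic_genes)
        return call
    call.klass = "novel_locus"
    return call


def classify_isoforms(
    records: Sequence[AlignmentRecord], index: AnnotationIndex, fuzz: int = 0
) -> List[IsoformCall]:
    return [classify_isoform(r, index, fuzz=fuzz) for r in records]


def _novel_locus_clusters(calls: Sequence[IsoformCall]) -> int:
    """Count novel loci as connected overlap components of novel_locus reads."""
    by_loc: Dict[Tuple[str, str], List[IsoformCall]] = defaultdict(list)
    for c in calls:
        if c.klass == "novel_locus":
            by_loc[(c.chrom, c.strand)].append(c)
    n = 0
    for members in by_loc.values():
        members.sort(key=lambda c: c.span)
        reach = None
        for c in members:
            lo, hi = c.span
            if reach is None or lo > reach:
                n += 1
                reach = hi
            else:
                reach = max(reach, hi)
    return n


def summarize_classes(calls: Sequence[IsoformCall]) -> dict:
    """Counts per class, plus distinct genes per class (novel loci counted
    as overlap clusters)."""
    counts = {k: 0 for k in ISOFORM_CLASSES}
    genes: Dict[str, set] = {k: set() for k in ISOFORM_CLASSES}
    for c in calls:
        counts[c.klass] += 1
        if c.gene_id is not None:
            genes[c.klass].add(c.gene_id)
    summary = {"class_counts": counts}
    summary["distinct_genes"] = {k: len(genes[k]) for k in ISOFORM_CLASSES if k != "novel_locus"}
    summary["distinct_genes"]["novel_locus"] = _novel_locus_clusters(calls)
    return summary


def calls_to_frame(calls: Sequence[IsoformCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "class": c.klass,
                "matched_transcript": c.matched_transcript or "",
                "shared_junctions": c.shared_junctions,
                "contained": c.contained,
                "gene_id": c.gene_id or "",
            }
            for c in calls
        ],
        columns=["read_id", "class", "matched_transcript", "shared_junctions",
                 "contained", "gene_id"],
    )
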