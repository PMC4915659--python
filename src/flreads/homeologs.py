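"""Homeolog ambiguity detection and best-match resolution.

In an allopolyploid, a read from one subgenome copy often also aligns to
its homeologous sister loci. A read hitting two or more members of the
same declared homeolog group is flagged multi-homeolog; it is then
resolved by (1) the inclusive 90% identity filter and (2) the best
alignment match: the candidate minimizing d = read_length - alignment
length. A unique minimum resolves the read; a tie leaves it ambiguous.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .classify import AnnotationIndex, IDENTITY_THRESHOLD
from .models import AlignmentRecord, HomeologGroup, ReadAssignment


@dataclass
class Resolution:
    """Outcome of best-match resolution for one read."""

    read_id: str
    status: str  # resolved | ambiguous | filtered
    gene_id: Optional[str] = None
    candidates: List[dict] = field(default_factory=list)


def _gene_of(record: AlignmentRecord, index: AnnotationIndex) -> Optional[str]:
    tid, _tie = index.assign_target(record)
    return index.by_transcript[tid].gene_id if tid is not None else None


def flag_homeolog_hits(
    records: Sequence[AlignmentRecord],
    groups: Sequence[HomeologGroup],
    index: AnnotationIndex,
) -> Dict[str, Set[Tuple[str, str]]]:
    """Per read, the set of (gene_id, group_id) homeolog-group members hit.

    A read appears in the result only if at least one of its alignments
    (primary or secondary) lands on a gene belonging to some group. Use
    :func:`multi_homeolog_reads` to get the reads hitting >= 2 members of
    the same group.
    """
    group_of: Dict[str, str] = {}
    for grp in groups:
        for gid in grp.gene_ids:
            group_of[gid] = grp.group_id
    hits: Dict[str, Set[Tuple[str, str]]] = defaultdict(set)
    for rec in records:
        gene_id = _gene_of(rec, index)
        if gene_id is not None and gene_id in group_of:
            hits[rec.read_id].add((gene_id, group_of[gene_id]))
    return dict(hits)


def multi_homeolog_reads(hits: Dict[str, Set[Tuple[str, str]]]) -> Set[str]:
    """Reads whose alignments hit >= 2 members of the same homeolog group."""
    flagged = set()
    for read_id, pairs in hits.items():
        per_group: Dict[str, int] = defaultdict(int)
        for _gene, group in pairs:
            per_group[group] += 1
        if any(n >= 2 for n in per_group.values()):
            flagged.add(read_id)
    return flagged


def alignment_length(record: AlignmentRecord, side: str = "read") -> int:
    """Alignment length used in d = read_length - alignment length.

    ``read`` side counts aligned read bases (PAF column 11); ``target``
    side counts aligned reference bases (sum of block lengths).
    """
    if side == "read":
        return record.aln_length
    if side == "target":
        return sum(e - s for s, e in record.blocks)
    raise ValueError(f"side must be 'read' or 'target', got {side!r}")


def resolve_best_match(
    read_records: Sequence[AlignmentRecord],
    index: AnnotationIndex,
    identity_threshold: float = IDENTITY_THRESHOLD,
    side: str = "read",
) -> Resolution:
    """Resolve one read's candidate alignments by identity then best match.

    Step 1 drops records below the (inclusive) identity threshold; step 2
    keeps the record(s) with minimal d = read_length - alignment length.
    Exactly one survivor resolves the read to its gene; several tied
    survivors leave it ambiguous; no survivor means filtered. The outcome
    does not depend on the order of the records.
    """
    if not read_records:
        raise ValueError("need at least one record")
    read_id = read_records[0].read_id
    survivors = [r for r in read_records if r.identity >= identity_threshold]
    candidates = []
    for r in sorted(read_records, key=lambda r: (r.chrom, r.span[0], not r.is_primary)):
        candidates.append(
            {
                "gene_id": _gene_of(r, index),
                "identity": r.identity,
                "aln_length": alignment_length(r, side),
                "d": r.read_length - alignment_length(r, side),
                "passed_identity": r.identity >= identity_threshold,
            }
        )
    if not survivors:
        return Resolution(read_id=read_id, status="filtered", candidates=candidates)
    d_min = min(r.read_length - alignment_length(r, side) for r in survivors)
    best = [r for r in survivors if r.read_length - alignment_length(r, side) == d_min]
    if len(best) == 1:
        return Resolution(
            read_id=read_id,
            status="resolved",
            gene_id=_gene_of(best[0], index),
            candidates=candidates,
        )
    return Resolution(read_id=read_id, status="ambiguous", candidates=candidates)


def promote_resolved(
    assignments: Sequence[ReadAssignment],
    resolutions: Sequence[Resolution],
    index: AnnotationIndex,
    records: Sequence[AlignmentRecord],
) -> List[ReadAssignment]:
    """Optionally promote resolved multi-homeolog reads to unique status.

    Off the main path by default: the primary FL/offset analyses discard
    multi-mapped reads, and homeolog resolution is evaluated separately.
    Returns a new assignment list where each read resolved to a gene is
    re-classified against that gene using its alignment to it.
    """
    from .classify import classify_read

    resolved = {r.read_id: r.gene_id for r in resolutions if r.status == "resolved"}
    by_read: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        by_read[rec.read_id].append(rec)
    out = []
    for a in assignments:
        if a.uniqueness == "multi" and a.read_id in resolved:
            gene_id = resolved[a.read_id]
            rec = next(
                (r for r in by_read[a.read_id] if _gene_of(r, index) == gene_id), None
            )
            if rec is not None:
                tid, tie = index.assign_target(rec)
                out.append(classify_read(rec, index.by_transcript[tid], tie_flag=tie))
                continue
        out.append(a)
    return out


def resolve_homeologs(
    records: Sequence[AlignmentRecord],
    groups: Sequence[HomeologGroup],
    index: AnnotationIndex,
    identity_threshold: float = IDENTITY_THRESHOLD,
    side: str = "read",
) -> Tuple[pd.DataFrame, dict]:
    """Flag and resolve every multi-homeolog read; returns (table, summary)."""
    hits = flag_homeolog_hits(records, groups, index)
    flagged = multi_homeolog_reads(hits)
    by_read: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    for r in records:
        by_read[r.read_id].append(r)
    group_of: Dict[str, str] = {}
    for grp in groups:
        for gid in grp.gene_ids:
            group_of[gid] = grp.group_id

    rows = []
    n_resolved = n_ambiguous = n_filtered = 0
    for read_id in sorted(flagged):
        res = resolve_best_match(
            by_read[read_id], index, identity_threshold=identity_threshold, side=side
        )
        if res.status == "resolved":
            n_resolved += 1
        elif res.status == "ambiguous":
            n_ambiguous += 1
        else:
            n_filtered += 1
        group_ids = sorted({g for _gene, g in hits[read_id]})
        rows.append(
            {
                "read_id": read_id,
                "group_id": ",".join(group_ids),
                "status": res.status,
                "resolved_gene": res.gene_id if res.gene_id else "",
                "candidates": ";".join(
                    f"{c['gene_id']}:id={c['identity']:.4f}:aln={c['aln_length']}:d={c['d']}"
                    for c in res.candidates
                ),
            }
        )
    table = pd.DataFrame(
        rows, columns=["read_id", "group_id", "status", "resolved_gene", "candidates"]
    )
    summary = {
        "n_multi_homeolog": len(flagged),
        "n_resolved": n_resolved,
        "n_ambiguous": n_ambiguous,
        "n_filtered": n_filtered,
    }
    return table, summary
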