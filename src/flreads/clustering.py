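"""Redundancy estimation by end-tolerant single-linkage clustering.

Two reads of the same locus are putatively redundant when their alignment
ends agree within a tolerance: 100 bp at the 5' end and 5 bp at the 3' end
by default (both inclusive). Clusters are the connected components of the
pairwise "both tolerances hold" graph — true single linkage — so a chain
of reads each within tolerance of its neighbour forms one cluster even if
its extremes differ by more than the tolerance.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .models import EndCluster, ReadAssignment


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _transcript_ends(a: ReadAssignment) -> Tuple[int, int]:
    """5'/3' genomic end coordinates on a transcript-oriented axis.

    On the minus strand coordinates are negated so that 'downstream'
    always increases; minus-strand genes then behave identically.
    """
    if a.strand == "+":
        return a.end5, a.end3
    return -a.end5, -a.end3


def _overlap_groups(assignments: List[ReadAssignment]) -> List[List[ReadAssignment]]:
    """Group unassigned reads by connected overlap of their alignment spans."""
    by_loc: Dict[Tuple[str, str], List[ReadAssignment]] = defaultdict(list)
    for a in assignments:
        by_loc[(a.chrom, a.strand)].append(a)
    groups = []
    for members in by_loc.values():
        members.sort(key=lambda a: (min(a.end5, a.end3), a.read_id))
        current: List[ReadAssignment] = []
        reach = None
        for a in members:
            lo, hi = sorted((a.end5, a.end3))
            if reach is None or lo <= reach:
                current.append(a)
                reach = hi if reach is None else max(reach, hi)
            else:
                groups.append(current)
                current, reach = [a], hi
        if current:
            groups.append(current)
    return groups


def cluster_ends(
    assignments: Sequence[ReadAssignment], tol5: int = 100, tol3: int = 5
) -> List[EndCluster]:
    """Cluster unique reads whose 5'/3' ends agree within the tolerances.

    Reads are grouped by (gene_id, strand); reads without a target are
    grouped by overlap of their alignment spans per (chrom, strand).
    Within a group, clusters are connected components of the graph with an
    edge wherever \\|d5\\| <= tol5 AND \\|d3\\| <= tol3 (inclusive).
    Cluster membership is independent of input order; the representative
    is the longest member (ties to the smaller read_id).
    """
    if tol5 < 0 or tol3 < 0:
        raise ValueError("tolerances must be >= 0")
    usable = [
        a for a in assignments
        if a.uniqueness == "unique" and a.end5 is not None and a.end3 is not None
    ]
    groups: List[Tuple[Optional[str], List[ReadAssignment]]] = []
    assigned: Dict[Tuple[str, str], List[ReadAssignment]] = defaultdict(list)
    unassigned: List[ReadAssignment] = []
    for a in usable:
        if a.gene_id is not None:
            assigned[(a.gene_id, a.strand)].append(a)
        else:
            unassigned.append(a)
    for (gid, _strand), members in sorted(assigned.items()):
        groups.append((gid, members))
    for members in _overlap_groups(unassigned):
        groups.append((None, members))

    clusters: List[EndCluster] = []
    for gid, members in groups:
        members = sorted(members, key=lambda a: (_transcript_ends(a)[0], a.read_id))
        ends = [_transcript_ends(a) for a in members]
        uf = _UnionFind(len(members))
        for i in range(len(members)):
            t5_i, t3_i = ends[i]
            for j in range(i + 1, len(members)):
                t5_j, t3_j = ends[j]
                if t5_j - t5_i > tol5:
                    break
                if abs(t3_j - t3_i) <= tol3:
                    uf.union(i, j)
        comp: Dict[int, List[int]] = defaultdict(list)
        for i in range(len(members)):
            comp[uf.find(i)].append(i)
        ordered = sorted(comp.values(), key=lambda idxs: min(idxs))
        for k, idxs in enumerate(ordered):
            mem = [members[i] for i in idxs]
            rep = max(mem, key=lambda a: (a.read_length or 0, a.read_id))
            label = gid if gid is not None else f"{mem[0].chrom}{mem[0].strand}"
            clusters.append(
                EndCluster(
                    cluster_id=f"{label}:c{k + 1}",
                    gene_id=gid,
                    chrom=mem[0].chrom,
                    strand=mem[0].strand,
                    member_read_ids=tuple(sorted(a.read_id for a in mem)),
                    representative=rep.read_id,
                )
            )
    return clusters


def redundancy_fraction(clusters: Sequence[EndCluster]) -> float:
    """Percent of putatively redundant reads: 100 * (n_reads - n_clusters) / n_reads."""
    n_reads = sum(c.n_members for c in clusters)
    if n_reads == 0:
        raise ValueError("no reads in clusters")
    return 100.0 * (n_reads - len(clusters)) / n_reads


def clusters_to_frame(clusters: Sequence[EndCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "gene_id": c.gene_id if c.gene_id is not None else "",
                "chrom": c.chrom,
                "strand": c.strand,
                "n_members": c.n_members,
                "representative": c.representative,
                "members": ",".join(c.member_read_ids),
            }
            for c in clusters
        ],
        columns=["cluster_id", "gene_id", "chrom", "strand", "n_members",
                 "representative", "members"],
    )
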