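"""Shared test utilities: toy builders, strand mirroring, and independent
brute-force oracles (kept deliberately separate from the implementations
they check)."""

from __future__ import annotations

import math
from itertools import combinations
from typing import List, Sequence, Tuple

import networkx as nx

from flreads.models import AlignmentRecord, GeneModel, ReadAssignment


def make_gene(gene_id="G1", chrom="chr1", strand="+", exons=((100, 200), (300, 400))):
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.1",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
    )


def make_record(
    read_id="r1",
    chrom="chr1",
    strand="+",
    blocks=((100, 200),),
    read_length=None,
    identity=1.0,
    is_primary=True,
    aln_length=None,
):
    total = sum(e - s for s, e in blocks)
    aln_length = total if aln_length is None else aln_length
    read_length = aln_length if read_length is None else read_length
    return AlignmentRecord(
        read_id=read_id,
        read_length=read_length,
        chrom=chrom,
        strand=strand,
        blocks=tuple(blocks),
        matches=int(round(identity * aln_length)),
        aln_length=aln_length,
        is_primary=is_primary,
    )


def make_assignment(read_id, end5, end3, gene_id="G1", chrom="chr1", strand="+", read_length=1000):
    return ReadAssignment(
        read_id=read_id,
        uniqueness="unique",
        gene_id=gene_id,
        read_length=read_length,
        chrom=chrom,
        strand=strand,
        end5=end5,
        end3=end3,
    )


def mirror_gene(gene: GeneModel, genome_length: int) -> GeneModel:
    """Reverse-complement the coordinate system: x -> L - x, strand flipped."""
    exons = tuple(sorted((genome_length - e, genome_length - s) for s, e in gene.exons))
    return GeneModel(
        gene_id=gene.gene_id,
        transcript_id=gene.transcript_id,
        chrom=gene.chrom,
        strand="-" if gene.strand == "+" else "+",
        exons=exons,
    )


def mirror_record(record: AlignmentRecord, genome_length: int) -> AlignmentRecord:
    blocks = tuple(sorted((genome_length - e, genome_length - s) for s, e in record.blocks))
    return AlignmentRecord(
        read_id=record.read_id,
        read_length=record.read_length,
        chrom=record.chrom,
        strand="-" if record.strand == "+" else "+",
        blocks=blocks,
        matches=record.matches,
        aln_length=record.aln_length,
        is_primary=record.is_primary,
    )


# ---------------------------------------------------------------------------
# Brute-force Mann-Whitney oracle (direct pair counting + full enumeration)


def pair_count_u(a: Sequence[float], b: Sequence[float]) -> float:
    """U_a = #{(x,y): x < y} + 1/2 ties, counted pair by pair."""
    u = 0.0
    for x in a:
        for y in b:
            if x < y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def brute_force_mw(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Enumerate all C(n+m, n) group labelings of the pooled sample and
    return (min-U statistic, two-sided permutation p)."""
    n, m = len(a), len(b)
    pooled = list(a) + list(b)
    u_a = pair_count_u(a, b)
    u_obs = min(u_a, n * m - u_a)
    hits = 0
    total = 0
    for idx in combinations(range(n + m), n):
        chosen = set(idx)
        ga = [pooled[i] for i in range(n + m) if i in chosen]
        gb = [pooled[i] for i in range(n + m) if i not in chosen]
        u = pair_count_u(ga, gb)
        if min(u, n * m - u) <= u_obs + 1e-9:
            hits += 1
        total += 1
    assert total == math.comb(n + m, n)
    return u_obs, hits / total


# ---------------------------------------------------------------------------
# Brute-force clustering oracle (pairwise tolerance graph components)


def _oriented_ends(a: ReadAssignment) -> Tuple[int, int]:
    if a.strand == "+":
        return a.end5, a.end3
    return -a.end5, -a.end3


def brute_force_cluster_count(assignments: List[ReadAssignment], tol5: int, tol3: int) -> int:
    """Connected components of the graph with an edge wherever both end
    differences are within tolerance, per (gene_id, strand) group."""
    groups = {}
    for a in assignments:
        groups.setdefault((a.gene_id, a.strand), []).append(a)
    n_clusters = 0
    for members in groups.values():
        g = nx.Graph()
        g.add_nodes_from(range(len(members)))
        for i in range(len(members)):
            t5i, t3i = _oriented_ends(members[i])
            for j in range(i + 1, len(members)):
                t5j, t3j = _oriented_ends(members[j])
                if abs(t5i - t5j) <= tol5 and abs(t3i - t3j) <= tol3:
                    g.add_edge(i, j)
        n_clusters += nx.number_connected_components(g)
    return n_clusters


# ---------------------------------------------------------------------------
# Isoform truth battery: hand-enumerated read/annotation chain relations


def isoform_battery():
    """Annotation plus >= 30 (record, expected_class) cases covering chain
    equality, contiguous sub-chains, shifted junctions, exon skipping,
    antisense overlap, mono-exon containment and intergenic reads.

    Returns a list of (genes, record, expected_class) instances; every base
    case also appears strand-mirrored (through genome_length, against the
    mirrored annotation) with the same expected class.
    """
    genome_length = 20000
    gene_a = make_gene(
        "GA", "chr1", "+", ((100, 200), (300, 400), (500, 600), (700, 800))
    )
    gene_b = make_gene("GB", "chr1", "-", ((2000, 2150), (2300, 2450), (2600, 2750)))
    gene_mono = make_gene("GM", "chr1", "+", ((4000, 5000),))
    genes = [gene_a, gene_b, gene_mono]

    base_cases = [
        # exact chain -> known
        (make_record("k1", blocks=((100, 200), (300, 400), (500, 600), (700, 800))), "known"),
        (make_record("k2", blocks=((120, 200), (300, 400), (500, 600), (700, 780))), "known"),
        # minus-strand exact chain -> known
        (make_record("k3", strand="-", blocks=((2000, 2150), (2300, 2450), (2600, 2750))), "known"),
        (make_record("k4", strand="-", blocks=((2050, 2150), (2300, 2450), (2600, 2700))), "known"),
        # contiguous sub-chain (5'-truncated read) -> novel_isoform
        (make_record("n1", blocks=((300, 400), (500, 600), (700, 800))), "novel_isoform"),
        (make_record("n2", blocks=((100, 200), (300, 400), (500, 600))), "novel_isoform"),
        (make_record("n3", blocks=((300, 400), (500, 600))), "novel_isoform"),
        # exon skipping: first junction kept, internal exon dropped
        (make_record("n4", blocks=((100, 200), (300, 400), (700, 800))), "novel_isoform"),
        # one junction shifted, one kept
        (make_record("n5", blocks=((100, 210), (300, 400), (500, 600), (700, 800))), "novel_isoform"),
        (make_record("n6", blocks=((100, 200), (310, 400), (500, 600), (700, 800))), "novel_isoform"),
        # novel junction appended after a known one
        (make_record("n7", blocks=((100, 200), (300, 450), (550, 600))), "novel_isoform"),
        # minus-strand shares one junction
        (make_record("n8", strand="-", blocks=((2000, 2150), (2300, 2500), (2600, 2750))), "novel_isoform"),
        # all junctions shifted -> exonic overlap, no shared junction -> other
        (make_record("o1", blocks=((110, 210), (310, 410), (510, 610))), "other"),
        # spliced read antisense over gene A: strand rule forbids known -> other
        (make_record("o2", strand="-", blocks=((100, 200), (300, 400), (500, 600), (700, 800))), "other"),
        # mono-exon read overlapping exon boundary -> other
        (make_record("o3", blocks=((150, 250),)), "other"),
        # mono-exon read inside an intron of gene A (no exonic overlap,
        # between exon 2 and 3) -> novel_locus
        (make_record("l4", blocks=((420, 480),)), "novel_locus"),
        # mono-exon fully inside one exon -> mono_exon_contained
        (make_record("m1", blocks=((4100, 4900),)), "mono_exon_contained"),
        (make_record("m2", blocks=((120, 180),)), "mono_exon_contained"),
        (make_record("m3", strand="-", blocks=((2310, 2440),)), "mono_exon_contained"),
        # exact exon boundaries count as contained
        (make_record("m4", blocks=((4000, 5000),)), "mono_exon_contained"),
        # intergenic reads -> novel_locus
        (make_record("l1", blocks=((8000, 8200), (8400, 8600))), "novel_locus"),
        (make_record("l2", blocks=((9000, 9500),)), "novel_locus"),
        (make_record("l3", strand="-", blocks=((8000, 8200), (8400, 8600))), "novel_locus"),
    ]
    mirrored_genes = [mirror_gene(g, genome_length) for g in genes]
    instances = [(genes, rec, expected) for rec, expected in base_cases]
    instances += [
        (mirrored_genes, mirror_record(rec, genome_length), expected)
        for rec, expected in base_cases
    ]
    return instances
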