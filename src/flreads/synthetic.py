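"""Synthetic two-chemistry cDNA library simulator.

Generates a toy multi-exon annotation (with homeologous triplets placed on
distinct chromosomes, mimicking the subgenomes of an allopolyploid), draws
mRNA molecules with log-normal gene abundances, applies 5' truncation
(degraded molecules lose their cap), and emulates two capture chemistries:

* ``cap_dependent`` — an adapter is ligated to the 5' cap, so capped
  molecules are captured with high probability and uncapped ones leak
  through rarely;
* ``template_switch`` — cap-blind capture of every molecule, plus an extra
  5' loss from incomplete first-strand cDNA synthesis.

Both chemistries prime at the 3' poly-A end; the 3' alignment end gets a
small, symmetric, bounded Gaussian jitter. Reads are emitted as spliced
PAF alignments against the generated genome together with per-read ground
truth. No base-level sequence is produced: homeolog divergence is modelled
directly on alignment quality (secondary alignments to sister loci with
proportionally reduced aligned length and identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import assign_size_fraction
from .models import (
    AlignmentRecord,
    GeneModel,
    HomeologGroup,
    PROTOCOLS,
    SimConfig,
    TruthRecord,
)

_CHROM_START_PAD = 15000  # room upstream of the first gene (offset windows)
_MIN_REMAINING = 50  # a molecule never truncates below this many bases

_READ_PREFIX = {"cap_dependent": "cd", "template_switch": "ts"}


@dataclass
class Molecule:
    """An mRNA molecule drawn from the pool, before library capture."""

    gene: GeneModel
    capped: bool
    bases_lost_5p: int


@dataclass
class SimResult:
    genes: List[GeneModel]
    groups: List[HomeologGroup]
    chrom_lengths: Dict[str, int]
    libraries: Dict[str, Tuple[List[AlignmentRecord], List[TruthRecord]]]
    config: SimConfig


# ---------------------------------------------------------------------------
# Annotation generation


def _gene_structure(config: SimConfig, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Draw exon lengths and intron lengths for one gene."""
    k_lo, k_hi = config.exons_per_gene
    k = int(rng.integers(k_lo, k_hi + 1))
    l_lo, l_hi = config.spliced_length_range
    spliced = int(rng.integers(l_lo, l_hi + 1))
    extra = spliced - k * config.min_exon_length
    if extra < 0:
        raise ValueError("spliced_length_range too small for exons_per_gene * min_exon_length")
    exon_lengths = config.min_exon_length + rng.multinomial(extra, [1.0 / k] * k)
    i_lo, i_hi = config.intron_length_range
    intron_lengths = rng.integers(i_lo, i_hi + 1, size=k - 1) if k > 1 else np.array([], dtype=int)
    return exon_lengths, intron_lengths


def _place_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
) -> GeneModel:
    exons = []
    pos = start
    for i, el in enumerate(exon_lengths):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < len(intron_lengths):
            pos += int(intron_lengths[i])
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.1",
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
    )


def generate_annotation(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[GeneModel], List[HomeologGroup], Dict[str, int]]:
    """Generate non-overlapping multi-exon genes plus homeolog triplets.

    Triplets are near-copies of selected genes (identical exon/intron
    structure) placed on the two other chromosomes, registered as
    :class:`HomeologGroup` rows; sequence divergence (``homeolog_identity``)
    only manifests later, in simulated alignment quality.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursor = {c: _CHROM_START_PAD for c in chroms}
    g_lo, g_hi = config.intergenic_gap_range

    genes: List[GeneModel] = []
    for i in range(config.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lengths, intron_lengths = _gene_structure(config, rng)
        start = cursor[chrom]
        gene = _place_gene(f"G{i + 1:04d}", chrom, strand, start, exon_lengths, intron_lengths)
        cursor[chrom] = gene.span[1] + int(rng.integers(g_lo, g_hi + 1))
        genes.append(gene)

    groups: List[HomeologGroup] = []
    if config.n_homeolog_triplets > 0:
        if config.n_homeolog_triplets > config.n_genes:
            raise ValueError("more triplets requested than genes available")
        chosen = sorted(rng.choice(config.n_genes, size=config.n_homeolog_triplets, replace=False))
        for t, gi in enumerate(chosen):
            base = genes[gi]
            others = [c for c in chroms if c != base.chrom]
            sel = [others[int(j)] for j in rng.choice(len(others), size=2, replace=False)]
            member_ids = [base.gene_id]
            for suffix, chrom in zip(("B", "D"), sel):
                start = cursor[chrom]
                exon_lengths = [e - s for s, e in base.exons]
                intron_lengths = [
                    base.exons[i + 1][0] - base.exons[i][1] for i in range(len(base.exons) - 1)
                ]
                copy = _place_gene(
                    f"{base.gene_id}{suffix}", chrom, base.strand, start,
                    exon_lengths, intron_lengths,
                )
                cursor[chrom] = copy.span[1] + int(rng.integers(g_lo, g_hi + 1))
                genes.append(copy)
                member_ids.append(copy.gene_id)
            groups.append(HomeologGroup(group_id=f"HG{t + 1:03d}", gene_ids=frozenset(member_ids)))

    chrom_lengths = {c: cursor[c] + _CHROM_START_PAD for c in chroms}
    return genes, groups, chrom_lengths


# ---------------------------------------------------------------------------
# Molecule and library simulation


def simulate_molecules(
    genes: Sequence[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
    n: Optional[int] = None,
) -> List[Molecule]:
    """Draw mRNA molecules with log-normal abundances and 5' truncation.

    With probability ``p_truncated`` a molecule loses a ``truncation_extent``
    share of its 5' (spliced) length and is flagged uncapped; truncated
    molecules always lose at least one base so the cap state and the 5'
    intactness of the molecule coincide exactly.
    """
    if not genes:
        raise ValueError("no genes to simulate from")
    n = config.n_reads_per_protocol if n is None else n
    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    probs = weights / weights.sum()
    idx = rng.choice(len(genes), size=n, p=probs)
    e_lo, e_hi = config.truncation_extent
    molecules: List[Molecule] = []
    for gi in idx:
        gene = genes[int(gi)]
        truncated = rng.random() < config.p_truncated
        lost5 = 0
        if truncated:
            extent = rng.uniform(e_lo, e_hi)
            lost5 = max(1, int(round(extent * gene.spliced_length)))
            lost5 = min(lost5, gene.spliced_length - _MIN_REMAINING)
        molecules.append(Molecule(gene=gene, capped=not truncated, bases_lost_5p=lost5))
    return molecules


def map_transcript_interval(gene: GeneModel, t0: int, t1: int) -> Tuple[Tuple[int, int], ...]:
    """Map a transcript-coordinate interval [t0, t1) to genomic blocks.

    Transcript coordinate 0 is the TSS (strand-aware); returned blocks are
    sorted genomically.
    """
    if not (0 <= t0 < t1 <= gene.spliced_length):
        raise ValueError(f"transcript interval [{t0},{t1}) outside [0,{gene.spliced_length})")
    blocks = []
    c = 0
    exons = gene.exons if gene.strand == "+" else tuple(reversed(gene.exons))
    for s, e in exons:
        ln = e - s
        lo, hi = max(t0, c), min(t1, c + ln)
        if hi > lo:
            if gene.strand == "+":
                blocks.append((s + (lo - c), s + (hi - c)))
            else:
                blocks.append((e - (hi - c), e - (lo - c)))
        c += ln
    return tuple(sorted(blocks))


def _extend_3p(blocks: Tuple[Tuple[int, int], ...], strand: str, n: int) -> Tuple[Tuple[int, int], ...]:
    if n <= 0:
        return blocks
    b = list(blocks)
    if strand == "+":
        s, e = b[-1]
        b[-1] = (s, e + n)
    else:
        s, e = b[0]
        b[0] = (s - n, e)
    return tuple(b)


def _trim_3p(blocks: Tuple[Tuple[int, int], ...], strand: str, n: int) -> Tuple[Tuple[int, int], ...]:
    """Remove n aligned bases from the 3' end of a spliced block chain."""
    if n <= 0:
        return blocks
    b = list(blocks)
    order = range(len(b) - 1, -1, -1) if strand == "+" else range(len(b))
    remaining = n
    out = {i: b[i] for i in range(len(b))}
    for i in order:
        s, e = out[i]
        ln = e - s
        if remaining >= ln:
            del out[i]
            remaining -= ln
        else:
            out[i] = (s, e - remaining) if strand == "+" else (s + remaining, e)
            remaining = 0
            break
    if remaining > 0 or not out:
        raise ValueError("trim removed the whole alignment")
    return tuple(out[i] for i in sorted(out))


def _sister_map(groups: Sequence[HomeologGroup], genes: Sequence[GeneModel]) -> Dict[str, List[GeneModel]]:
    by_id = {g.gene_id: g for g in genes}
    sisters: Dict[str, List[GeneModel]] = {}
    for grp in groups:
        for gid in grp.gene_ids:
            sisters[gid] = [by_id[o] for o in sorted(grp.gene_ids) if o != gid and o in by_id]
    return sisters


def simulate_library(
    molecules: Sequence[Molecule],
    protocol: str,
    config: SimConfig,
    rng: np.random.Generator,
    groups: Sequence[HomeologGroup] = (),
    all_genes: Optional[Sequence[GeneModel]] = None,
) -> Tuple[List[AlignmentRecord], List[TruthRecord]]:
    """Capture molecules with one chemistry and emit alignments + truth.

    Cap-dependent capture keeps capped molecules with probability
    ``cap_capture`` and uncapped ones with ``cap_leakage``; template
    switching captures everything and adds an extra 5' loss with
    probability ``p_incomplete_synthesis``. Captured molecules get bounded
    Gaussian 3' jitter; when ``size_selection`` is on (the default), only
    cDNAs falling in the 1-6 kb gel bands are sequenced. Surviving
    molecules are written as spliced alignments with identity
    ``1 - error_rate``. Homeolog-derived reads additionally receive, with
    probability ``p_homeolog_multimap``, secondary alignments to their
    sister loci with aligned length reduced by
    ``(1 - homeolog_identity) * read_length``.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    config.validate()
    sisters = _sister_map(groups, all_genes) if groups and all_genes is not None else {}
    prefix = _READ_PREFIX[protocol]
    e_lo, e_hi = config.truncation_extent

    records: List[AlignmentRecord] = []
    truths: List[TruthRecord] = []
    for i, mol in enumerate(molecules):
        if protocol == "cap_dependent":
            p_capture = config.cap_capture if mol.capped else config.cap_leakage
            if rng.random() >= p_capture:
                continue
            lost5 = mol.bases_lost_5p
        else:
            lost5 = mol.bases_lost_5p
            if rng.random() < config.p_incomplete_synthesis:
                remaining = mol.gene.spliced_length - lost5
                extent = rng.uniform(e_lo, e_hi)
                extra = max(1, int(round(extent * remaining)))
                lost5 = min(lost5 + extra, mol.gene.spliced_length - _MIN_REMAINING)

        jitter = 0
        if config.three_prime_jitter_sd > 0:
            jitter = int(round(rng.normal(0.0, config.three_prime_jitter_sd)))
            jitter = max(-config.max_three_prime_jitter, min(config.max_three_prime_jitter, jitter))
        lost3 = max(0, -jitter)
        gained3 = max(0, jitter)
        spliced = mol.gene.spliced_length
        lost3 = min(lost3, spliced - lost5 - 1)

        read_length = spliced - lost5 - lost3 + gained3
        # gel fractionation: only the 1-2 / 2-3 / 3-6 kb bands are sequenced
        if config.size_selection and not (1000 <= read_length <= 6000):
            continue
        blocks = map_transcript_interval(mol.gene, lost5, spliced - lost3)
        blocks = _extend_3p(blocks, mol.gene.strand, gained3)
        aln_length = read_length
        matches = aln_length - int(round(config.error_rate * aln_length))
        read_id = f"{prefix}_{i:06d}"
        records.append(
            AlignmentRecord(
                read_id=read_id,
                read_length=read_length,
                chrom=mol.gene.chrom,
                strand=mol.gene.strand,
                blocks=blocks,
                matches=matches,
                aln_length=aln_length,
                is_primary=True,
            )
        )
        truths.append(
            TruthRecord(
                read_id=read_id,
                gene_id=mol.gene.gene_id,
                protocol=protocol,
                capped=mol.capped,
                bases_lost_5p=lost5,
                bases_lost_3p=lost3,
                bases_gained_3p=gained3,
                size_fraction=assign_size_fraction(read_length),
                read_length=read_length,
            )
        )

        sis = sisters.get(mol.gene.gene_id)
        if sis and rng.random() < config.p_homeolog_multimap:
            reduction = int(round((1.0 - config.homeolog_identity) * read_length))
            for sister in sis:
                t1 = min(spliced - lost3, sister.spliced_length)
                if lost5 >= t1:
                    continue
                sblocks = map_transcript_interval(sister, lost5, t1)
                sblocks = _extend_3p(sblocks, sister.strand, gained3)
                total = sum(e - s for s, e in sblocks)
                if total - reduction <= 0:
                    continue
                sblocks = _trim_3p(sblocks, sister.strand, reduction)
                s_aln = sum(e - s for s, e in sblocks)
                s_matches = int(round(config.homeolog_identity * s_aln))
                records.append(
                    AlignmentRecord(
                        read_id=read_id,
                        read_length=read_length,
                        chrom=sister.chrom,
                        strand=sister.strand,
                        blocks=sblocks,
                        matches=s_matches,
                        aln_length=s_aln,
                        is_primary=False,
                    )
                )

    if not truths:
        raise ValueError(
            f"no molecule captured under {protocol}; increase n_reads_per_protocol"
        )
    return records, truths


def simulate_run(config: SimConfig) -> SimResult:
    """Run the full simulation: annotation, then one library per protocol.

    All randomness flows from ``config.seed``; an identical config yields
    byte-identical GFF3/PAF/truth outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, groups, chrom_lengths = generate_annotation(config, rng)
    libraries = {}
    for protocol in PROTOCOLS:
        molecules = simulate_molecules(genes, config, rng)
        libraries[protocol] = simulate_library(
            molecules, protocol, config, rng, groups=groups, all_genes=genes
        )
    return SimResult(
        genes=genes,
        groups=groups,
        chrom_lengths=chrom_lengths,
        libraries=libraries,
        config=config,
    )
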