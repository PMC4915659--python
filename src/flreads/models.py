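"""Core domain types.

All genomic coordinates are 0-based half-open intervals on the forward
strand of the reference. GFF3 input (1-based inclusive) is converted on
read; PAF is already 0-based half-open and is taken as-is.

The transcript orientation ("5'" / "3'") is strand-aware: on the minus
strand the 5' end of a gene or read is its rightmost genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

Interval = Tuple[int, int]

SIZE_FRACTIONS = ("sub1k", "1-2kb", "2-3kb", "3-6kb", "over6k")
PROTOCOLS = ("cap_dependent", "template_switch")


def _check_blocks(blocks: Sequence[Interval], what: str) -> None:
    prev_end = None
    for start, end in blocks:
        if end <= start:
            raise ValueError(f"{what}: empty or inverted interval ({start}, {end})")
        if prev_end is not None and start < prev_end:
            raise ValueError(f"{what}: intervals overlap or are unsorted at {start}")
        prev_end = end


@dataclass(frozen=True)
class GeneModel:
    """One annotated transcript: the 'target' of full-length classification.

    ``exons`` are non-overlapping genomic intervals sorted by start.
    ``tss``/``tes`` are derived strand-aware: on '+' the TSS is the first
    exon start; on '-' it is the last exon end.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        _check_blocks(self.exons, f"exons of {self.transcript_id}")

    @property
    def tss(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1]

    @property
    def tes(self) -> int:
        return self.exons[-1][1] if self.strand == "+" else self.exons[0][0]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    def introns(self) -> Tuple[Interval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-genome alignment (one PAF line).

    ``aln_length`` counts aligned read bases (PAF column 11 as emitted by
    this package); ``matches`` is the residue-match count (column 10).
    ``blocks`` are the aligned genomic intervals (exons of the alignment).
    """

    read_id: str
    read_length: int
    chrom: str
    strand: str
    blocks: Tuple[Interval, ...]
    matches: int
    aln_length: int
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        _check_blocks(self.blocks, f"alignment blocks of {self.read_id}")
        if self.aln_length <= 0:
            raise ValueError(f"{self.read_id}: non-positive alignment length")
        if self.aln_length > self.read_length:
            raise ValueError(f"{self.read_id}: aln_length exceeds read_length")
        if self.matches > self.aln_length:
            raise ValueError(f"{self.read_id}: matches exceed aln_length")

    @property
    def identity(self) -> float:
        return self.matches / self.aln_length

    @property
    def span(self) -> Interval:
        return (self.blocks[0][0], self.blocks[-1][1])

    def end5(self) -> int:
        """Genomic coordinate of the read's 5' alignment end (strand-aware)."""
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1]

    def end3(self) -> int:
        """Genomic coordinate of the read's 3' alignment end (strand-aware)."""
        return self.blocks[-1][1] if self.strand == "+" else self.blocks[0][0]


@dataclass(frozen=True)
class HomeologGroup:
    """A set (typically a triplet) of gene IDs declared homeologous."""

    group_id: str
    gene_ids: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if len(self.gene_ids) < 2:
            raise ValueError(f"{self.group_id}: needs >= 2 distinct gene ids")


@dataclass
class ReadAssignment:
    """A read joined to its target gene, with offsets and the FL verdict.

    Offsets are signed, in transcript orientation: a negative 5' offset
    means the read end lies upstream of the annotated TSS; a positive 3'
    offset means downstream of the annotated TES.
    """

    read_id: str
    uniqueness: str  # unique | multi | unaligned | filtered
    gene_id: Optional[str] = None
    five_prime_offset: Optional[int] = None
    three_prime_offset: Optional[int] = None
    read_length: Optional[int] = None
    target_spliced_length: Optional[int] = None
    is_full_length: Optional[bool] = None
    size_fraction: Optional[str] = None
    tie_flag: bool = False
    # genomic end coordinates and location, kept for end clustering
    chrom: Optional[str] = None
    strand: Optional[str] = None
    end5: Optional[int] = None
    end3: Optional[int] = None

    def to_row(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TruthRecord:
    """Simulator ground truth for one emitted read."""

    read_id: str
    gene_id: str
    protocol: str
    capped: bool
    bases_lost_5p: int
    bases_lost_3p: int
    bases_gained_3p: int
    size_fraction: str
    read_length: int


@dataclass(frozen=True)
class EndCluster:
    """A group of same-locus reads whose alignment ends agree within tolerance."""

    cluster_id: str
    gene_id: Optional[str]
    chrom: str
    strand: str
    member_read_ids: Tuple[str, ...]
    representative: str

    @property
    def n_members(self) -> int:
        return len(self.member_read_ids)


@dataclass
class SimConfig:
    """Parameters of the synthetic two-chemistry library simulator.

    The generative contrast: a fraction ``p_truncated`` of mRNA molecules
    has lost part of its 5' end (degradation/shearing) and therefore lacks
    the 5' cap. The cap-dependent protocol captures capped molecules with
    probability ``cap_capture`` and uncapped ones with ``cap_leakage``;
    template switching is cap-blind (captures everything) but adds an extra
    5' loss with probability ``p_incomplete_synthesis`` (incomplete cDNA
    synthesis). Both protocols prime at the 3' poly-A end, modelled as a
    small Gaussian jitter of the 3' alignment end.
    """

    n_genes: int = 30
    exons_per_gene: Tuple[int, int] = (2, 8)
    spliced_length_range: Tuple[int, int] = (800, 6500)
    p_truncated: float = 0.4
    truncation_extent: Tuple[float, float] = (0.0, 0.8)  # uniform on (lo, hi]
    cap_capture: float = 0.95
    cap_leakage: float = 0.02
    p_incomplete_synthesis: float = 0.3
    three_prime_jitter_sd: float = 2.0
    max_three_prime_jitter: int = 10
    n_reads_per_protocol: int = 1000
    homeolog_identity: float = 0.97
    n_homeolog_triplets: int = 3
    p_homeolog_multimap: float = 0.5
    error_rate: float = 0.0
    size_selection: bool = True  # gel fractionation keeps only 1-6 kb cDNA
    n_chromosomes: int = 3
    intron_length_range: Tuple[int, int] = (60, 500)
    intergenic_gap_range: Tuple[int, int] = (2000, 8000)
    min_exon_length: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "p_truncated",
            "cap_capture",
            "cap_leakage",
            "p_incomplete_synthesis",
            "homeolog_identity",
            "p_homeolog_multimap",
            "error_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "n_reads_per_protocol", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_homeolog_triplets < 0:
            raise ValueError("n_homeolog_triplets must be >= 0")
        lo, hi = self.spliced_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("spliced_length_range must be positive and ordered")
        lo, hi = self.truncation_extent
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("truncation_extent must satisfy 0 <= lo < hi <= 1")
        if self.three_prime_jitter_sd < 0:
            raise ValueError("three_prime_jitter_sd must be >= 0")
        if self.n_homeolog_triplets > 0 and self.n_chromosomes < 3:
            raise ValueError("homeolog triplets need >= 3 chromosomes")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        cfg = cls(**d)
        for name in (
            "exons_per_gene",
            "spliced_length_range",
            "truncation_extent",
            "intron_length_range",
            "intergenic_gap_range",
        ):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.validate()
        return cfg
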