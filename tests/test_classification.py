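"""Identity filter, multiplicity partition, target assignment, offsets,
full-length calls and size fractions."""

import pytest
from helpers import make_gene, make_record, mirror_gene, mirror_record

from flreads import AnnotationIndex, SimConfig, simulate_run
from flreads.classify import (
    assign_size_fraction,
    classify_alignments,
    classify_read,
    filter_identity,
    partition_multiplicity,
)


# ---------------------------------------------------------------------- filter


def test_identity_filter_inclusive_boundary():
    records = [
        make_record("a", identity=0.90, aln_length=10000),
        make_record("b", identity=0.8999, aln_length=10000),
    ]
    kept, rejected = filter_identity(records)
    assert [r.read_id for r in kept] == ["a"]
    assert [r.read_id for r in rejected] == ["b"]


def test_identity_filter_empty_input():
    assert filter_identity([]) == ([], [])


# ------------------------------------------------------------------- partition


def test_partition_two_surviving_records_is_multi():
    recs = [
        make_record("r1", chrom="chr1", identity=0.95, aln_length=100),
        make_record("r1", chrom="chr2", identity=0.92, aln_length=100),
    ]
    kept, _ = filter_identity(recs)
    assert partition_multiplicity(kept)["r1"] == "multi"


def test_partition_identity_filter_rescues_uniqueness():
    """A second alignment below 90% identity is removed first, leaving the
    read unique."""
    recs = [
        make_record("r1", chrom="chr1", identity=0.95, aln_length=100),
        make_record("r1", chrom="chr2", identity=0.85, aln_length=100),
    ]
    kept, _ = filter_identity(recs)
    part = partition_multiplicity(kept, prefilter_read_ids=[r.read_id for r in recs])
    assert part["r1"] == "unique"


def test_partition_manifest_and_totality():
    recs = [make_record("r1", identity=0.95, aln_length=100),
            make_record("r2", identity=0.80, aln_length=100)]
    kept, _ = filter_identity(recs)
    part = partition_multiplicity(
        kept, manifest=["r1", "r2", "r3"], prefilter_read_ids=["r1", "r2"]
    )
    assert part == {"r1": "unique", "r2": "filtered", "r3": "unaligned"}


# -------------------------------------------------------------- size fractions


@pytest.mark.parametrize(
    "length,label",
    [
        (800, "sub1k"), (999, "sub1k"),
        (1000, "1-2kb"), (1999, "1-2kb"),
        (2000, "2-3kb"), (2999, "2-3kb"),
        (3000, "3-6kb"), (4500, "3-6kb"), (6000, "3-6kb"),
        (6001, "over6k"),
    ],
)
def test_size_fraction_boundaries(length, label):
    assert assign_size_fraction(length) == label


def test_size_fraction_rejects_nonpositive():
    with pytest.raises(ValueError):
        assign_size_fraction(0)


# ------------------------------------------------------------------ assignment


def make_two_gene_index():
    g1 = make_gene("G1", exons=((1000, 1400), (1600, 2200)))
    g2 = make_gene("G2", exons=((2150, 2400),))
    g_minus = make_gene("G3", strand="-", exons=((1000, 1400), (1600, 2200)))
    return AnnotationIndex([g1, g2, g_minus])


def test_assign_target_max_exonic_overlap():
    index = make_two_gene_index()
    rec = make_record("r", blocks=((1000, 1400), (1600, 2200)))
    tid, tie = index.assign_target(rec)
    assert tid == "G1.1" and not tie
    # overlapping G1 by many exonic bases and G2 by 50 -> still G1
    rec2 = make_record("r2", blocks=((1600, 2200),))
    tid2, _ = index.assign_target(rec2)
    assert tid2 == "G1.1"


def test_assign_target_requires_strand_agreement():
    g_plus = make_gene("G1", exons=((1000, 2000),))
    index = AnnotationIndex([g_plus])
    rec = make_record("r", strand="-", blocks=((1100, 1900),))
    assert index.assign_target(rec) == (None, False)


def test_assign_target_tie_breaks_lexicographically_with_flag():
    ga = make_gene("GA", exons=((1000, 2000),))
    gb = make_gene("GB", exons=((1000, 2000),))
    index = AnnotationIndex([ga, gb])
    rec = make_record("r", blocks=((1200, 1800),))
    tid, tie = index.assign_target(rec)
    assert tid == "GA.1" and tie


# --------------------------------------------------------------------- offsets


def test_offsets_plus_strand_and_fl_boundary():
    gene = make_gene("G", exons=((1000, 1500), (1700, 2200)))  # spliced 1000, tss 1000
    rec = make_record("r", blocks=gene.exons, read_length=1000)
    a = classify_read(rec, gene)
    assert (a.five_prime_offset, a.three_prime_offset) == (0, 0)
    assert a.is_full_length  # equal length counts as FL

    rec2 = make_record("r2", blocks=((1150, 1500), (1700, 2200)), read_length=850)
    a2 = classify_read(rec2, gene)
    assert a2.five_prime_offset == 150
    assert not a2.is_full_length


def test_fl_is_false_one_base_short():
    gene = make_gene("G", exons=((1000, 2000),))
    rec = make_record("r", blocks=((1001, 2000),), read_length=999)
    assert classify_read(rec, gene).is_full_length is False


def test_offsets_minus_strand_upstream_is_negative():
    """On a '-' gene with TSS at its right edge 5000, a read whose rightmost
    aligned base is 5040 starts 40 bp upstream: offset5 = -40."""
    gene = make_gene("G", strand="-", exons=((3000, 3600), (4400, 5000)))
    rec = make_record("r", strand="-", blocks=((3000, 3600), (4400, 5040)), read_length=1240)
    a = classify_read(rec, gene)
    assert a.five_prime_offset == -40
    assert a.three_prime_offset == 0


def test_classify_read_rejects_strand_mismatch():
    gene = make_gene("G", exons=((1000, 2000),))
    rec = make_record("r", strand="-", blocks=((1000, 2000),))
    with pytest.raises(ValueError, match="strand mismatch"):
        classify_read(rec, gene)


def test_strand_mirror_symmetry():
    """Mirroring the genome and flipping strands leaves offsets and the FL
    flag unchanged."""
    L = 10000
    gene = make_gene("G", exons=((1000, 1500), (1700, 2300)))
    recs = [
        make_record("r1", blocks=((1050, 1500), (1700, 2290)), read_length=1040),
        make_record("r2", blocks=((1000, 1500), (1700, 2300)), read_length=1100),
        make_record("r3", blocks=((900, 1500), (1700, 2300)), read_length=1200),
    ]
    mgene = mirror_gene(gene, L)
    for rec in recs:
        a = classify_read(rec, gene)
        m = classify_read(mirror_record(rec, L), mgene)
        assert (a.five_prime_offset, a.three_prime_offset) == (
            m.five_prime_offset, m.three_prime_offset)
        assert a.is_full_length == m.is_full_length


def test_fl_monotone_in_upstream_extension():
    """Extending the 5' alignment upstream (same 3' end) never turns an FL
    read into a non-FL read."""
    gene = make_gene("G", exons=((1000, 2000),))
    previous = False
    fls = []
    for start in (1100, 1050, 1000, 900):
        rec = make_record("r", blocks=((start, 2000),), read_length=2000 - start)
        fls.append(classify_read(rec, gene).is_full_length)
        assert fls[-1] >= previous
        previous = fls[-1]
    assert fls == [False, False, True, True]


# --------------------------------------------------------- simulator agreement


def test_fl_flag_equals_intact_5p_truth_at_zero_jitter():
    """With zero 3' jitter, FL is exactly equivalent to 'no 5' loss'."""
    cfg = SimConfig(seed=13, three_prime_jitter_sd=0.0, n_reads_per_protocol=600)
    res = simulate_run(cfg)
    index = AnnotationIndex(res.genes)
    for records, truths in res.libraries.values():
        truth = {t.read_id: t for t in truths}
        assignments = classify_alignments(records, index, manifest=truth.keys())
        for a in assignments:
            if a.uniqueness == "unique" and a.gene_id is not None:
                assert a.is_full_length == (truth[a.read_id].bases_lost_5p == 0)


def test_partition_totality_on_simulated_library(sim_default, sim_index):
    records, truths = sim_default.libraries["cap_dependent"]
    manifest = [t.read_id for t in truths]
    assignments = classify_alignments(records, sim_index, manifest=manifest)
    classes = {a.read_id: a.uniqueness for a in assignments}
    assert set(classes) == set(manifest)
    assert set(classes.values()) <= {"unique", "multi", "unaligned", "filtered"}
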