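"""Homeolog-hit flagging and best-alignment-match resolution."""

import itertools

import pytest
from helpers import make_gene, make_record

from flreads import AnnotationIndex, SimConfig, simulate_run
from flreads.homeologs import (
    flag_homeolog_hits,
    multi_homeolog_reads,
    resolve_best_match,
    resolve_homeologs,
)
from flreads.models import HomeologGroup


@pytest.fixture()
def triplet_world():
    """Three homeologous copies of one gene on three chromosomes, plus an
    unrelated gene."""
    g1a = make_gene("G1A", "chr1", "+", ((1000, 3000),))
    g1b = make_gene("G1B", "chr2", "+", ((1000, 3000),))
    g1d = make_gene("G1D", "chr3", "+", ((1000, 3000),))
    g7 = make_gene("G7D", "chr1", "+", ((9000, 11000),))
    genes = [g1a, g1b, g1d, g7]
    groups = [HomeologGroup("HG001", frozenset({"G1A", "G1B", "G1D"}))]
    return AnnotationIndex(genes), groups


def rec_at(read_id, chrom, start, end, identity=1.0, read_length=None, primary=True):
    return make_record(
        read_id, chrom=chrom, blocks=((start, end),), identity=identity,
        read_length=read_length, is_primary=primary,
    )


def test_flag_same_group_hits(triplet_world):
    index, groups = triplet_world
    records = [
        rec_at("r1", "chr1", 1000, 3000),
        rec_at("r1", "chr2", 1000, 2940, primary=False),
    ]
    hits = flag_homeolog_hits(records, groups, index)
    assert hits["r1"] == {("G1A", "HG001"), ("G1B", "HG001")}
    assert multi_homeolog_reads(hits) == {"r1"}


def test_hits_in_different_groups_not_homeolog_ambiguous(triplet_world):
    index, groups = triplet_world
    records = [
        rec_at("r1", "chr1", 1000, 3000),
        rec_at("r1", "chr1", 9000, 11000, primary=False),  # G7D, not in any triplet with G1A
    ]
    hits = flag_homeolog_hits(records, groups, index)
    assert multi_homeolog_reads(hits) == set()


def test_single_locus_read_not_flagged(triplet_world):
    index, groups = triplet_world
    hits = flag_homeolog_hits([rec_at("r1", "chr1", 1000, 3000)], groups, index)
    assert multi_homeolog_reads(hits) == set()


def test_resolve_best_match_minimal_d(triplet_world):
    """d = read_length - alignment length; the smaller d wins regardless of
    which candidate has the higher identity margin."""
    index, _ = triplet_world
    records = [
        rec_at("r1", "chr1", 1000, 2990, identity=0.99, read_length=2000, ),
        rec_at("r1", "chr2", 1000, 2900, identity=0.97, read_length=2000, primary=False),
    ]
    # aln lengths 1990 and 1900 -> d = 10 vs 100
    res = resolve_best_match(records, index)
    assert res.status == "resolved"
    assert res.gene_id == "G1A"


def test_resolve_tie_is_ambiguous(triplet_world):
    index, _ = triplet_world
    records = [
        rec_at("r1", "chr1", 1000, 2990, identity=0.99, read_length=2000),
        rec_at("r1", "chr2", 1000, 2990, identity=0.95, read_length=2000, primary=False),
    ]
    res = resolve_best_match(records, index)
    assert res.status == "ambiguous"
    assert res.gene_id is None


def test_resolve_all_below_identity_is_filtered(triplet_world):
    index, _ = triplet_world
    records = [
        rec_at("r1", "chr1", 1000, 2990, identity=0.89, read_length=2000),
        rec_at("r1", "chr2", 1000, 2990, identity=0.88, read_length=2000, primary=False),
    ]
    assert resolve_best_match(records, index).status == "filtered"


def test_resolution_is_permutation_invariant(triplet_world):
    index, _ = triplet_world
    records = [
        rec_at("r1", "chr1", 1000, 2990, identity=0.99, read_length=2000),
        rec_at("r1", "chr2", 1000, 2900, identity=0.97, read_length=2000, primary=False),
        rec_at("r1", "chr3", 1000, 2800, identity=0.95, read_length=2000, primary=False),
    ]
    outcomes = {
        (resolve_best_match(list(perm), index).status,
         resolve_best_match(list(perm), index).gene_id)
        for perm in itertools.permutations(records)
    }
    assert outcomes == {("resolved", "G1A")}


def test_simulated_multi_homeolog_reads_resolve_to_truth():
    """On simulator fixtures the true locus always has strictly minimal d,
    so best-match resolution recovers it for every flagged read."""
    cfg = SimConfig(seed=19, n_genes=20, n_homeolog_triplets=6,
                    p_homeolog_multimap=1.0, n_reads_per_protocol=400)
    res = simulate_run(cfg)
    index = AnnotationIndex(res.genes)
    records, truths = res.libraries["template_switch"]
    truth = {t.read_id: t.gene_id for t in truths}
    table, summary = resolve_homeologs(records, res.groups, index)
    assert summary["n_multi_homeolog"] >= 50
    assert summary["n_ambiguous"] == 0
    resolved = table[table.status == "resolved"]
    assert len(resolved) == summary["n_multi_homeolog"]
    assert all(row.resolved_gene == truth[row.read_id] for row in resolved.itertuples())


def test_promote_resolved_reclassifies_multi_reads(triplet_world):
    """Opt-in promotion turns a resolved multi-homeolog read into a unique
    assignment against its resolved gene."""
    from flreads.classify import classify_alignments
    from flreads.homeologs import promote_resolved, resolve_best_match

    index, _groups = triplet_world
    records = [
        rec_at("r1", "chr1", 1000, 3000, read_length=2000),
        rec_at("r1", "chr2", 1000, 2940, read_length=2000, primary=False),
    ]
    assignments = classify_alignments(records, index)
    assert assignments[0].uniqueness == "multi"
    resolution = resolve_best_match(records, index)
    promoted = promote_resolved(assignments, [resolution], index, records)
    assert promoted[0].uniqueness == "unique"
    assert promoted[0].gene_id == "G1A"
    assert promoted[0].is_full_length


def test_ambiguity_never_exceeds_flagged_count(triplet_world):
    index, groups = triplet_world
    records = [
        rec_at("r1", "chr1", 1000, 3000),
        rec_at("r1", "chr2", 1000, 2940, primary=False),
        rec_at("r2", "chr2", 1000, 3000),
        rec_at("r2", "chr3", 1000, 2940, primary=False),
    ]
    _table, summary = resolve_homeologs(records, groups, index)
    assert summary["n_resolved"] + summary["n_ambiguous"] + summary["n_filtered"] == summary["n_multi_homeolog"]
    assert summary["n_ambiguous"] <= summary["n_multi_homeolog"]
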