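"""Offset histograms and the Mann-Whitney rank test, checked against
independent enumeration and scipy."""

import numpy as np
import pytest
from helpers import brute_force_mw, make_assignment, pair_count_u
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from flreads.profiling import build_profile, compare_protocols, mann_whitney


# -------------------------------------------------------------------- profile


def test_profile_zero_offsets_land_in_first_positive_bin():
    prof = build_profile([0, 0, 0], "TSS")
    idx = np.searchsorted(prof.bin_edges, 0)
    assert prof.counts[idx] == 3  # bin [0, 50)
    assert prof.n_outside == 0
    assert prof.n_in_window == 3


def test_profile_window_boundary():
    prof = build_profile([10000, 10001, -10001], "TSS")
    assert prof.n_in_window == 1
    assert prof.n_outside == 2


def test_profile_sign_split_and_count_conservation():
    prof = build_profile([-25, 25], "TSS", bin_width=50)
    zero = np.searchsorted(prof.bin_edges, 0)
    assert prof.counts[zero - 1] == 1 and prof.counts[zero] == 1
    assert prof.counts.sum() == prof.n_in_window
    assert prof.n_in_window + prof.n_outside == 2


def test_profile_anchored_fraction_semantics():
    tss = build_profile([-10, 0, 5, 20], "TSS")
    assert tss.anchored_fraction == pytest.approx(0.5)  # <= 0 for TSS
    tes = build_profile([-10, 0, 5, 20], "TES")
    assert tes.anchored_fraction == pytest.approx(0.75)  # >= 0 for TES


def test_profile_rejects_bad_bin_width():
    with pytest.raises(ValueError):
        build_profile([0], "TSS", bin_width=0)


# --------------------------------------------------------------- mann-whitney


@pytest.mark.parametrize(
    "a,b,u,p",
    [
        ([1, 2, 3], [4, 5, 6], 0.0, 0.1),       # 2 of C(6,3)=20 labelings as extreme
        ([1, 3], [2, 4], 1.0, 2.0 / 3.0),       # 4 of C(4,2)=6 labelings
    ],
)
def test_mann_whitney_exact_frozen_examples(a, b, u, p):
    got_u, got_p = mann_whitney(a, b, mode="exact")
    assert got_u == u
    assert got_p == pytest.approx(p)


def test_mann_whitney_identical_samples_p_one():
    u, p = mann_whitney([1, 2, 2, 5], [1, 2, 2, 5])
    assert p == 1.0


def test_mann_whitney_rejects_empty_sample():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


@settings(deadline=None, derandomize=True)
@given(
    a=st.lists(st.integers(0, 9), min_size=1, max_size=6),
    b=st.lists(st.integers(0, 9), min_size=1, max_size=6),
)
def test_mann_whitney_symmetry_and_u_sum(a, b):
    """U and p are symmetric in the samples; U_a + U_b == n*m with ties
    counted half to each side."""
    u_ab, p_ab = mann_whitney(a, b)
    u_ba, p_ba = mann_whitney(b, a)
    assert u_ab == u_ba
    assert p_ab == pytest.approx(p_ba)
    assert pair_count_u(a, b) + pair_count_u(b, a) == pytest.approx(len(a) * len(b))


def test_mann_whitney_exact_matches_brute_force_with_ties():
    rng = np.random.default_rng(42)
    for _ in range(25):
        n, m = rng.integers(1, 7, size=2)
        a = rng.integers(0, 8, size=n).tolist()
        b = rng.integers(0, 8, size=m).tolist()
        u_ref, p_ref = brute_force_mw(a, b)
        u, p = mann_whitney(a, b, mode="exact")
        assert u == u_ref
        assert p == pytest.approx(p_ref, abs=1e-12)


def test_mann_whitney_exact_matches_scipy_without_ties():
    """Independent cross-check: for tie-free data the permutation p equals
    scipy's exact two-sided p."""
    rng = np.random.default_rng(7)
    for n, m in [(5, 5), (8, 12), (30, 30)]:
        a, b = rng.normal(size=n), rng.normal(1.0, 1.0, size=m)
        _, p = mann_whitney(a, b, mode="exact")
        ref = mannwhitneyu(a, b, method="exact", alternative="two-sided").pvalue
        assert p == pytest.approx(ref, abs=1e-10)


def test_mann_whitney_exact_and_normal_agree_at_n30():
    rng = np.random.default_rng(123)
    for _ in range(5):
        a, b = rng.normal(size=30), rng.normal(0.3, 1.0, size=30)
        _, p_exact = mann_whitney(a, b, mode="exact")
        _, p_norm = mann_whitney(a, b, mode="normal_approx")
        assert abs(p_exact - p_norm) < 0.02


def test_mann_whitney_exact_mode_with_large_tied_samples_errors():
    a = [1] * 50
    b = [1] * 50
    with pytest.raises(ValueError, match="exact mode with ties"):
        mann_whitney(a, b, mode="exact")


# ------------------------------------------------------------------ comparison


def _assignments_with_offsets(offsets, fraction="1-2kb", fl=False, prefix="r"):
    out = []
    for i, off in enumerate(offsets):
        a = make_assignment(f"{prefix}{i}", end5=1000 + off, end3=2000, read_length=1500)
        a.five_prime_offset = off
        a.three_prime_offset = 0
        a.size_fraction = fraction
        a.is_full_length = fl
        out.append(a)
    return out


def test_compare_identical_inputs_gives_p_one_everywhere():
    asg = _assignments_with_offsets([0, 10, 30, 50, -5])
    table = compare_protocols(asg, asg, label_a="A", label_b="B")
    filled = table.dropna(subset=["p_value"])
    assert not filled.empty
    assert (filled["p_value"] == 1.0).all()
    assert (filled["fl_pct_A"] == filled["fl_pct_B"]).all()


def test_compare_empty_fraction_yields_na_row_and_warning():
    a = _assignments_with_offsets([0, 1, 2], fraction="1-2kb", prefix="a")
    b = _assignments_with_offsets([5, 6, 7], fraction="2-3kb", prefix="b")
    with pytest.warns(UserWarning, match="empty in one protocol"):
        table = compare_protocols(a, b, label_a="A", label_b="B")
    row = table[(table.size_fraction == "1-2kb") & (table.anchor == "TSS")].iloc[0]
    assert np.isnan(row["p_value"])


def test_compare_bonferroni_scales_fraction_pvalues():
    a = _assignments_with_offsets([0, 1, 2, 3, 4], prefix="a")
    b = _assignments_with_offsets([10, 11, 12, 13, 14], prefix="b")
    raw = compare_protocols(a, b, label_a="A", label_b="B")
    adj = compare_protocols(a, b, label_a="A", label_b="B", bonferroni=True)
    raw_f = raw[(raw.size_fraction == "1-2kb") & (raw.anchor == "TSS")].iloc[0]
    adj_f = adj[(adj.size_fraction == "1-2kb") & (adj.anchor == "TSS")].iloc[0]
    n_tests = ((raw.size_fraction != "all") & raw.p_value.notna()).sum()
    assert adj_f.p_value == pytest.approx(min(1.0, raw_f.p_value * n_tests))
    # 'all' rows stay uncorrected
    assert adj[adj.size_fraction == "all"].p_value.equals(raw[raw.size_fraction == "all"].p_value)


def test_compare_cap_dependent_median_never_larger(sim_default, sim_index):
    """Under the generative contrast, the cap-selected library's median 5'
    offset never exceeds the template-switch one in any populated fraction."""
    from flreads.classify import classify_alignments

    asg = {}
    for protocol, (records, truths) in sim_default.libraries.items():
        asg[protocol] = classify_alignments(
            records, sim_index, manifest=[t.read_id for t in truths]
        )
    table = compare_protocols(asg["cap_dependent"], asg["template_switch"])
    tss = table[(table.anchor == "TSS")].dropna(subset=["p_value"])
    assert (tss["median_cap_dependent"] <= tss["median_template_switch"]).all()
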