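"""End-offset profiling and protocol comparison.

Histograms of signed 5'/3' alignment-end offsets within a window around the
annotated TSS/TES, per size fraction, and a Mann-Whitney rank test
comparing two protocols' offset distributions.

The Mann-Whitney statistic here is U = min(U_a, U_b) with
U_a = #{(a,b): a < b} + 1/2 #ties. The exact two-sided p-value is the
permutation probability P(min(U_a, U_b) <= U_observed) over all
C(n+m, n) equally likely group labelings of the pooled sample. For small
problems it is computed by full enumeration (ties handled exactly); for
larger tie-free samples by the classical U-distribution counting
recurrence, which is equivalent to enumeration; otherwise by a normal
approximation with tie-corrected variance and continuity correction.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .models import ReadAssignment, SIZE_FRACTIONS

ENUMERATION_LIMIT = 100_000  # max C(n+m, n) labelings for full enumeration


@dataclass
class OffsetProfile:
    """Histogram of signed end offsets around an anchor (TSS or TES)."""

    anchor: str
    size_fraction: str
    bin_width: int
    window: int
    bin_edges: np.ndarray
    counts: np.ndarray
    n_in_window: int
    n_outside: int
    anchored_fraction: float  # fraction at/upstream of TSS, or at/downstream of TES


def build_profile(
    offsets: Sequence[int],
    anchor: str,
    size_fraction: str = "all",
    bin_width: int = 50,
    window: int = 10000,
) -> OffsetProfile:
    """Bin signed offsets into half-open bins with one edge exactly at 0.

    Offsets with \\|offset\\| <= window are binned; the rest are counted in
    ``n_outside``. The anchored fraction is, over all supplied offsets, the
    share at or upstream of the anchor (<= 0) for TSS, or at or downstream
    (>= 0) for TES.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if anchor not in ("TSS", "TES"):
        raise ValueError(f"anchor must be TSS or TES, got {anchor!r}")
    arr = np.asarray(offsets, dtype=float)
    nbins_side = int(math.ceil(window / bin_width))
    edges = np.arange(-nbins_side, nbins_side + 2) * bin_width  # covers [-w, w] incl.
    in_window = arr[np.abs(arr) <= window]
    counts, _ = np.histogram(in_window, bins=edges)
    if arr.size:
        anchored = float(np.mean(arr <= 0)) if anchor == "TSS" else float(np.mean(arr >= 0))
    else:
        anchored = float("nan")
    return OffsetProfile(
        anchor=anchor,
        size_fraction=size_fraction,
        bin_width=bin_width,
        window=window,
        bin_edges=edges,
        counts=counts,
        n_in_window=int(in_window.size),
        n_outside=int(arr.size - in_window.size),
        anchored_fraction=anchored,
    )


def profile_to_frame(profile: OffsetProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_start": profile.bin_edges[:-1],
            "bin_end": profile.bin_edges[1:],
            "count": profile.counts,
        }
    )


# ---------------------------------------------------------------------------
# Mann-Whitney


def _u_less(a: np.ndarray, b: np.ndarray) -> float:
    """U_a = #{(a,b): a < b} + 1/2 #ties, via the rank-sum identity."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # average ranks
    r_a = ranks[: a.size].sum()
    n, m = a.size, b.size
    u_greater = r_a - n * (n + 1) / 2.0  # #{a > b} + 1/2 ties
    return n * m - u_greater


def _exact_enumeration(pooled: np.ndarray, n: int, u_obs: float) -> float:
    """P(min(U_a, U_b) <= u_obs) over all labelings, by full enumeration."""
    N = pooled.size
    m = N - n
    ranks = rankdata(pooled)
    total = math.comb(N, n)
    hits = 0
    offset = n * (n + 1) / 2.0
    for idx in combinations(range(N), n):
        r_a = sum(ranks[i] for i in idx)
        u_greater = r_a - offset
        u_min = min(u_greater, n * m - u_greater)
        if u_min <= u_obs + 1e-9:
            hits += 1
    return hits / total


def _exact_no_ties(n: int, m: int, u_obs: float) -> float:
    """Exact p for tie-free data via the U-distribution counting recurrence.

    count[u] after processing is the number of labelings with U_a = u;
    p = min(1, 2 * P(U <= u_obs)), which equals the enumeration definition
    P(min(U_a, U_b) <= u_obs) for tie-free samples.
    """
    max_u = n * m
    # f(i, j, u): ways to interleave i 'a's and j 'b's with statistic u
    prev = np.zeros((m + 1, max_u + 1))
    prev[:, 0] = 1.0  # i == 0
    for i in range(1, n + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for j in range(1, m + 1):
            cur[j] = cur[j - 1].copy()
            shifted = np.roll(prev[j], j)
            shifted[:j] = 0.0
            cur[j] += shifted
        prev = cur
    counts = prev[m]
    total = counts.sum()
    k = int(math.floor(u_obs + 1e-9))
    p = 2.0 * counts[: k + 1].sum() / total
    return min(1.0, p)


def _normal_approx(pooled: np.ndarray, n: int, m: int, u_obs: float) -> float:
    N = n + m
    mu = n * m / 2.0
    tie_counts = np.array(list(Counter(pooled.tolist()).values()), dtype=float)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (u_obs - mu + 0.5) / math.sqrt(var)  # continuity correction toward the mean
    return min(1.0, 2.0 * norm.cdf(z))


def mann_whitney(
    sample_a: Sequence[float], sample_b: Sequence[float], mode: str = "auto"
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (U, p) with U = min(U_a, U_b).

    ``mode``: ``exact`` (enumeration, or the counting recurrence for
    tie-free data too large to enumerate), ``normal_approx``, or ``auto``
    (enumeration when C(n+m, n) <= 1e5, else the normal approximation).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    n, m = a.size, b.size
    u_a = _u_less(a, b)
    u_b = n * m - u_a
    u_obs = min(u_a, u_b)
    pooled = np.concatenate([a, b])
    small = math.comb(n + m, n) <= ENUMERATION_LIMIT

    if mode == "normal_approx" or (mode == "auto" and not small):
        return u_obs, _normal_approx(pooled, n, m, u_obs)
    if small:
        return u_obs, _exact_enumeration(pooled, n, u_obs)
    # mode == "exact", too large to enumerate
    if np.unique(pooled).size == pooled.size:
        return u_obs, _exact_no_ties(n, m, u_obs)
    raise ValueError(
        "exact mode with ties requires C(n+m, n) <= "
        f"{ENUMERATION_LIMIT}; use mode='auto' or 'normal_approx'"
    )


# ---------------------------------------------------------------------------
# Protocol comparison


def _assigned(assignments: Sequence[ReadAssignment]) -> List[ReadAssignment]:
    return [a for a in assignments if a.uniqueness == "unique" and a.gene_id is not None]


def compare_protocols(
    assignments_a: Sequence[ReadAssignment],
    assignments_b: Sequence[ReadAssignment],
    label_a: str = "cap_dependent",
    label_b: str = "template_switch",
    mode: str = "auto",
    fractions: Sequence[str] = SIZE_FRACTIONS,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per size fraction and per anchor: sample sizes, median offsets,
    Mann-Whitney U and p, and FL% per protocol. The last row ('all')
    aggregates every fraction.

    Fractions empty in either protocol yield a row with NaN p and a warning.
    With ``bonferroni`` the per-fraction p-values (not the 'all' rows) are
    multiplied by the number of populated fraction/anchor tests, capped at 1.
    """
    a_all = _assigned(assignments_a)
    b_all = _assigned(assignments_b)
    rows = []
    for fraction in list(fractions) + ["all"]:
        if fraction == "all":
            sub_a, sub_b = a_all, b_all
        else:
            sub_a = [x for x in a_all if x.size_fraction == fraction]
            sub_b = [x for x in b_all if x.size_fraction == fraction]
        for anchor, attr in (("TSS", "five_prime_offset"), ("TES", "three_prime_offset")):
            off_a = [getattr(x, attr) for x in sub_a]
            off_b = [getattr(x, attr) for x in sub_b]
            row: Dict[str, object] = {
                "size_fraction": fraction,
                "anchor": anchor,
                f"n_{label_a}": len(off_a),
                f"n_{label_b}": len(off_b),
                f"median_{label_a}": float(np.median(off_a)) if off_a else float("nan"),
                f"median_{label_b}": float(np.median(off_b)) if off_b else float("nan"),
                f"fl_pct_{label_a}": (
                    100.0 * np.mean([x.is_full_length for x in sub_a]) if sub_a else float("nan")
                ),
                f"fl_pct_{label_b}": (
                    100.0 * np.mean([x.is_full_length for x in sub_b]) if sub_b else float("nan")
                ),
            }
            if off_a and off_b:
                u, p = mann_whitney(off_a, off_b, mode=mode)
                row["U"] = u
                row["p_value"] = p
            else:
                if off_a or off_b:
                    warnings.warn(
                        f"size fraction {fraction!r} empty in one protocol; p set to NA"
                    )
                row["U"] = float("nan")
                row["p_value"] = float("nan")
            rows.append(row)
    table = pd.DataFrame(rows)
    if bonferroni:
        tested = (table.size_fraction != "all") & table.p_value.notna()
        table.loc[tested, "p_value"] = (table.loc[tested, "p_value"] * tested.sum()).clip(upper=1.0)
    return table
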