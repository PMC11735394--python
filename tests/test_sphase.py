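"""RTP computation, directional statistics and the permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scphase.segment import segment_cell
from scphase.sphase import (
    SPhaseCall,
    compute_rtp,
    correct_multiple_testing,
    permutation_test,
    sphase_statistic,
)


def _table(chrom_blocks):
    """Build an rtp table from (chrom_ix, rtp array, timing array) blocks."""
    rows = []
    for ci, rtp, timing in chrom_blocks:
        rows.append(
            pd.DataFrame(
                {"chrom_ix": ci, "rtp": rtp, "timing": timing, "testable": True}
            )
        )
    return pd.concat(rows, ignore_index=True)


def test_rtp_removes_cna_signal(cna_g1_batch):
    res, genome, cells = cna_g1_batch
    for cw in cells[:3]:
        seg = segment_cell(cw, genome)
        t = compute_rtp(cw, seg)
        # the cn=3 region's rtp sits at 1 like everywhere else
        tt = t[t["testable"]]
        on_gain = (tt["first_bin"] >= 550) & (tt["first_bin"] < 630)
        assert abs(tt.loc[on_gain, "rtp"].median() - 1.0) < 0.05
        assert abs(tt.loc[~on_gain, "rtp"].median() - 1.0) < 0.05


def test_rtp_invariant_to_count_scaling(cna_g1_batch):
    from scphase.signals import build_windows, compute_rdr

    res, genome, _ = cna_g1_batch
    c0 = res.counts[:, 0]
    a = compute_rdr(build_windows("a", c0, genome))
    b = compute_rdr(build_windows("b", c0 * 10, genome))
    a.windows["rdr_corr"] = a.windows["rdr_raw"]
    b.windows["rdr_corr"] = b.windows["rdr_raw"]
    ta = compute_rtp(a, segment_cell(a, genome))
    tb = compute_rtp(b, segment_cell(b, genome))
    assert np.allclose(ta["rtp"].to_numpy(), tb["rtp"].to_numpy(), atol=1e-9)


def test_statistic_matches_direct_enumeration():
    # 10-value toy: count early values strictly above the late 0.75-order
    # statistic, computed here independently by brute force
    rtp = np.array([1.3, 0.8, 1.1, 0.9, 1.4, 0.7, 1.0, 1.2, 0.85, 0.95])
    timing = np.array(
        ["early", "late", "early", "late", "early", "late", "early", "late", "late", "late"],
        dtype=object,
    )
    late_vals = np.sort(rtp[timing == "late"])
    j = int(np.ceil(0.75 * late_vals.size))
    margin = late_vals[j - 1]
    expected = np.mean(rtp[timing == "early"] > margin)
    assert sphase_statistic(rtp, timing, "early_high", 0.75) == pytest.approx(expected)
    # complete separation
    rtp2 = np.where(timing == "early", 1.3, 0.8)
    assert sphase_statistic(rtp2, timing, "early_high", 0.75) == 1.0
    # all values identical: strict exceedance gives 0
    assert sphase_statistic(np.ones(10), timing, "early_high", 0.75) == 0.0


def test_strong_mid_s_cell_reaches_minimum_p():
    rng = np.random.default_rng(0)
    blocks = []
    for ci in range(4):
        timing = np.array(["early"] * 20 + ["late"] * 20, dtype=object)
        rtp = np.where(timing == "early", 1.5, 0.75) + rng.normal(0, 0.02, 40)
        blocks.append((ci, rtp, timing))
    call = permutation_test(_table(blocks), 2000, seed=1)
    assert call.p_raw == pytest.approx(1 / 2001)


def test_refuses_too_few_permutations():
    with pytest.raises(ValueError):
        permutation_test(_table([]), 50, seed=0)


def test_exact_rank_sampler_agrees_with_literal_shuffles():
    rng = np.random.default_rng(5)
    blocks = []
    for ci in range(3):
        timing = np.array(["early"] * 14 + ["late"] * 16, dtype=object)
        rng.shuffle(timing)
        blocks.append((ci, rng.normal(1, 0.1, 30), timing))
    t = _table(blocks)
    p_fast = permutation_test(t, 3000, seed=7, include_mean_diff=False).p_raw
    p_slow = permutation_test(
        t, 3000, seed=8, method="shuffle", include_mean_diff=False
    ).p_raw
    assert abs(p_fast - p_slow) < 0.06


def test_invariance_to_rank_preserving_transform():
    rng = np.random.default_rng(9)
    blocks = []
    for ci in range(3):
        timing = np.array(["early"] * 15 + ["late"] * 15, dtype=object)
        rng.shuffle(timing)
        blocks.append((ci, rng.normal(1, 0.1, 30), timing))
    t = _table(blocks)
    t2 = t.copy()
    t2["rtp"] = np.exp(t2["rtp"])  # strictly monotone, rank-preserving
    p1 = permutation_test(t, 2000, seed=3, include_mean_diff=False).p_raw
    p2 = permutation_test(t2, 2000, seed=3, include_mean_diff=False).p_raw
    assert p1 == pytest.approx(p2)


def test_monte_carlo_matches_exhaustive_enumeration():
    # single small chromosome: exhaustive p over all C(10,5) assignments
    rng = np.random.default_rng(11)
    rtp = rng.normal(1, 0.1, 10)
    timing = np.array(["early"] * 5 + ["late"] * 5, dtype=object)
    obs = sphase_statistic(rtp, timing, "early_high", 0.75)
    stats = []
    for pos in itertools.combinations(range(10), 5):
        lab = np.array(["late"] * 10, dtype=object)
        lab[list(pos)] = "early"
        stats.append(sphase_statistic(rtp, lab, "early_high", 0.75))
    p_exact = np.mean(np.array(stats) >= obs - 1e-12)
    t = _table([(0, rtp, timing)])
    call = permutation_test(
        t,
        100_000,
        seed=4,
        margin_quantile=0.75,
        min_testable_chromosomes=1,
        include_mean_diff=False,
    )
    mc_se = np.sqrt(p_exact * (1 - p_exact) / 100_000)
    assert abs(call.p_early - p_exact) <= 3 * mc_se + 1e-4


def test_holm_sidak_closed_form_and_monotonicity():
    calls = [
        SPhaseCall(f"c{i}", 0, 0, p, p, p, 4) for i, p in enumerate([0.001, 0.02, 0.4])
    ]
    out = correct_multiple_testing(calls, fwer=0.05)
    expected = [1 - 0.999**3, max(1 - 0.999**3, 1 - 0.98**2), 0.4]
    assert np.allclose(np.sort(out["p_adjusted"]), expected, atol=1e-6)
    assert (np.diff(out.sort_values("p_raw")["p_adjusted"]) >= -1e-12).all()
    assert out["is_s_phase"].sum() == 2
    # single cell: adjusted equals raw
    single = correct_multiple_testing([SPhaseCall("x", 0, 0, 0.03, 0.03, 0.03, 4)])
    assert single["p_adjusted"].iloc[0] == pytest.approx(0.03)
    # all p = 1: nothing called
    ones = correct_multiple_testing(
        [SPhaseCall(f"y{i}", 0, 0, 1.0, 1.0, 1.0, 4) for i in range(5)]
    )
    assert not ones["is_s_phase"].any()
    # empty input
    assert correct_multiple_testing([]).empty
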