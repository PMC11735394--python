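"""Clone fraction summaries, heterogeneity testing and ART calls."""

import numpy as np
import pandas as pd
import pytest

from scphase.summaries import infer_clone_art, summarize_clone_fractions
from scphase.summaries import test_within_sample_heterogeneity as heterogeneity_test


def _phases(clone_counts):
    rows = []
    i = 0
    for clone, (n_s, n_g2, n_g1) in clone_counts.items():
        for ph, n in (("S", n_s), ("G2", n_g2), ("G1", n_g1)):
            for _ in range(n):
                rows.append({"cell_id": f"c{i}", "clone_id": clone, "phase": ph})
                i += 1
    return pd.DataFrame(rows)


def test_fractions_are_exact_ratios_and_g2s_ratio():
    t = summarize_clone_fractions(_phases({0: (10, 5, 85)}), n_boot=50, seed=0)
    r = t.iloc[0]
    assert r["s_fraction"] == pytest.approx(0.10)
    assert r["g2_fraction"] == pytest.approx(0.05)
    assert r["g2_s_ratio"] == pytest.approx(0.5)
    # zero S cells: ratio undefined
    t0 = summarize_clone_fractions(_phases({0: (0, 5, 95)}), n_boot=50, seed=0)
    assert np.isnan(t0.iloc[0]["g2_s_ratio"])


def test_degenerate_all_s_clone_has_point_interval():
    t = summarize_clone_fractions(_phases({0: (30, 0, 0)}), n_boot=100, seed=1)
    assert t.iloc[0]["s_ci_low"] == 1.0
    assert t.iloc[0]["s_ci_high"] == 1.0


def test_bootstrap_is_deterministic_given_seed():
    p = _phases({0: (12, 3, 85), 1: (5, 2, 93)})
    a = summarize_clone_fractions(p, n_boot=100, seed=7)
    b = summarize_clone_fractions(p, n_boot=100, seed=7)
    pd.testing.assert_frame_equal(a, b)


def test_chi_square_matches_hand_computed_two_by_two():
    # clone A 40 S / 60 non-S vs rest 10 S / 90 non-S
    summary = pd.DataFrame(
        {
            "sample_id": ["s", "s"],
            "clone_id": [0, 1],
            "n_s": [40, 10],
            "n_cells": [100, 100],
        }
    )
    out = heterogeneity_test(summary, fwer=0.1)
    table = np.array([[40, 60], [10, 90]])
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    chi2 = ((table - expected) ** 2 / expected).sum()
    assert out.loc[out["clone_id"] == 0, "statistic"].iloc[0] == pytest.approx(chi2)
    assert out["significant"].all()


def test_identical_fractions_not_significant():
    summary = pd.DataFrame(
        {
            "sample_id": ["s", "s"],
            "clone_id": [0, 1],
            "n_s": [30, 30],
            "n_cells": [100, 100],
        }
    )
    out = heterogeneity_test(summary, fwer=0.1)
    assert not out["significant"].any()


def test_small_expected_counts_use_exact_test():
    summary = pd.DataFrame(
        {
            "sample_id": ["s", "s"],
            "clone_id": [0, 1],
            "n_s": [2, 1],
            "n_cells": [20, 25],
        }
    )
    out = heterogeneity_test(summary, fwer=0.1)
    assert out["exact_test"].all()


def test_null_heterogeneity_calibration():
    rng = np.random.default_rng(5)
    flagged = 0
    trials = 200
    for t in range(trials):
        n_s = rng.binomial(100, 0.2, size=3)
        summary = pd.DataFrame(
            {
                "sample_id": "s",
                "clone_id": range(3),
                "n_s": n_s,
                "n_cells": [100] * 3,
            }
        )
        out = heterogeneity_test(summary, fwer=0.1)
        flagged += int(out["significant"].any())
    # family-wise flag rate within binomial error of the 0.1 target
    assert flagged / trials <= 0.1 + 3 * np.sqrt(0.1 * 0.9 / trials)


def test_art_requires_confident_contradiction():
    rng = np.random.default_rng(6)
    ref = np.array(["early"] * 400 + ["late"] * 400 + ["unknown"] * 200, dtype=object)
    # clone-average rtp faithful to the reference: high where early
    rtp = np.where(ref == "early", 1.5, 0.8) + rng.normal(0, 0.05, 1000)
    out = infer_clone_art(rtp, ref, confidence=0.9, seed=0)
    assert (out.loc[ref == "unknown", "art"] == "none").all()
    assert (out["art"] != "none").mean() <= 0.01
    # flip a contiguous block late->early in the clone signal
    rtp2 = rtp.copy()
    rtp2[400:500] = 1.5 + rng.normal(0, 0.05, 100)
    out2 = infer_clone_art(rtp2, ref, confidence=0.9, seed=0)
    assert (out2.loc[400:499, "art"] == "late_to_early").mean() >= 0.8


def test_art_refuses_without_enough_s_cells():
    with pytest.raises(ValueError):
        infer_clone_art(np.ones(10), np.array(["early"] * 10), min_s_cells_met=False)
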