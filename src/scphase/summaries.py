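"""Clone-level phenotypes: S/G2 fractions, heterogeneity tests and ART.

The S fraction of a clone (S cells over all member cells) proxies its
proliferation rate; the G2/S ratio tracks the relative length of the two
phases.  Uncertainty comes from a percentile bootstrap over cells (300
repeats by default).  Within a sample, each clone's S count is compared to
the rest of the sample with a two-sided chi-square test on the 2x2 table
(exact test fallback when expected counts are small) and clones are flagged
after Benjamini-Hochberg correction at rate 0.1.

Altered replication timing (ART) re-derives per-bin timing classes from a
clone's own S-phase cells -- their clone-average replication timing profile
is bimodal exactly like a replication score -- and calls ART where the clone
classification confidently contradicts the reference timing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact
from statsmodels.stats.multitest import multipletests

from .genome import EARLY, LATE, UNKNOWN, classify_replication_timing

ART_NONE = "none"
ART_EARLY_TO_LATE = "early_to_late"
ART_LATE_TO_EARLY = "late_to_early"


def summarize_clone_fractions(
    phases: pd.DataFrame,
    n_boot: int = 300,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-clone S/G2 fractions with percentile bootstrap confidence intervals.

    ``phases`` columns: ``cell_id``, ``clone_id``, ``phase`` in {G1, S, G2}
    and optionally ``sample_id``.  Clones with zero cells are excluded; a
    zero S count flags the G2/S ratio as undefined (NaN).
    """
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    group_cols = ["clone_id"]
    if "sample_id" in phases.columns:
        group_cols = ["sample_id", "clone_id"]
    for key, sub in phases.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        is_s = (sub["phase"] == "S").to_numpy()
        is_g2 = (sub["phase"] == "G2").to_numpy()
        n = len(sub)
        if n == 0:
            continue
        boots_s = np.empty(n_boot)
        boots_g2 = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            boots_s[b] = is_s[idx].mean()
            boots_g2[b] = is_g2[idx].mean()
        s_frac = is_s.mean()
        g2_frac = is_g2.mean()
        rows.append(
            {
                **dict(zip(group_cols, key)),
                "n_cells": n,
                "n_s": int(is_s.sum()),
                "n_g2": int(is_g2.sum()),
                "s_fraction": s_frac,
                "g2_fraction": g2_frac,
                "s_ci_low": float(np.percentile(boots_s, lo_q)),
                "s_ci_high": float(np.percentile(boots_s, hi_q)),
                "g2_ci_low": float(np.percentile(boots_g2, lo_q)),
                "g2_ci_high": float(np.percentile(boots_g2, hi_q)),
                "g2_s_ratio": g2_frac / s_frac if s_frac > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def test_within_sample_heterogeneity(
    summary: pd.DataFrame,
    fwer: float = 0.1,
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Flag clones whose S fraction differs from the rest of their sample.

    For each clone in a sample with >= 2 clones, the 2x2 table
    [[clone S, clone non-S], [rest S, rest non-S]] is tested with a
    two-sided chi-square without continuity correction (Fisher's exact test
    when any expected count is below ``min_expected``, flagged).  Raw
    p-values are Benjamini-Hochberg corrected across all tested clones.
    """
    if "sample_id" not in summary.columns:
        summary = summary.assign(sample_id="sample")
    rows = []
    for sample, sub in summary.groupby("sample_id", sort=True):
        if len(sub) < 2:
            continue
        tot_s = sub["n_s"].sum()
        tot_n = sub["n_cells"].sum()
        for _, r in sub.iterrows():
            a, b = int(r["n_s"]), int(r["n_cells"] - r["n_s"])
            c, d = int(tot_s - r["n_s"]), int((tot_n - r["n_cells"]) - (tot_s - r["n_s"]))
            table = np.array([[a, b], [c, d]])
            exact = False
            if table.sum() == 0 or table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
                p = 1.0
                stat = 0.0
            else:
                expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
                if expected.min() < min_expected:
                    stat, p = fisher_exact(table, alternative="two-sided")
                    exact = True
                else:
                    stat, p, _, _ = chi2_contingency(table, correction=False)
            rows.append(
                {
                    "sample_id": sample,
                    "clone_id": r["clone_id"],
                    "statistic": float(stat),
                    "p_raw": float(p),
                    "exact_test": exact,
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(p_adjusted=pd.Series(dtype=float), significant=pd.Series(dtype=bool))
    reject, p_adj, _, _ = multipletests(out["p_raw"], alpha=fwer, method="fdr_bh")
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out


def clone_average_rtp(
    rtp_tables: list[pd.DataFrame],
    win_of_bin_list: list[np.ndarray],
    m: int,
) -> np.ndarray:
    """Average the RTP of a clone's S-phase cells onto bins (NaN where absent)."""
    total = np.zeros(m)
    count = np.zeros(m)
    for table, win_of_bin in zip(rtp_tables, win_of_bin_list):
        rtp = table["rtp"].to_numpy(dtype=float)
        mapped = win_of_bin >= 0
        vals = rtp[win_of_bin[mapped]]
        ok = np.isfinite(vals)
        idx = np.flatnonzero(mapped)[ok]
        total[idx] += vals[ok]
        count[idx] += 1.0
    with np.errstate(invalid="ignore"):
        avg = total / count
    avg[count == 0] = np.nan
    return avg


def infer_clone_art(
    clone_rtp: np.ndarray,
    reference_timing: np.ndarray,
    confidence: float = 0.9,
    min_s_cells_met: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin clone timing classes and ART calls versus the reference.

    ``clone_rtp`` is the clone-average RTP per bin (replicated bins high,
    unreplicated low across the clone's S cells); its two modes are
    classified with the same confident mixture procedure used for reference
    replication scores.  ART requires a confident clone class that
    contradicts a known reference class.
    """
    if not min_s_cells_met:
        raise ValueError("ART requires the clone to have enough S-phase cells")
    labels, info = classify_replication_timing(
        clone_rtp, confidence=confidence, seed=seed, min_mode_separation=0.5
    )
    ref = np.asarray(reference_timing, dtype=object)
    art = np.full(len(labels), ART_NONE, dtype=object)
    art[(labels == EARLY) & (ref == LATE)] = ART_LATE_TO_EARLY
    art[(labels == LATE) & (ref == EARLY)] = ART_EARLY_TO_LATE
    art[(labels == UNKNOWN) | (ref == UNKNOWN)] = ART_NONE
    return pd.DataFrame({"clone_timing": labels, "reference_timing": ref, "art": art})
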