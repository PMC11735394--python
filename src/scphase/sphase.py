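"""Per-cell S-phase identification via a replication-timing permutation test.

The replication timing profile (RTP) divides every window's RDR by the median
RDR of its copy-number segment, removing CNA signal.  In an S-phase cell,
replicated early windows sit above 1 and unreplicated late windows below 1,
so a subset of early windows exceeds the bulk of the late windows (and vice
versa).  Two directional statistics capture this per chromosome:

* ``early_high``: fraction of early windows strictly above the
  ``margin_quantile`` (default 0.75) order statistic of the late windows;
* ``late_low``: fraction of late windows strictly below the
  ``1 - margin_quantile`` order statistic of the early windows.

Timing labels are permuted within each chromosome; per-chromosome statistics
are combined across chromosomes with a harmonic mean (zeros floored at
``1/(2 * windows)``), the two directional p-values are combined with the
minimum, and Holm-Sidak controls the family-wise error rate across cells.

Because the statistics depend on the data only through within-chromosome
ranks, their permutation distribution is the distribution of the rank of an
order statistic of a uniformly random label subset, which follows a negative
hypergeometric law.  The default ``exact-rank`` method samples that law
directly (orders of magnitude faster than shuffling and exactly equivalent
for tie-free data); ``method="shuffle"`` performs literal label permutations
and is kept as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import nhypergeom, norm
from statsmodels.stats.multitest import multipletests

from .genome import EARLY, LATE
from .segment import Segmentation
from .signals import CellWindows

#: minimum windows of each timing class for a chromosome to be testable
MIN_WINDOWS_PER_CLASS = 5
#: segments below this window count are excluded from testing
MIN_SEGMENT_WINDOWS = 4


def compute_rtp(cw: CellWindows, seg: Segmentation) -> pd.DataFrame:
    """Replication timing profile: RDR over its segment's median RDR.

    Returns the window table with added columns ``seg``, ``rtp`` and
    ``testable`` (False for windows in segments with fewer than
    ``MIN_SEGMENT_WINDOWS`` windows, which are reported but not tested).
    """
    w = cw.windows.copy()
    rdr = cw.rdr()
    seg_of_window = seg.seg_of_window
    w["seg"] = seg_of_window
    med = np.full(len(w), np.nan)
    testable = np.zeros(len(w), dtype=bool)
    for s in np.unique(seg_of_window):
        if s < 0:
            continue
        sel = seg_of_window == s
        med[sel] = np.median(rdr[sel])
        testable[sel] = sel.sum() >= MIN_SEGMENT_WINDOWS
    w["rtp"] = rdr / med
    w["testable"] = testable & np.isfinite(w["rtp"].to_numpy())
    return w


def center_class_offset(rtp_tables: dict, min_batch: int = 10) -> dict:
    """Remove the batch-shared early/late RTP offset (in place).

    Residual technical structure (GC-slope estimation error, realized
    covariance between GC fluctuations and timing) shifts every cell's early
    windows against its late windows coherently, which the per-cell
    permutation test would read as replication signal across the whole
    batch.  The batch median of the per-cell class contrast estimates that
    offset robustly -- G0/G1 cells dominate the median, so real S-phase
    separation is preserved -- and it is divided out of every cell's RTP.
    Computed on the RTP (copy-number-normalised) scale so that clone CNA
    structure cannot leak into the estimate.
    """
    if len(rtp_tables) < min_batch:
        return rtp_tables
    offsets = {}
    for cell, t in rtp_tables.items():
        tt = t[t["testable"]]
        lr = np.log(np.clip(tt["rtp"].to_numpy(dtype=float), 1e-9, None))
        timing = tt["timing"].to_numpy(dtype=object)
        e = lr[timing == EARLY]
        l = lr[timing == LATE]
        if e.size and l.size:
            offsets[cell] = float(e.mean() - l.mean())
    if not offsets:
        return rtp_tables
    shared = float(np.median(list(offsets.values())))
    for cell, t in rtp_tables.items():
        timing = t["timing"].to_numpy(dtype=object)
        is_e = timing == EARLY
        is_l = timing == LATE
        k, L = int(is_e.sum()), int(is_l.sum())
        n = max(k + L, 1)
        rtp = t["rtp"].to_numpy(dtype=float).copy()
        rtp[is_e] *= np.exp(-shared * (L / n))
        rtp[is_l] *= np.exp(shared * (k / n))
        t["rtp"] = rtp
    return rtp_tables


def _order_index(q: float, n: int) -> int:
    """1-based index of the ceil(q*n)-th order statistic."""
    return max(1, int(np.ceil(q * n)))


def sphase_statistic(
    rtp: np.ndarray,
    timing: np.ndarray,
    direction: str,
    margin_quantile: float = 0.75,
) -> float:
    """Directional exceedance statistic on one chromosome (see module docs)."""
    rtp = np.asarray(rtp, dtype=float)
    early = rtp[timing == EARLY]
    late = rtp[timing == LATE]
    if early.size == 0 or late.size == 0:
        raise ValueError("both timing classes must be present")
    if direction == "early_high":
        j = _order_index(margin_quantile, late.size)
        margin = np.sort(late)[j - 1]
        return float(np.mean(early > margin))
    if direction == "late_low":
        j = _order_index(1.0 - margin_quantile, early.size)
        margin = np.sort(early)[j - 1]
        return float(np.mean(late < margin))
    raise ValueError(f"unknown direction {direction!r}")


@dataclass
class SPhaseCall:
    cell_id: str
    stat_early_high: float
    stat_late_low: float
    p_early: float
    p_late: float
    p_raw: float
    n_chromosomes: int
    per_chromosome: pd.DataFrame = field(repr=False, default=None)
    p_adjusted: float = np.nan
    is_s_phase: bool = False


def _harmonic_mean(stats: np.ndarray, floors: np.ndarray) -> np.ndarray:
    """Harmonic mean along the last axis with per-chromosome zero floors."""
    s = np.maximum(stats, floors)
    return s.shape[-1] / np.sum(1.0 / s, axis=-1)


def _perm_pvalues(hm_perm: np.ndarray, n_permutations: int, tol: float) -> np.ndarray:
    """p-value of each permutation draw against the same permutation set."""
    order = np.sort(hm_perm)
    # number of draws >= value (inclusive of self)
    ge = n_permutations - np.searchsorted(order, hm_perm - tol, side="left")
    return (1.0 + ge) / (1.0 + n_permutations)


def _nhg_pmf(M: int, n_success: int, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of the negative hypergeometric NHG(M, n_success, r)."""
    support = np.arange(0, n_success + 1)
    pmf = nhypergeom.pmf(support, M, n_success, r)
    pmf = np.clip(pmf, 0.0, None)
    return support, pmf / pmf.sum()


def _sample_stat_early(rng, n, k, L, j, n_perm):
    """Permutation draws of the early_high statistic via negative hypergeometric.

    Scanning the pooled within-chromosome ranks in ascending order, the number
    of early windows seen before the j-th late window is NHG(M=n, K=k, r=j);
    the statistic follows deterministically from that rank.  The pmf is
    computed exactly and sampled directly.
    """
    support, pmf = _nhg_pmf(n, k, j)
    y = rng.choice(support, size=n_perm, p=pmf)
    r = j + y  # overall rank of the j-th smallest late value
    return ((n - r) - (L - j)) / k


def _sample_stat_late(rng, n, k, L, j2, n_perm):
    """Permutation draws of the late_low statistic (late below early order stat)."""
    support, pmf = _nhg_pmf(n, L, j2)
    y = rng.choice(support, size=n_perm, p=pmf)
    return y / L


class JointNull:
    """Shared joint permutation null of all directional statistics.

    Under the within-chromosome label permutation, the joint law of the
    exceedance statistics depends only on each chromosome's class counts
    (it is rank-based), and the studentized mean difference is standardized;
    neither depends on the cell's actual RDR values.  The joint null can
    therefore be simulated once per dataset -- capturing the true dependence
    between the directions, which per-direction independent sampling cannot
    -- and every cell with the same chromosome layout is calibrated against
    it.  Gaussian pseudo-values stand in for the exchangeable noise.
    """

    def __init__(
        self,
        layout: list,
        margins: tuple = (0.75, 0.9),
        n_permutations: int = 100_000,
        seed: int = 0,
        include_mean_diff: bool = True,
        chunk: int = 4000,
    ) -> None:
        self.layout = tuple(sorted(layout))
        self.margins = tuple(margins)
        self.n_permutations = n_permutations
        self.include_mean_diff = include_mean_diff
        rng = np.random.default_rng(seed)
        tests = [(d, m) for m in margins for d in ("early_high", "late_low")]
        floors = np.array([1.0 / (2.0 * (k + L)) for _, k, L in self.layout])
        sums: dict = {key: [] for key in tests}
        mean_z = []
        for ci, k, L in self.layout:
            n = k + L
            stat_parts = {key: [] for key in tests}
            z_parts = []
            done = 0
            while done < n_permutations:
                size = min(chunk, n_permutations - done)
                X = rng.normal(size=(size, n))
                early = X[:, :k]
                late = X[:, k:]
                for d, m in tests:
                    if d == "early_high":
                        j = _order_index(m, L)
                        thr = np.partition(late, j - 1, axis=1)[:, j - 1]
                        stat_parts[(d, m)].append(
                            np.mean(early > thr[:, None], axis=1)
                        )
                    else:
                        j2 = _order_index(1.0 - m, k)
                        thr = np.partition(early, j2 - 1, axis=1)[:, j2 - 1]
                        stat_parts[(d, m)].append(
                            np.mean(late < thr[:, None], axis=1)
                        )
                if include_mean_diff:
                    d_m = early.mean(axis=1) - late.mean(axis=1)
                    s2 = X.var(axis=1, ddof=1)
                    z_parts.append(
                        d_m / np.sqrt(np.maximum(s2 * (1.0 / k + 1.0 / L), 1e-18))
                    )
                done += size
            for key in tests:
                sums[key].append(np.concatenate(stat_parts[key]))
            if include_mean_diff:
                mean_z.append(np.concatenate(z_parts))
        self.tests = tests
        self.floors = floors
        tol = 1e-12
        self.hm_draws = {
            key: _harmonic_mean(np.column_stack(sums[key]), floors) for key in tests
        }
        self.sorted_hm = {key: np.sort(self.hm_draws[key]) for key in tests}
        p_perm = {
            key: _perm_pvalues(self.hm_draws[key], n_permutations, tol)
            for key in tests
        }
        if include_mean_diff:
            z = np.sum(np.column_stack(mean_z), axis=1) / np.sqrt(len(self.layout))
            self.z_draws = z
            self.sorted_z = np.sort(z)
            for key, vals in (("mean_high", z), ("mean_low", -z)):
                srt = np.sort(vals)
                ge = n_permutations - np.searchsorted(srt, vals - tol, side="left")
                p_perm[(key, None)] = (1.0 + ge) / (1.0 + n_permutations)
        self.pmin_perm = np.sort(np.min(np.column_stack(list(p_perm.values())), axis=1))

    def marginal_p(self, key, observed: float) -> float:
        tol = 1e-12
        if key[0] in ("mean_high", "mean_low"):
            vals = self.sorted_z if key[0] == "mean_high" else np.sort(-self.z_draws)
            ge = self.n_permutations - np.searchsorted(vals, observed - tol, side="left")
        else:
            srt = self.sorted_hm[key]
            ge = self.n_permutations - np.searchsorted(srt, observed - tol, side="left")
        return (1.0 + ge) / (1.0 + self.n_permutations)

    def combined_p(self, pmin_obs: float, u: float) -> float:
        tol = 1e-12
        less = int(np.searchsorted(self.pmin_perm, pmin_obs - tol, side="left"))
        upto = int(np.searchsorted(self.pmin_perm, pmin_obs + tol, side="right"))
        eq = upto - less
        return (less + 1.0 + u * eq) / (1.0 + self.n_permutations)


def layout_of(rtp_table: pd.DataFrame) -> list:
    """Per-chromosome (chrom_ix, n_early, n_late) of the testable windows."""
    t = rtp_table[rtp_table["testable"]]
    out = []
    for ci, sub in t.groupby("chrom_ix", sort=True):
        timing = sub["timing"].to_numpy(dtype=object)
        k = int((timing == EARLY).sum())
        L = int((timing == LATE).sum())
        if k >= MIN_WINDOWS_PER_CLASS and L >= MIN_WINDOWS_PER_CLASS:
            out.append((int(ci), k, L))
    return out


def permutation_test(
    rtp_table: pd.DataFrame,
    n_permutations: int = 100_000,
    seed: int = 0,
    margin_quantile=(0.75, 0.9),
    method: str = "exact-rank",
    min_testable_chromosomes: int = 2,
    include_mean_diff: bool = True,
    joint_null: "JointNull | None" = None,
    cell_id: str = "",
) -> SPhaseCall:
    """Permutation test of replication-timing classifications for one cell.

    ``rtp_table`` is the output of :func:`compute_rtp`.  Labels are permuted
    within each chromosome preserving class counts; see the module docstring
    for the statistics and combination rules.  ``margin_quantile`` may be a
    single quantile or a tuple: each margin contributes one test per
    direction, and all are combined with the calibrated minimum (a strict
    margin is more sensitive for cells early or late in S phase, where only
    a small fraction of windows has switched replication state).
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be at least 100")
    rng = np.random.default_rng(seed)
    margins = (
        (margin_quantile,) if np.isscalar(margin_quantile) else tuple(margin_quantile)
    )
    t = rtp_table[rtp_table["testable"]]
    tests = [(d, m) for m in margins for d in ("early_high", "late_low")]
    obs = {key: [] for key in tests}
    perm = {key: [] for key in tests}
    floors = []
    layout = []
    mean_diff_z = []  # studentized early-minus-late mean difference per chrom
    use_joint = (
        joint_null is not None
        and joint_null.margins == margins
        and joint_null.include_mean_diff == include_mean_diff
        and joint_null.n_permutations == n_permutations
    )
    for ci, sub in t.groupby("chrom_ix", sort=True):
        timing = sub["timing"].to_numpy(dtype=object)
        rtp = sub["rtp"].to_numpy(dtype=float)
        k = int((timing == EARLY).sum())
        L = int((timing == LATE).sum())
        if k < MIN_WINDOWS_PER_CLASS or L < MIN_WINDOWS_PER_CLASS:
            continue
        n = k + L
        sel = (timing == EARLY) | (timing == LATE)
        rtp = rtp[sel]
        timing = timing[sel]
        floors.append(1.0 / (2.0 * n))
        layout.append((int(ci), k, L))
        if include_mean_diff:
            # exact permutation moments of the class-mean difference: under
            # label shuffling E[d]=0 and Var[d] = s^2 (1/k + 1/L) with s^2
            # the variance of the pooled values
            d = float(rtp[timing == EARLY].mean() - rtp[timing == LATE].mean())
            s2 = float(np.var(rtp, ddof=1))
            mean_diff_z.append(d / np.sqrt(max(s2 * (1.0 / k + 1.0 / L), 1e-18)))
        for d, m in tests:
            obs[(d, m)].append(sphase_statistic(rtp, timing, d, m))
            if use_joint:
                continue  # calibration comes from the shared joint null
            if method == "exact-rank":
                if d == "early_high":
                    j = _order_index(m, L)
                    perm[(d, m)].append(
                        _sample_stat_early(rng, n, k, L, j, n_permutations)
                    )
                else:
                    j2 = _order_index(1.0 - m, k)
                    perm[(d, m)].append(
                        _sample_stat_late(rng, n, k, L, j2, n_permutations)
                    )
            elif method == "shuffle":
                pass  # filled below from shared shuffles
            else:
                raise ValueError(f"unknown method {method!r}")
        if method == "shuffle":
            draws = {key: np.empty(n_permutations) for key in tests}
            for p in range(n_permutations):
                shuffled = rng.permutation(timing)
                for d, m in tests:
                    draws[(d, m)][p] = sphase_statistic(rtp, shuffled, d, m)
            for key in tests:
                perm[key].append(draws[key])
    n_chrom = len(floors)
    if n_chrom < min_testable_chromosomes:
        return SPhaseCall(cell_id, np.nan, np.nan, 1.0, 1.0, 1.0, n_chrom)
    if use_joint and tuple(sorted(layout)) != joint_null.layout:
        # this cell's testable layout differs from the shared one (for
        # example a dropped segment); fall back to per-cell sampling
        return permutation_test(
            rtp_table,
            n_permutations=n_permutations,
            seed=seed,
            margin_quantile=margin_quantile,
            method=method,
            min_testable_chromosomes=min_testable_chromosomes,
            include_mean_diff=include_mean_diff,
            joint_null=None,
            cell_id=cell_id,
        )
    floors = np.asarray(floors)
    tol = 1e-12
    hm_obs = {}
    p_marg = {}
    p_perm = {}
    for key in tests:
        hm_obs[key] = float(_harmonic_mean(np.asarray(obs[key]), floors))
        if use_joint:
            p_marg[key] = joint_null.marginal_p(key, hm_obs[key])
        else:
            hm_p = _harmonic_mean(np.column_stack(perm[key]), floors)
            p_marg[key] = (1.0 + np.sum(hm_p >= hm_obs[key] - tol)) / (
                1.0 + n_permutations
            )
            p_perm[key] = _perm_pvalues(hm_p, n_permutations, tol)
    z_comb = None
    if include_mean_diff and mean_diff_z:
        # magnitude-aware supplement: replicated windows sit far above the
        # unreplicated bulk, so the studentized class-mean difference keeps
        # power for cells early or late in S phase where only a small
        # fraction of windows carries signal; Stouffer-combined across
        # chromosomes, two one-sided directions
        z_comb = float(np.sum(mean_diff_z) / np.sqrt(len(mean_diff_z)))
        if use_joint:
            p_marg[("mean_high", None)] = joint_null.marginal_p(
                ("mean_high", None), z_comb
            )
            p_marg[("mean_low", None)] = joint_null.marginal_p(
                ("mean_low", None), -z_comb
            )
        else:
            p_marg[("mean_high", None)] = float(norm.sf(z_comb))
            p_marg[("mean_low", None)] = float(norm.cdf(z_comb))
            u = rng.random(n_permutations)
            p_perm[("mean_high", None)] = u
            p_perm[("mean_low", None)] = 1.0 - u
    # Combine all directional p-values with the minimum, calibrated against
    # the permutation distribution of the min-p itself (Westfall-Young
    # style) so that the combined p-value is uniform under the null.
    pmin_obs = min(p_marg.values())
    if use_joint:
        p_raw = joint_null.combined_p(pmin_obs, rng.random())
    else:
        pmin_perm = np.min(np.column_stack(list(p_perm.values())), axis=1)
        # randomized (tie-smoothed) p-value: the permutation statistics are
        # discrete and cells can share atom structure (same genome, same
        # labels); smearing uniformly across the observed atom keeps the
        # null p uniform while a strong cell (no permutation as extreme)
        # still gets 1/(n_permutations + 1)
        less = int(np.sum(pmin_perm < pmin_obs - tol))
        eq = int(np.sum(np.abs(pmin_perm - pmin_obs) <= tol))
        p_raw = (less + 1.0 + rng.random() * eq) / (1.0 + n_permutations)
    m0 = margins[0]
    per_chrom = pd.DataFrame(
        {
            "stat_early_high": obs[("early_high", m0)],
            "stat_late_low": obs[("late_low", m0)],
            "floor": floors,
        }
    )
    p_e = min(p_marg[(d, m)] for d, m in tests if d == "early_high")
    p_l = min(p_marg[(d, m)] for d, m in tests if d == "late_low")
    return SPhaseCall(
        cell_id=cell_id,
        stat_early_high=hm_obs[("early_high", m0)],
        stat_late_low=hm_obs[("late_low", m0)],
        p_early=float(p_e),
        p_late=float(p_l),
        p_raw=float(p_raw),
        n_chromosomes=n_chrom,
        per_chromosome=per_chrom,
    )


def correct_multiple_testing(
    calls: list[SPhaseCall], fwer: float = 0.05
) -> pd.DataFrame:
    """Holm-Sidak step-down adjustment across cells; fills each call in place.

    Returns a tidy table (cell_id, stat_early_high, stat_late_low, p_raw,
    p_adjusted, is_s_phase).
    """
    if not calls:
        return pd.DataFrame(
            columns=[
                "cell_id",
                "stat_early_high",
                "stat_late_low",
                "p_raw",
                "p_adjusted",
                "is_s_phase",
            ]
        )
    p_raw = np.array([c.p_raw for c in calls])
    reject, p_adj, _, _ = multipletests(p_raw, alpha=fwer, method="holm-sidak")
    for c, pa, rej in zip(calls, p_adj, reject):
        c.p_adjusted = float(pa)
        c.is_s_phase = bool(rej)
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in calls],
            "stat_early_high": [c.stat_early_high for c in calls],
            "stat_late_low": [c.stat_late_low for c in calls],
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "is_s_phase": reject,
        }
    )
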