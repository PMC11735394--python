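"""Clone assignment and CNA inference for S-phase cells.

Replication-induced RDR fluctuations are removed by rescaling groups of
windows inferred to share the same replication state -- maximal runs within a
retained segment not separated by any candidate breakpoint of their own
timing track -- so that each group's median matches the segment median.  The
corrected RDRs are then scored against every clone's consensus copy-number
profile with a robust Student-t emission model, combined with a clone-size
prior, and the cell is assigned to the maximum-a-posteriori clone.  Finally
the cell's own CNAs are decoded at the assigned clone's ploidy, and small or
single-timing-class private deviations (which replication noise can mimic)
are reset to the clone consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import t as student_t

from .clones import MAX_CN, CloneSet, CopyNumberProfile
from .genome import EARLY, LATE, UNKNOWN
from .segment import Segmentation
from .signals import CellWindows

#: degrees of freedom of the emission density on log RDR
EMISSION_DF = 5
#: private deviations shorter than this (bp) are reverted to the consensus
MIN_PRIVATE_CNA_SPAN = 3_000_000


@dataclass
class CorrectedRDR:
    cell_id: str
    rdr: np.ndarray  # replication-corrected, mean-1 normalised per window
    group_of_window: np.ndarray
    flags: dict = field(default_factory=dict)


@dataclass
class CloneAssignment:
    cell_id: str
    clone_ids: list
    log_likelihoods: np.ndarray
    posteriors: np.ndarray
    map_clone: int
    low_confidence: bool = False

    def as_row(self) -> dict:
        order = np.argsort(self.posteriors)[::-1]
        second = order[1] if len(order) > 1 else order[0]
        return {
            "cell_id": self.cell_id,
            "map_clone": self.map_clone,
            "posterior_map": float(self.posteriors[order[0]]),
            "second_best": self.clone_ids[second],
            "posterior_second": float(self.posteriors[second]) if len(order) > 1 else 0.0,
        }


def replication_state_groups(cw: CellWindows, seg: Segmentation) -> np.ndarray:
    """Partition windows into same-replication-state groups.

    Within each retained segment and timing class, a group is a maximal run
    of windows not separated by a candidate breakpoint of that timing track
    (breakpoints discarded by the segment filter delimit replication-state
    changes).  Returns a group id per window.
    """
    w = cw.windows
    first_bin = w["first_bin"].to_numpy()
    group = np.full(len(w), -1, dtype=int)
    gid = 0
    for s in np.unique(seg.seg_of_window):
        if s < 0:
            continue
        in_seg = seg.seg_of_window == s
        for cls in (EARLY, LATE, UNKNOWN):
            sel = np.flatnonzero(in_seg & (w["timing"] == cls).to_numpy())
            if sel.size == 0:
                continue
            bps = seg.group_breakpoints.get(cls, np.array([], dtype=int))
            run_id = np.searchsorted(bps, first_bin[sel], side="right")
            for r in np.unique(run_id):
                group[sel[run_id == r]] = gid
                gid += 1
    return group


def _harmonise_segment_levels(
    rdr: np.ndarray, seg_of_window: np.ndarray, trusted: dict | None = None
) -> np.ndarray:
    """Resolve the factor-2 ambiguity of per-segment reference levels.

    In a cell late in S phase a whole segment can be fully replicated, so
    its within-segment reference lands on twice the copy-number level.
    Segments whose reference came from a bimodal group split are trusted
    anchors (their unreplicated level is identified); the copy-number unit
    ``u`` is fitted to the trusted levels only, and each untrusted segment
    is divided by two when half its level fits the integer lattice ``cn * u``
    better than the level itself.
    """
    segs = np.unique(seg_of_window[seg_of_window >= 0])
    if segs.size < 2 or not trusted:
        return rdr
    levels = {s: float(np.median(rdr[seg_of_window == s])) for s in segs}
    sizes = {s: int((seg_of_window == s).sum()) for s in segs}
    anchor = [s for s in segs if trusted.get(s, False)]
    suspect = [s for s in segs if not trusted.get(s, False)]
    if not anchor or not suspect:
        return rdr

    def d_int(q):
        return (q - np.clip(np.round(q), 1, None)) ** 2

    lv_a = np.array([levels[s] for s in anchor])
    sz_a = np.array([sizes[s] for s in anchor], dtype=float)
    cands = np.unique(np.concatenate([lv_a / j for j in (1, 2, 3, 4, 6)]))
    cands = cands[cands > 0.05]
    costs = [float(np.sum(sz_a * d_int(lv_a / u))) for u in cands]
    u = float(cands[int(np.argmin(costs))])
    out = rdr.copy()
    for s in suspect:
        d1 = d_int(np.array([levels[s] / u]))[0]
        d2 = 1.05 * d_int(np.array([levels[s] / (2 * u)]))[0] + 1e-4
        if d2 < d1:
            out[seg_of_window == s] /= 2.0
    return out


def correct_replication_fluctuations(
    cw: CellWindows, seg: Segmentation, bimodal_ratio: float = 1.4
) -> CorrectedRDR:
    """Rescale each replication-state group's RDRs to a common segment level.

    Within a segment, group medians concentrate on at most two levels: the
    unreplicated copy-number level and (in S-phase cells) its replicated
    double.  When the group medians split by more than ``bimodal_ratio`` the
    reference level is the median of the lower (unreplicated) mode -- using
    the plain segment median there would make the reference depend on the
    segment's early/late composition and break proportionality to copy
    number across segments.  Otherwise (no replication structure, e.g. a
    G0/G1 cell) the reference is the segment median itself, which leaves a
    noiseless profile untouched.  Groups of a single window cannot be
    rescaled robustly and are left unscaled (flagged).  The profile is
    re-normalised to genome mean 1.
    """
    rdr = cw.rdr().copy()
    group = replication_state_groups(cw, seg)
    seg_of_window = seg.seg_of_window
    singletons = 0
    trusted: dict = {}
    for s in np.unique(seg_of_window):
        if s < 0:
            continue
        in_seg = np.flatnonzero(seg_of_window == s)
        gids = np.unique(group[in_seg])
        gids = gids[gids >= 0]
        meds = {}
        weights = {}
        for g in gids:
            sel = np.flatnonzero(group == g)
            if sel.size >= 2:
                meds[g] = float(np.median(rdr[sel]))
                weights[g] = sel.size
        if not meds:
            singletons += len(gids)
            continue
        vals = np.array(list(meds.values()))
        wts = np.array([weights[g] for g in meds], dtype=float)
        if vals.max() > bimodal_ratio * max(vals.min(), 1e-12):
            # cluster the group medians; replication modes differ by exactly
            # a factor of two, so the unreplicated reference is the cluster
            # best explained as "level with a 2x replicated partner" --
            # clusters at other ratios (copy-number contamination from a
            # missed boundary, or stray windows) must not hijack the level
            order = np.argsort(vals)
            clusters = [[order[0]]]
            for ix in order[1:]:
                if vals[ix] <= bimodal_ratio * vals[clusters[-1][0]]:
                    clusters[-1].append(ix)
                else:
                    clusters.append([ix])
            lev = np.array([float(np.median(vals[cl])) for cl in clusters])
            wt = np.array([float(wts[cl].sum()) for cl in clusters])
            score = wt.copy()
            has_partner = np.zeros(len(clusters), dtype=bool)
            for a in range(len(clusters)):
                for b in range(len(clusters)):
                    ratio = lev[b] / max(lev[a], 1e-12)
                    if 1.75 < ratio < 2.3:
                        score[a] += wt[b]
                        has_partner[a] = True
            best = int(np.argmax(score))
            ref = float(lev[best])
            # a 2x partner identifies the unreplicated level unambiguously,
            # anchoring the cell's copy-number lattice
            trusted[s] = bool(has_partner[best])
        else:
            ref = float(np.median(rdr[in_seg]))
            trusted[s] = False
        for g in gids:
            sel = np.flatnonzero(group == g)
            if sel.size < 2:
                singletons += 1
                continue
            if meds[g] > 0:
                rdr[sel] *= ref / meds[g]
        # replication doubles coverage exactly, so windows still sitting
        # near twice (or half) the segment reference after group rescaling
        # are isolated mis-grouped replication states: snap them back
        sel_seg = np.flatnonzero(seg_of_window == s)
        ratio = rdr[sel_seg] / max(ref, 1e-12)
        high = (ratio > 1.6) & (ratio < 2.5)
        low = (ratio > 0.4) & (ratio < 0.625)
        rdr[sel_seg[high]] /= 2.0
        rdr[sel_seg[low]] *= 2.0
    rdr = _harmonise_segment_levels(rdr, seg_of_window, trusted)
    rdr /= rdr.mean()
    flags = {"singleton_groups": singletons} if singletons else {}
    return CorrectedRDR(cell_id=cw.cell_id, rdr=rdr, group_of_window=group, flags=flags)


def _expected_rdr(cw: CellWindows, cons: np.ndarray, scale: float) -> np.ndarray:
    """Expected RDR per window under a clone consensus: mean member-bin cn / scale."""
    mapped = cw.win_of_bin >= 0
    cn_of_win = np.zeros(cw.n_windows)
    cnt = np.zeros(cw.n_windows)
    np.add.at(cn_of_win, cw.win_of_bin[mapped], cons[np.flatnonzero(mapped)])
    np.add.at(cnt, cw.win_of_bin[mapped], 1.0)
    return (cn_of_win / np.maximum(cnt, 1.0)) / scale


def assign_to_clone(
    corrected: CorrectedRDR,
    cw: CellWindows,
    clone_set: CloneSet,
    seg: Segmentation | None = None,
) -> CloneAssignment:
    """MAP clone assignment of an S-phase cell.

    Likelihood: Student-t (df 5) on log RDR around log(cn/ploidy) per window,
    with a robust per-cell scale from within-segment residuals.  Prior:
    proportional to the clone's G0/G1/G2 cell count.  Ties break
    deterministically towards the smallest clone id.
    """
    ids = clone_set.clone_ids
    rdr = np.clip(corrected.rdr, 1e-6, None)
    log_rdr = np.log(rdr)
    if seg is not None:
        resid = np.full(len(rdr), np.nan)
        for s in np.unique(seg.seg_of_window):
            if s < 0:
                continue
            sel = seg.seg_of_window == s
            resid[sel] = log_rdr[sel] - np.log(max(np.median(rdr[sel]), 1e-6))
        resid = resid[np.isfinite(resid)]
    else:
        resid = log_rdr - np.median(log_rdr)
    sd = max(1.4826 * np.median(np.abs(resid)), 0.02)
    # replication doubles coverage exactly; residuals the correction missed
    # appear either as isolated windows at twice/half the clone level
    # (handled by a small-weight emission mixture) or as whole segments
    # left at the replicated level (handled by an optional per-segment
    # +-log2 shift, paid for with a fixed penalty so it is only invoked
    # when it clearly helps)
    comps = np.log(np.array([1.0, 2.0, 0.5]))
    log_weights = np.log(np.array([0.8, 0.14, 0.06]))
    shift_penalty = 5.0
    if seg is not None:
        seg_ids = seg.seg_of_window
    else:
        seg_ids = np.zeros(len(rdr), dtype=int)
    logliks = np.empty(len(ids))
    for i, c in enumerate(ids):
        mu = _expected_rdr(cw, clone_set.consensus[c], max(clone_set.ploidies[c], 1e-6))
        mu = np.clip(mu, 1e-6, None)
        total = 0.0
        deltas = np.array([0.0, np.log(2.0), -np.log(2.0)])
        resid0 = log_rdr - np.log(mu)
        # the corrected profile is only defined up to a global scale (its
        # mean-1 normalisation depends on how many segments kept their
        # replicated level), so a robust global offset is profiled out
        resid0 = resid0 - np.median(resid0)
        z = (resid0[:, None, None] - deltas[None, :, None] - comps[None, None, :]) / sd
        lp = student_t.logpdf(z, df=EMISSION_DF) - np.log(sd) + log_weights[None, None, :]
        per_win = logsumexp(lp, axis=2)  # (windows, deltas)
        for s in np.unique(seg_ids):
            sel = seg_ids == s
            seg_scores = per_win[sel].sum(axis=0)
            seg_scores[1:] -= shift_penalty
            total += float(seg_scores.max())
        logliks[i] = total
    sizes = np.array([len(clone_set.members[c]) for c in ids], dtype=float)
    log_prior = np.log(sizes / sizes.sum())
    log_post = logliks + log_prior
    low_confidence = False
    if not np.isfinite(log_post).any():
        log_post = log_prior.copy()
        low_confidence = True
    post = np.exp(log_post - logsumexp(log_post))
    post /= post.sum()
    map_ix = int(np.argmax(post))  # argmax takes the first (smallest id) on ties
    return CloneAssignment(
        cell_id=corrected.cell_id,
        clone_ids=list(ids),
        log_likelihoods=logliks,
        posteriors=post,
        map_clone=ids[map_ix],
        low_confidence=low_confidence,
    )


def infer_sphase_cnas(
    corrected: CorrectedRDR,
    cw: CellWindows,
    clone_set: CloneSet,
    clone_id: int,
    genome,
    sd: float | None = None,
) -> CopyNumberProfile:
    """Copy numbers of an S-phase cell at the assigned clone's ploidy scale."""
    from .clones import _decode_at_scale
    from .segment import estimate_noise_sd

    rdr = corrected.rdr
    w = cw.windows
    if sd is None:
        sd = max(estimate_noise_sd(rdr), 0.03)
    cons = clone_set.consensus[clone_id]
    mapped = cw.win_of_bin >= 0
    # scale such that rdr * scale ~ cn: mean consensus cn over windowed bins,
    # after aligning the profile's global scale to the clone (the mean-1
    # normalisation drifts when segments keep their replicated level)
    scale = float(np.mean(cons[np.flatnonzero(mapped)]))
    mu = np.clip(_expected_rdr(cw, cons, scale), 1e-6, None)
    align = float(np.median(np.log(np.clip(rdr, 1e-6, None)) - np.log(mu)))
    rdr = rdr * np.exp(-align)
    cn_w, cost = _decode_at_scale(rdr, w["chrom_ix"].to_numpy(), scale, sd)
    cn_bin = np.zeros(genome.m, dtype=int)
    cn_bin[mapped] = cn_w[cw.win_of_bin[mapped]]
    ploidy = float(np.average(cn_bin, weights=genome.widths))
    return CopyNumberProfile(
        cell_id=corrected.cell_id, cn=cn_bin, ploidy=ploidy, scale=scale, cost=cost
    )


def correct_small_cnas(
    profile: CopyNumberProfile,
    clone_consensus: np.ndarray,
    genome,
    min_span: int = MIN_PRIVATE_CNA_SPAN,
) -> CopyNumberProfile:
    """Reset implausible private CNAs of an S-phase cell to the clone consensus.

    A private deviation (maximal run of bins whose cn differs from the
    consensus) is reverted when it is shorter than ``min_span`` or confined
    to a single replication-timing class; replication fluctuations produce
    exactly such deviations, while real CNAs are larger and span both
    classes.
    """
    cn = profile.cn.copy()
    timing = genome.timing
    widths = genome.widths
    chrom_ix = genome.chrom_index
    diff = cn != clone_consensus
    # maximal runs of deviation within a chromosome
    boundaries = np.flatnonzero(
        np.diff(np.concatenate(([0], diff.view(np.int8), [0]))) != 0
    )
    for lo, hi in zip(boundaries[::2], boundaries[1::2]):
        if chrom_ix[lo] != chrom_ix[hi - 1]:
            # split at chromosome boundary
            split = lo + np.flatnonzero(np.diff(chrom_ix[lo:hi]) != 0) + 1
            pieces = np.split(np.arange(lo, hi), split - lo)
        else:
            pieces = [np.arange(lo, hi)]
        for piece in pieces:
            span = int(widths[piece].sum())
            classes = set(timing[piece]) - {UNKNOWN}
            cons_piece = clone_consensus[piece]
            # exact doubling/halving of the consensus over a run is residual
            # replication signal, not a CNA (replication factor is exactly 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                doubled = np.mean(cn[piece] == 2 * cons_piece) >= 0.8
                halved = np.mean(2 * cn[piece] == cons_piece) >= 0.8
            # a real CNA decodes to one copy number; fragmented deviations
            # (no dominant value) are correction artifacts
            vals, counts = np.unique(cn[piece], return_counts=True)
            fragmented = counts.max() < 0.8 * piece.size
            if span < min_span or len(classes) < 2 or doubled or halved or fragmented:
                cn[piece] = clone_consensus[piece]
    profile.cn = cn
    profile.ploidy = float(np.average(cn, weights=widths))
    return profile


def assignment_table(assignments: list[CloneAssignment]) -> pd.DataFrame:
    return pd.DataFrame([a.as_row() for a in assignments])
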