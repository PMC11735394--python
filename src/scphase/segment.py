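"""Replication-aware copy-number segmentation.

Candidate breakpoints are detected independently in the early-timing and the
late-timing window tracks of each chromosome with a sticky Gaussian HMM over
discretised RDR levels.  Because copy-number alterations (CNAs) are tens of
megabases while same-timing replication domains are sub-megabase, a true CNA
boundary appears in both tracks, whereas replication fluctuations in S-phase
cells produce breakpoints in only one track.  The union of breakpoints
defines raw segments; segments that contain only one timing class (or fall
below a minimum span) are merged into the flanking segment with the closer
median RDR, so every retained segment contains both early and late bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import EARLY, LATE, BinnedGenome
from .signals import CellWindows

#: HMM parameterisation: equally spaced RDR levels with sticky transitions
N_STATES = 12
STATE_LEVELS = np.linspace(0.0, 3.0, N_STATES)
SWITCH_EPS = 1e-3
#: minimum genomic span of a retained segment (bp)
MIN_SEGMENT_SPAN = 2_000_000


def viterbi(log_emission: np.ndarray, log_stay: float, log_switch: float) -> np.ndarray:
    """Most likely state path for a sticky HMM with uniform initial state.

    ``log_emission`` is (T, K).  All off-diagonal transitions share
    ``log_switch``; the diagonal is ``log_stay``.
    """
    T, K = log_emission.shape
    delta = log_emission[0] - np.log(K)
    psi = np.zeros((T, K), dtype=int)
    states = np.arange(K)
    for t in range(1, T):
        # all off-diagonal transitions are equal, so the best switch
        # predecessor of state k is the best overall state, or the runner-up
        # when the best state is k itself
        top2 = np.argpartition(delta, K - 2)[-2:]
        top2 = top2[np.argsort(delta[top2])][::-1]
        best, second = int(top2[0]), int(top2[1])
        switch_prev = np.where(states == best, second, best)
        stay = delta + log_stay
        switch = delta[switch_prev] + log_switch
        choose_stay = stay >= switch
        psi[t] = np.where(choose_stay, states, switch_prev)
        delta = np.where(choose_stay, stay, switch) + log_emission[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def estimate_noise_sd(values: np.ndarray) -> float:
    """Robust noise scale from first differences of a value series."""
    diffs = np.diff(values)
    if diffs.size == 0:
        return 0.1
    sd = 1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0)
    return float(max(sd, 1e-3))


def within_track_noise_sd(cw: CellWindows, rdr: np.ndarray) -> float:
    """Noise scale from first differences within each (chromosome, timing)
    track.  Differences across timing classes jump between replication
    states in S-phase cells and would inflate a global estimate; within a
    track most adjacent windows share their replication state, so the median
    absolute difference stays robust."""
    diffs = []
    w = cw.windows
    for (ci, cls), sub in w.groupby(["chrom_ix", "timing"], sort=False, observed=True):
        vals = rdr[sub["win"].to_numpy()]
        if vals.size >= 2:
            diffs.append(np.diff(vals))
    if not diffs:
        return estimate_noise_sd(rdr)
    diffs = np.concatenate(diffs)
    return float(max(1.4826 * np.median(np.abs(diffs)) / np.sqrt(2.0), 1e-3))


def decode_levels(
    values: np.ndarray,
    levels: np.ndarray = STATE_LEVELS,
    sd: float | None = None,
    eps: float = SWITCH_EPS,
) -> np.ndarray:
    """Viterbi state path of RDR values over the discrete level grid."""
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if sd is None:
        sd = estimate_noise_sd(values[finite])
    le = -0.5 * ((values[:, None] - levels[None, :]) / sd) ** 2
    le[~finite] = 0.0  # masked observations are uninformative
    K = levels.size
    path = viterbi(le, np.log1p(-eps), np.log(eps / (K - 1)))
    return path


def detect_breakpoints_per_group(
    values: np.ndarray, sd: float | None = None, eps: float = SWITCH_EPS
) -> np.ndarray:
    """Indices ``i`` such that a state change occurs between ``i-1`` and ``i``."""
    if values.size < 2:
        return np.array([], dtype=int)
    path = decode_levels(np.asarray(values, dtype=float), sd=sd, eps=eps)
    return np.flatnonzero(np.diff(path) != 0) + 1


@dataclass
class Segmentation:
    """Retained segmentation plus the raw per-group candidate breakpoints.

    ``segments`` columns: ``seg``, ``chrom_ix``, ``start_bin``, ``end_bin``
    (half-open bin indices), ``n_windows``, ``median_rdr``,
    ``contains_early``, ``contains_late``, ``flagged``.
    ``group_breakpoints`` maps timing class to the genomic bin indices of all
    candidate breakpoints in that track (used later to delimit
    replication-state groups in S-phase cells).
    """

    segments: pd.DataFrame
    seg_of_window: np.ndarray
    group_breakpoints: dict = field(default_factory=dict)


def _window_track(cw: CellWindows, chrom_ix: int, timing: str):
    w = cw.windows
    sel = (w["chrom_ix"] == chrom_ix).to_numpy() & (w["timing"] == timing).to_numpy()
    return w.loc[sel]


def _class_masks(cw: CellWindows, chrom_ix: int):
    w = cw.windows
    on = (w["chrom_ix"] == chrom_ix).to_numpy()
    fb = w["first_bin"].to_numpy()
    timing = w["timing"].to_numpy(dtype=object)
    return on, fb, timing


def _joint_step_z(rdr, on, fb, timing, lo, p, hi, sd, min_side=3, flanks=(40, 60)):
    """Two-class support z of a step at ``p`` within [lo, hi).

    Flanks are limited per side so that a boundary's contrast is not diluted
    by further copy-number changes in the same span; the maximum over the
    flank scales is returned (a short flank resolves boundaries close
    together, a long flank has more power in clean surroundings).  Per
    scale, the statistic is the minimum over timing classes of the robust z
    of the median RDR difference across ``p`` when both classes shift in the
    same direction, else 0.  Classes with too few windows on either side are
    uninformative (ignored); if neither class is informative, returns 0.
    """
    best = 0.0
    for flank in flanks:
        flo = max(lo, p - flank)
        fhi = min(hi, p + flank)
        zs = []
        for cls in (EARLY, LATE):
            sel = on & (timing == cls) & (fb >= flo) & (fb < fhi)
            left = rdr[sel & (fb < p)]
            right = rdr[sel & (fb >= p)]
            if left.size < min_side or right.size < min_side:
                continue
            delta = float(np.median(right) - np.median(left))
            se = 1.2533 * sd * np.sqrt(1.0 / left.size + 1.0 / right.size)
            zs.append(delta / max(se, 1e-9))
        if not zs:
            continue
        if len(zs) == 2 and np.sign(zs[0]) != np.sign(zs[1]):
            continue
        best = max(best, float(min(abs(z) for z in zs)))
    return best


def _refine_position(rdr, on, fb, timing, lo, p, hi, slack=10):
    """Local joint L1 step fit: the position in ``p +- slack`` minimising the
    summed absolute deviation of each class around its side medians."""
    best_p, best_cost = p, np.inf
    for q in range(max(lo + 1, p - slack), min(hi - 1, p + slack) + 1):
        cost = 0.0
        for cls in (EARLY, LATE):
            sel = on & (timing == cls) & (fb >= lo) & (fb < hi)
            left = rdr[sel & (fb < q)]
            right = rdr[sel & (fb >= q)]
            if left.size:
                cost += np.abs(left - np.median(left)).sum()
            if right.size:
                cost += np.abs(right - np.median(right)).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_p = cost, q
    return int(best_p)


def _split_segments(
    rdr, on, fb, timing, candidates, lo, hi, sd, z_split
) -> list:
    """Recursive change-point splitting over candidate positions.

    At each level the candidate with the strongest two-class same-sign
    support is refined and, if its support reaches ``z_split``, accepted and
    both halves are re-examined.  Candidates come from the per-track HMM
    decodings, so every accepted boundary is supported by both timing
    tracks.
    """
    inside = [c for c in candidates if lo < c < hi]
    if not inside:
        return []
    zs = [_joint_step_z(rdr, on, fb, timing, lo, p, hi, sd) for p in inside]
    best = int(np.argmax(zs))
    if zs[best] < z_split:
        return []
    p = _refine_position(rdr, on, fb, timing, lo, inside[best], hi)
    left = _split_segments(rdr, on, fb, timing, candidates, lo, p, sd, z_split)
    right = _split_segments(rdr, on, fb, timing, candidates, p, hi, sd, z_split)
    return sorted(left + [p] + right)


def segment_cell(
    cw: CellWindows,
    genome: BinnedGenome,
    min_span: int = MIN_SEGMENT_SPAN,
    min_windows_per_group: int = 10,
    eps: float = SWITCH_EPS,
    breakpoint_z: float = 6.0,
) -> Segmentation:
    """Replication-aware segmentation of one cell.

    Breakpoints are decoded per chromosome in the early and late tracks,
    mapped to genomic bin coordinates (start bin of the window following the
    state change) and merged; see the module docstring for the filter.
    A chromosome with only one timing class present becomes a single flagged
    whole-chromosome segment.
    """
    w = cw.windows
    rdr = cw.rdr()
    timing_of_bin = genome.timing
    chrom_of_bin = genome.chrom_index
    widths = genome.widths
    bin_start = genome.bins["start"].to_numpy()
    sd = within_track_noise_sd(cw, rdr)

    seg_rows = []
    group_bp: dict[str, list[int]] = {EARLY: [], LATE: []}
    seg_of_window = np.full(len(w), -1, dtype=int)
    seg_id = 0
    n_chrom = chrom_of_bin.max() + 1
    for ci in range(n_chrom):
        chrom_bins = np.flatnonzero(chrom_of_bin == ci)
        b0, b1 = chrom_bins[0], chrom_bins[-1] + 1
        present = {
            g: (timing_of_bin[chrom_bins] == g).any() for g in (EARLY, LATE)
        }
        track_hits: dict[str, list] = {EARLY: [], LATE: []}
        for g in (EARLY, LATE):
            track = _window_track(cw, ci, g)
            if len(track) < min_windows_per_group:
                continue
            vals = rdr[track["win"].to_numpy()]
            fbs = track["first_bin"].to_numpy()
            hits = detect_breakpoints_per_group(vals, sd=sd, eps=eps)
            for h in hits:
                lo_h = max(0, h - 5)
                hi_h = min(vals.size, h + 5)
                direction = np.sign(
                    np.median(vals[h:hi_h]) - np.median(vals[lo_h:h])
                )
                track_hits[g].append((int(fbs[h]), float(direction)))
            group_bp[g].extend(int(fbs[h]) for h in hits)
        flagged = not (present[EARLY] and present[LATE])
        # retain only boundaries supported by BOTH timing tracks: a real CNA
        # boundary shifts the RDR level of early and late windows alike and
        # in the same direction, whereas replication fluctuations move only
        # one track; candidate positions come from the per-track decodings
        # and are validated by recursive joint change-point splitting
        candidates = sorted({pos for g in (EARLY, LATE) for pos, _ in track_hits[g]})
        on, fbv, timv = _class_masks(cw, ci)
        accepted = (
            []
            if flagged
            else _split_segments(rdr, on, fbv, timv, candidates, b0, b1, sd, breakpoint_z)
        )
        bounds = [b0] + accepted + [b1]
        raw = list(zip(bounds[:-1], bounds[1:]))

        # merge one-class and short raw segments into the closer neighbour
        def seg_stats(lo, hi):
            bins = np.arange(lo, hi)
            wsel = np.flatnonzero(
                (w["chrom_ix"].to_numpy() == ci)
                & (w["first_bin"].to_numpy() >= lo)
                & (w["first_bin"].to_numpy() < hi)
            )
            med = float(np.median(rdr[wsel])) if wsel.size else np.nan
            has_e = (timing_of_bin[bins] == EARLY).any()
            has_l = (timing_of_bin[bins] == LATE).any()
            span = int(widths[bins].sum())
            return med, has_e, has_l, span, wsel.size

        changed = True
        while changed and len(raw) > 1:
            changed = False
            stats = [seg_stats(lo, hi) for lo, hi in raw]
            for i, (med, has_e, has_l, span, nw) in enumerate(stats):
                keepable = has_e and has_l and span >= min_span and nw > 0
                if keepable:
                    continue
                neighbours = []
                if i > 0:
                    neighbours.append((abs(stats[i - 1][0] - med), i - 1))
                if i < len(raw) - 1:
                    neighbours.append((abs(stats[i + 1][0] - med), i + 1))
                if not neighbours:
                    continue
                neighbours.sort(key=lambda t: (t[0] if np.isfinite(t[0]) else np.inf, t[1]))
                j = neighbours[0][1]
                a, b = (i, j) if i < j else (j, i)
                raw[a] = (raw[a][0], raw[b][1])
                del raw[b]
                changed = True
                break

        for lo, hi in raw:
            med, has_e, has_l, span, nw = seg_stats(lo, hi)
            wsel = np.flatnonzero(
                (w["chrom_ix"].to_numpy() == ci)
                & (w["first_bin"].to_numpy() >= lo)
                & (w["first_bin"].to_numpy() < hi)
            )
            seg_of_window[wsel] = seg_id
            seg_rows.append(
                (
                    seg_id,
                    ci,
                    int(lo),
                    int(hi),
                    int(nw),
                    med,
                    bool(has_e),
                    bool(has_l),
                    bool(flagged or not (has_e and has_l)),
                    int(bin_start[lo]),
                    int(genome.bins["end"].iloc[hi - 1]),
                )
            )
            seg_id += 1

    segments = pd.DataFrame(
        seg_rows,
        columns=[
            "seg",
            "chrom_ix",
            "start_bin",
            "end_bin",
            "n_windows",
            "median_rdr",
            "contains_early",
            "contains_late",
            "flagged",
            "start_bp",
            "end_bp",
        ],
    )
    return Segmentation(
        segments=segments,
        seg_of_window=seg_of_window,
        group_breakpoints={g: np.array(sorted(set(v)), dtype=int) for g, v in group_bp.items()},
    )
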