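"""Copy-number calling, clone inference and ploidy-artifact resolution.

Integer copy numbers for non-S cells are decoded with the same sticky
Gaussian HMM used for segmentation, with emission means ``cn / scale`` over a
grid of candidate ploidy scales; the selected scale minimises the decoding
cost plus a small parsimony penalty per unit scale, which prefers the lowest
ploidy among equally good fits (half/double degenerate profiles are flagged).
Non-S cells carry no replication fluctuations, so decoding runs freely over
windows and can recover CNAs confined to a single timing domain that the
replication-aware segmentation deliberately discards.

Clones are inferred by average-linkage agglomerative clustering on the
fraction of bins with differing copy number, with the cut height auto-tuned
by silhouette over a grid; clusters below ``min_clone_size`` become outlier
cells.  A likelihood-ratio test then dissolves artefactual clones whose RDRs
are equally well explained by another clone's profile at a different ploidy
(the classic halved/doubled-genome artifact) while genuinely
whole-genome-doubled clones with private CNAs are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .segment import viterbi
from .signals import CellWindows

#: candidate ploidy scales
PLOIDY_GRID = np.round(np.arange(1.5, 5.0 + 1e-9, 0.05), 2)
MAX_CN = 12
#: parsimony penalty (cost units) per unit of ploidy scale
SCALE_PENALTY = 5.0
MIN_CLONE_SIZE = 15
#: per-cell mean log-likelihood slack (nats/window) below which an
#: alternative clone "equally explains" a cell
PLOIDY_LR_TOL = 0.02


@dataclass
class CopyNumberProfile:
    cell_id: str
    cn: np.ndarray  # integer copy number per bin
    ploidy: float  # span-weighted mean copy number
    scale: float  # selected ploidy scale (rdr * scale ~ cn)
    cost: float
    degenerate: bool = False


@dataclass
class CloneSet:
    """Clone memberships with consensus profiles.

    ``members`` maps clone_id -> list of cell ids; ``consensus`` maps
    clone_id -> integer cn per bin; ``ploidies`` maps clone_id -> span
    weighted mean cn; ``outlier_cells`` lists unassigned cells.
    """

    members: dict
    consensus: dict
    ploidies: dict
    outlier_cells: list = field(default_factory=list)

    @property
    def clone_ids(self) -> list:
        return sorted(self.members)

    def sizes(self) -> dict:
        return {c: len(v) for c, v in self.members.items()}

    def membership_table(self) -> pd.DataFrame:
        rows = [
            (cell, clone, self.ploidies[clone])
            for clone in self.clone_ids
            for cell in self.members[clone]
        ]
        rows += [(cell, -1, np.nan) for cell in self.outlier_cells]
        return pd.DataFrame(rows, columns=["cell_id", "clone_id", "ploidy"])


def _decode_at_scale(
    rdr: np.ndarray, chrom_ix: np.ndarray, scale: float, sd: float, eps: float = 1e-3
) -> tuple[np.ndarray, float]:
    """Viterbi cn path per chromosome at one ploidy scale; returns (cn, cost)."""
    levels = np.arange(0, MAX_CN + 1) / scale
    K = levels.size
    log_stay = np.log1p(-eps)
    log_switch = np.log(eps / (K - 1))
    cn = np.empty(rdr.size, dtype=int)
    cost = 0.0
    for ci in np.unique(chrom_ix):
        sel = chrom_ix == ci
        le = -0.5 * ((rdr[sel, None] - levels[None, :]) / sd) ** 2
        path = viterbi(le, log_stay, log_switch)
        cn[sel] = path
        cost += -le[np.arange(path.size), path].sum()
        cost += np.log(1.0 / eps) * np.count_nonzero(np.diff(path))
    return cn, cost


def select_ploidy_scale(
    rdr: np.ndarray,
    seg_of_window: np.ndarray,
    ploidy_grid: np.ndarray = PLOIDY_GRID,
    scale_penalty: float = SCALE_PENALTY,
    sd: float = 0.05,
) -> tuple[float, float, bool]:
    """Grid search for the ploidy scale by quantising segment medians.

    Copy number is constant within segments, so the scale-dependent part of
    the fit is how closely each segment's median RDR lands on an integer copy
    number at that scale: ``cost(s) = sum_seg n_seg (med_seg - round(med_seg
    s)/s)^2 / (2 sd^2) + penalty * s``.  Returns (scale, cost, degenerate);
    degenerate means several well-separated scales fit almost equally (a flat
    or even-only profile), in which case the lowest is returned.
    """
    segs = np.unique(seg_of_window[seg_of_window >= 0])
    meds = np.array([np.median(rdr[seg_of_window == s]) for s in segs])
    sizes = np.array([(seg_of_window == s).sum() for s in segs], dtype=float)
    prod = meds[None, :] * ploidy_grid[:, None]
    q = np.clip(np.round(prod), 0, MAX_CN) / ploidy_grid[:, None]
    costs = ((meds[None, :] - q) ** 2 * sizes[None, :]).sum(axis=1) / (2 * sd**2)
    costs += scale_penalty * ploidy_grid
    best = int(np.argmin(costs))
    scale = float(ploidy_grid[best])
    # a perfect fit always recurs at exact multiples of the scale (handled by
    # the penalty and the clone-level artifact test); flag as degenerate only
    # when non-multiple scales also fit, i.e. the profile is essentially flat
    near = np.flatnonzero(costs - scale_penalty * ploidy_grid <= (costs - scale_penalty * ploidy_grid)[best] + 1.0)
    ratios = ploidy_grid[near] / scale
    off_multiple = np.abs(ratios - np.round(ratios)) > 0.05
    degenerate = bool(np.any(off_multiple & (ratios > 1.05)))
    return scale, float(costs[best]), degenerate


def call_copy_numbers(
    cw: CellWindows,
    genome,
    segmentation,
    ploidy_grid: np.ndarray = PLOIDY_GRID,
    scale_penalty: float = SCALE_PENALTY,
    sd: float | None = None,
) -> CopyNumberProfile:
    """Integer copy-number profile of a non-S cell.

    The ploidy scale is selected with :func:`select_ploidy_scale` on the
    replication-aware segments, then the copy-number path is decoded freely
    over windows with the sticky HMM at that scale, which also recovers CNAs
    confined to a single timing domain.  Flat profiles where a scale and its
    doubling fit equally well are unidentifiable from RDRs alone; the lowest
    compatible ploidy is chosen and the profile flagged ``degenerate``
    (resolved later at clone level).
    """
    from .segment import estimate_noise_sd

    w = cw.windows
    rdr = cw.rdr()
    chrom_ix = w["chrom_ix"].to_numpy()
    if sd is None:
        sd = max(estimate_noise_sd(rdr), 0.03)
    scale, _, degenerate = select_ploidy_scale(
        rdr, segmentation.seg_of_window, ploidy_grid, scale_penalty, sd
    )
    cn_w, cost = _decode_at_scale(rdr, chrom_ix, scale, sd)

    cn_bin = np.zeros(genome.m, dtype=int)
    mapped = cw.win_of_bin >= 0
    cn_bin[mapped] = cn_w[cw.win_of_bin[mapped]]
    widths = genome.widths
    ploidy = float(np.average(cn_bin, weights=widths))
    return CopyNumberProfile(
        cell_id=cw.cell_id,
        cn=cn_bin,
        ploidy=ploidy,
        scale=scale,
        cost=float(cost),
        degenerate=degenerate,
    )


def cluster_cells(
    profiles: list[CopyNumberProfile],
    min_clone_size: int = MIN_CLONE_SIZE,
    height_floor: float = 0.01,
    n_heights: int = 40,
) -> CloneSet:
    """Agglomerative clustering of non-S cells into clones.

    Distance is the fraction of bins with differing copy number; average
    linkage; the cut height maximises the silhouette over a grid floored at
    ``height_floor`` (the expected within-clone disagreement from noise).
    """
    if not profiles:
        raise ValueError("no profiles to cluster")
    cells = [p.cell_id for p in profiles]
    cn = np.vstack([p.cn for p in profiles])
    n = len(profiles)
    if n < min_clone_size:
        warnings.warn("fewer cells than min_clone_size; returning a single clone")
        labels = np.zeros(n, dtype=int)
    elif np.all(cn == cn[0]):
        labels = np.zeros(n, dtype=int)
    else:
        dist = pdist(cn, metric="hamming")
        Z = linkage(dist, method="average")
        # candidate cut heights: midpoints between consecutive merge heights
        # realize every possible partition of the dendrogram
        hs = np.sort(np.unique(Z[:, 2]))
        mids = (hs[:-1] + hs[1:]) / 2.0 if hs.size > 1 else hs
        heights = np.unique(np.clip(mids, height_floor, None))
        if heights.size > n_heights:
            idx = np.linspace(0, heights.size - 1, n_heights).astype(int)
            heights = heights[idx]
        sq = squareform(dist)
        candidates = []
        for h in heights:
            lab = fcluster(Z, t=h, criterion="distance")
            k = np.unique(lab).size
            if k < 2 or k >= n:
                continue
            try:
                score = silhouette_score(sq, lab, metric="precomputed")
            except ValueError:
                continue
            candidates.append((score, h, lab))
        if not candidates:
            labels = np.zeros(n, dtype=int)
        else:
            best_score = max(s for s, _, _ in candidates)
            # among near-optimal cuts prefer the largest height: it absorbs
            # straggler cells into their clone instead of leaving them as
            # spurious singleton clusters
            labels = max(
                (c for c in candidates if c[0] >= best_score - 0.01),
                key=lambda c: c[1],
            )[2]
    return _build_clone_set(cells, cn, labels, min_clone_size, profiles)


def _consensus(cn_rows: np.ndarray) -> np.ndarray:
    """Per-bin majority copy number across member cells."""
    out = np.empty(cn_rows.shape[1], dtype=int)
    for b in range(cn_rows.shape[1]):
        vals, counts = np.unique(cn_rows[:, b], return_counts=True)
        out[b] = int(vals[np.argmax(counts)])
    return out


def _build_clone_set(cells, cn, labels, min_clone_size, profiles) -> CloneSet:
    members: dict = {}
    consensus: dict = {}
    ploidies: dict = {}
    outliers: list = []
    next_id = 0
    # deterministic clone ids: order clusters by first member appearance
    seen = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    widths = None
    for lab in seen:
        idx = np.flatnonzero(labels == lab)
        if idx.size < min_clone_size and len(seen) > 1:
            outliers.extend(cells[i] for i in idx)
            continue
        cons = _consensus(cn[idx])
        members[next_id] = [cells[i] for i in idx]
        consensus[next_id] = cons
        ploidies[next_id] = float(np.mean(cons))
        next_id += 1
    if not members:  # everything fell below the size threshold
        members[0] = list(cells)
        consensus[0] = _consensus(cn)
        ploidies[0] = float(np.mean(consensus[0]))
        outliers = []
    return CloneSet(members=members, consensus=consensus, ploidies=ploidies, outlier_cells=outliers)


def _mean_loglik_under(
    cw: CellWindows, cons: np.ndarray, scale: float, sd: float
) -> float:
    """Per-window mean Gaussian log-likelihood of a cell's RDRs under a profile."""
    w = cw.windows
    rdr = cw.rdr()
    mapped = cw.win_of_bin >= 0
    # expected rdr per window: consensus cn averaged over member bins / scale
    cn_of_win = np.zeros(len(w))
    cnt = np.zeros(len(w))
    np.add.at(cn_of_win, cw.win_of_bin[mapped], cons[np.flatnonzero(mapped)])
    np.add.at(cnt, cw.win_of_bin[mapped], 1.0)
    mu = (cn_of_win / np.maximum(cnt, 1.0)) / scale
    ll = -0.5 * np.log(2 * np.pi * sd**2) - 0.5 * ((rdr - mu) / sd) ** 2
    return float(ll.mean())


def resolve_ploidy_artifacts(
    clone_set: CloneSet,
    windows_by_cell: dict,
    lr_tol: float = PLOIDY_LR_TOL,
) -> CloneSet:
    """Dissolve clones whose RDRs another clone's profile explains equally well.

    For each clone whose rounded ploidy differs from the cell-weighted
    majority, the mean per-window log-likelihood of its members' RDRs under
    its own consensus is compared with the likelihood under every other
    clone's consensus (each at its own ploidy scale).  If the best
    alternative is within ``lr_tol`` nats/window, the clone is dissolved and
    its members join that alternative clone.  Never increases clone count.
    """
    from .segment import estimate_noise_sd

    ids = clone_set.clone_ids
    if len(ids) < 2:
        return clone_set
    rounded = {c: int(round(clone_set.ploidies[c])) for c in ids}
    sizes = clone_set.sizes()
    ploidy_weight: dict[int, int] = {}
    for c in ids:
        ploidy_weight[rounded[c]] = ploidy_weight.get(rounded[c], 0) + sizes[c]
    majority = max(sorted(ploidy_weight), key=lambda p: ploidy_weight[p])
    for c in list(ids):
        if rounded[c] == majority or c not in clone_set.members:
            continue
        own_cons = clone_set.consensus[c]
        own_scale = max(clone_set.ploidies[c], 1e-6)
        diffs = []
        for alt in clone_set.clone_ids:
            if alt == c:
                continue
            alt_cons = clone_set.consensus[alt]
            alt_scale = max(clone_set.ploidies[alt], 1e-6)
            d_cells = []
            for cell in clone_set.members[c]:
                cw = windows_by_cell[cell]
                sd = max(estimate_noise_sd(cw.rdr()), 0.03)
                own = _mean_loglik_under(cw, own_cons, own_scale, sd)
                other = _mean_loglik_under(cw, alt_cons, alt_scale, sd)
                d_cells.append(own - other)
            diffs.append((float(np.mean(d_cells)), alt))
        diffs.sort(key=lambda t: (t[0], t[1]))
        best_diff, best_alt = diffs[0]
        if best_diff < lr_tol:
            clone_set.members[best_alt].extend(clone_set.members.pop(c))
            clone_set.consensus.pop(c)
            clone_set.ploidies.pop(c)
    return clone_set


def rescue_outliers(
    clone_set: CloneSet,
    windows_by_cell: dict,
    profiles_by_cell: dict,
    lr_tol: float = PLOIDY_LR_TOL,
) -> CloneSet:
    """Re-assign outlier cells whose RDRs an existing clone explains equally well.

    Cell-level ploidy errors (half/double solutions) leave a cell's own
    decoded profile disagreeing with every clone even though its RDRs match
    one clone perfectly; such cells are recovered by comparing mean
    log-likelihoods exactly as in :func:`resolve_ploidy_artifacts`.  Cells
    whose own profile fits better by more than ``lr_tol`` nats/window (for
    example undetected S-phase cells with replication fluctuations) remain
    outliers.
    """
    from .segment import estimate_noise_sd

    kept = []
    for cell in clone_set.outlier_cells:
        cw = windows_by_cell[cell]
        sd = max(estimate_noise_sd(cw.rdr()), 0.03)
        own = profiles_by_cell[cell]
        own_ll = _mean_loglik_under(cw, own.cn, max(own.ploidy, 1e-6), sd)
        best_ll, best_clone = -np.inf, None
        for c in clone_set.clone_ids:
            ll = _mean_loglik_under(
                cw, clone_set.consensus[c], max(clone_set.ploidies[c], 1e-6), sd
            )
            if ll > best_ll:
                best_ll, best_clone = ll, c
        if best_clone is not None and own_ll - best_ll < lr_tol:
            clone_set.members[best_clone].append(cell)
        else:
            kept.append(cell)
    clone_set.outlier_cells = kept
    return clone_set
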