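"""Binned genome representation and replication-timing classification.

The genome is partitioned into fixed-width bins (50 kb by default).  Each bin
carries a GC fraction, a replication score (higher = earlier replication) and
a timing class.  Timing classes are obtained by fitting a two-component
Gaussian mixture to the replication-score distribution: bins that confidently
belong to the high-score mode are ``early``, bins in the low-score mode are
``late`` and everything else (including bins with missing scores) is
``unknown``.  Early/late bins drive the replication-aware analysis of S-phase
cells; unknown bins are retained only for copy-number analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

EARLY = "early"
LATE = "late"
UNKNOWN = "unknown"

#: canonical dtype for the timing column
TIMING_DTYPE = pd.CategoricalDtype(categories=[EARLY, LATE, UNKNOWN])


def classify_replication_timing(
    rt_scores: np.ndarray,
    confidence: float = 0.9,
    seed: int = 0,
    min_mode_separation: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Label each bin ``early``/``late``/``unknown`` from replication scores.

    A two-component Gaussian mixture (EM, 10 restarts, seeded) is fitted to
    the finite scores.  A bin is assigned to a mode when its posterior for
    that component is at least ``confidence``; the component with the higher
    mean is the early mode.  Degenerate distributions (fewer than two distinct
    values, or modes separated by less than ``min_mode_separation`` pooled
    standard deviations) yield all-``unknown`` labels with a warning.

    Returns ``(labels, info)`` where ``info`` reports the fitted means and the
    fraction of bins classified.
    """
    scores = np.asarray(rt_scores, dtype=float)
    labels = np.full(scores.shape[0], UNKNOWN, dtype=object)
    finite = np.isfinite(scores)
    x = scores[finite]
    info: dict = {"n_bins": scores.shape[0], "classified_fraction": 0.0}
    if x.size < 2 or np.unique(x).size < 2:
        warnings.warn(
            "replication-score distribution is degenerate; all bins unknown",
            stacklevel=2,
        )
        return labels, info
    gmm = GaussianMixture(
        n_components=2, n_init=10, random_state=seed, covariance_type="full"
    )
    gmm.fit(x.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    order = np.argsort(means)  # order[0] = low (late) mode, order[1] = high (early)
    pooled_sd = float(np.sqrt(np.mean(sds**2)))
    separation = abs(means[order[1]] - means[order[0]]) / max(pooled_sd, 1e-12)
    info.update(
        mean_late=float(means[order[0]]),
        mean_early=float(means[order[1]]),
        separation=float(separation),
    )
    if separation < min_mode_separation:
        warnings.warn(
            "replication-score distribution looks unimodal "
            f"(mode separation {separation:.2f} sd); all bins unknown",
            stacklevel=2,
        )
        return labels, info
    post = gmm.predict_proba(x.reshape(-1, 1))
    early_post = post[:, order[1]]
    sub = np.full(x.shape[0], UNKNOWN, dtype=object)
    sub[early_post >= confidence] = EARLY
    sub[1.0 - early_post >= confidence] = LATE
    labels[finite] = sub
    info["classified_fraction"] = float(np.mean(labels != UNKNOWN))
    return labels, info


def average_score_tracks(tracks: list[np.ndarray]) -> np.ndarray:
    """Combine several replication-score tracks into one per-bin score.

    Each track is z-scaled over its finite entries and the tracks are then
    averaged bin-wise, ignoring missing values.
    """
    scaled = []
    for t in tracks:
        t = np.asarray(t, dtype=float)
        finite = np.isfinite(t)
        mu = np.nanmean(np.where(finite, t, np.nan))
        sd = np.nanstd(np.where(finite, t, np.nan))
        scaled.append((t - mu) / max(sd, 1e-12))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.vstack(scaled), axis=0)


@dataclass
class BinnedGenome:
    """Ordered genomic bins with GC content, replication score and timing.

    ``bins`` is a DataFrame with columns ``chrom``, ``start``, ``end``
    (0-based half-open), ``gc`` (fraction in [0, 1], NaN when missing),
    ``rt_score`` and ``timing``.  Bins are sorted and non-overlapping within
    each chromosome, with equal width except possibly the last bin of a
    chromosome.
    """

    bins: pd.DataFrame
    timing_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"bin table missing columns: {sorted(missing)}")
        if (self.bins["end"] <= self.bins["start"]).any():
            raise ValueError("bins must satisfy end > start")
        for col, default in (("gc", np.nan), ("rt_score", np.nan), ("timing", UNKNOWN)):
            if col not in self.bins.columns:
                self.bins[col] = default
        self.bins = self.bins.reset_index(drop=True)
        self.bins["timing"] = self.bins["timing"].astype(TIMING_DTYPE)
        for chrom, sub in self.bins.groupby("chrom", sort=False, observed=True):
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            if not (np.diff(s) > 0).all() or (s[1:] < e[:-1]).any():
                raise ValueError(f"bins on {chrom} are unsorted or overlapping")
        gc = self.bins["gc"].to_numpy(dtype=float)
        ok = ~np.isfinite(gc) | ((gc >= 0) & (gc <= 1))
        if not ok.all():
            raise ValueError("gc values must lie in [0, 1] or be missing")

    @property
    def m(self) -> int:
        """Number of bins."""
        return len(self.bins)

    @property
    def chroms(self) -> list:
        return list(dict.fromkeys(self.bins["chrom"]))

    @property
    def timing(self) -> np.ndarray:
        return self.bins["timing"].to_numpy(dtype=object)

    @property
    def chrom_index(self) -> np.ndarray:
        """Integer chromosome index per bin (order of first appearance)."""
        mapping = {c: i for i, c in enumerate(self.chroms)}
        return self.bins["chrom"].map(mapping).to_numpy(dtype=int)

    @property
    def widths(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy(dtype=int)

    def classify_timing(self, confidence: float = 0.9, seed: int = 0) -> "BinnedGenome":
        """Fill the ``timing`` column from ``rt_score`` (in place) and return self."""
        labels, info = classify_replication_timing(
            self.bins["rt_score"].to_numpy(dtype=float), confidence=confidence, seed=seed
        )
        self.bins["timing"] = pd.Series(labels, dtype=TIMING_DTYPE)
        self.timing_info = info
        return self

    def drop_blacklisted(self, blacklist: pd.DataFrame) -> "BinnedGenome":
        """Return a genome without bins overlapping intervals in ``blacklist``
        (columns ``chrom``, ``start``, ``end``)."""
        keep = np.ones(self.m, dtype=bool)
        for _, row in blacklist.iterrows():
            hit = (
                (self.bins["chrom"] == row["chrom"])
                & (self.bins["start"] < row["end"])
                & (self.bins["end"] > row["start"])
            )
            keep &= ~hit.to_numpy()
        return BinnedGenome(self.bins.loc[keep].reset_index(drop=True).copy())


def make_bin_grid(chrom_sizes: dict[str, int], bin_width: int = 50_000) -> pd.DataFrame:
    """Tile each chromosome with ``bin_width`` bins (last bin may be short)."""
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, bin_width)
        ends = np.minimum(starts + bin_width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)
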