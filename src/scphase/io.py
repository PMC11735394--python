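"""Readers and writers for the pipeline's tabular formats.

All genomic coordinates are 0-based half-open, including bedGraph output.
Counts are accepted either as a long table (``cell_id, chrom, start, end,
count``) or as a matrix (rows = bins with ``chrom, start, end`` columns,
one column per cell).  Interval tracks (bedGraph/BED) are projected onto the
bin grid by span-weighted averaging.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinnedGenome


def read_bed_like(path, value_col: str = "score") -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", value_col],
        comment="#",
    )
    return df


def project_track_to_bins(track: pd.DataFrame, bins: pd.DataFrame, value_col: str = "score") -> np.ndarray:
    """Span-weighted average of interval values onto the bin grid.

    An interval overlapping a bin contributes its value weighted by the
    overlap span; bins with no overlap get NaN.
    """
    chroms_bins = set(bins["chrom"])
    chroms_track = set(track["chrom"])
    only_track = sorted(chroms_track - chroms_bins)
    if only_track and not (chroms_track & chroms_bins):
        raise ValueError(
            f"no chromosome names shared with the bin grid; track-only: {only_track}"
        )
    out = np.full(len(bins), np.nan)
    weight = np.zeros(len(bins))
    total = np.zeros(len(bins))
    for chrom, sub in track.groupby("chrom", sort=False):
        sel = np.flatnonzero((bins["chrom"] == chrom).to_numpy())
        if sel.size == 0:
            continue
        bstart = bins["start"].to_numpy()[sel]
        bend = bins["end"].to_numpy()[sel]
        if not np.all(np.diff(bstart) > 0):
            order = np.argsort(bstart)
            sel, bstart, bend = sel[order], bstart[order], bend[order]
        for _, row in sub.iterrows():
            lo = np.searchsorted(bend, row["start"], side="right")
            hi = np.searchsorted(bstart, row["end"], side="left")
            for i in range(lo, hi):
                ov = min(bend[i], row["end"]) - max(bstart[i], row["start"])
                if ov > 0:
                    total[sel[i]] += ov * row[value_col]
                    weight[sel[i]] += ov
    mask = weight > 0
    out[mask] = total[mask] / weight[mask]
    return out


def read_counts_matrix(path) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Matrix counts: chrom, start, end columns then one integer column per cell."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["chrom", "start", "end"]
    cells = [c for c in df.columns if c not in meta_cols]
    return df[meta_cols].copy(), df[cells].to_numpy(dtype=np.int64), cells


def read_counts_long(path, bins: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Long counts aligned to an existing bin grid; errors on unknown bins."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "chrom", "start", "end", "count"}
    if not required <= set(df.columns):
        raise ValueError(f"long count table needs columns {sorted(required)}")
    key = bins["chrom"].astype(str) + ":" + bins["start"].astype(str)
    index = pd.Series(np.arange(len(bins)), index=key)
    dkey = df["chrom"].astype(str) + ":" + df["start"].astype(str)
    bin_ix = index.reindex(dkey)
    if bin_ix.isna().any():
        bad = df.loc[bin_ix.isna().to_numpy(), ["chrom", "start"]].drop_duplicates()
        raise ValueError(f"counts reference bins absent from the grid: {bad.values[:5]}")
    cells = sorted(df["cell_id"].unique())
    cell_ix = pd.Series(range(len(cells)), index=cells)
    counts = np.zeros((len(bins), len(cells)), dtype=np.int64)
    counts[bin_ix.to_numpy(dtype=int), cell_ix[df["cell_id"]].to_numpy()] = df[
        "count"
    ].to_numpy()
    return counts, cells


def read_inputs(
    counts_path,
    rt_score_paths: list,
    gc_path=None,
    bins_path=None,
) -> tuple[BinnedGenome, np.ndarray, list]:
    """Load counts plus replication-score and GC tracks into bin-aligned form.

    ``counts_path`` may be a matrix file (carrying its own bin grid) or a
    long table (requiring ``bins_path``).  Multiple replication-score tracks
    are z-scaled and averaged per bin.
    """
    from .genome import average_score_tracks

    counts_path = Path(counts_path)
    head = pd.read_csv(counts_path, sep="\t", nrows=1)
    if {"cell_id", "count"} <= set(head.columns):
        if bins_path is None:
            raise ValueError("long-format counts require a bin grid (bins_path)")
        bins = pd.read_csv(
            bins_path, sep="\t", header=None, names=["chrom", "start", "end"]
        )
        counts, cells = read_counts_long(counts_path, bins)
    else:
        bins, counts, cells = read_counts_matrix(counts_path)
    if not bins[["chrom", "start"]].equals(
        bins.sort_values(["chrom", "start"], kind="mergesort")[["chrom", "start"]].reset_index(drop=True)
    ):
        warnings.warn("bin grid was unsorted; sorting")
        order = bins.sort_values(["chrom", "start"], kind="mergesort").index.to_numpy()
        bins = bins.iloc[order].reset_index(drop=True)
        counts = counts[order]
    tracks = [
        project_track_to_bins(read_bed_like(p), bins) for p in rt_score_paths
    ]
    bins["rt_score"] = average_score_tracks(tracks) if tracks else np.nan
    if gc_path is not None:
        bins["gc"] = project_track_to_bins(read_bed_like(gc_path, "gc"), bins, "gc")
    genome = BinnedGenome(bins)
    if counts.sum() == 0 or not cells:
        raise ValueError("no cells with reads in the input")
    return genome, counts, cells


def gc_from_fasta(fasta_path, bins: pd.DataFrame) -> np.ndarray:
    """GC fraction per bin computed from a reference FASTA (requires pyfaidx)."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    out = np.full(len(bins), np.nan)
    for i, row in bins.iterrows():
        seq = str(fa[row["chrom"]][row["start"] : row["end"]]).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt:
            out[i] = (seq.count("G") + seq.count("C")) / acgt
    return out


def write_population(result, outdir) -> None:
    """Write a simulated population in the formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bins = result.genome.bins
    matrix = pd.concat(
        [
            bins[["chrom", "start", "end"]],
            pd.DataFrame(result.counts, columns=result.cell_ids),
        ],
        axis=1,
    )
    matrix.to_csv(outdir / "counts.tsv", sep="\t", index=False)
    bins.assign(score=bins["rt_score"])[["chrom", "start", "end", "score"]].to_csv(
        outdir / "rt_scores.bedgraph", sep="\t", index=False, header=False
    )
    bins[["chrom", "start", "end", "gc"]].to_csv(
        outdir / "gc.bed", sep="\t", index=False, header=False
    )
    result.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)


def write_window_table(cells_windows: list, genome: BinnedGenome, path) -> None:
    """Per-cell window table: cell_id, chrom, start, end, timing, rdr columns."""
    rows = []
    starts = genome.bins["start"].to_numpy()
    ends = genome.bins["end"].to_numpy()
    chroms = genome.bins["chrom"].to_numpy()
    for cw in cells_windows:
        w = cw.windows
        for _, r in w.iterrows():
            rows.append(
                (
                    cw.cell_id,
                    chroms[int(r["first_bin"])],
                    int(starts[int(r["first_bin"])]),
                    int(ends[int(r["last_bin"])]),
                    r["timing"],
                    r["rdr_raw"],
                    r.get("rdr_corr", np.nan),
                )
            )
    pd.DataFrame(
        rows,
        columns=["cell_id", "chrom", "start", "end", "timing", "rdr_raw", "rdr_corrected"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
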