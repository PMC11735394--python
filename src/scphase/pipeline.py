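"""End-to-end pipeline: signals -> segmentation -> S test -> clones ->
S-cell assignment -> G2 calling -> clone summaries and ART.

Every source of randomness derives from a single global seed; per-cell
random streams are keyed by a hash of the cell id, so results do not depend
on the order in which cells are processed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import (
    assign_to_clone,
    assignment_table,
    correct_replication_fluctuations,
    correct_small_cnas,
    infer_sphase_cnas,
)
from .clones import (
    call_copy_numbers,
    cluster_cells,
    rescue_outliers,
    resolve_ploidy_artifacts,
)
from .g2 import MIN_CELLS_PER_FIT, call_g2_cells, fit_g2_mixture
from .genome import BinnedGenome
from .segment import segment_cell
from .signals import build_windows, compute_rdr, correct_gc_bias
from .sphase import (
    JointNull,
    center_class_offset,
    compute_rtp,
    correct_multiple_testing,
    layout_of,
    permutation_test,
)
from .summaries import (
    clone_average_rtp,
    infer_clone_art,
    summarize_clone_fractions,
    test_within_sample_heterogeneity,
)


@dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline (defaults are the method's
    published operating point where one exists)."""

    bin_width: int = 50_000
    timing_confidence: float = 0.9
    target_reads_per_window: int = 200
    n_permutations: int = 100_000
    fwer: float = 0.05
    min_clone_size: int = 15
    g2_threshold: float = 0.3
    n_boot: int = 300
    heterogeneity_fwer: float = 0.1
    min_s_cells_for_art: int = 10
    margin_quantile: tuple = (0.75, 0.9)
    seed: int = 0
    sample_id: str = "sample"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def cell_seed(global_seed: int, cell_id: str) -> int:
    """Stable per-cell seed (independent of processing order), < 2**31."""
    h = zlib.crc32(cell_id.encode())
    return int((np.uint64(global_seed) * np.uint64(1000003) + np.uint64(h)) % np.uint64(2**31))


def _consensus_segments(cons: np.ndarray, chrom_ix: np.ndarray) -> np.ndarray:
    """Segment id per bin induced by a clone's consensus copy numbers."""
    change = np.ones(len(cons), dtype=bool)
    change[1:] = (np.diff(cons) != 0) | (np.diff(chrom_ix) != 0)
    return np.cumsum(change) - 1


def run_pipeline(
    genome: BinnedGenome,
    counts: np.ndarray,
    cell_ids: list,
    config: PipelineConfig | None = None,
) -> dict:
    """Run all stages and return a result bundle of tables and objects.

    Bundle keys: ``genome``, ``windows`` (dict cell -> CellWindows),
    ``segmentations``, ``sphase_table``, ``clone_set``, ``assignments``,
    ``cn_profiles``, ``phases``, ``g2_fits``, ``clone_summary``,
    ``heterogeneity``, ``art`` (dict clone -> table), ``low_quality_cells``,
    ``manifest``.
    """
    if config is None:
        config = PipelineConfig()
    if len(cell_ids) == 0:
        raise ValueError("no cells")
    counts = np.asarray(counts)

    # -- step 1: timing classes, windows, RDRs, GC correction
    genome.classify_timing(confidence=config.timing_confidence, seed=config.seed)
    windows = {}
    low_quality = []
    for i, cell in enumerate(cell_ids):
        try:
            cw = build_windows(cell, counts[:, i], genome, config.target_reads_per_window)
        except ValueError:
            low_quality.append(cell)
            continue
        if cw.low_quality:
            low_quality.append(cell)
            continue
        windows[cell] = compute_rdr(cw)
    if not windows:
        raise ValueError("no cells passed quality filtering")
    correct_gc_bias(list(windows.values()))

    # -- step 2: replication-aware segmentation
    segmentations = {c: segment_cell(cw, genome) for c, cw in windows.items()}

    # -- step 3: S-phase permutation test
    rtp_tables = {
        cell: compute_rtp(cw, segmentations[cell]) for cell, cw in windows.items()
    }
    center_class_offset(rtp_tables)
    # all cells with the same testable layout share one joint permutation
    # null (the law of the statistics is rank-based and cell-independent)
    margins = (
        (config.margin_quantile,)
        if np.isscalar(config.margin_quantile)
        else tuple(config.margin_quantile)
    )
    layout_counts: dict = {}
    for cell, tbl in rtp_tables.items():
        lay = tuple(sorted(layout_of(tbl)))
        layout_counts[lay] = layout_counts.get(lay, 0) + 1
    shared_layout = max(sorted(layout_counts), key=lambda k: layout_counts[k])
    joint = (
        JointNull(
            list(shared_layout),
            margins=margins,
            n_permutations=config.n_permutations,
            seed=cell_seed(config.seed, "joint-null"),
        )
        if shared_layout
        else None
    )
    calls = []
    for cell, cw in windows.items():
        calls.append(
            permutation_test(
                rtp_tables[cell],
                n_permutations=config.n_permutations,
                seed=cell_seed(config.seed, cell),
                margin_quantile=margins,
                joint_null=joint,
                cell_id=cell,
            )
        )
    sphase_table = correct_multiple_testing(calls, fwer=config.fwer)
    s_cells = set(sphase_table.loc[sphase_table["is_s_phase"], "cell_id"])

    # -- step 4: copy numbers and clones from non-S cells
    non_s = [c for c in windows if c not in s_cells]
    profiles = {
        c: call_copy_numbers(windows[c], genome, segmentations[c]) for c in non_s
    }
    clone_set = cluster_cells(
        [profiles[c] for c in non_s], min_clone_size=config.min_clone_size
    )
    clone_set = resolve_ploidy_artifacts(clone_set, windows)
    clone_set = rescue_outliers(clone_set, windows, profiles)

    clone_of_cell = {}
    for clone, cells in clone_set.members.items():
        for c in cells:
            clone_of_cell[c] = clone
    for c in clone_set.outlier_cells:
        clone_of_cell[c] = -1

    # -- step 5: assign S cells to clones and infer their CNAs
    assignments = []
    corrected = {}
    for cell in sorted(s_cells):
        corr = correct_replication_fluctuations(windows[cell], segmentations[cell])
        corrected[cell] = corr
        a = assign_to_clone(corr, windows[cell], clone_set, segmentations[cell])
        assignments.append(a)
        clone_of_cell[cell] = a.map_clone
        prof = infer_sphase_cnas(
            corr, windows[cell], clone_set, a.map_clone, genome
        )
        profiles[cell] = correct_small_cnas(
            prof, clone_set.consensus[a.map_clone], genome
        )
    assign_table = assignment_table(assignments)

    # -- step 6: G2 cells per clone from total read counts
    totals = {c: cw.total_reads for c, cw in windows.items()}
    phases = {c: ("S" if c in s_cells else "G1") for c in windows}
    g2_fits = {}
    pooled_non_s = np.array([totals[c] for c in non_s], dtype=float)
    pooled_s = np.array([totals[c] for c in sorted(s_cells)], dtype=float)
    for clone in clone_set.clone_ids:
        members_non_s = [c for c in clone_set.members[clone]]
        members_s = [c for c in sorted(s_cells) if clone_of_cell[c] == clone]
        x = np.array([totals[c] for c in members_non_s], dtype=float)
        xs = np.array([totals[c] for c in members_s], dtype=float)
        if len(x) < MIN_CELLS_PER_FIT:
            fit = fit_g2_mixture(
                pooled_non_s, pooled_s, clone_id=clone,
                seed=cell_seed(config.seed, f"g2_pooled"),
            )
            # evaluate pooled fit on the clone's own cells
            from .g2 import _nb_logpmf

            l1 = _nb_logpmf(x, fit.mean_g1, fit.disp_g1)
            l2 = _nb_logpmf(x, fit.mean_g2, fit.disp_g2)
            mx = np.maximum(l1, l2)
            if fit.mu > 0:
                p = np.exp(l1 - mx) / (np.exp(l1 - mx) + np.exp(l2 - mx))
            else:
                p = np.ones(len(x))
            fit.p_g0g1 = p
            fit.flags["pooled_fallback"] = True
        else:
            fit = fit_g2_mixture(
                x, xs, clone_id=clone, seed=cell_seed(config.seed, f"g2_{clone}")
            )
        g2_fits[clone] = fit
        is_g2 = call_g2_cells(fit, config.g2_threshold)
        for c, g2 in zip(members_non_s, is_g2):
            if g2:
                phases[c] = "G2"

    phase_table = pd.DataFrame(
        {
            "cell_id": list(windows),
            "clone_id": [clone_of_cell.get(c, -1) for c in windows],
            "phase": [phases[c] for c in windows],
            "sample_id": config.sample_id,
        }
    ).sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    p_lookup = {
        f.clone_id: dict(zip(clone_set.members[f.clone_id], f.p_g0g1))
        for f in g2_fits.values()
        if f.clone_id in clone_set.members
    }
    phase_table["p_g0g1"] = [
        p_lookup.get(cl, {}).get(c, np.nan)
        for c, cl in zip(phase_table["cell_id"], phase_table["clone_id"])
    ]

    # -- summaries: fractions, heterogeneity, ART
    assigned = phase_table[phase_table["clone_id"] >= 0]
    clone_summary = summarize_clone_fractions(
        assigned, n_boot=config.n_boot, seed=config.seed
    )
    heterogeneity = test_within_sample_heterogeneity(
        clone_summary, fwer=config.heterogeneity_fwer
    )

    chrom_of_bin = genome.chrom_index
    art = {}
    for clone in clone_set.clone_ids:
        members_s = [c for c in sorted(s_cells) if clone_of_cell[c] == clone]
        if len(members_s) < config.min_s_cells_for_art:
            continue
        seg_of_bin = _consensus_segments(clone_set.consensus[clone], chrom_of_bin)
        tables = []
        maps = []
        for cell in members_s:
            cw = windows[cell]
            seg_win = np.full(cw.n_windows, -1, dtype=int)
            fb = cw.windows["first_bin"].to_numpy()
            seg_win = seg_of_bin[fb]
            rdr = cw.rdr()
            med = np.ones(cw.n_windows)
            t = cw.windows.copy()
            for s in np.unique(seg_win):
                sel = seg_win == s
                med[sel] = max(np.median(rdr[sel]), 1e-9)
            t["rtp"] = rdr / med
            tables.append(t)
            maps.append(cw.win_of_bin)
        avg = clone_average_rtp(tables, maps, genome.m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            art[clone] = infer_clone_art(
                avg, genome.timing, confidence=config.timing_confidence,
                seed=config.seed,
            )

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "n_cells": len(cell_ids),
        "n_low_quality": len(low_quality),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
    }
    return {
        "genome": genome,
        "windows": windows,
        "segmentations": segmentations,
        "rtp_tables": rtp_tables,
        "sphase_table": sphase_table,
        "clone_set": clone_set,
        "cn_profiles": profiles,
        "assignments": assign_table,
        "phases": phase_table,
        "g2_fits": g2_fits,
        "clone_summary": clone_summary,
        "heterogeneity": heterogeneity,
        "art": art,
        "low_quality_cells": low_quality,
        "manifest": manifest,
    }


def write_bundle(bundle: dict, outdir) -> None:
    """Write the result tables of a run (deterministic byte-identical output)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ff = "%.6g"
    bundle["sphase_table"].to_csv(outdir / "sphase.tsv", sep="\t", index=False, float_format=ff)
    bundle["clone_set"].membership_table().to_csv(
        outdir / "clones.tsv", sep="\t", index=False, float_format=ff
    )
    if len(bundle["assignments"]):
        bundle["assignments"].to_csv(
            outdir / "assignments.tsv", sep="\t", index=False, float_format=ff
        )
    bundle["phases"].to_csv(outdir / "phases.tsv", sep="\t", index=False, float_format=ff)
    bundle["clone_summary"].to_csv(
        outdir / "clone_summary.tsv", sep="\t", index=False, float_format=ff
    )
    bundle["heterogeneity"].to_csv(
        outdir / "heterogeneity.tsv", sep="\t", index=False, float_format=ff
    )
    genome = bundle["genome"]
    for clone, table in bundle["art"].items():
        t = table.copy()
        t.insert(0, "chrom", genome.bins["chrom"].to_numpy())
        t.insert(1, "start", genome.bins["start"].to_numpy())
        t.insert(2, "end", genome.bins["end"].to_numpy())
        t.insert(3, "clone_id", clone)
        t[t["art"] != "none"].to_csv(
            outdir / f"art_clone{clone}.bed", sep="\t", index=False, float_format=ff
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle["manifest"], fh, indent=2, sort_keys=True)
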