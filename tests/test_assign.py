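"""Replication-fluctuation correction, clone assignment and S-cell CNAs."""

import numpy as np
import pytest

from scphase.assign import (
    assign_to_clone,
    correct_replication_fluctuations,
    correct_small_cnas,
    infer_sphase_cnas,
)
from scphase.clones import CloneSet, CopyNumberProfile
from scphase.genome import BinnedGenome, make_bin_grid
from scphase.segment import segment_cell
from scphase.signals import build_windows, compute_rdr
from scphase.simulate import CloneSpec, SimConfig, simulate_population, _two_clone_cnas
from tests.conftest import prepare_batch


def _noiseless_cell(genome, counts):
    cw = compute_rdr(build_windows("c", counts, genome))
    cw.windows["rdr_corr"] = cw.windows["rdr_raw"]
    return cw


def _timed_genome(n_bins=800, n_chrom=4, seed=0):
    rng = np.random.default_rng(seed)
    bins = make_bin_grid(
        {f"chr{i}": (n_bins // n_chrom) * 50_000 for i in range(n_chrom)}, 50_000
    )
    g = BinnedGenome(bins)
    # alternating 10-bin early/late domains
    pattern = np.tile(np.repeat(["early", "late"], 10), n_bins // 20 + 1)[:n_bins]
    g.bins["timing"] = pattern
    g.bins["gc"] = rng.uniform(0.4, 0.5, n_bins)
    return g


def test_noiseless_g1_cell_correction_is_identity():
    g = _timed_genome()
    cw = _noiseless_cell(g, np.full(g.m, 300))
    seg = segment_cell(cw, g)
    corr = correct_replication_fluctuations(cw, seg)
    assert np.max(np.abs(corr.rdr - cw.rdr())) < 1e-6
    # segment medians preserved exactly on noiseless input
    for s in np.unique(seg.seg_of_window):
        sel = seg.seg_of_window == s
        assert np.median(corr.rdr[sel]) == pytest.approx(np.median(cw.rdr()[sel]))


def test_correction_restores_copy_number_signal_mid_s():
    # mid-S cells from a cn2/cn3 clone at the stated noise level (sd ~ 0.05):
    # correction lifts the correlation with true cn far above the raw RDR
    cfg = SimConfig(
        clones=[CloneSpec("B", 8, cnas=_two_clone_cnas(), s_fraction=1.0)],
        s_progression_range=(0.45, 0.55),
        reads_per_cell=1e6,
        overdispersion=1000.0,
    )
    res = simulate_population(cfg, seed=5)
    genome, cells = prepare_batch(res)
    truecn = res.clone_profiles["B"]
    r_raw, r_corr = [], []
    for cw in cells:
        seg = segment_cell(cw, genome)
        corr = correct_replication_fluctuations(cw, seg)
        fb = cw.windows["first_bin"].to_numpy()
        r_raw.append(np.corrcoef(cw.rdr(), truecn[fb])[0, 1])
        r_corr.append(np.corrcoef(corr.rdr, truecn[fb])[0, 1])
    assert np.median(r_raw) <= 0.8
    assert np.median(r_corr) >= 0.90


def test_prior_only_posteriors_for_identical_clones(g1_batch):
    res, genome, cells = g1_batch
    cw = cells[0]
    seg = segment_cell(cw, genome)
    corr = correct_replication_fluctuations(cw, seg)
    cons = np.full(genome.m, 2)
    cs = CloneSet(
        members={0: [f"x{i}" for i in range(90)], 1: [f"y{i}" for i in range(10)]},
        consensus={0: cons, 1: cons.copy()},
        ploidies={0: 2.0, 1: 2.0},
    )
    a = assign_to_clone(corr, cw, cs, seg)
    assert a.posteriors.sum() == pytest.approx(1.0)
    assert a.posteriors[0] == pytest.approx(0.9, abs=1e-6)
    assert a.map_clone == 0
    # single clone: posterior 1
    cs1 = CloneSet(members={0: ["x"]}, consensus={0: cons}, ploidies={0: 2.0})
    a1 = assign_to_clone(corr, cw, cs1, seg)
    assert a1.posteriors[0] == pytest.approx(1.0)


def test_assignment_invariant_to_clone_ordering(mid_s_batch):
    res, genome, cells = mid_s_batch
    truth = res.cells
    s_ix = truth.index[truth["phase"] == "S"][0]
    cw = cells[s_ix]
    seg = segment_cell(cw, genome)
    corr = correct_replication_fluctuations(cw, seg)
    cons_a = np.full(genome.m, 2)
    cons_b = cons_a.copy()
    cons_b[:500] = 3
    cs = CloneSet(
        members={0: ["a"] * 30, 1: ["b"] * 30},
        consensus={0: cons_a, 1: cons_b},
        ploidies={0: 2.0, 1: float(cons_b.mean())},
    )
    cs_swapped = CloneSet(
        members={0: ["b"] * 30, 1: ["a"] * 30},
        consensus={0: cons_b, 1: cons_a},
        ploidies={0: float(cons_b.mean()), 1: 2.0},
    )
    a = assign_to_clone(corr, cw, cs, seg)
    b = assign_to_clone(corr, cw, cs_swapped, seg)
    assert a.posteriors[0] == pytest.approx(b.posteriors[1], abs=1e-9)


def test_infer_cnas_flat_profile_is_diploid():
    g = _timed_genome()
    cw = _noiseless_cell(g, np.full(g.m, 300))
    seg = segment_cell(cw, g)
    corr = correct_replication_fluctuations(cw, seg)
    cons = np.full(g.m, 2)
    cs = CloneSet(members={0: ["x"] * 20}, consensus={0: cons}, ploidies={0: 2.0})
    prof = infer_sphase_cnas(corr, cw, cs, 0, g)
    assert (prof.cn == 2).all()


def _small_cna_genome():
    g = _timed_genome(n_bins=800, n_chrom=4)
    return g


def test_small_cna_correction_rules():
    g = _small_cna_genome()
    cons = np.full(g.m, 2)
    # 1-Mb (20-bin) deviation inside a single timing class -> reverted;
    # craft it inside one early domain block extended: use 15 bins of an
    # early run (bins 0..9 early, 20..29 early...) -> pick bins 0..9 (early)
    cn = cons.copy()
    cn[0:10] = 3  # 0.5 Mb, single class
    prof = CopyNumberProfile("c", cn.copy(), cn.mean(), 2.0, 0.0)
    out = correct_small_cnas(prof, cons, g)
    assert (out.cn == cons).all()
    # 10-Mb (200-bin) deviation spanning both classes -> kept
    cn2 = cons.copy()
    cn2[0:200] = 3
    prof2 = CopyNumberProfile("c", cn2.copy(), cn2.mean(), 2.0, 0.0)
    out2 = correct_small_cnas(prof2, cons, g)
    assert (out2.cn == cn2).all()
    # exact doubling of the consensus over a run -> replication residue,
    # reverted even though large
    cn3 = cons.copy()
    cn3[0:200] = 4
    prof3 = CopyNumberProfile("c", cn3.copy(), cn3.mean(), 2.0, 0.0)
    out3 = correct_small_cnas(prof3, cons, g)
    assert (out3.cn == cons).all()
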