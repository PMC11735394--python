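"""Window sizing, RDR normalisation and replication-aware GC correction."""

import warnings

import numpy as np
import pytest

from scphase.genome import BinnedGenome, EARLY, LATE, make_bin_grid
from scphase.signals import (
    build_windows,
    compute_rdr,
    correct_gc_bias,
    correct_gc_bias_pooled,
    early_late_separation,
    select_window_size,
)
from scphase.simulate import CloneSpec, SimConfig, simulate_population
from tests.conftest import prepare_batch


def _toy_genome(n_bins=600, n_chrom=3, width=50_000, seed=0):
    rng = np.random.default_rng(seed)
    per = n_bins // n_chrom
    bins = make_bin_grid({f"chr{i}": per * width for i in range(n_chrom)}, width)
    g = BinnedGenome(bins)
    timing = np.where(rng.random(n_bins) < 0.5, EARLY, LATE)
    g.bins["timing"] = timing
    g.bins["timing"] = g.bins["timing"].astype(g.bins["timing"].dtype)
    g.bins["gc"] = rng.uniform(0.35, 0.55, n_bins)
    return g


def test_window_size_arithmetic_and_halving():
    g = _toy_genome()
    counts = np.full(g.m, 100)
    assert select_window_size(counts, g, target_reads_per_window=300) == 3
    # halving all counts doubles the bins per window
    assert select_window_size(counts // 2, g, target_reads_per_window=300) == 6
    cw = build_windows("c", counts, g, 300)
    sizes = cw.windows["n_bins"].to_numpy()
    assert sizes.max() == 3
    # identical counts give identical windows
    cw2 = build_windows("c2", counts.copy(), g, 300)
    assert np.array_equal(cw.win_of_bin, cw2.win_of_bin)


def test_rdr_uniform_scaling_and_arm_doubling():
    g = _toy_genome()
    counts = np.full(g.m, 100)
    cw = compute_rdr(build_windows("c", counts, g, 100))
    assert np.allclose(cw.rdr(corrected=False), 1.0)
    assert abs(cw.rdr(corrected=False).mean() - 1.0) < 1e-9
    # scaling counts x5 leaves rdr unchanged
    cw5 = compute_rdr(build_windows("c", counts * 5, g, 100))
    assert np.allclose(cw.rdr(corrected=False), cw5.rdr(corrected=False))
    # doubling counts on 10% of the genome: closed-form normalisation
    doubled = counts.copy()
    doubled[:60] *= 2  # 60 of 600 bins
    cwd = compute_rdr(build_windows("c", doubled, g, 100))
    w = cwd.windows
    on_arm = w["first_bin"] < 60
    assert np.allclose(cwd.rdr(corrected=False)[on_arm.to_numpy()], 2 / 1.1, atol=1e-9)
    assert np.allclose(cwd.rdr(corrected=False)[~on_arm.to_numpy()], 1 / 1.1, atol=1e-9)


def test_zero_read_window_gets_pseudocount_and_flag():
    g = _toy_genome()
    counts = np.full(g.m, 50)
    counts[:3] = 0
    cw = compute_rdr(build_windows("c", counts, g, 50))
    assert cw.flags.get("zero_read_windows", 0) >= 1
    assert (cw.rdr(corrected=False) > 0).all()


def test_window_sizing_equalises_null_rdr_variance_across_depths():
    # sparse bins relative to the window target: cells with 4x different
    # totals end up with near-equal expected reads per window, hence
    # near-equal null RDR sampling variance
    g = _toy_genome(n_bins=20_000, n_chrom=4)
    rng = np.random.default_rng(3)
    sds = []
    for total in (2.5e5, 1e6):
        lam = total / g.m
        counts = rng.poisson(lam, g.m)
        cw = compute_rdr(build_windows("c", counts, g, 200))
        sds.append(np.std(cw.rdr(corrected=False)))
    ratio = (sds[0] / sds[1]) ** 2
    assert 0.8 < ratio < 1.25


def test_gc_correction_noop_without_bias():
    cfg = SimConfig(clones=[CloneSpec("g", 12)], gc_bias=0.0)
    res = simulate_population(cfg, seed=7)
    genome, cells = prepare_batch(res)
    for cw in cells:
        diff = np.abs(np.log(cw.rdr()) - np.log(cw.rdr(corrected=False)))
        assert np.max(diff) < 0.02


def test_gc_correction_removes_injected_bias():
    cfg = SimConfig(clones=[CloneSpec("g", 15)], gc_bias=1.5)
    res = simulate_population(cfg, seed=8)
    genome, cells = prepare_batch(res)
    for cw in cells[:8]:
        w = cw.windows
        sel = (w["timing"] != "unknown").to_numpy()
        slope = np.polyfit(
            w["gc"].to_numpy()[sel], np.log(cw.rdr())[sel], 1
        )[0]
        assert abs(slope) < 0.15


def test_stratified_correction_preserves_replication_separation(mid_s_batch):
    # pooled lowess regresses the replication signal out together with GC;
    # the timing-stratified fit keeps nearly all of it
    res, genome, cells = mid_s_batch
    truth = res.cells
    kept, pooled = [], []
    for i, cw in enumerate(cells):
        if truth["phase"][i] != "S":
            continue
        # truth separation from the noiseless expected profile (cn x factor)
        fb = cw.windows["first_bin"].to_numpy()
        factor = np.where(res.replicated[i][fb], 2.0, 1.0)
        sep_true = early_late_separation(cw, factor / factor.mean())
        sep_corr = early_late_separation(cw)
        sep_pool = early_late_separation(cw, correct_gc_bias_pooled(cw))
        kept.append((sep_corr - 1) / (sep_true - 1))
        pooled.append((sep_pool - 1) / (sep_true - 1))
    assert np.median(kept) >= 0.9
    assert np.median(pooled) <= 0.5


def test_pooled_fallback_warns_on_tiny_cells():
    g = _toy_genome(n_bins=60, n_chrom=1)
    rng = np.random.default_rng(5)
    cells = [
        compute_rdr(build_windows(f"c{i}", rng.poisson(100, g.m), g, 400))
        for i in range(3)
    ]
    with pytest.warns(UserWarning, match="pooled"):
        correct_gc_bias(cells, min_windows=20, min_batch=10)
    assert all(c.flags.get("gc_pooled_fallback") for c in cells)
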