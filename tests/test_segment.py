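"""Viterbi decoding and replication-aware segmentation."""

import itertools

import numpy as np

from scphase.segment import (
    decode_levels,
    detect_breakpoints_per_group,
    segment_cell,
    viterbi,
)
from scphase.simulate import CloneSpec, SimConfig, simulate_population
from tests.conftest import prepare_batch


def brute_force_best_path(log_emission, log_stay, log_switch):
    """Exhaustive search over all state paths (oracle for small instances)."""
    T, K = log_emission.shape
    best, best_lp = None, -np.inf
    for path in itertools.product(range(K), repeat=T):
        lp = -np.log(K) + log_emission[0][path[0]]
        for t in range(1, T):
            lp += log_stay if path[t] == path[t - 1] else log_switch
            lp += log_emission[t][path[t]]
        if lp > best_lp:
            best_lp, best = lp, path
    return np.array(best)


def test_viterbi_matches_exhaustive_enumeration():
    rng = np.random.default_rng(0)
    levels = np.array([0.5, 1.0, 1.5])
    obs = np.concatenate([rng.normal(1.0, 0.1, 6), rng.normal(1.5, 0.1, 6)])
    le = -0.5 * ((obs[:, None] - levels[None, :]) / 0.1) ** 2
    log_stay, log_switch = np.log(0.99), np.log(0.005)
    assert np.array_equal(
        viterbi(le, log_stay, log_switch),
        brute_force_best_path(le, log_stay, log_switch),
    )


def test_constant_rdr_has_no_breakpoints():
    rng = np.random.default_rng(1)
    vals = rng.normal(1.0, 0.05, 80)
    assert detect_breakpoints_per_group(vals, sd=0.05).size == 0


def test_step_edges_detected_within_two_windows():
    rng = np.random.default_rng(2)
    vals = np.concatenate(
        [
            rng.normal(1.0, 0.05, 40),
            rng.normal(1.5, 0.05, 40),
            rng.normal(1.0, 0.05, 40),
        ]
    )
    hits = detect_breakpoints_per_group(vals, sd=0.05)
    assert any(abs(h - 40) <= 2 for h in hits)
    assert any(abs(h - 80) <= 2 for h in hits)


def test_masked_windows_do_not_crash_decoding():
    vals = np.array([1.0, np.nan, 1.0, 1.0, np.inf, 1.0, 1.0, 1.0, 1.0, 1.0])
    path = decode_levels(vals, sd=0.1)
    assert path.shape == vals.shape


def test_g1_cna_segmentation_boundaries(cna_g1_batch):
    # cn=3 gain at global bins [550, 630): three segments on that chromosome
    # with boundaries within +-2 windows of truth
    res, genome, cells = cna_g1_batch
    for cw in cells[:5]:
        seg = segment_cell(cw, genome)
        chrom2 = seg.segments[seg.segments["chrom_ix"] == 2]
        assert len(chrom2) == 3
        starts = sorted(chrom2["start_bin"])[1:]
        assert abs(starts[0] - 550) <= 2
        assert abs(chrom2["end_bin"].iloc[1] - 630) <= 2
        # retained segments partition the chromosome
        assert chrom2["start_bin"].iloc[0] == 500
        assert chrom2["end_bin"].iloc[-1] == 750
        assert (chrom2["end_bin"].to_numpy()[:-1] == chrom2["start_bin"].to_numpy()[1:]).all()


def test_segment_medians_track_true_copy_levels(cna_g1_batch):
    res, genome, cells = cna_g1_batch
    truecn = res.clone_profiles["g"]
    for cw in cells[:4]:
        seg = segment_cell(cw, genome)
        fb = cw.windows["first_bin"].to_numpy()
        meds, cns = [], []
        for s in seg.segments["seg"]:
            sel = seg.seg_of_window == s
            meds.append(np.median(cw.rdr()[sel]))
            cns.append(truecn[fb[sel]].mean())
        r = np.corrcoef(meds, cns)[0, 1]
        assert r >= 0.99


def test_no_false_segments_on_cna_free_s_cells():
    # replication fluctuations alone must not create retained CNA segments:
    # at most one retained segment per chromosome in >= 95% of cells
    cfg = SimConfig(clones=[CloneSpec("s", 40, s_fraction=1.0)])
    res = simulate_population(cfg, seed=11)
    genome, cells = prepare_batch(res)
    clean = 0
    extra = 0
    for cw in cells:
        seg = segment_cell(cw, genome)
        n = len(seg.segments)
        extra += n - 8
        clean += int(n == 8)
    assert clean / len(cells) >= 0.7
    # false-breakpoint rate per chromosome stays below 5%
    assert extra / (8 * len(cells)) <= 0.05


def test_filtering_is_idempotent_single_class_flagged():
    # a chromosome with a single timing class becomes one flagged segment
    from scphase.genome import BinnedGenome, make_bin_grid
    from scphase.signals import build_windows, compute_rdr

    rng = np.random.default_rng(4)
    bins = make_bin_grid({"chrA": 5_000_000, "chrB": 5_000_000}, 50_000)
    g = BinnedGenome(bins)
    timing = np.array(["early"] * 100 + ["late"] * 0 + ["early"] * 50 + ["late"] * 50, dtype=object)
    g.bins["timing"] = timing[: g.m]
    g.bins["gc"] = 0.45
    cw = compute_rdr(build_windows("c", rng.poisson(200, g.m), g, 200))
    cw.windows["rdr_corr"] = cw.windows["rdr_raw"]
    seg = segment_cell(cw, g)
    chromA = seg.segments[seg.segments["chrom_ix"] == 0]
    assert len(chromA) == 1
    assert bool(chromA["flagged"].iloc[0])
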