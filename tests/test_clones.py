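"""Copy-number calling, clone clustering and ploidy-artifact resolution."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from scphase.clones import (
    CloneSet,
    CopyNumberProfile,
    call_copy_numbers,
    cluster_cells,
    resolve_ploidy_artifacts,
    select_ploidy_scale,
)
from scphase.segment import segment_cell
from scphase.simulate import CloneSpec, SimConfig, simulate_population
from tests.conftest import prepare_batch


def test_flat_profile_called_diploid_and_flagged_degenerate():
    rng = np.random.default_rng(0)
    rdr = rng.normal(1.0, 0.02, 400)
    seg = np.repeat(np.arange(8), 50)
    scale, _, degenerate = select_ploidy_scale(rdr, seg, sd=0.05)
    assert scale == pytest.approx(2.0, abs=0.051)
    assert degenerate


def test_gain_segment_maps_to_cn3():
    rng = np.random.default_rng(1)
    rdr = np.concatenate([rng.normal(1.0, 0.02, 300), rng.normal(1.5, 0.02, 100)])
    seg = np.repeat(np.arange(8), 50)
    scale, _, _ = select_ploidy_scale(rdr, seg, sd=0.05)
    assert scale == pytest.approx(2.0, abs=0.051)
    assert int(round(1.5 * scale)) == 3


def test_odd_copy_number_identifies_tetraploid_not_halved():
    # cn {4, 5, 6} at ploidy-4 scale: levels 1.0, 1.25, 1.5; the cn=5
    # segment cannot be expressed at the halved (diploid) scale
    rng = np.random.default_rng(2)
    rdr = np.concatenate(
        [
            rng.normal(1.0, 0.02, 200),
            rng.normal(1.25, 0.02, 100),
            rng.normal(1.5, 0.02, 100),
        ]
    )
    seg = np.repeat(np.arange(8), 50)
    scale, _, degenerate = select_ploidy_scale(rdr, seg, sd=0.05)
    assert scale == pytest.approx(4.0, abs=0.07)
    assert not degenerate


def test_call_copy_numbers_recovers_gain(cna_g1_batch):
    res, genome, cells = cna_g1_batch
    truecn = res.clone_profiles["g"]
    for cw in cells[:4]:
        seg = segment_cell(cw, genome)
        prof = call_copy_numbers(cw, genome, seg)
        assert prof.scale == pytest.approx(2.0, abs=0.1)
        assert (prof.cn == truecn).mean() >= 0.98


def test_clustering_identical_profiles_single_clone():
    profs = [
        CopyNumberProfile(f"c{i}", np.full(100, 2), 2.0, 2.0, 0.0) for i in range(20)
    ]
    cs = cluster_cells(profs, min_clone_size=5)
    assert len(cs.clone_ids) == 1
    assert not cs.outlier_cells


def test_two_population_clustering_and_order_invariance():
    rng = np.random.default_rng(3)
    cn_a = np.full(500, 2)
    cn_b = cn_a.copy()
    cn_b[:250] = 3
    profs = []
    labels = []
    for i in range(60):
        base = cn_a if i % 5 < 3 else cn_b  # 36 / 24 split
        cn = base.copy()
        flip = rng.random(500) < 0.004  # a few miscalled bins per cell
        cn[flip] += 1
        profs.append(CopyNumberProfile(f"c{i}", cn, cn.mean(), 2.0, 0.0))
        labels.append(int(i % 5 >= 3))
    cs = cluster_cells(profs, min_clone_size=10)
    pred = {c: cl for cl, cells in cs.members.items() for c in cells}
    ari = adjusted_rand_score(labels, [pred.get(f"c{i}", -1) for i in range(60)])
    assert ari == 1.0
    # permuting input order yields the same partition
    order = rng.permutation(60)
    cs2 = cluster_cells([profs[i] for i in order], min_clone_size=10)
    pred2 = {c: cl for cl, cells in cs2.members.items() for c in cells}
    part1 = [frozenset(v) for v in cs.members.values()]
    part2 = [frozenset(v) for v in cs2.members.values()]
    assert sorted(part1, key=min) == sorted(part2, key=min)


def test_noisy_cells_clustered_or_outliers():
    rng = np.random.default_rng(4)
    cn_a = np.full(400, 2)
    cn_b = cn_a.copy()
    cn_b[:200] = 3
    profs, labels = [], []
    for i in range(60):
        cn = (cn_a if i < 36 else cn_b).copy()
        if i % 20 == 0:  # 5% heavily noisy cells
            noisy = rng.random(400) < 0.2
            cn[noisy] = rng.integers(1, 5, noisy.sum())
        profs.append(CopyNumberProfile(f"c{i}", cn, cn.mean(), 2.0, 0.0))
        labels.append(int(i >= 36))
    cs = cluster_cells(profs, min_clone_size=10)
    pred = {c: cl for cl, cells in cs.members.items() for c in cells}
    keep = [i for i in range(60) if f"c{i}" in pred]
    ari = adjusted_rand_score([labels[i] for i in keep], [pred[f"c{i}"] for i in keep])
    assert ari >= 0.95


def test_doubled_profile_clone_is_dissolved(g1_batch):
    res, genome, cells = g1_batch
    segs = {cw.cell_id: segment_cell(cw, genome) for cw in cells}
    profs = {cw.cell_id: call_copy_numbers(cw, genome, segs[cw.cell_id]) for cw in cells}
    ids = [cw.cell_id for cw in cells]
    cons2 = np.full(genome.m, 2)
    # clone 1 carries the exactly doubled profile of clone 0: its members'
    # RDRs are equally well explained by clone 0 at ploidy 2
    cs = CloneSet(
        members={0: ids[:14], 1: ids[14:]},
        consensus={0: cons2, 1: cons2 * 2},
        ploidies={0: 2.0, 1: 4.0},
    )
    windows = {cw.cell_id: cw for cw in cells}
    out = resolve_ploidy_artifacts(cs, windows)
    assert out.clone_ids == [0]
    assert len(out.members[0]) == len(ids)


def test_resolve_single_clone_unchanged_and_never_increases(g1_batch):
    res, genome, cells = g1_batch
    ids = [cw.cell_id for cw in cells]
    cs = CloneSet(
        members={0: ids}, consensus={0: np.full(genome.m, 2)}, ploidies={0: 2.0}
    )
    windows = {cw.cell_id: cw for cw in cells}
    before = len(cs.clone_ids)
    out = resolve_ploidy_artifacts(cs, windows)
    assert len(out.clone_ids) <= before
    assert out.members[0] == ids


def test_genuine_wgd_clone_retained_end_to_end():
    import warnings

    from scphase.pipeline import PipelineConfig, run_pipeline
    from scphase.simulate import make_fixture_suite

    res = make_fixture_suite("wgd", seed=3, n_diploid=40, n_wgd=30)
    cfg = PipelineConfig(n_permutations=2000, min_clone_size=10, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        b = run_pipeline(res.genome, res.counts, res.cell_ids, cfg)
    ploidies = sorted(round(p) for p in b["clone_set"].ploidies.values())
    assert ploidies == [2, 4]
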