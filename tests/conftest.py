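"""Shared fixtures: small simulated batches prepared once per session."""

import warnings

import numpy as np
import pytest

from scphase.signals import build_windows, compute_rdr, correct_gc_bias
from scphase.simulate import CloneSpec, SimConfig, simulate_population


def prepare_batch(result):
    """Windows + RDR + GC correction for every cell of a simulation."""
    genome = result.genome.classify_timing()
    cells = []
    for i, cid in enumerate(result.cell_ids):
        cells.append(compute_rdr(build_windows(cid, result.counts[:, i], genome)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        correct_gc_bias(cells)
    return genome, cells


@pytest.fixture(scope="session")
def g1_batch():
    """20 diploid G0/G1 cells, no CNAs (null material)."""
    res = simulate_population(
        SimConfig(clones=[CloneSpec("g1", 20)]), seed=101
    )
    genome, cells = prepare_batch(res)
    return res, genome, cells


@pytest.fixture(scope="session")
def mid_s_batch():
    """Mixed batch: 30 G1 cells plus 10 mid-S cells (f in 0.45-0.55)."""
    cfg = SimConfig(
        clones=[CloneSpec("g1", 30), CloneSpec("s", 10, s_fraction=1.0)],
        s_progression_range=(0.45, 0.55),
    )
    res = simulate_population(cfg, seed=202)
    genome, cells = prepare_batch(res)
    return res, genome, cells


@pytest.fixture(scope="session")
def cna_g1_batch():
    """G0/G1 cells carrying one 4-Mb cn=3 gain on chromosome 3."""
    cfg = SimConfig(clones=[CloneSpec("g", 8, cnas=[(2, 50, 130, 3)])])
    res = simulate_population(cfg, seed=303)
    genome, cells = prepare_batch(res)
    return res, genome, cells
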