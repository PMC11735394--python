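"""Synthetic single-cell whole-genome count simulator with ground truth.

Emulates tagmentation-style scDNA-seq of a heterogeneous tumor: clones with
specified ploidies and CNAs, cell-cycle phases per clone, replication-driven
count fluctuations in S-phase cells structured by an early/late timing
profile, DNA-content doubling in G2 cells, GC bias and negative-binomial
overdispersion.  Every cell carries full ground-truth labels (clone, phase,
S progression, per-bin replicated flags), which makes the whole pipeline
testable at desk scale.

The replication-score track is built from alternating early/late domains
with geometric lengths (median a few hundred kb at 50-kb bins, matching the
short replication domains that motivate the replication-aware segmentation),
and GC content is positively correlated with early timing as it is in real
genomes -- the property that makes naive GC correction destructive for
S-phase signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import BinnedGenome


@dataclass
class CloneSpec:
    """One simulated clone: size, ploidy, CNAs and phase fractions.

    ``cnas`` entries are ``(chrom_ix, start_bin, end_bin, cn)`` with bin
    coordinates local to the chromosome, half-open.  ``rt_flip_regions``
    invert the replication order inside the region (ART ground truth).
    """

    name: str
    n_cells: int
    ploidy: int = 2
    cnas: list = field(default_factory=list)
    s_fraction: float = 0.0
    g2_fraction: float = 0.0
    rt_flip_regions: list = field(default_factory=list)

    def validate(self, n_chromosomes: int, bins_per_chrom: int) -> None:
        if not 0 <= self.s_fraction <= 1 or not 0 <= self.g2_fraction <= 1:
            raise ValueError(f"clone {self.name}: phase fractions must be in [0,1]")
        if self.s_fraction + self.g2_fraction > 1:
            raise ValueError(f"clone {self.name}: S + G2 fraction exceeds 1")
        for interval in list(self.cnas) + [(*r, None) for r in self.rt_flip_regions]:
            ci, lo, hi = interval[0], interval[1], interval[2]
            if not (0 <= ci < n_chromosomes and 0 <= lo < hi <= bins_per_chrom):
                raise ValueError(
                    f"clone {self.name}: interval (chrom {ci}, bins [{lo},{hi})) "
                    "outside chromosome bounds"
                )


@dataclass
class SimConfig:
    """Study conditions of the simulated population (defaults are the
    conditions used throughout the test-bench)."""

    n_chromosomes: int = 8
    bins_per_chrom: int = 250
    bin_width: int = 50_000
    #: mean early/late domain length in bins (geometric)
    domain_length_mean: float = 8.0
    rt_mode: float = 1.0  # modes at +/- rt_mode
    rt_mode_sd: float = 0.25
    gc_base: float = 0.45
    gc_timing_amplitude: float = 0.045
    gc_noise_sd: float = 0.035
    clones: list = field(default_factory=lambda: [CloneSpec("clone0", 100)])
    reads_per_cell: float = 5e5
    reads_log_sd: float = 0.15
    #: negative-binomial size parameter per bin (larger = less overdispersed)
    overdispersion: float = 300.0
    gc_bias: float = 1.0
    #: logistic jitter width of the replication front, in rank-quantile units
    s_jitter: float = 0.05
    #: per-bin probability of flipping the replication state (salt-and-pepper
    #: noise on top of the domain-coherent replication front)
    bin_flip_prob: float = 0.02
    g2_attenuation: float = 1.0
    s_progression_range: tuple = (0.02, 0.98)
    #: sd of noise added to the score before ranking the replication order
    rank_noise_sd: float = 0.0
    #: optional private CNA carried by every S cell: (chrom_ix, lo, hi, cn)
    private_cna_s_cells: tuple | None = None

    @property
    def m(self) -> int:
        return self.n_chromosomes * self.bins_per_chrom


@dataclass
class SimResult:
    genome: BinnedGenome
    counts: np.ndarray  # (m, n_cells) integer matrix
    cells: pd.DataFrame  # cell_id, clone, phase, s_progression, total_reads
    replicated: np.ndarray  # (n_cells, m) bool
    clone_profiles: dict  # clone name -> true cn per bin
    true_timing: np.ndarray  # 'early'/'late' domain label per bin
    rep_quantile: dict  # clone name -> replication-order quantile per bin
    config: SimConfig

    @property
    def cell_ids(self) -> list:
        return list(self.cells["cell_id"])

    def counts_of(self, cell_id: str) -> np.ndarray:
        ix = self.cell_ids.index(cell_id)
        return self.counts[:, ix]


def simulate_genome(config: SimConfig, rng: np.random.Generator):
    """Replication-score and GC tracks with alternating early/late domains.

    Returns ``(genome, domain_label, domain_id)``; domains are the contiguous
    same-timing runs along which replication fires coherently.
    """
    m = config.m
    domain = np.empty(m, dtype=object)
    domain_id = np.empty(m, dtype=int)
    score = np.empty(m)
    p = 1.0 / config.domain_length_mean
    did = 0
    for ci in range(config.n_chromosomes):
        pos = 0
        current = "early" if rng.random() < 0.5 else "late"
        while pos < config.bins_per_chrom:
            length = min(int(rng.geometric(p)), config.bins_per_chrom - pos)
            lo = ci * config.bins_per_chrom + pos
            domain[lo : lo + length] = current
            domain_id[lo : lo + length] = did
            mode = config.rt_mode if current == "early" else -config.rt_mode
            score[lo : lo + length] = rng.normal(mode, config.rt_mode_sd, length)
            pos += length
            did += 1
            current = "late" if current == "early" else "early"
    gc = (
        config.gc_base
        + config.gc_timing_amplitude * np.tanh(score)
        + rng.normal(0.0, config.gc_noise_sd, m)
    )
    gc = np.clip(gc, 0.25, 0.75)
    bins = pd.DataFrame(
        {
            "chrom": np.repeat(
                [f"chr{i + 1}" for i in range(config.n_chromosomes)],
                config.bins_per_chrom,
            ),
            "start": np.tile(
                np.arange(config.bins_per_chrom) * config.bin_width,
                config.n_chromosomes,
            ),
            "end": np.tile(
                (np.arange(config.bins_per_chrom) + 1) * config.bin_width,
                config.n_chromosomes,
            ),
            "gc": gc,
            "rt_score": score,
        }
    )
    return BinnedGenome(bins), domain, domain_id


def _clone_cn(config: SimConfig, spec: CloneSpec) -> np.ndarray:
    cn = np.full(config.m, spec.ploidy, dtype=int)
    for ci, lo, hi, c in spec.cnas:
        cn[ci * config.bins_per_chrom + lo : ci * config.bins_per_chrom + hi] = c
    return cn


def simulate_population(config: SimConfig, seed: int = 0) -> SimResult:
    """Generate the binned count matrix and full ground truth for a population.

    Expected bin count is proportional to ``cn x replication_factor x
    exp(gc_bias * gc)`` with replication factor 2 for replicated bins; counts
    are gamma-Poisson (negative binomial) around the cell's total-read draw.
    S cells replicate bins whose replication-order quantile lies below their
    progression ``f`` up to logistic jitter; G2 cells have every bin
    replicated and draw about twice the G1 total read count.
    """
    rng = np.random.default_rng(seed)
    for spec in config.clones:
        spec.validate(config.n_chromosomes, config.bins_per_chrom)
    genome, domain, domain_id = simulate_genome(config, rng)
    m = config.m

    rep_quantile: dict = {}
    clone_profiles: dict = {}
    for spec in config.clones:
        score_eff = genome.bins["rt_score"].to_numpy().copy()
        for ci, lo, hi in spec.rt_flip_regions:
            g0 = ci * config.bins_per_chrom
            score_eff[g0 + lo : g0 + hi] *= -1.0
        if config.rank_noise_sd > 0:
            score_eff = score_eff + rng.normal(0, config.rank_noise_sd, m)
        order = np.argsort(np.argsort(-score_eff))  # 0 = earliest
        rep_quantile[spec.name] = (order + 0.5) / m
        clone_profiles[spec.name] = _clone_cn(config, spec)

    gc = genome.bins["gc"].to_numpy()
    gc_term = np.exp(config.gc_bias * (gc - gc.mean()))

    rows = []
    counts = []
    replicated_all = []
    r = config.overdispersion
    cell_ix = 0
    for spec in config.clones:
        n_s = int(round(spec.s_fraction * spec.n_cells))
        n_g2 = int(round(spec.g2_fraction * spec.n_cells))
        phases = ["S"] * n_s + ["G2"] * n_g2 + ["G1"] * (spec.n_cells - n_s - n_g2)
        q = rep_quantile[spec.name]
        cn = clone_profiles[spec.name].astype(float)
        for phase in phases:
            cell_id = f"{spec.name}_c{cell_ix:05d}"
            cell_ix += 1
            f = np.nan
            if phase == "G1":
                rep = np.zeros(m, dtype=bool)
            elif phase == "G2":
                rep = np.ones(m, dtype=bool)
            else:
                f = rng.uniform(*config.s_progression_range)
                # domain-coherent replication front: each domain fires as a
                # unit with logistic jitter, plus rare per-bin flips
                qbar = np.bincount(domain_id, weights=q) / np.bincount(domain_id)
                p_dom = 1.0 / (1.0 + np.exp(-(f - qbar) / config.s_jitter))
                rep = (rng.random(p_dom.size) < p_dom)[domain_id]
                if config.bin_flip_prob > 0:
                    rep = rep ^ (rng.random(m) < config.bin_flip_prob)
            cn_cell = cn.copy()
            if phase == "S" and config.private_cna_s_cells is not None:
                ci, lo, hi, c = config.private_cna_s_cells
                g0 = ci * config.bins_per_chrom
                cn_cell[g0 + lo : g0 + hi] = c
            factor = np.where(rep, 2.0, 1.0)
            content_ratio = float(np.sum(cn_cell * factor) / np.sum(cn_cell))
            t_base = float(
                np.exp(rng.normal(np.log(config.reads_per_cell), config.reads_log_sd))
            )
            multiplier = 1.0 + (content_ratio - 1.0) * config.g2_attenuation
            total = t_base * multiplier
            w = cn_cell * factor * gc_term
            w = w / w.sum()
            lam = total * w
            gamma = rng.gamma(r, 1.0 / r, m)
            c_vec = rng.poisson(lam * gamma)
            counts.append(c_vec)
            replicated_all.append(rep)
            rows.append(
                {
                    "cell_id": cell_id,
                    "clone": spec.name,
                    "phase": phase,
                    "s_progression": f,
                    "total_reads": int(c_vec.sum()),
                }
            )
    return SimResult(
        genome=genome,
        counts=np.column_stack(counts),
        cells=pd.DataFrame(rows),
        replicated=np.vstack(replicated_all),
        clone_profiles=clone_profiles,
        true_timing=domain,
        rep_quantile=rep_quantile,
        config=config,
    )


FIXTURE_PROFILES = (
    "null_calibration",
    "two_clone",
    "three_clone",
    "wgd",
    "spikein_cna",
    "art_flip",
)


def _third_clone_cnas() -> list:
    """Clone C's distinguishing CNAs (chromosomes 6-8, terminal layout)."""
    return [
        (5, 0, 100, 3),
        (5, 150, 250, 1),
        (6, 0, 100, 1),
        (6, 150, 250, 3),
        (7, 0, 100, 3),
        (7, 150, 250, 3),
    ]


def _two_clone_cnas(bins_per_chrom: int = 250) -> list:
    """Ten >= 5-Mb gained segments (cn 3) distinguishing clone B from clone A.

    Both gains per chromosome are terminal (p- and q-arm), leaving a >= 2-Mb
    normal spacer between them, as terminal gains commonly do in tumors.
    """
    cnas = []
    for ci in range(5):
        cnas.append((ci, 0, 100, 3))
        cnas.append((ci, 150, 250, 3))
    return cnas


def fixture_config(profile: str, **overrides) -> SimConfig:
    """Named study designs used across the test bench."""
    if profile == "null_calibration":
        clones = [CloneSpec("clone0", overrides.pop("n_cells", 500))]
    elif profile == "two_clone":
        n_a = overrides.pop("n_a", 100)
        n_b = overrides.pop("n_b", 100)
        s_a = overrides.pop("s_a", 0.0)
        s_b = overrides.pop("s_b", 0.0)
        clones = [
            CloneSpec("cloneA", n_a, s_fraction=s_a),
            CloneSpec("cloneB", n_b, cnas=_two_clone_cnas(), s_fraction=s_b),
        ]
    elif profile == "three_clone":
        # proliferation-heterogeneity study design: one clone proliferates
        # at less than half the rate of the other two
        clones = [
            CloneSpec(
                "cloneA",
                overrides.pop("n_a", 200),
                s_fraction=overrides.pop("s_a", 0.25),
                g2_fraction=overrides.pop("g2_a", 0.05),
            ),
            CloneSpec(
                "cloneB",
                overrides.pop("n_b", 150),
                cnas=_two_clone_cnas(),
                s_fraction=overrides.pop("s_b", 0.10),
                g2_fraction=overrides.pop("g2_b", 0.05),
            ),
            CloneSpec(
                "cloneC",
                overrides.pop("n_c", 100),
                cnas=_third_clone_cnas(),
                s_fraction=overrides.pop("s_c", 0.25),
                g2_fraction=overrides.pop("g2_c", 0.05),
            ),
        ]
    elif profile == "wgd":
        # genuinely genome-doubled clone with five private CNAs (odd cns make
        # the tetraploid solution identifiable from RDRs)
        wgd_cnas = [
            (5, 0, 120, 6),
            (5, 160, 250, 5),
            (6, 0, 100, 5),
            (6, 150, 250, 6),
            (7, 40, 190, 5),
        ]
        clones = [
            CloneSpec("diploid", overrides.pop("n_diploid", 60)),
            CloneSpec("wgd", overrides.pop("n_wgd", 40), ploidy=4, cnas=wgd_cnas),
        ]
    elif profile == "spikein_cna":
        clones = [
            CloneSpec("cloneA", overrides.pop("n_a", 60), s_fraction=overrides.pop("s_a", 0.4)),
            CloneSpec(
                "cloneB",
                overrides.pop("n_b", 60),
                cnas=_two_clone_cnas(),
                s_fraction=overrides.pop("s_b", 0.4),
            ),
        ]
        overrides.setdefault("private_cna_s_cells", (6, 50, 250, 3))
    elif profile == "art_flip":
        clones = [
            CloneSpec(
                "flip",
                overrides.pop("n_cells", 120),
                s_fraction=overrides.pop("s_fraction", 0.4),
                rt_flip_regions=[(0, 100, 200)],
            )
        ]
    else:
        raise ValueError(
            f"unknown fixture profile {profile!r}; valid: {FIXTURE_PROFILES}"
        )
    return SimConfig(clones=clones, **overrides)


def make_fixture_suite(profile: str, seed: int = 0, outdir=None, **overrides) -> SimResult:
    """Simulate a named fixture; optionally write it as pipeline-format files."""
    result = simulate_population(fixture_config(profile, **overrides), seed=seed)
    if outdir is not None:
        from . import io

        io.write_population(result, outdir)
    return result
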