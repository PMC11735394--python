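# Methods

This note documents the model and the numerical choices behind `scphase`,
the assumptions they rest on, and what the simulation-based tests do and
do not establish about real data.

## Signal model

For a cell with integer copy numbers `cn_b` over bins `b`, expected
binned coverage is proportional to `cn_b × ρ_b × exp(β·gc_b)`, where
`ρ_b` is 2 if the bin has been replicated (S/G2 phase) and 1 otherwise,
and `β` is a shared GC bias. The read-depth ratio (RDR) normalises
coverage to genome-wide mean 1, so it is invariant to sequencing depth
and proportional to local DNA content. Because DNA replication is
asynchronous — early-replicating domains duplicate before late ones — an
S-phase cell shows coherent early-above-late RDR structure after CNAs are
removed, which is the basis of S-phase identification; total DNA content
(hence total read count under tagmentation) separates G2 from G0/G1.

## Windows and GC correction

Windows aggregate consecutive same-timing bins per chromosome, sized per
cell so that a window carries at least `target_reads_per_window` (default
200) expected reads; cells in different phases yield very different
totals and this equalises RDR sampling variance across them. 200 reads
gives a Poisson coefficient of variation of about 7% per window.

GC bias is fitted per timing class as a τ=0.5 quantile regression of
Δlog RDR on ΔGC over adjacent same-class windows (differencing cancels
copy-number levels, which would otherwise make the fit unstable on
genomes where half the bins sit at a different copy number; replication
state transitions between adjacent windows are rare and the median
regression resists them). Cells sequenced together share library
chemistry, so the batch median slope per class is applied to every cell;
this matters because the per-cell slope error times the early/late GC gap
produces a coherent 1–2% early-vs-late shift that a 2,000-window
permutation test reliably mistakes for replication signal. Correction is
centred at the cell's global mean GC, which removes the between-class RDR
difference attributable to GC while preserving replication-driven
separation; cells whose own slope is a >3 robust-z outlier (replication
inflates the apparent slope of S cells) are flagged. A residual
batch-shared early/late offset is estimated at the RTP level as the batch
median of per-cell class contrasts and divided out; the median is
dominated by G0/G1 cells, which assumes the population is not
majority-S (true of tumor samples).

## Replication-aware segmentation

Candidate breakpoints are decoded separately in the early-track and
late-track window series of each chromosome by a sticky Gaussian HMM
(12 equally spaced RDR levels on [0, 3], shared noise scale from robust
within-track first differences, self-transition 1−10⁻³, Viterbi
decoding). A CNA shifts both tracks at the same position and in the same
direction, while replication fluctuations move one track only, so
boundaries are retained by recursive joint change-point splitting: among
candidate positions, the one with the strongest two-class same-sign
robust z of the median RDR shift (flanks limited to 40 and 60 bins, the
larger of the two scales) is refined by a joint L1 step fit and accepted
if z ≥ 6; both sides are then re-examined. Retained segments must span
≥ 2 Mb and contain both timing classes (short or one-class remnants are
merged into the flank with the closer median). CNAs confined to a single
timing domain are knowingly invisible here; they are recovered for non-S
cells by the free HMM decode and for S cells by the clone-consensus
correction.

## S-phase test

The replication timing profile (RTP) divides each window's RDR by its
segment's median, cancelling CNAs exactly for segments with ≥ 4 windows.
Per chromosome with ≥ 5 windows of each class, four exceedance statistics
(fraction of early windows strictly above the late 0.75 and 0.9 order
statistics; symmetric late-below-early versions) and a studentized
early-minus-late mean difference are computed. The exceedance margins
make the test robust to replication-timing classification errors (only a
subset of windows needs to move); the mean difference supplies magnitude
sensitivity, without which cells very early or late in S phase (few
switched windows among ~2,000) are undetectable at desk scale — at
genome scale (~60,000 bins) the exceedance statistics alone regain that
power. Exceedance statistics are combined across chromosomes by a
harmonic mean with zero values floored at 1/(2·windows); the mean
difference uses exact permutation moments per chromosome and Stouffer
combination.

Timing labels are permuted within chromosomes. Because all statistics
are rank-based (or standardized), their joint permutation law depends
only on each chromosome's early/late window counts, so the joint null is
simulated once per dataset on Gaussian pseudo-values and every cell with
the same testable layout is calibrated against it; this captures the
true dependence between the directions. The directional p-values are
combined by their minimum, itself calibrated against the permutation
distribution of the min-p (so the combined p-value is uniform under the
null) with randomized tie-smoothing across the shared discrete atoms.
A cell whose observed statistics beat every permutation receives
p = 1/(n_permutations+1). Holm–Šidák across cells controls the
family-wise error (default 0.05). The default 10⁵ permutations support
Holm across up to ~5,000 cells; scaled-down runs must keep
n_permutations ≳ 20 × n_cells or no cell can pass the step-down
threshold.

## Clones and ploidy

For non-S cells, the ploidy scale is chosen on a 1.5–5.0 grid (step
0.05) by quantizing segment medians to integers (cost = size-weighted
squared lattice distance / 2σ² + 5·scale; the small per-unit penalty
prefers the lowest scale among exact-multiple ties, and flat profiles are
flagged degenerate). Copy numbers are then decoded freely over windows by
the same sticky HMM at that scale (recovering intra-domain CNAs).
Clustering uses average linkage on per-bin copy-number disagreement;
candidate cut heights are the midpoints between consecutive dendrogram
merge heights, the silhouette picks the cut, and among near-ties (within
0.01) the largest height wins so stragglers join their clone. Clusters
below `min_clone_size` (default 15) become outliers. A minority-ploidy
clone whose members' RDRs another clone's profile explains within 0.02
nats/window is dissolved into it (the halved/doubled-genome artifact);
genuinely genome-doubled clones survive because odd-copy private CNAs
break the degeneracy. Outlier cells are rescued by the same likelihood
criterion.

## S-cell correction and assignment

Within each retained segment, windows are partitioned into
replication-state groups (maximal same-timing runs not split by any
candidate breakpoint of their own track). Group medians concentrate on
the unreplicated copy-number level and its replicated double; the
reference level is the group-median cluster best explained as "level
with a ×2 partner" (weighted), which is robust both to the segment's
early/late composition and to contaminating clusters from boundary
errors. All groups are rescaled to the reference, residual windows still
near twice/half the reference are snapped (replication doubles coverage
exactly), and whole segments left at the doubled level (possible late in
S phase) are resolved against the integer lattice anchored on segments
whose unreplicated level is identified.

Assignment likelihood: Student-t (df 5) on log RDR around
log(cn/ploidy), scale from within-segment robust residuals (floor 0.02),
a small-weight {1×, 2×, ½×} emission mixture plus an optional
per-segment ±log 2 shift at a 5-nat penalty (both absorb residual
replication structure the correction missed), and a robust global offset
profiled out because the mean-1 normalisation drifts with the number of
segments kept at the replicated level. The prior is proportional to
clone size; ties break toward the smaller clone id. S-cell CNAs are
decoded at the assigned clone's ploidy after aligning the profile scale
to the clone; private deviations shorter than 3 Mb, confined to one
timing class, equal to an exact doubling/halving of the consensus, or
without a dominant copy-number value are reverted to the consensus.

## G2 mixture

Per clone (≥ 30 non-S cells, else a pooled fit evaluated on the clone),
total counts are deconvolved by a two-component negative-binomial
mixture with a dispersion shared between components (both components
reflect the same library mechanism; a free per-component dispersion lets
a wrong split absorb the other mode's tail). Estimation is
sampling-importance-resampling (4,000 draws; μ uniform, means
log-uniform in the data range, dispersions log-uniform in [2, 2000],
draws violating the constraint that the G2 mean exceed the clone's
S-cell mean are rejected) followed by constrained EM from the best draw
and from a deterministic quantile start, keeping the better likelihood.
If the mixture does not beat the single-component fit by the BIC margin
for its three extra parameters, μ collapses to 0. Posteriors use a
uniform class prior; a cell is G2 iff P(G0/G1) < 0.3 (strict).

## Summaries and ART

Clone S/G2 fractions are exact ratios with percentile bootstrap
intervals over cells (300 repeats). Within a sample, each clone's S
count is tested against the rest in a 2×2 chi-square without continuity
correction (Fisher's exact test when an expected count is below 5),
Benjamini–Hochberg corrected at rate 0.1. ART re-derives per-bin timing
from a clone's own S cells (≥ 10 required): their RTPs, computed over
segments induced by the clone consensus, are averaged per bin and
classified by the same confident two-mode mixture used for reference
scores; ART is called only where a confident clone class contradicts a
known reference class.

## The generator

`scphase.simulate` is the desk-scale study system: 8 chromosomes × 250
bins of 50 kb (2,000 bins) by default, early/late domains with geometric
lengths (mean 8 bins, i.e. 400 kb, matching the short replication
domains that motivate the design), replication score modes at ±1
(sd 0.25), GC = 0.45 + 0.045·tanh(score) + N(0, 0.035) (moderate,
realistic GC–timing correlation), GC bias β = 1, reads log-normal around
5×10⁵ per cell (≈ 250 per bin), negative-binomial size 300 per bin
(variance/mean ≈ 1.8, typical of tagmentation libraries at 50 kb), a
domain-coherent replication front with logistic jitter (width 0.05 in
rank-quantile units) plus 2% per-bin state flips, S progression uniform
on (0.02, 0.98), and G2 totals 2× G1 (attenuation configurable). Named
fixtures provide the study designs used throughout the tests (null
calibration, two- and three-clone mixes with ten ≥5-Mb terminal gains,
a genome-doubled clone with odd-copy private CNAs, S-cell spike-in CNAs,
and a replication-order flip for ART).

What the generator does not emulate: mappability and blacklist
structure, chromosome-scale copy-number waves, doublets, cell-to-cell GC
bias differences, breakage-fusion-bridge-style focal complexity, or
read-level artifacts. Passing tests therefore demonstrate the method's
behaviour under its own model assumptions at desk scale, not performance
on any particular real dataset; in particular, real data offer ~30×
more bins, which benefits the exceedance statistics most.

## Problem sizes and scaled-down settings

The test-bench runs 10⁴ permutations (default 10⁵), populations of
120–1,120 cells, and 2,000-bin genomes; the power benchmark raises reads
to 3.5×10⁵ per cell so that every cell clears 1,000 windows. The
acceptance script (`scripts/acceptance.py`) uses the same sizes and
completes in about 12 minutes on one CPU.

## Known limitations

- Cells at the extremes of S phase (fraction replicated < 0.15 or >
  0.85) are under-detected at desk scale, biasing clone S fractions
  slightly low (≈ 0.02–0.04 at the default conditions).
- G2 calling relies on total read counts alone; clones whose cells were
  sequenced at systematically different depths would confound it.
- The batch-offset centering assumes the population is not majority-S.
- Per-cell idiosyncratic GC bias (deviating from the batch) is not
  corrected, by the shared-chemistry assumption.
- ART requires ≥ 10 assigned S cells per clone; small clones get no ART
  call.
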