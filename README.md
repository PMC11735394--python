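# scphase

Cell-cycle phase inference and clone assignment for single-cell
whole-genome DNA sequencing (scDNA-seq) of tumors.

Tumors are mixtures of genetically distinct clones, and clones can
proliferate at different rates. Tagmentation-style scDNA-seq (e.g. DLP+)
carries both signals at once: binned read counts reveal copy-number
alterations (CNAs) that define clones, and DNA replication leaves a
characteristic fingerprint in S-phase cells — early-replicating regions
are already duplicated and yield higher coverage than late-replicating
regions. `scphase` turns that fingerprint into per-clone proliferation
estimates:

1. **Replication-aware signals.** The genome is partitioned into 50-kb
   bins; bins are classified early/late from a replication-score
   (Repli-Seq-like) track via a two-component Gaussian mixture. Per-cell
   read-depth ratios (RDRs) are computed over cell-specific windows of
   same-timing bins sized to a fixed expected read count, with a
   timing-stratified GC-bias correction that removes technical bias
   without erasing the replication signal (early DNA is GC rich, so a
   naive GC fit destroys exactly the signal of interest).
2. **Replication-aware segmentation.** Candidate breakpoints are decoded
   separately in the early and late window tracks with a sticky HMM; only
   boundaries supported by a same-sign RDR shift in *both* tracks are
   CNA boundaries — replication fluctuations move one track only.
3. **S-phase identification.** The replication timing profile (RTP) —
   RDR divided by its copy-number segment's median — isolates
   replication fluctuations from CNAs. Per chromosome, directional
   statistics measure the fraction of early windows above the late
   windows' margin quantile (and vice versa) plus a studentized
   early-minus-late mean difference; statistics are combined across
   chromosomes by a harmonic mean, permutation-tested by shuffling
   timing labels within chromosomes (10^5 permutations by default),
   combined across directions by a calibrated minimum, and corrected
   across cells with Holm–Šidák.
4. **Clone inference.** Integer copy numbers for non-S cells are decoded
   at a grid of ploidy scales; cells are clustered into clones by
   per-bin copy-number disagreement with an auto-tuned cut, and clones
   that merely re-express another clone's profile at a doubled/halved
   ploidy are dissolved by a likelihood-ratio test.
5. **S-cell assignment.** Replication fluctuations are corrected by
   rescaling same-replication-state window groups to their segment's
   unreplicated level; cells are assigned to the maximum-a-posteriori
   clone (robust Student-t likelihood × clone-size prior) and their own
   CNAs are decoded at the clone's ploidy, with implausible private
   deviations reverted.
6. **G2 identification.** Within each clone, total read counts are
   deconvolved with a two-component negative-binomial mixture (G2 cells
   carry twice the DNA), constrained so the G2 mean exceeds the S-cell
   mean; a cell is G2 when P(G0/G1) < 0.3.

Per clone, the package reports S and G2 fractions with bootstrap
confidence intervals (300 repeats), within-sample proliferation
heterogeneity (chi-square + Benjamini–Hochberg), the G2/S ratio, and
clone-specific altered replication timing (ART) — regions whose
clone-derived timing class confidently contradicts the reference.

A full synthetic-data generator (`scphase.simulate`) emulates
tagmentation counts with clone-specific CNAs, a domain-coherent
replication front, GC bias and negative-binomial overdispersion, with
complete ground-truth labels; the whole pipeline is testable at desk
scale.

## Worked example

Simulate a three-clone tumor (450 cells; clones of 200/150/100 cells with
S fractions 0.25/0.10/0.25 and G2 fractions 0.05) and run the pipeline:

```bash
scphase simulate --profile three_clone --seed 3 --out simdata
scphase run --counts simdata/counts.tsv \
            --rt-scores simdata/rt_scores.bedgraph \
            --gc simdata/gc.bed --seed 7 --out results
```

which prints

```
450 cells: 79 S-phase, 3 clones; results in results
```

and `results/clone_summary.tsv` contains

```
sample_id  clone_id  n_cells  n_s  n_g2  s_fraction  g2_fraction  ...  g2_s_ratio
sample     0         197      45   11    0.228426    0.0558376         0.244444
sample     1         149      14   8     0.0939597   0.0536913         0.571429
sample     2         97       20   6     0.206186    0.0618557         0.3
```

The three clones are recovered at their configured sizes; the estimated
S fractions 0.23/0.09/0.21 sit within the bootstrap intervals of the
configured 0.25/0.10/0.25 (cells very early or very late in S phase are
intrinsically hard to detect, which biases S fractions slightly low), and
clone 1 is flagged by the heterogeneity test as significantly less
proliferative than the rest of the sample (`results/heterogeneity.tsv`).
`results/` also holds per-cell phase calls with p-values, clone
memberships, S-cell assignments with posteriors, and per-clone ART tracks.

Library use mirrors the CLI: `scphase.run_pipeline(genome, counts,
cell_ids, PipelineConfig(...))` returns all tables as DataFrames; the
stage functions (`scphase.signals`, `scphase.segment`, `scphase.sphase`,
`scphase.clones`, `scphase.assign`, `scphase.g2`, `scphase.summaries`)
are importable individually.

## Conventions

All genomic coordinates are 0-based half-open, including bedGraph output.
Counts are accepted as a bins-by-cells matrix (with `chrom start end`
columns) or a long table (`cell_id chrom start end count` plus a bin BED).
Results are deterministic given inputs, configuration and seed; per-cell
random streams are keyed by cell id, so parallel or reordered processing
cannot change any output.
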