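# rhythmscan

Circadian transcriptome analysis for constant-light expression time
courses:

- **Rhythmicity detection** — phase-scanned Pearson correlation against
  24-h cosine templates (1-h phase grid), a t-test on the best r, and
  dual amplitude criteria (extrapolated 1.5-fold peak-to-trough change
  *or* an absolute min-to-max change relative to the dataset grand
  mean). Each gene gets a phase, r, p-value, predicted fold change, and
  a failure reason when arrhythmic.
- **Circadiome comparison** — shared/lost/gained gene sets between
  conditions or genotypes, failure-reason attribution for lost genes,
  phase cross-tabs/histograms, circular phase-shift medians, and
  log2 mean-expression-change profiles binned by phase.
- **Promoter motif scanning** — exact IUPAC matching of recognized cis
  elements (evening element, TBS variants, G-box, fbs, GA motifs,
  morning element) on both strands of 500-bp promoters, with positional
  distributions and hypergeometric set enrichment.
- **Phase enrichment** — bootstrap z-scores for over-representation of
  motif carriers in a rolling 4-phase window (100 same-size random
  groups drawn from all rhythmic genes), 3-point circular smoothing,
  and a ±1.96 significance mask.
- **Synthetic data** — a fully seeded generator for cosine expression
  matrices (both sampling schedules: 12 samples/4-h and 4 samples/8-h),
  paired-condition effects (phase delay, amplitude loss, forced
  arrhythmicity, mean shifts), and promoters with phase-coupled motif
  planting — so every stage is testable with known ground truth.

## CLI

All stages are exposed through one entry point:

```sh
# synthetic paired dataset
rhythmscan simulate --n-genes 500 --seed 1 --paired --phase-delay 3 \
    --out-prefix out/sim

# annotation + expression-floor filtering
rhythmscan filter --matrix m.tsv --design d.tsv --annotation a.tsv \
    --out-prefix out/filtered

# rhythmicity classification for one group
rhythmscan detect --matrix m.tsv --design d.tsv --annotation a.tsv \
    --group condition=red,genotype=WT --abs-mult 2.5 --out out/calls.tsv

# compare two call sets
rhythmscan compare --calls-a white.tsv --calls-b red.tsv --out-prefix out/cmp

# motif scan + phase enrichment
rhythmscan scan-motifs --promoters promoters.fasta --out out/motifs.tsv
rhythmscan enrich-phase --calls out/calls.tsv --motifs out/motifs.tsv \
    --seed 7 --out-prefix out/enrich

# config-driven end-to-end run with a manifest
rhythmscan run-all --config run.yaml --out-dir out/
```

`--abs-mult` (the absolute-change threshold as a multiple of the grand
mean) is deliberately mandatory: the literal published multiplier (250)
is implausibly strict on normalized scales, so the value must be an
explicit analysis choice (0 disables the absolute route).

A minimal `run.yaml`:

```yaml
matrix: m.tsv
design: d.tsv
annotation: a.tsv
promoters: promoters.fasta     # optional; enables scan + enrichment
groups: [[red, WT], [red, fhy3]]
comparisons: [[[red, WT], [red, fhy3]]]
rhythm: {abs_change_multiplier: 2.5}
enrichment: {seed: 7}
```

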