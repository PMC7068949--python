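# hicsig

Identification and visualization of statistically significant chromatin
interactions in Hi-C contact maps.

`hicsig` ingests contact maps in three common text dialects (HiCUP-style
paired reads + restriction digest, HiC-Pro sparse matrix + bed, a minimal
HOMER-like table), preprocesses them (resolution change, diagonal removal,
cis/trans splitting), calls significant interactions under three background
models, and renders arc diagrams and heatmaps.

## Background models

- **gothic** — coverage-product binomial null: a read pair joins bins j, h
  by spurious ligation with probability `2·rc_j·rc_h` where
  `rc_j = reads_j / (2N)`; p-values are binomial upper tails over all N
  read pairs, q-values are Benjamini–Hochberg. Cis and trans jointly.
- **hicnorm** — per-chromosome (cis) / per-chromosome-pair (trans) Poisson
  regression of counts on log effective-length and log GC products with
  log mappability as a fixed offset; produces a normalized map `e = u/t`.
  Significance calling (Poisson upper tail vs fitted `t`, then BH) is a
  documented extension, labeled `hicnorm+poisson-tail` in the output.
- **fithic** — intra-chromosomal distance-decay model: equal-occupancy
  distance binning, smoothing-spline estimate of the contact probability
  `f(d)` (projected to be non-increasing), binomial tails over the
  mid-range reads, and a two-phase refit that excludes likely-real
  contacts from the null.

A synthetic-data module (`hicsig.synth`) generates bins, covariates, and
contact maps from each model's own generative assumptions — including
planted loops — plus fixture writers for every input dialect, so the whole
pipeline is testable without any download.

## CLI

```sh
# generate a synthetic fixture
hicsig synth --kind decay --chroms chr1:5000000 --binsize 100000 \
    --n-reads 100000 --seed 7 --dialect hicpro --outdir fixtures/

# convert any dialect to the 5-column interaction table
hicsig convert --format hicpro --matrix fixtures/synthetic.matrix \
    --bed fixtures/synthetic.bed --out interactions.tsv

# call significant interactions (gothic | hicnorm | fithic)
hicsig call --format hicpro --matrix fixtures/synthetic.matrix \
    --bed fixtures/synthetic.bed --model fithic --fdr 0.05 \
    --out significant.tsv

# plot
hicsig plot arc --input significant.tsv --min-count 5 --out arc.png
hicsig plot heatmap --input significant.tsv --chroms chr1 --out heat.png
```

`call --model hicnorm` additionally needs `--features` (a tab-separated
per-bin table: chrom, start, end, effective_length, gc, mappability).
Model flags: `--bins` (equal-occupancy bins, default 200), `--dist-low` /
`--dist-high` (mid-range window; default lower bound 2× bin size),
`--refine-q` (phase-2 exclusion threshold, default 0.05).

Output format: tab-separated `chr1 locus1 chr2 locus2 readCount` for raw
maps, plus `pvalue qvalue significant` after a model run; locus columns
are bin starts.

## Layout

- `src/hicsig/core_data.py` — contact-map model, canonicalization, rebin,
  diagonal removal, cis/trans split, distances
- `src/hicsig/io_formats.py` — dialect readers/writers, feature tables,
  BED annotations, interaction files
- `src/hicsig/multitest.py` — binomial survival function, BH adjustment
- `src/hicsig/gothic.py`, `hicnorm.py`, `fithic.py` — the three models
- `src/hicsig/synth.py` — synthetic generators and fixture emitters
- `src/hicsig/viz.py` — arc diagrams and heatmaps (PNG/SVG by extension)
- `src/hicsig/cli.py` — `hicsig` entry point
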