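# strainmapqtl

Reusable pipeline for genetic analysis of inbred strain panels descended
from a single outbred colony:

- **`strainmapqtl.synthetic`** — ground-truth generators: founder pools,
  inbred strains as homozygous founder mosaics (with the true segment map),
  F2/backcross datasets with planted additive QTLs, and expression matrices
  with cis effects tied to haplotype state.
- **`strainmapqtl.hapmap`** — ancestral haplotype map reconstruction:
  canonical strain-distribution-pattern (SDP) enumeration, haplotype-segment
  detection (runs of ≥20 same-SDP variants with <100 intervening non-SDP
  variants), region tiling with haplotype-class counts, pairwise inter-strain
  diversity, and cis-candidacy of genomic positions.
- **`strainmapqtl.linkage`** — per-cross genome scans (forward–backward HMM
  genotype posteriors on a 0.5 cM grid, Haldane map function, error rate
  0.01; additive score test on posterior-expected dosage of
  quantile-normalized phenotypes) combined across crosses by
  inverse-variance fixed-effect meta-analysis (|Z| > 3.89 significance,
  Cochran's Q heterogeneity, background-stratified epistasis screen).
- **`strainmapqtl.expression`** — microarray differential expression:
  call-rate probe filtering, across-array quantile normalization, two-group
  linear-model tests (optional variance moderation), Benjamini–Hochberg FDR,
  the two-comparison shared/non-shared classification (10⁻⁴/10⁻⁸/0.05
  thresholds), and cis annotation via the haplotype map.
- **`strainmapqtl.fileio` / `strainmapqtl.pipeline` / `strainmapqtl.cli`** —
  VCF/BED/TSV IO, YAML-configured end-to-end orchestration, and the
  `strainmap-qtl` command-line interface.

## CLI

```sh
# full synthetic end-to-end run (simulate -> hapmap -> linkage -> de)
strainmap-qtl all --seed 1 --out run/

# individual stages
strainmap-qtl simulate strains --seed 1 --out data/
strainmap-qtl hapmap segments --vcf data/strains.vcf --min-run 20 --max-gap 100 --out segs.bed
strainmap-qtl hapmap regions --vcf data/strains.vcf --chrom-lengths 1=40000000,2=30000000 --out regions.tsv
strainmap-qtl hapmap diversity --vcf data/strains.vcf --chrom-lengths 1=40000000,2=30000000 --out div.tsv
strainmap-qtl simulate cross --seed 1 --out data/
strainmap-qtl linkage --cross data/cross1.map.tsv:data/cross1.data.tsv \
    --pheno trait --error-rate 0.01 --step 0.5 --threshold-z 3.89 --out scan.tsv
strainmap-qtl de --matrix expr.tsv --probes probes.tsv \
    --group-a S01 --group-b S02 --group-ref S03 --out de.tsv
```

All stages accept `--config config.yaml` (see `strainmapqtl.pipeline.
PipelineConfig` for the schema); exit codes are 0 (ok), 1 (validation
error), 2 (runtime error).

## Conventions

Coordinates are 1-based inclusive internally; BED output is 0-based
half-open. Genotype tokens in cross TSVs are `AA`/`AB`/`BB`/`NA`. TSVs are
tab-separated with `#`-prefixed header comments and `NA` for missing.
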