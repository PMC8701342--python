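# copyamp

Inference of gene amplification from whole-genome sequencing coverage and
qPCR, exercised end-to-end on synthetic data with planted, recorded truth.

The pipeline covers:

- **Plasmid copy number** — mean per-base depth over plasmid-specific
  sequence (the complement of a plasmid/genome shared-region mask) divided
  by the genome mean coverage, with a seeded bin-bootstrap confidence
  interval and a whole-plasmid uniformity diagnostic (`copyamp.plasmid`).
- **Chromosome copy number** — whole-chromosome disomy calls from the
  median of normalized binned coverage, and segmental-duplication calling
  by permutation-tested recursive binary segmentation with posterior-median
  boundary refinement and cross-strain boundary comparison (`copyamp.cnv`).
- **Variant recurrence screening** — cross-sample aggregation of VCF calls,
  flagging of heterozygous artifacts inside shared plasmid/genome sequence
  and of deliberately introduced alleles, and a recurrent-variant report
  (carried by more than two samples) (`copyamp.variants`).
- **ΔΔCT quantification** — triplicate collapse, relative quantities vs a
  calibrator, exact/asymptotic Wilcoxon rank-sum group comparisons and
  Benjamini–Hochberg (or Holm) adjustment (`copyamp.qpcr`).
- **WGS/qPCR concordance** — Pearson r² and OLS fit over paired per-strain
  estimates (`copyamp.concordance`).
- **Synthetic data** — negative-binomial depth tracks with planted plasmid
  copy numbers, disomies and segmental duplications; variant call sets with
  recurrent shared-region artifacts, private true variants and introduced
  alleles; qPCR plates consistent with planted quantities. Every generator
  is seeded, has a deterministic (noise-free) mode, and serializes its
  truth record (`copyamp.simulate`). Depth I/O (samtools-depth TSV,
  bedGraph), binning, masking and normalization live in `copyamp.coverage`;
  BED interval masks in `copyamp.regions`.

## CLI

```sh
# generate synthetic inputs (depth bedGraph, plasmid depth TSV, truth JSON)
copyamp simulate --config sim.yaml --out-dir out/

# plasmid copy number + uniformity verdict
copyamp plasmid-cn --depth out/plasmid_depth.tsv --plasmid-bed plasmid.bed \
    --name plasmid --length 6000 --genome-mean 30 --out cn.json

# disomy + segment calls from genome coverage
copyamp cnv-call --depth out/genome_depth.bedgraph --out-dir calls/

# cross-sample recurrence report from per-sample VCFs
copyamp recurrence --vcf s01.vcf --vcf s02.vcf --shared-bed shared.bed \
    --introduced-csv introduced.csv --out report.tsv

# ΔΔCT quantities from a plate CSV (sample,target,role,replicate,ct)
copyamp qpcr --plate plate.csv --calibrator wt --out quantities.csv

# WGS/qPCR concordance from a pairs CSV (strain,wgs_cn,qpcr_cn)
copyamp concord --pairs pairs.csv --out concordance.json
```

A `simulate` config looks like:

```yaml
genome:
  sequences:
    - {name: chrI, length: 500000}
    - {name: chrII, length: 800000}
events:
  plasmid_cn: 7.5
  disomies: [chrII]
  segments:
    - {sequence: chrI, start: 100000, end: 200000, factor: 2.0}
noise: {mean_depth: 30, dispersion: 10, seed: 1}
bin_size: 1000
plasmid:
  name: plasmid
  length: 8000
  shared:
    - {start: 1600, end: 3200}
```

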