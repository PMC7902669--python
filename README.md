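# popsweep

Population-genomic sweep scans, haplotype-locus analysis and pairwise
genome comparison for haploid (inbred-line) SNP data, with a built-in
synthetic-data generator so every stage is testable without external
downloads.

## What it does

- **`popsweep.sim`** — seeded generators with planted ground truth: a
  forward haploid Wright–Fisher simulator (two diverged populations,
  optional completed selective sweep at a known site), a two-haplotype-group
  locus generator, a genome pair with planted genome-specific insertions and
  annotated genes, and an error-free k-mer histogram sampler.
- **`popsweep.io`** — VCF (haploid or diploid GT; diploid calls split into
  two haplotypes), FASTA, GFF3, BED3, Newick and sample→population TSV.
  Internal coordinates are 0-based half-open everywhere; only the VCF/GFF
  boundary converts.
- **`popsweep.stats`** — nucleotide diversity, Watterson's theta, Tajima's D,
  haploid Weir–Cockerham F_ST (per-site and ratio-of-sums), LD r², the
  missingness → MAF → LD-pruning filter cascade, and sliding-window tracks.
- **`popsweep.xpclr`** — a self-contained cross-population composite
  likelihood ratio scan (deterministic hitchhiking map + censored-normal
  drift, 64-point quadrature), with per-window SNP caps and reference-panel
  r² down-weighting.
- **`popsweep.sweeps`** — LOESS track smoothing, empirical top-fraction
  (nearest-rank) thresholds, candidate-region merging and CDS-overlap gene
  annotation.
- **`popsweep.haplo`** — SNP-count distance matrices, two-group k-means
  haplotype assignment, per-group diversity, JC69 distances and a
  deterministic neighbor-joining tree builder.
- **`popsweep.compare`** — genome-specific window/sequence detection with a
  minimal seed-and-extend mapper (pluggable hit tables), gene conservation
  categories, dual-method specific-gene intersection, pan-gene
  core/dispensable/singleton classes, interval overlap fractions and k-mer
  genome-size estimation.

## CLI

```sh
popsweep sim sweep --pop-size 200 --sel-coeff 0.1 --sweep-pos 5000 \
    --seed 1 --out-vcf sim.vcf --out-pops pops.tsv
popsweep filter --vcf sim.vcf --maf-min 0.1 --r2-max 0.2 --missing-max 0.3 --out kept.vcf
popsweep stats window --vcf sim.vcf --pops pops.tsv --stat tajimas_d \
    --population query --window 1000 --step 500 --out d.tsv
popsweep fst --vcf sim.vcf --pops pops.tsv --pop-pair reference query
popsweep xpclr --vcf sim.vcf --pops pops.tsv --ref-pop reference \
    --query-pop query --window 2000 --step 500 --seed 1 --out xpclr.tsv
popsweep sweeps call --track xpclr.tsv --fraction 0.01 --out-tsv regions.tsv
popsweep haplo dist --vcf locus.vcf --out dist.tsv
popsweep haplo kmeans --vcf locus.vcf --k 2 --seed 1 --out labels.tsv
popsweep haplo tree --vcf locus.vcf --outgroup OUTGRP --out tree.nwk
popsweep compare specific --query b.fa --target a.fa --out-bed specific.bed
popsweep compare pangene --families fams.tsv --n-genomes 7 --out classes.tsv
popsweep compare genome-size --histogram hist.tsv
```

`popsweep <group> <command> --help` documents every option.

## Conventions and caveats

- Haplotypes are the unit of analysis; diploid VCF samples `S` become
  haplotypes `S|1` / `S|2`, and population tables may address either level.
- The F_ST estimator is the haploid Weir–Cockerham variant (no
  heterozygosity component); the multi-locus default is the ratio of sums.
- The XP-CLR likelihood is a self-contained normative model; numeric
  agreement with any external implementation is not a goal.
- The built-in mapper is minimal (exact k-mer seeding, ungapped X-drop
  extension).  All classification rules consume only (coverage, identity)
  pairs, so externally computed hit tables can be substituted.
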