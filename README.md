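# regmap

Tools for integrative analysis of histone-mark regulatory landscapes:

- **intervals** — genomic-interval data model (0-based, half-open BED
  coordinates) with exact set operations: gap-tolerant merge (bedtools
  `-d` semantics), base-pair intersection, whole-interval overlap
  filtering, and multi-sample consensus; BED3/BED6/narrowPeak I/O.
- **enhancers** — putative-enhancer calling from H3K27ac + H3K4me1
  double-positive regions (union or intersection mode), multi-sample
  common catalogs, and geometric super-enhancer stitching (peaks within
  12.5 kb merged; stitched spans strictly larger than 15 kb).
- **association** — enhancer–gene linking by TSS window (default 100 kb,
  midpoint or edge distance) and by Hi-C loop anchors (BEDPE), FPKM
  expression bins (inactive &lt;1, low [1,5), mid [5,15), high ≥15), and
  per-bin association fractions computed over enhancers.
- **colocalization** — percent of a region catalog overlapping a TF
  occupancy cistrome, with an optional 2×2 Fisher-exact contrast (the
  statistical contrast is an addition beyond raw percentages).
- **tf_activity** — per-specimen signature activity scores (Welch
  t-statistic of up- vs down-signature per-gene z-scores; documented
  stand-in for the upstream scoring tool), depth scaling of bulk counts
  to 56.5 M mapped pairs, the strict mean-count &gt; 1 expressed filter, and
  Pearson correlation of activity with a target gene.
- **perturb** — CRISPRa Perturb-seq calls: gRNA-to-cell assignment,
  singlet/multiplet classification, multiplet exclusion, median-depth +
  log1p normalization, activation at fold change strictly &gt; 1.5, and
  Wilcoxon rank-sum differential expression with Benjamini–Hochberg
  adjustment (hits: FC &gt; 1.5 and adjusted p &lt; 0.05).
- **synthetic** — seeded generators for every input format with planted
  ground truth recorded in JSON manifests, so all stages are testable
  offline.
- **pipeline** — YAML-configured end-to-end run producing per-stage
  BED/TSV outputs and a deterministic JSON run report.

## CLI

```sh
regmap simulate full --seed 7 -o scenario/     # write a synthetic dataset
regmap run --config scenario/config.yaml       # end-to-end run

regmap merge peaks.bed --max-gap 12500 -o stitched.bed
regmap consensus s1.bed s2.bed s3.bed --min-samples 3 -o common.bed
regmap call-enhancers --h3k27ac k27.bed --h3k4me1 k4.bed -o enh.bed
regmap call-superenhancers --h3k27ac k27.bed -o se.bed
regmap associate --enhancers enh.bed --genes genes.tsv \
    --expression fpkm.tsv --loops loops.bedpe --window 100000 -o links.tsv
regmap colocalize --regions se.bed --occupancy occupancy.bed
regmap tf-activity --signature sig.tsv --expression fpkm.tsv --target PLCL2
regmap perturb-call --grna-counts grna.tsv --expr expr.tsv \
    --targets targets.tsv --control NonTargeting -o calls.tsv
```

Gene annotation is a 4-column TSV (`gene_id chrom strand tss`) or BED6
(TSS derived from the stranded span: `+` → start, `-` → end − 1);
signatures are two-column TSV (`gene_id up|down`); loops are BEDPE.

## Conventions

All coordinates are 0-based half-open. Strand is ignored for peak math.
Chromosome names match by exact string equality. Overlap thresholds
default to ≥ 1 bp. Boundary rules are strict as documented: spans &gt; 15 kb,
gaps ≤ 12.5 kb, FC &gt; 1.5, mean count &gt; 1, FPKM bin edges land in the
upper bin.
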