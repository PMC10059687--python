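# omixmod

Integrated RNA–protein expression-module discovery for sorted-cell
developmental time courses, with downstream posttranscriptional feature
analysis.

The package targets the study design in which neural **progenitors** and
**neurons** are sorted from brain organoids at several ages (days 40, 60, 90,
120 across replicate differentiation batches) and profiled in parallel by
RNA-seq (TPM) and multiplexed TMT proteomics. It answers, end to end:

1. Which genes follow shared RNA–protein expression programs ("modules")
   across cell class and developmental time?
2. Which *cis* features (Kozak context, uORFs, 5'TOP starts, UTR lengths,
   AU-rich elements) and *trans* features (RBP k-mer motifs, miRNA seed
   sites) distinguish the modules?
3. Do module transcripts differ in relative stability (exonic vs intronic
   reads) and in polysome association between genotypes (e.g. TSC2 knockout
   with mTOR overactivation of 5'TOP translation)?

Because the deposited datasets are not needed to exercise the methods, a
first-class synthetic-data generator plants nine module templates, sequence
features, decay rates and translation shifts with full ground truth, making
every stage testable offline.

## The model in brief

**Integration.** Protein reporter intensities are divided by each protein's
number of theoretically observable tryptic peptides (length 7–30 aa) and
referenced to a pooled bridge channel per TMT batch. Gene-level TPMs of genes
encoding one protein are summed. Both assays are log10-transformed and
z-scored gene-by-gene per assay, then joined by protein identifier.

**Module discovery.** For gene *g* with z-profile *y<sub>g</sub>* over
samples, stage 1 tests the group × polynomial(time) model (groups = assay ×
cell class)

&nbsp;&nbsp;*y<sub>g</sub>* = Σ<sub>group</sub> 1<sub>group</sub>(β₀ + β₁t + β₂t²) + ε

against the intercept-only model by F-test, with Benjamini–Hochberg selection
at FDR 0.05. Stage 2 refits survivors by backward stepwise elimination
(α = 0.05, model hierarchy respected) and keeps genes with R² > 0.6. Their 16
condition means (2 assays × 2 classes × 4 days) are Ward-clustered; the
cluster number is a majority vote of average silhouette width, the
within-cluster-sum-of-squares elbow, and the gap statistic. Modules are
categorized C (cell-class driven), T (temporal) or A (ambiguous / RNA–protein
discordant) from a variance decomposition of the module mean profile plus the
mean per-gene RNA–protein correlation.

**Downstream statistics.** Hypergeometric tests for k-mer motif
over/underrepresentation (per module vs the whole gene set, counted on
overlapping scan positions) and for gene-set ORA; a curved volcano rule
−log10 p ≥ c·|x| − x₀ (c = 3.65, x₀ = 1.75); relative stability as the
residual of Δexon on a per-sample linear bias fit in Δintron (0.99
stringency); and per-fraction negative-binomial Wald tests of genotype effect
on polysome counts (|log2FC| ≥ 1, FDR 0.1) with a paired t-test on the
high-polysome:monosome ratio of the 5'TOP set.

## Worked example

```bash
python examples/02_module_discovery.py
```

prints (seed 1):

```
genes: 1200 total, 921 carried past stage 1, 833 with R2 > 0.6
labels: 833 clustered, 88 not clustered, 279 not fit
cluster number votes: {'silhouette': 9, 'wss': 5, 'gap': 9} -> k = 9
module sizes and categories:
  module 1:  100 genes, category C
  ...
```

1200 integrated genes (nine planted 100-gene templates plus 300 unstructured
genes) go through the two-stage selection; the accounting closes exactly
(1200 = 833 + 88 + 279). Silhouette and gap statistic agree on nine clusters
— the planted template count — and the recovered categories split 5 C / 2 T /
2 A, the planted taxonomy. The other scripts in `examples/` demonstrate
integration and PCA, transcript features, motif enrichment/ORA, stability
estimation, and polysome statistics, each printing the recovered planted
effect next to what it means.

The same pipeline is scriptable from the shell:

```bash
omixmod simulate --seed 0 --outdir dataset/
omixmod all --config dataset/config.yaml --outdir results_dir/
```

which writes one TSV per stage plus `run_info.json` with the per-stage gene
accounting, each output stamped with the configuration hash and seed.

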