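# Methods

This note documents the statistical procedures, the synthetic-data model, the
parameter defaults and the open design choices of `omixmod`.

## Proteomics normalization

Reporter intensities per protein and channel are divided by the protein's
number of theoretically observable tryptic peptides: fully tryptic products
(cleavage C-terminal to K/R, suppressed before P; zero missed cleavages by
default) of length 7–30 amino acids. This iBAQ-style molar correction is
followed by division by the same protein's value in the batch's bridge
channel (a pooled mix of all samples); bridge channels are removed from the
output. The two divisions commute, so their order is immaterial; we divide by
peptide count first. Proteins with a zero peptide count or zero bridge
intensity are excluded with a warning, never silently divided. A consequence
worth knowing: in the bridge *ratio*, the peptide-count correction cancels —
it matters only where absolute abundances are consumed.

The volcano significance rule is provided in two forms. The default applies
the linear inequality −log10 p ≥ c·|x| − x₀ with c = 3.65, x₀ = 1.75 exactly
as commonly printed. That form admits significance at x = 0 whenever
p ≤ 10^−x₀ ·(…), which contradicts reading x₀ as a minimum enrichment; the
`hyperbolic` form (|x| > x₀ and −log10 p ≥ c/(|x| − x₀)) is the conventional
curved cutoff and is the recommended choice where the intent is a
fold-change-gated test. Both are monotone in p at fixed x.

## Integration

TPMs of genes encoding the same protein are summed; both assays are
log10-transformed (pseudocount 1 for TPM, where zeros occur; 0 for the
strictly positive normalized protein ratios) and z-scored per gene. Z-scoring
is computed **per assay across all of that assay's samples jointly** (classes,
days, batches pooled). Scaling jointly across both assays would reintroduce
the platform unit mismatch the normalization is meant to remove; a per-batch
option exists but is off by default. Constant rows are emitted as all-zero
and flagged. Assays are joined by protein identifier; only genes present in
both assays are retained, with join counts logged.

Note one structural consequence of per-gene z-scoring: a gene whose true
signal is weak in one assay has its noise amplified to unit variance there.
This is faithful to the normalization, and it is why the discordant
("ambiguous") module templates need a non-degenerate protein shape to remain
separable (see below).

## Two-stage module discovery

* **Design.** Four series (assay × cell class) over the four sampling days;
  time is centered and scaled to [−1, 1] and entered as a polynomial of
  degree 2 (configurable to 3). Degree 2 is the default because degree 3
  saturates a four-point series, which inflates stage-2 R² for any smooth
  profile; the saturating design remains available and is the right choice
  for exact noiseless checks.
* **Stage 1.** Per gene, an F-test of the full group × polynomial model
  against intercept-only; BH adjustment across genes; selection at FDR 0.05.
  Genes with a constant (flagged) profile or zero total variance are `not
  fit`. Perfect zero-residual fits receive the smallest representable
  p-value.
* **Stage 2.** Backward elimination from a reference-coded model (intercept,
  time powers, group dummies, group × time interactions). The least
  significant *droppable* term (one with no surviving higher-order relatives)
  is removed while its p-value exceeds α = 0.05. Genes pass with strict
  R² > 0.6 on the final model.
* **Accounting.** Terminal labels mirror the published bookkeeping: genes not
  carried past stage 1 are `not_fit`; carried genes without a module are
  `not_clustered`, so that `not_fit = total − fit` and `not_clustered = fit −
  significant` hold structurally on every run and are logged. The source
  study reports 300 clustered genes fewer than its stepwise-passing count
  without stating the removing rule; this implementation removes none by
  default (`min_module_size` exists but is 0/off).
* **Cluster number.** Candidates k ∈ [4, 15] are evaluated on the Ward
  dendrogram of the 16 condition-mean z-scores: average silhouette width
  (argmax), WSS elbow (largest second difference), and the gap statistic
  (uniform reference over per-feature ranges, B = 50 bootstraps, smallest k
  with gap(k) ≥ gap(k+1) − se(k+1)). Majority vote decides; silhouette breaks
  ties; a gap curve that never satisfies its criterion falls back to its
  argmax and flags the selection low-confidence. On the default synthetic
  data the elbow criterion systematically undershoots (it favors the
  coarse C-module split), while silhouette and gap agree on the planted nine
  — the vote is robust to one weak criterion, which is why three are used.
* **Clustering.** Agglomerative Ward/Euclidean on observed condition means
  (not fitted curves); modules renumbered by descending size, making labels
  deterministic given the input and invariant (up to renumbering) under gene
  permutation and positive rescaling.
* **C/T/A categories.** The published labels were assigned by inspection; the
  reproducible heuristic here decomposes each module's mean profile per assay
  into a class component (variance of class means) and a time component
  (variance of day means): class-dominant in both assays with mean RNA–protein
  correlation r̄ ≥ 0.5 → **C**; time-dominant in both assays → **T**;
  everything else → **A**. This reproduces the planted taxonomy on default
  synthetic data.

## Transcript features

All sequence handling is in the DNA alphabet (U→T), coordinates 0-based.
Kozak context is scored on the 10-nt window −6..+4 around the start codon
against GCCRCCATGG as matches/7 over the seven informative positions, with
N-padding for short 5'UTRs (N never matches); equal position weights are used
deliberately — the original position-specific weighting is not reproduced in
the text this follows, and the transparent scheme orders contexts the same
way. uORFs are bare [ACT]TG occurrences in the 5'UTR (overlapping counted; no
in-frame-stop requirement — a stricter mode is a documented extension point).
The 5'TOP sequence rule is the classical one: a transcript 5' end starting C
with an initial pyrimidine run ≥ 5; curated-list membership (the path used
for the published enrichment figure) is handled by the ORA module. ARE
density is overlapping ATTTA pentamers per kb of 3'UTR. Transcripts are kept
when their gene's mean TPM is strictly above 1. Module-wise comparisons use
two-sided rank-sum tests for every module pair (p < 0.01 marks), with
per-gene feature values averaged across a gene's transcripts.

## Enrichment

k-mer enrichment counts occurrences on overlapping scan positions (k = 6 and
7 by default; occurrence counting matches the k-mer mode of the standard RBP
motif tool, and a per-sequence mode is available behind a flag). The test is
hypergeometric — foreground positions drawn from background positions —
two-sided by doubling the smaller tail, BH-adjusted across all k-mers, with
the over/under direction from the sign of the frequency deviation. Gene-set
ORA reports both one-sided hypergeometric tails separately (over- and
underrepresentation are reported separately in the source figures), BH across
modules × sets, odds ratios with Haldane correction on zero margins. The
motif table (IUPAC consensus per RBP) and miRNA seed list are user inputs;
miRNA site density scans 3'UTRs for reverse-complement seed matches per kb.

## Relative stability

For genes with all-positive exonic and intronic counts, Δexon and Δintron are
the per-gene-centered log2 matrices. Per sample, a stability-free linear bias
Δexon = a_s + b_s·Δintron is fit by least squares over fit genes; the
stringency parameter (default 0.99) iteratively retains that fraction of
genes with the smallest summed absolute residuals for the bias refit, after
which **all** included genes are scored as residuals from the final line and
gene-centered. This is a deliberate, documented simplification of the cited
tool's linear bias mode — one global line per sample, stringency read as the
retained-gene fraction — chosen because the original's exact stringency
semantics are not specified in the text this follows. Properties: exon=intron
input scores exactly zero; per-sample rescaling of both matrices is absorbed
by the intercept. Because scores are doubly relative (per gene and per
sample), a class-wide planted contrast is recovered up to partial absorption
of the cohort mean into the sample intercepts: a planted 2× (−1 log2)
neuron/progenitor decay contrast affecting ~17% of genes is recovered at
about −0.9 log2, within the stated ±0.2 band.

## Polysome statistics

Genes are pre-filtered to protein-coding genes with ≥ 2 reads in ≥ 2 samples
of at least one (fraction × genotype) condition ("multiple" read as ≥ 2).
Each fraction is analyzed independently: median-of-ratios size factors;
method-of-moments NB dispersions from pooled within-genotype variances of
normalized counts, shrunk toward a fraction-wide a₀ + a₁/mean trend (equal
log-space weights, floor 1e−8, cap 10); a vectorized IRLS NB GLM (log link,
design ~ genotype, size-factor offsets) with Wald p-values from the normal
reference; BH across genes; DAG flags at |log2FC| ≥ 1 and FDR ≤ 0.1. This is
a self-contained Wald test judged by calibration and power, not a
coefficient-level clone of the external package the study used. At the
study's three replicates the Wald p-values are mildly anti-conservative in
the extreme tail (the dispersion estimate has few degrees of freedom); they
are uniform to a Kolmogorov–Smirnov test by eight replicates, which is the
simulation size the calibration test uses. The high:mono shift test computes,
per genotype, log2 of the ratio of size-factor-normalized means
(replicates averaged after normalization) of high-polysome to monosome
counts for a gene set, and compares genotypes by a two-sided paired t-test
across genes; sets of size 1 report the effect with an undefined p and a
degeneracy flag.

## Synthetic-data generator

The generator is the package's test substrate and emulates the study design:
2 cell classes × 4 days (40/60/90/120) × 3 batches, RNA and protein per
condition.

* **Templates.** Nine 16-condition mean log2 profiles spanning the C/T/A
  taxonomy: five class-dominant concordant templates (progenitor-high flat,
  progenitor-high saturating onset, neuron-high flat, neuron-high onset, and
  a progenitor shut-down shape), two temporal templates (falling and rising
  in both classes, with an opposite-sign protein class offset), and two
  discordant templates (the 5'TOP-like one: progenitor-skewed RNA with
  near-equal mildly drifting protein; and rising RNA with progenitor-high
  protein). The shapes were designed once for mutual separability *after*
  per-assay z-scoring (maximum pairwise centroid correlation ≈ 0.77 at
  default noise): because z-scoring rescales each gene per assay, two
  class-dominant templates differing only in a small amplitude would collapse
  onto the same direction, so the five C templates differ in temporal
  signature, and the discordant protein halves carry a small non-degenerate
  shape rather than exact flatness.
* **Noise.** RNA counts are negative-binomial (dispersion 0.1) around
  template-scaled means (amplitude 1.0 log2 per template unit; per-gene base
  TPM log-normal around 30; library factors log-normal σ = 0.1); TPM is
  recomputed per sample from counts. Protein intensities are log-normal
  (σ = 0.25 natural log) with a per-batch multiplicative offset (σ = 0.5) and
  a bridge channel equal to the per-batch mean of all channels. TMT ratio
  compression and channel cross-talk are **not** simulated by default (an
  optional multiplicative compression factor exists): the pipeline's
  correctness, not TMT physics, is under test. Setting the noise parameters
  to zero reduces every generator to its template equations exactly, which
  the tests exploit.
* **Sequences.** One transcript per gene. 5'TOP-module genes get a C +
  pyrimidine-run start (run 5–12), short UTRs/CDS, near-consensus Kozak
  contexts and scrubbed-then-replanted uORFs (Poisson 0.3); the other A/T
  modules get strong Kozak and ~1 planted uORF; class-dominant modules carry
  a distinct planted 6-mer (3 copies per 3'UTR) and weak Kozak; one temporal
  module is ARE-enriched (Poisson 4 planted ATTTA); two modules carry planted
  miRNA seed target sites. Protein sequences have per-gene K/R frequency
  drawn from 0.05–0.2 so observable-peptide counts vary.
* **Exon/intron.** Intron counts ∝ transcription; exon counts ∝
  transcription/decay (base rate 0.2/h; neurons decay 2× faster for the
  progenitor-stable templates 1 and 3, progenitors 2× faster for template 9).
  Both channels share a library factor; the intron channel's log abundance is
  additionally distorted by a per-sample slope in [0.85, 1.15], so bias
  removal is exercised.
* **Polysome.** NB counts (dispersion 0.05) over 3 fractions × 2 genotypes ×
  3 replicates; under the knockout, TOP-gene high-polysome means are scaled
  by 2^shift (default +1 log2, the scale of the published effect) with
  monosome and low-polysome fixed.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: mapping/quantification artifacts, isoform mixtures
(one transcript per gene), TMT compression and cross-talk (off by default),
identifier ambiguity beyond simple many-to-one mapping, batch-confounded
designs, and realistic gene-gene correlation (genes are independent given
their template). Recovery rates on this substrate are upper bounds for field
data.

## Numerical choices and degenerate inputs

Stage-1 p-values underflow to the smallest normal float for zero-residual
fits; stage-2 stops eliminating when the residual is numerically zero.
Constant rows z-score to zero and are flagged rather than dropped. Ward
clustering ties are resolved by SciPy's deterministic merge order; module
renumbering by size makes labels reproducible byte-for-byte under a fixed
seed (the pipeline writes identical tables across reruns). Hypergeometric
tails come from SciPy's exact implementation (verified against exhaustive
enumeration in the tests for universes ≤ 25). Division-by-zero paths (empty
UTRs, zero monosome means, zero bridge intensities, proteins without
peptides) are excluded-and-logged rather than propagated as NaN.

## Problem sizes used in tests and the acceptance script

Default synthetic datasets use 100 genes per template plus 300 unstructured
and 10 protein-unmapped genes (1210 total), three batches, three polysome
replicates — a desk-scale rendering of the study's design chosen so the full
pipeline runs in seconds and the complete test suite plus acceptance script
in a few minutes on one core. Recovery experiments use 20 seeds (cluster
number, ARI), 10 seeds (k-mer recovery), 2000 genes (stage-1 null), and 1000
random inputs per scanner oracle.
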