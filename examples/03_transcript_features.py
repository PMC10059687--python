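"""Per-transcript cis-regulatory features and module-wise contrasts.

Computes Kozak context scores (similarity to GCCRCCATGG), uORF counts
([ACT]TG occurrences in the 5'UTR), 5'TOP starts (C + pyrimidine run >= 5),
AU-rich-element density (ATTTA per kb of 3'UTR) and region lengths, then
compares the 5'TOP-planted module against the cell-class-dominant modules.
"""

import numpy as np
from scipy.stats import mannwhitneyu

from omixmod import SimParams, detect_top_motif, feature_table, generate_multiomics, generate_sequences

params = SimParams(seed=3)
data = generate_multiomics(params, np.random.default_rng(3))
transcripts, proteins = generate_sequences(data.truth, params, np.random.default_rng(4))

table = feature_table(transcripts, data.rna_tpm, min_mean_tpm=1.0)
print(f"feature table: {len(table)} transcripts above mean TPM 1")

tpl = data.truth.table["template"].reindex(table["gene_id"]).to_numpy()
top = table[tpl == "3"]          # the 5'TOP-like module
cdom = table[np.isin(tpl, list("12789"))]
for feat in ("kozak_score", "uorf_count", "len_utr5", "len_utr3"):
    p = mannwhitneyu(top[feat], cdom[feat]).pvalue
    print(f"  {feat:12s}: TOP module median {top[feat].median():8.2f}  "
          f"class modules {cdom[feat].median():8.2f}  rank-sum p = {p:.2e}")

detected = np.mean([detect_top_motif(transcripts[g].utr5)[0]
                    for g in data.truth.top_genes])
print(f"planted 5'TOP genes detected by the sequence rule: {detected:.0%}")
# TOP-module transcripts are shorter, carry near-consensus Kozak contexts and
# almost no uORFs - the signature of efficiently initiated translation-
# machinery mRNAs.
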