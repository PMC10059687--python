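"""Polysome-fraction differential association and the 5'TOP shift test.

Simulates monosome / low-polysome / high-polysome counts for control and
TSC2-knockout genotypes, where the knockout doubles the high-polysome
occupancy of 5'TOP genes (mTOR overactivation).  A per-fraction negative-
binomial Wald test flags differentially associated genes at |log2FC| >= 1,
FDR 0.1, and a paired t-test quantifies the high:mono shift of the TOP set.
"""

import numpy as np

from omixmod import SimParams, filter_polysome_genes, generate_polysome
from omixmod.simulate import build_truth
from omixmod.translation import differential_association, polysome_shift_test

params = SimParams(seed=9, translation_shift=1.0)  # 2-fold high-polysome shift
truth = build_truth(params, np.random.default_rng(9))
counts = generate_polysome(truth, params, np.random.default_rng(10))
counts = filter_polysome_genes(counts, set(truth.table.index))

da = differential_association(counts, lfc_threshold=1.0, fdr=0.1)
top = set(truth.top_genes)
for fraction in ("monosome", "low_poly", "high_poly"):
    sub = da[da["fraction"] == fraction]
    in_top = sub[sub["gene_id"].isin(top)]
    print(f"{fraction:9s}: {int(sub['dag_flag'].sum()):3d} DAGs flagged, "
          f"mean log2FC of TOP genes {in_top['log2fc'].mean():+.2f}")

res = polysome_shift_test(counts, truth.top_genes)
print(f"\nTOP-set high:mono shift, knockout - control: "
      f"{res['mean_difference']:+.2f} log2 over {res['n_genes']} genes, "
      f"paired-t p = {res['p']:.1e}")
# Only the high-polysome fraction responds; the recovered shift matches the
# planted +1 log2 (2-fold) effect of mTOR overactivation on TOP mRNAs.
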