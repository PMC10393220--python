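"""Serology classification: can autoreactivity separate cohorts?

Fits an L1-regularized logistic regression (liblinear) on the gene x sample
z-score matrix under stratified 5-fold cross-validation and reports the
pooled held-out ROC AUC plus the top coefficient-ranked antigens — the
candidate serologic signature.
"""

import pandas as pd

from phipkit import (
    SimulationConfig, collapse_to_genes, fit_and_evaluate, fold_change,
    generate_library, percent_normalize, scenarios, simulate_cohort,
    top_features, zscore_vs_reference,
)

config = scenarios.signature_cohort(seed=5)  # 10 shared antigens, 500 genes
library = generate_library(config)
counts, sheet, _ = simulate_cohort(config, library)
fc = fold_change(percent_normalize(collapse_to_genes(counts, library)), sheet)
z = zscore_vs_reference(fc, sheet)

cases = sheet.index[sheet["role"] == "case"]
pres = sheet.index[sheet["role"] == "pre_control"]
cols = cases.append(pres)
labels = pd.Series([1] * len(cases) + [0] * len(pres), index=cols)

result = fit_and_evaluate(z[cols], labels, folds=5, seed=5)
print(f"pooled held-out AUC: {result.pooled_auc:.3f} "
      f"(per-fold mean {result.mean_fold_auc:.3f})")
top = top_features(result, k=20)
planted = set(scenarios.planted_genes())
hits = [g for g in top.index if g in planted]
print(f"top-20 coefficient antigens contain {len(hits)}/10 planted antigens:")
print(top.head(10).to_string(float_format=lambda v: f"{v:.3f}"))
print()
print("An AUC near 1 with the planted antigens at the head of the ranking")
print("means the shared post-infection reactivities form a recoverable")
print("serologic signature; on null cohorts the same pipeline sits at ~0.5.")
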