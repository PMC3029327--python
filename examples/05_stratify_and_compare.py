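"""Median risk stratification and Kaplan-Meier group comparison.

Patients are split into low/high risk halves by the window-mean of their
LOOCV-predicted survival curves; the groups' observed recurrence-free
survival is compared with the log-rank and generalized Wilcoxon tests.
"""

import mirecur as mr
from mirecur.model_builder import loocv_predict, ta_auroc_table

expr, clin, _ = mr.generate_dataset(mr.SimulationDesign(seed=0))
norm = mr.quantile_normalize(expr)
feats = mr.assemble_features(norm, mr.filter_expressed(norm), clin)

cfg = mr.RunConfig(dataset_choice="ALL", representation="FEATURES", max_k=5)
grid = loocv_predict(feats, clin, cfg)
table = ta_auroc_table(grid, clin, cfg.eval_window)
best_k = int(table.loc[table["ta_auroc"].idxmax(), "k"])
curves = grid.curves[best_k]

strata = mr.stratify_median(curves, cfg.eval_window)
km, (lr_chi2, lr_p), (wx_chi2, wx_p) = mr.compare_strata(strata, clin)
n_low = (strata.assignment == "LOW").sum()
n_high = (strata.assignment == "HIGH").sum()
print(f"best k = {best_k} (ta-AUROC {table['ta_auroc'].max():.4f})")
print(f"risk groups: {n_low} low / {n_high} high")
print(f"log-rank:  chi2 = {lr_chi2:.3f}, p = {lr_p:.4g}")
print(f"Wilcoxon:  chi2 = {wx_chi2:.3f}, p = {wx_p:.4g}")
print(f"KM survival at 2 years: low {km['LOW'].at(730):.3f}, high {km['HIGH'].at(730):.3f}")
# Small p-values mean the cross-validated model separates patients whose
# observed recurrence experience genuinely differs.
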