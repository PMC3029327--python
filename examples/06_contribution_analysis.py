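"""Convert PC-level Cox coefficients to per-miRNA contributions with CIs.

A model fit on principal components assigns hazard to PCs; the combined
coefficient beta_i = sum_j b_j C_ji re-expresses the same linear predictor
feature by feature. Bootstrap resampling of patients (refitting PCA,
ranking and the Cox model each time) yields percentile confidence intervals.
"""

import mirecur as mr

expr, clin, _ = mr.generate_dataset(mr.SimulationDesign(seed=0))
norm = mr.quantile_normalize(expr)
feats = mr.assemble_features(norm, mr.filter_expressed(norm), clin)

ct = mr.bootstrap_ci(feats, clin, k=5, B=100, seed=0)
cols = ["mirna", "source", "coefficient", "ci_low", "ci_high"]
print("top 5 features positively associated with recurrence:")
print(ct.top_positive(5)[cols].round(4).to_string())
print("\ntop 5 features negatively associated with recurrence:")
print(ct.top_negative(5)[cols].round(4).to_string())
# Positive coefficients: higher expression tracks earlier recurrence.
# A CI excluding zero marks a contribution stable under patient resampling.
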