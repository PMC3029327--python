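"""Differential expression: paired tumor vs non-tumor, reference subgroup,
and one-way ANOVA across tumor grades.

Fold changes are linear-scale (2 ** difference of log2 means); paired tests
list at p < 0.01, the others at p < 0.05, following the source conventions.
"""

import mirecur as mr

expr, clin, _ = mr.generate_dataset(mr.SimulationDesign(seed=0))
norm = mr.quantile_normalize(expr)
kept = mr.filter_expressed(norm)

paired = mr.paired_t_test(norm, kept)
print(f"paired T vs N: {len(paired.up_regulated())} up-regulated, "
      f"{len(paired.down_regulated())} down-regulated at p<0.01")
print(paired.table.head(3).round(4))

# non-tumor tissue of the normal-adjacent subgroup as reference
normal_pat = clin.data.index[clin.data["normal_adjacent"] == 1]
n_mat = norm.tissue_matrix("N")[kept]
if len(normal_pat) >= 2:
    vs_normal = mr.unpaired_t_test(
        n_mat.drop(index=normal_pat), n_mat.loc[normal_pat]
    )
    print(f"\nvs normal-adjacent livers (n={len(normal_pat)}): "
          f"{(vs_normal.table['p'] < 0.05).sum()} miRNAs at p<0.05")

t_mat = norm.tissue_matrix("T")[kept]
anova = mr.anova_by_group(t_mat, clin.data["tumor_grade"].to_numpy())
print(f"\nANOVA across tumor grades: {(anova.table['p'] < 0.05).sum()} miRNAs at p<0.05")
print(anova.table.head(3).round(4))
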