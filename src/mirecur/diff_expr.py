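"""Differential-expression analyses: paired tumor vs non-tumor tests,
unpaired comparisons against a reference subgroup, and one-way ANOVA
across tumor grades.

Fold changes are reported on linear scale as 2 ** (difference of log2
means). Listing thresholds follow the source conventions: paired tests list
at p < 0.01, unpaired tests and ANOVA at p < 0.05, all on raw p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix

PAIRED_P_THRESHOLD = 0.01
UNPAIRED_P_THRESHOLD = 0.05


@dataclass
class DiffExprResult:
    table: pd.DataFrame       # per miRNA, sorted by fold change descending
    p_threshold: float

    def up_regulated(self) -> pd.DataFrame:
        t = self.table
        return t[(t["p"] < self.p_threshold) & (t["fold_change"] > 1)]

    def down_regulated(self) -> pd.DataFrame:
        t = self.table
        return t[(t["p"] < self.p_threshold) & (t["fold_change"] < 1)].sort_values(
            "fold_change"
        )


def paired_t_test(matrix: ExpressionMatrix, kept: list[str]) -> DiffExprResult:
    """Paired t-test of tumor vs non-tumor expression per miRNA."""
    unpaired = matrix.unpaired_patients()
    if unpaired:
        raise ValueError(f"unpaired patients: {unpaired}")
    t_mat = matrix.tissue_matrix("T")[kept].to_numpy(dtype=float)
    n_mat = matrix.tissue_matrix("N")[kept].to_numpy(dtype=float)
    diff = t_mat - n_mat
    mean_t, mean_n = t_mat.mean(axis=0), n_mat.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    n = diff.shape[0]
    mean_d = diff.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(sd > 0, mean_d / (sd / np.sqrt(n)), 0.0)
    p = np.where(sd > 0, 2 * stats.t.sf(np.abs(tstat), df=n - 1), 1.0)
    # constant non-zero difference: infinitely significant, guarded
    const_shift = (sd == 0) & (mean_d != 0)
    tstat = np.where(const_shift, np.sign(mean_d) * np.inf, tstat)
    p = np.where(const_shift, 0.0, p)
    table = pd.DataFrame(
        {
            "mean_T": mean_t,
            "mean_N": mean_n,
            "fold_change": 2.0 ** (mean_t - mean_n),
            "t": tstat,
            "p": p,
        },
        index=pd.Index(kept, name="mirna"),
    ).sort_values("fold_change", ascending=False)
    return DiffExprResult(table=table, p_threshold=PAIRED_P_THRESHOLD)


def unpaired_t_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> DiffExprResult:
    """Equal-variance (Student) two-sample t-test per miRNA.

    ``group_a`` / ``group_b``: samples x miRNAs on the same miRNA columns.
    A zero pooled variance with unequal means yields p = 0 and a
    ``zero_variance`` flag rather than an error.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if not group_a.columns.equals(group_b.columns):
        raise ValueError("groups must share the same miRNA columns")
    A = group_a.to_numpy(dtype=float)
    B = group_b.to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-zero variances are handled by the explicit guard below
        warnings.simplefilter("ignore", RuntimeWarning)
        tstat, p = stats.ttest_ind(A, B, axis=0, equal_var=True)
    pooled_var = A.var(axis=0, ddof=1) + B.var(axis=0, ddof=1)
    zero_var = pooled_var == 0
    equal_means = np.isclose(mean_a, mean_b)
    tstat = np.where(zero_var, np.where(equal_means, 0.0, np.sign(mean_a - mean_b) * np.inf), tstat)
    p = np.where(zero_var, np.where(equal_means, 1.0, 0.0), p)
    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "fold_change": 2.0 ** (mean_a - mean_b),
            "t": tstat,
            "p": p,
            "zero_variance": zero_var,
        },
        index=group_a.columns,
    ).sort_values("fold_change", ascending=False)
    return DiffExprResult(table=table, p_threshold=UNPAIRED_P_THRESHOLD)


def anova_by_group(samples: pd.DataFrame, labels) -> DiffExprResult:
    """One-way fixed-effects ANOVA per miRNA across >= 2 label levels."""
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("ANOVA requires at least 2 levels")
    groups = [samples.to_numpy(dtype=float)[labels == lev] for lev in levels]
    if any(len(g) < 2 for g in groups) and sum(len(g) >= 2 for g in groups) < 2:
        raise ValueError("need at least 2 samples in at least 2 levels")
    with np.errstate(divide="ignore", invalid="ignore"):
        F, p = stats.f_oneway(*groups, axis=0)
    F = np.where(np.isnan(F), 0.0, F)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame({"F": F, "p": p}, index=samples.columns).sort_values("p")
    return DiffExprResult(table=table, p_threshold=UNPAIRED_P_THRESHOLD)
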