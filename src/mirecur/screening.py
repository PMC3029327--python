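"""Univariate Cox screening of features, permutation FDR, and count comparison.

Features with hazard ratio > 1 are labeled "OncomiR" (higher expression
tracks earlier recurrence), those with hazard ratio < 1 "Ts-miR"
(tumor-suppressor-like). The FDR of a feature compares how many features
reach its observed p-value under random reassignment of (time, event) pairs
to patients with how many reach it in the observed screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClinicalTable, FeatureMatrix
from .survival import cox_univariate_many


@dataclass
class ScreenResult:
    """Ranked univariate screen; one row per feature."""

    table: pd.DataFrame  # index feature id; beta, hazard_ratio, se, p, mir_type, rank [, fdr]
    subset: np.ndarray | None = None  # boolean patient mask the screen used

    def top(self, k: int) -> pd.Index:
        return self.table.sort_values("rank").index[:k]

    def significant(self, alpha: float = 0.05) -> pd.Index:
        return self.table.index[self.table["p"] < alpha]


def _rank_screen_table(table: pd.DataFrame) -> pd.DataFrame:
    """Rank ascending p; ties by |beta| descending then feature id; degenerate last."""
    key = pd.DataFrame(
        {
            "degenerate": table["degenerate"].astype(int),
            "p": table["p"],
            "neg_abs_beta": -table["beta"].abs(),
            "fid": table.index,
        },
        index=table.index,
    )
    order = key.sort_values(["degenerate", "p", "neg_abs_beta", "fid"], kind="stable").index
    table = table.copy()
    table.loc[order, "rank"] = np.arange(1, len(table) + 1)
    table["rank"] = table["rank"].astype(int)
    return table


def _screen_frame(values: pd.DataFrame, time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    res = cox_univariate_many(values.to_numpy(dtype=float), time, event)
    table = pd.DataFrame(
        {
            "beta": res["beta"],
            "hazard_ratio": res["hazard_ratio"],
            "se": res["se"],
            "p": res["p"],
            "converged": res["converged"],
            "degenerate": res["degenerate"],
        },
        index=values.columns,
    )
    table["mir_type"] = np.where(
        table["degenerate"], "none", np.where(table["hazard_ratio"] > 1, "OncomiR", "Ts-miR")
    )
    return _rank_screen_table(table)


def univariate_screen(
    features: FeatureMatrix | pd.DataFrame,
    clinical: ClinicalTable,
    subset: np.ndarray | None = None,
) -> ScreenResult:
    """One univariate Cox fit per feature, ranked by p-value.

    ``subset`` is an optional boolean mask over the canonical patient order
    (e.g. HBV-positive cases only); it must retain at least one event.
    """
    values = features.values if isinstance(features, FeatureMatrix) else features
    values = values.loc[clinical.patient_ids]
    time, event = clinical.time, clinical.event
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        if subset.sum() == 0 or event[subset].sum() == 0:
            raise ValueError("subset contains no events")
        values, time, event = values.loc[values.index[subset]], time[subset], event[subset]
    table = _screen_frame(values, time, event)
    return ScreenResult(table=table, subset=subset)


def permutation_fdr(
    screen: ScreenResult,
    features: FeatureMatrix | pd.DataFrame,
    clinical: ClinicalTable,
    B: int = 1000,
    seed: int = 0,
) -> ScreenResult:
    """Permutation-based FDR for each feature's observed p-value.

    Each permutation randomly reassigns the (time, event) pairs to patients
    with expression fixed; FDR_i = min(1, mean_B #{null p <= p_i} /
    #{observed p <= p_i}), then made monotone by a running minimum from the
    largest p downward.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    values = features.values if isinstance(features, FeatureMatrix) else features
    values = values.loc[clinical.patient_ids]
    time, event = clinical.time, clinical.event
    if screen.subset is not None:
        mask = screen.subset
        values, time, event = values.loc[values.index[mask]], time[mask], event[mask]
    X = values.to_numpy(dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    obs_p = screen.table.loc[values.columns, "p"].to_numpy()
    null_p = np.empty((B, len(obs_p)))
    for b in range(B):
        perm = rng.permutation(n)
        null_p[b] = cox_univariate_many(X, time[perm], event[perm])["p"]
    fdr = fdr_from_pvalues(obs_p, null_p)
    table = screen.table.copy()
    table.loc[values.columns, "fdr"] = fdr
    return ScreenResult(table=table, subset=screen.subset)


def fdr_from_pvalues(obs_p: np.ndarray, null_p: np.ndarray) -> np.ndarray:
    """FDR_i = min(1, mean_B #{null p <= p_i} / #{observed p <= p_i}),
    made monotone non-decreasing in p by a running minimum from the largest
    observed p downward."""
    obs_p = np.asarray(obs_p, dtype=float)
    null_p = np.asarray(null_p, dtype=float)
    B = null_p.shape[0]
    null_sorted = np.sort(null_p.ravel())
    null_counts = np.searchsorted(null_sorted, obs_p, side="right") / B
    obs_counts = np.searchsorted(np.sort(obs_p), obs_p, side="right")
    fdr = np.minimum(1.0, null_counts / obs_counts)
    order = np.argsort(-obs_p, kind="stable")
    fdr[order] = np.minimum.accumulate(fdr[order])
    return fdr


def compare_significant_counts(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> float:
    """Two-sided Fisher's exact p comparing significant-feature proportions."""
    for v in (count_a, total_a, count_b, total_b):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if count_a > total_a or count_b > total_b:
        raise ValueError("counts cannot exceed totals")
    table = [[count_a, total_a - count_a], [count_b, total_b - count_b]]
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)
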