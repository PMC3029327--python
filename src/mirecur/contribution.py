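"""Back-conversion of PC-level Cox coefficients to per-miRNA coefficients.

A model fit on principal-component scores assigns its hazard to PCs, not to
individual miRNAs. Because scores are linear in the (centered) features, the
PC-space linear predictor sum_j b_j * score_j rewrites exactly as a
feature-space linear predictor with combined coefficients

    beta_tilde_i = sum_j b_j * C_ji

where b_j is the Cox beta of the j-th selected PC and C_ji the loading of
feature i on that PC. Confidence intervals come from patient-level bootstrap
resampling in which the whole pipeline (PCA, PC ranking, top-k Cox fit,
conversion) is refit per resample with k held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, FeatureMatrix
from .pca import PCAModel, fit_pca, rank_pcs_by_cox
from .survival import cox_fit_multi


@dataclass
class ContributionTable:
    table: pd.DataFrame  # index feature id: mirna, source, coefficient [, ci_low, ci_high]

    def top_positive(self, n: int = 20) -> pd.DataFrame:
        pos = self.table[self.table["coefficient"] > 0]
        return pos.sort_values("coefficient", ascending=False).head(n)

    def top_negative(self, n: int = 20) -> pd.DataFrame:
        neg = self.table[self.table["coefficient"] < 0]
        return neg.sort_values("coefficient").head(n)


def convert_coefficients(
    pca_model: PCAModel,
    cox_betas: np.ndarray,
    selected_pcs: list[int] | None = None,
    feature_meta: pd.DataFrame | None = None,
) -> ContributionTable:
    """Combined per-feature coefficients beta_tilde = b @ C for the selected PCs.

    ``selected_pcs`` are 0-based component indices into the PCA model; by
    default the first len(cox_betas) components.
    """
    cox_betas = np.asarray(cox_betas, dtype=float)
    if selected_pcs is None:
        selected_pcs = list(range(len(cox_betas)))
    if len(selected_pcs) != len(cox_betas):
        raise ValueError("one Cox beta required per selected PC")
    if max(selected_pcs, default=-1) >= pca_model.n_components:
        raise ValueError("selected PC index exceeds the PCA model's components")
    C = pca_model.loadings[selected_pcs]  # k x m
    beta_tilde = cox_betas @ C
    table = pd.DataFrame(
        {"coefficient": beta_tilde}, index=pd.Index(pca_model.feature_ids, name="feature_id")
    )
    if feature_meta is not None:
        table = feature_meta.join(table, how="right")
    _attach_ranks(table)
    return ContributionTable(table=table)


def _attach_ranks(table: pd.DataFrame) -> None:
    coef = table["coefficient"]
    table["rank_positive"] = coef.where(coef > 0).rank(ascending=False).astype("Int64")
    table["rank_negative"] = coef.where(coef < 0).rank(ascending=True).astype("Int64")


def _fit_and_convert(
    values: pd.DataFrame, time: np.ndarray, event: np.ndarray, k: int
) -> np.ndarray:
    """Full-pipeline point estimate: PCA -> rank PCs by Cox p -> top-k Cox -> convert."""
    pca = fit_pca(values)
    from .screening import _screen_frame  # local import avoids a cycle

    screen = _screen_frame(pca.scores, time, event)
    top = screen.sort_values("rank").index[:k]
    pc_idx = [int(name[2:]) - 1 for name in top]
    X = pca.scores[list(top)].to_numpy(dtype=float)
    model = cox_fit_multi(X, time, event, feature_ids=list(top))
    return model.betas @ pca.loadings[pc_idx]


def bootstrap_ci(
    features: FeatureMatrix,
    clinical: ClinicalTable,
    k: int,
    B: int = 1000,
    seed: int = 0,
    resampler=None,
) -> ContributionTable:
    """Percentile 95% bootstrap CIs for the combined coefficients.

    Patients are resampled with replacement; resamples without any event are
    redrawn (at most 10*B redraws). PCA, PC ranking and the top-k Cox fit are
    all refit per resample, with k fixed at the selected model's size.
    ``resampler(rng, n) -> index array`` overrides the default draw (used to
    exercise degenerate-resampling behavior).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    values = features.values.loc[clinical.patient_ids]
    time, event = clinical.time, clinical.event
    n = len(values)
    point = _fit_and_convert(values, time, event, k)

    rng = np.random.default_rng(seed)
    draws = np.empty((B, values.shape[1]))
    redraws = 0
    for b in range(B):
        while True:
            idx = resampler(rng, n) if resampler is not None else rng.integers(0, n, size=n)
            if event[idx].sum() > 0:
                break
            redraws += 1
            if redraws > 10 * B:
                raise RuntimeError("too many event-free bootstrap resamples")
        draws[b] = _fit_and_convert(values.iloc[idx], time[idx], event[idx], k)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    table = features.feature_meta.copy()
    table["coefficient"] = point
    table["ci_low"] = lo
    table["ci_high"] = hi
    _attach_ranks(table)
    return ContributionTable(table=table)
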