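"""Leave-one-out cross-validated model construction and ta-AUROC selection.

For each held-out patient: (optionally) fit PCA on the training fold only
and project both sets, rank variables by univariate Cox p on the training
fold, then for k = 1..max_k fit a multivariate Cox model on the top-k
variables and predict the held-out patient's recurrence-free survival curve.
After all folds, each k has one predicted curve per patient; the model (and
the dataset / representation combination) with the best time-averaged AUROC
is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, FeatureMatrix, RunConfig, SurvivalCurve
from .evaluation import ta_auroc
from .pca import fit_pca
from .screening import _screen_frame
from .survival import cox_fit_multi, cox_univariate_many


@dataclass
class FoldRecord:
    held_out: str
    variable_order: list[str]
    betas_by_k: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class PredictionGrid:
    """curves[k][patient_id] is the curve predicted with the top-k model
    trained on the fold excluding that patient."""

    curves: dict[int, dict[str, SurvivalCurve]]
    dataset_choice: str
    representation: str
    folds: list[FoldRecord]
    max_k: int

    def n_curves(self) -> int:
        return sum(len(d) for d in self.curves.values())


@dataclass
class ModelSelection:
    table: pd.DataFrame  # dataset, representation, k, ta_auroc
    best_dataset: str
    best_representation: str
    best_k: int
    best_ta: float


def dataset_slice(
    features: FeatureMatrix, clinical: ClinicalTable, choice: str
) -> pd.DataFrame:
    """Patients x variables for one dataset choice.

    ALL/T/N/RATIO slice the miRNA feature matrix; CLINICAL encodes the
    typed covariates numerically (categorical covariates as ordinal integers).
    """
    if choice == "CLINICAL":
        cols = {}
        for cov, kind in clinical.covariate_types.items():
            x = clinical.data[cov]
            if kind == "continuous":
                cols[cov] = x.astype(float)
            else:  # dichotomous and ordered categorical -> integer codes
                codes = pd.Categorical(x, categories=sorted(x.dropna().unique())).codes
                cols[cov] = pd.Series(codes, index=x.index, dtype=float)
        return pd.DataFrame(cols, index=clinical.patient_ids)
    if choice == "ALL":
        return features.values.loc[clinical.patient_ids]
    return features.subset(choice).values.loc[clinical.patient_ids]


def rank_variables(values: pd.DataFrame, time, event) -> list[str]:
    """Variable ids by ascending univariate Cox p (ties: |beta| desc, then id);
    degenerate variables last."""
    table = _screen_frame(values, np.asarray(time, float), np.asarray(event, int))
    return table.sort_values("rank").index.tolist()


def loocv_predict(
    features: FeatureMatrix | pd.DataFrame,
    clinical: ClinicalTable,
    config: RunConfig,
) -> PredictionGrid:
    """The LOOCV loop: n folds, each producing max_k predicted curves.

    With representation="PCS" and pca_scope="fold" (the default), PCA is
    refit inside every fold so the held-out patient never influences the
    loadings; pca_scope="global" fits PCA once on the full cohort instead.
    """
    if isinstance(features, FeatureMatrix):
        values = dataset_slice(features, clinical, config.dataset_choice)
    else:
        values = features.loc[clinical.patient_ids]
    pids = list(clinical.patient_ids)
    n = len(pids)
    time, event = clinical.time, clinical.event

    global_pca = None
    if config.representation == "PCS" and config.pca_scope == "global":
        global_pca = fit_pca(values)

    curves: dict[int, dict[str, SurvivalCurve]] = {k: {} for k in range(1, config.max_k + 1)}
    folds: list[FoldRecord] = []
    for i, held in enumerate(pids):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if event[mask].sum() == 0:
            raise ValueError(f"fold holding out {held!r} has no training events")
        train_vals = values.iloc[mask]
        test_x = values.iloc[[i]].to_numpy(dtype=float)

        if config.representation == "PCS":
            pca = global_pca if global_pca is not None else fit_pca(train_vals)
            train_df = (
                pca.scores.loc[train_vals.index]
                if global_pca is not None
                else pca.scores
            )
            test_vec = pca.transform(test_x)[0]
            var_df = train_df
        else:
            var_df = train_vals
            test_vec = test_x[0]

        order = rank_variables(var_df, time[mask], event[mask])
        record = FoldRecord(held_out=held, variable_order=order)
        kmax = min(config.max_k, len(order))
        X_train_full = var_df[order].to_numpy(dtype=float)
        col_index = {v: j for j, v in enumerate(var_df.columns)}
        test_ordered = np.array([test_vec[col_index[v]] for v in order])
        for k in range(1, kmax + 1):
            model = cox_fit_multi(
                X_train_full[:, :k], time[mask], event[mask], feature_ids=order[:k]
            )
            record.betas_by_k[k] = model.betas
            curves[k][held] = model.predict_curve(test_ordered[:k])
        folds.append(record)
    # drop k levels with no curves (k exceeded available variables everywhere)
    curves = {k: d for k, d in curves.items() if d}
    return PredictionGrid(
        curves=curves,
        dataset_choice=config.dataset_choice,
        representation=config.representation,
        folds=folds,
        max_k=config.max_k,
    )


def ta_auroc_table(
    grid: PredictionGrid, clinical: ClinicalTable, window: tuple[float, float]
) -> pd.DataFrame:
    """ta-AUROC per k for one prediction grid. Patients without a curve at a
    given k are excluded from that k's evaluation."""
    rows = []
    for k, by_patient in sorted(grid.curves.items()):
        pids = sorted(by_patient)
        sub = ClinicalTable(
            data=clinical.data.loc[pids], covariate_types=clinical.covariate_types
        )
        try:
            ta = ta_auroc(by_patient, sub, window).ta
        except ValueError:
            ta = np.nan
        rows.append((grid.dataset_choice, grid.representation, k, ta))
    return pd.DataFrame(rows, columns=["dataset", "representation", "k", "ta_auroc"])


def select_best(
    grids: dict[tuple[str, str], PredictionGrid],
    clinical: ClinicalTable,
    config: RunConfig,
) -> ModelSelection:
    """Argmax of ta-AUROC over every (dataset, representation, k) candidate."""
    tables = [
        ta_auroc_table(grid, clinical, config.eval_window) for grid in grids.values()
    ]
    table = pd.concat(tables, ignore_index=True)
    if table["ta_auroc"].isna().all():
        raise ValueError("ta-AUROC undefined for every candidate model")
    best = table.loc[table["ta_auroc"].idxmax()]
    return ModelSelection(
        table=table,
        best_dataset=str(best["dataset"]),
        best_representation=str(best["representation"]),
        best_k=int(best["k"]),
        best_ta=float(best["ta_auroc"]),
    )
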