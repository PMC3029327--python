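"""Principal component analysis of the feature matrix and PC-level statistics.

PCA is centered but not scaled: all features share the log2 expression
scale, and the downstream contribution analysis applies loadings directly to
expression values, which is only coherent without per-feature rescaling.
The sign of each component is fixed so its largest-magnitude loading is
positive, making results deterministic across runs and platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClinicalTable, FeatureMatrix
from .screening import ScreenResult, _screen_frame


@dataclass
class PCAModel:
    means: np.ndarray               # per-feature mean
    loadings: np.ndarray            # components x features, rows orthonormal
    explained_variance: np.ndarray  # per component
    scores: pd.DataFrame            # patients x components ("PC1", "PC2", ...)
    feature_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def transform(self, X) -> np.ndarray:
        """Project new observations: score_j = sum_i C_ji (x_i - mu_i)."""
        X = np.asarray(X, dtype=float)
        return (X - self.means) @ self.loadings.T


def fit_pca(features: FeatureMatrix | pd.DataFrame) -> PCAModel:
    """Centered PCA via SVD; components ordered by explained variance."""
    values = features.values if isinstance(features, FeatureMatrix) else features
    X = values.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 patients")
    means = X.mean(axis=0)
    Xc = X - means
    if np.allclose(Xc, 0.0):
        raise ValueError("zero-variance matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = min(n - 1, m)
    U, s, Vt = U[:, :r], s[:r], Vt[:r]
    # deterministic sign: largest-magnitude loading of each PC is positive
    for j in range(r):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    explained = s**2 / (n - 1)
    score_df = pd.DataFrame(
        scores, index=values.index, columns=[f"PC{j + 1}" for j in range(r)]
    )
    return PCAModel(
        means=means,
        loadings=Vt,
        explained_variance=explained,
        scores=score_df,
        feature_ids=list(values.columns),
    )


def rank_pcs_by_cox(model: PCAModel, clinical: ClinicalTable) -> ScreenResult:
    """Univariate Cox fit on each PC score, ranked by p ascending."""
    scores = model.scores.loc[clinical.patient_ids]
    table = _screen_frame(scores, clinical.time, clinical.event)
    return ScreenResult(table=table)


def pc_clinical_association(model: PCAModel, clinical: ClinicalTable) -> pd.DataFrame:
    """Association p-value for every (PC, covariate) pair.

    Continuous covariates use the Pearson correlation test, categorical
    (>= 3 levels) the Kruskal-Wallis test, dichotomous the classical
    equal-variance two-sample t-test. Covariates with a single observed level
    are skipped with a warning.
    """
    scores = model.scores.loc[clinical.patient_ids]
    rows = []
    for cov, kind in clinical.covariate_types.items():
        x = clinical.data[cov]
        levels = x.dropna().unique()
        if len(levels) < 2 and kind != "continuous":
            warnings.warn(f"covariate {cov!r} has a single level; skipped")
            continue
        for pc in scores.columns:
            s = scores[pc].to_numpy()
            if kind == "continuous":
                xv = x.to_numpy(dtype=float)
                if np.std(xv) == 0 or np.std(s) == 0:
                    warnings.warn(f"covariate {cov!r} is constant; skipped")
                    break
                r, p = stats.pearsonr(s, xv)
                stat, test = r, "pearson"
            elif kind == "dichotomous":
                g = [s[x == lev] for lev in sorted(levels)]
                t, p = stats.ttest_ind(g[0], g[1], equal_var=True)
                stat, test = t, "t-test"
            else:  # categorical
                groups = [s[x == lev] for lev in sorted(levels)]
                if len(groups) >= 3:
                    stat, p = stats.kruskal(*groups)
                    test = "kruskal-wallis"
                else:
                    t, p = stats.ttest_ind(groups[0], groups[1], equal_var=True)
                    stat, test = t, "t-test"
            rows.append((pc, cov, test, float(stat), float(p)))
    return pd.DataFrame(rows, columns=["pc", "covariate", "test", "statistic", "p"])
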