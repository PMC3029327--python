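"""Core in-memory containers shared across the pipeline.

All expression values are stored and exchanged in log2 scale. Patients are
kept in one canonical order — lexicographic by patient id — fixed the moment
a table is constructed, so that cross-validation folds, permutations and
bootstrap draws are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TISSUES = ("T", "N")
SOURCES = ("T", "N", "RATIO")
COVARIATE_TYPES = ("continuous", "categorical", "dichotomous")
DATASET_CHOICES = ("ALL", "T", "N", "RATIO", "CLINICAL")
REPRESENTATIONS = ("FEATURES", "PCS")


@dataclass
class ExpressionMatrix:
    """Log2 expression intensities, samples x miRNAs, with sample metadata.

    ``values``: DataFrame indexed by sample id, columns = miRNA ids.
    ``meta``: DataFrame indexed by sample id with columns ``patient_id`` and
    ``tissue`` ("T" for tumor, "N" for paired non-tumor liver).
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dups}")
        if not set(self.meta.index) >= set(self.values.index):
            missing = sorted(set(self.values.index) - set(self.meta.index))
            raise ValueError(f"samples missing from metadata: {missing}")
        bad = set(self.meta["tissue"]) - set(TISSUES)
        if bad:
            raise ValueError(f"unknown tissue codes: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            # locate the first offending cell for a useful message
            for col in self.values.columns:
                coerced = pd.to_numeric(self.values[col], errors="coerce")
                if coerced.isna().any() and not self.values[col].isna().any():
                    row = self.values.index[coerced.isna()][0]
                    raise ValueError(f"non-numeric value at sample {row!r}, miRNA {col!r}")
            raise ValueError("non-numeric values in expression matrix")
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at sample {self.values.index[i]!r}, "
                f"miRNA {self.values.columns[j]!r}"
            )
        self.meta = self.meta.loc[self.values.index]

    @property
    def mirna_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    def patient_ids(self) -> list[str]:
        """Canonical (lexicographic) patient order."""
        return sorted(self.meta["patient_id"].unique())

    def unpaired_patients(self) -> list[str]:
        """Patients lacking exactly one T and one N sample."""
        out = []
        for pid, grp in self.meta.groupby("patient_id"):
            counts = grp["tissue"].value_counts()
            if counts.get("T", 0) != 1 or counts.get("N", 0) != 1:
                out.append(pid)
        return sorted(out)

    def tissue_matrix(self, tissue: str) -> pd.DataFrame:
        """Patients x miRNAs for one tissue, rows in canonical patient order."""
        if tissue not in TISSUES:
            raise ValueError(f"unknown tissue {tissue!r}")
        sel = self.meta[self.meta["tissue"] == tissue]
        sub = self.values.loc[sel.index]
        sub.index = sel["patient_id"].to_numpy()
        return sub.sort_index()


@dataclass
class ClinicalTable:
    """Per-patient recurrence-free survival outcome and typed covariates.

    ``data`` is indexed by patient id (lexicographic order), with columns
    ``time`` (days from resection to recurrence or censoring, > 0), ``event``
    (1 = recurrence observed, 0 = censored) and any number of covariates whose
    statistical type is declared in ``covariate_types``.
    """

    data: pd.DataFrame
    covariate_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate patient ids in clinical table")
        if "time" not in self.data or "event" not in self.data:
            raise ValueError("clinical table requires 'time' and 'event' columns")
        t = self.data["time"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            bad = self.data.index[(~np.isfinite(t)) | (t <= 0)].tolist()
            raise ValueError(f"non-positive survival time for patients: {bad}")
        e = self.data["event"].to_numpy()
        if not set(np.unique(e)) <= {0, 1}:
            raise ValueError("event indicator must be 0 or 1")
        for name, kind in self.covariate_types.items():
            if kind not in COVARIATE_TYPES:
                raise ValueError(f"unknown covariate type {kind!r} for {name!r}")
            if name not in self.data:
                raise ValueError(f"declared covariate {name!r} not in table")
            if kind == "dichotomous":
                levels = self.data[name].dropna().unique()
                if len(levels) > 2:
                    raise ValueError(
                        f"dichotomous covariate {name!r} has {len(levels)} levels"
                    )
        self.data = self.data.sort_index()

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    def covariates(self) -> pd.DataFrame:
        return self.data[list(self.covariate_types)]


@dataclass
class FeatureMatrix:
    """Patients x features; each feature is (miRNA id, source in {T, N, RATIO}).

    RATIO features are the log2 tumor-minus-non-tumor difference, i.e. the
    T/N expression ratio on linear scale.
    """

    values: pd.DataFrame                 # patients x feature ids
    feature_meta: pd.DataFrame           # index feature id; columns mirna, source

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.feature_meta.index):
            raise ValueError("feature ids of values and feature_meta disagree")
        bad = set(self.feature_meta["source"]) - set(SOURCES)
        if bad:
            raise ValueError(f"unknown feature sources: {sorted(bad)}")
        self.values = self.values.sort_index()

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, source: str) -> "FeatureMatrix":
        """Restrict to one source block (T, N or RATIO)."""
        keep = self.feature_meta.index[self.feature_meta["source"] == source]
        return FeatureMatrix(self.values[keep], self.feature_meta.loc[keep])


@dataclass
class SurvivalCurve:
    """Right-continuous step survival function, S(0) = 1, non-increasing."""

    times: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.times.shape != self.survival.shape:
            raise ValueError("times and survival must have the same length")
        if len(self.times) == 0 or self.times[0] != 0.0 or self.survival[0] != 1.0:
            raise ValueError("curve must start at (t=0, S=1)")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if np.any((self.survival < -1e-12) | (self.survival > 1 + 1e-12)):
            raise ValueError("survival values must lie in [0, 1]")

    def at(self, t) -> np.ndarray | float:
        """S(t) by right-continuous step interpolation."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        out = self.survival[idx]
        return float(out) if out.ndim == 0 else out

    def mean_over(self, window: tuple[float, float]) -> float:
        """Time-average of S over [t0, t1] (step-function integral / length)."""
        t0, t1 = window
        if not t0 < t1:
            raise ValueError("window must satisfy t0 < t1")
        knots = np.concatenate(([t0], self.times[(self.times > t0) & (self.times < t1)], [t1]))
        vals = self.at(knots[:-1])
        return float(np.sum(np.atleast_1d(vals) * np.diff(knots)) / (t1 - t0))


@dataclass
class RunConfig:
    """Pipeline constants: expression filter, evaluation window, search sizes.

    Defaults pin the study conventions: features kept when their 75th
    percentile of log2 expression exceeds 6; models evaluated between
    6 months (183 days) and 5 years (1826 days); 1..30 top-ranked variables
    searched; 1000 permutations / bootstrap resamples.
    """

    filter_threshold: float = 6.0
    filter_percentile: float = 0.75
    eval_window: tuple[float, float] = (183.0, 1826.0)
    max_k: int = 30
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    seed: int = 0
    dataset_choice: str = "ALL"
    representation: str = "PCS"
    pca_scope: str = "fold"   # refit PCA inside each LOOCV fold; "global" fits once

    def __post_init__(self) -> None:
        if not self.eval_window[0] < self.eval_window[1]:
            raise ValueError("eval_window must satisfy t_start < t_end")
        if not (0.0 < self.filter_percentile <= 1.0):
            raise ValueError("filter_percentile must lie in (0, 1]")
        for name in ("max_k", "n_permutations", "n_bootstrap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dataset_choice not in DATASET_CHOICES:
            raise ValueError(f"dataset_choice must be one of {DATASET_CHOICES}")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        if self.pca_scope not in ("fold", "global"):
            raise ValueError("pca_scope must be 'fold' or 'global'")


def validate_patients(expression: ExpressionMatrix, clinical: ClinicalTable) -> None:
    """Every profiled patient must have a clinical record."""
    missing = set(expression.meta["patient_id"]) - set(clinical.patient_ids)
    if missing:
        raise ValueError(f"patients in expression metadata missing from clinical table: {sorted(missing)}")
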