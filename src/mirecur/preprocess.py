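"""Quantile normalization, expression filtering, and feature assembly.

The per-patient feature matrix concatenates, for each miRNA passing the
expression filter, its tumor value (T), paired non-tumor value (N), and
their log2 difference (the T/N ratio): m kept miRNAs yield 3m features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, ExpressionMatrix, FeatureMatrix


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    After normalization each sample's sorted value vector equals the
    across-sample mean of sorted vectors; within-sample rank order is
    preserved. Ties within a sample receive the mean of the reference values
    at the tied positions.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    order = np.argsort(X, axis=1, kind="stable")
    reference = np.mean(np.take_along_axis(X, order, axis=1), axis=0)
    out = np.empty_like(X)
    for i in range(n_samples):
        row = np.empty(X.shape[1])
        row[order[i]] = reference
        # average reference values over tied input positions
        vals, inv, counts = np.unique(X[i], return_inverse=True, return_counts=True)
        if len(vals) < X.shape[1]:
            sums = np.bincount(inv, weights=row)
            row = (sums / counts)[inv]
        out[i] = row
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, meta=matrix.meta.copy())


def filter_expressed(
    matrix: ExpressionMatrix, percentile: float = 0.75, threshold: float = 6.0
) -> list[str]:
    """miRNAs whose per-miRNA percentile over all samples strictly exceeds threshold.

    Tumor and non-tumor samples are pooled. The percentile uses linear
    interpolation between order statistics (index = percentile * (n - 1)).
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.size == 0:
        raise ValueError("empty expression matrix")
    q = np.quantile(X, percentile, axis=0, method="linear")
    return [mir for mir, v in zip(matrix.mirna_ids, q) if v > threshold]


def assemble_features(
    matrix: ExpressionMatrix, kept: list[str], clinical: ClinicalTable | None = None
) -> FeatureMatrix:
    """Build the patients x 3m feature matrix: T block, N block, RATIO block.

    Feature ids are ``{mirna}_T``, ``{mirna}_N``, ``{mirna}_R``, in that block
    order; RATIO = T - N in log2 scale, exactly.
    """
    unpaired = matrix.unpaired_patients()
    if unpaired:
        raise ValueError(f"unpaired patients (need exactly one T and one N sample): {unpaired}")
    missing = set(kept) - set(matrix.mirna_ids)
    if missing:
        raise ValueError(f"kept miRNAs absent from matrix: {sorted(missing)}")
    t_mat = matrix.tissue_matrix("T")[kept]
    n_mat = matrix.tissue_matrix("N")[kept]
    if clinical is not None:
        missing_clin = set(t_mat.index) - set(clinical.patient_ids)
        if missing_clin:
            raise ValueError(f"patients missing from clinical table: {sorted(missing_clin)}")
    ratio = t_mat - n_mat
    blocks, meta_rows = [], []
    for source, block in (("T", t_mat), ("N", n_mat), ("RATIO", ratio)):
        suffix = {"T": "_T", "N": "_N", "RATIO": "_R"}[source]
        renamed = block.copy()
        renamed.columns = [f"{mir}{suffix}" for mir in kept]
        blocks.append(renamed)
        meta_rows += [(f"{mir}{suffix}", mir, source) for mir in kept]
    values = pd.concat(blocks, axis=1)
    values.index.name = "patient_id"
    feature_meta = pd.DataFrame(
        meta_rows, columns=["feature_id", "mirna", "source"]
    ).set_index("feature_id")
    return FeatureMatrix(values=values, feature_meta=feature_meta)


def write_features(features: FeatureMatrix, path) -> None:
    """TSV with a 3-line feature-meta header (feature id, miRNA, source)."""
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(features.feature_ids) + "\n")
        fh.write("mirna\t" + "\t".join(features.feature_meta["mirna"]) + "\n")
        fh.write("source\t" + "\t".join(features.feature_meta["source"]) + "\n")
        for pid, row in features.values.iterrows():
            fh.write(pid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_features(path) -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        mirna = fh.readline().rstrip("\n").split("\t")[1:]
        source = fh.readline().rstrip("\n").split("\t")[1:]
        rows, index = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            index.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    values = pd.DataFrame(rows, index=pd.Index(index, name="patient_id"), columns=header)
    feature_meta = pd.DataFrame(
        {"mirna": mirna, "source": source}, index=pd.Index(header, name="feature_id")
    )
    return FeatureMatrix(values=values, feature_meta=feature_meta)
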