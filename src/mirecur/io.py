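"""Readers and writers for the expression / clinical / curve text formats.

Expression files are tab-separated, miRNAs as rows: the first column holds
the miRNA id, the header row holds sample ids. A companion metadata TSV maps
each sample id to (patient_id, tissue). Clinical tables are CSV with the
covariate type declared in the header as ``name:type`` where type is one of
continuous / categorical / dichotomous; ``patient_id``, ``time`` and
``event`` carry no type suffix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import COVARIATE_TYPES, ClinicalTable, ExpressionMatrix, SurvivalCurve


def read_expression(path, meta_path, raw_scale: bool = False) -> ExpressionMatrix:
    """Read a miRNAs-by-samples TSV plus its sample metadata.

    If ``raw_scale`` is true, intensities are floored at 1 and log2-converted
    at read time; otherwise values are taken to be log2 already.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = {s for s in header if header.count(s) > 1}
    if seen:
        raise ValueError(f"duplicate sample ids in {path}: {sorted(seen)}")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate miRNA ids in {path}: {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in {path} at miRNA {raw.index[bad][0]!r}, sample {col!r}"
            )
        raw[col] = coerced
    values = raw.T  # samples x miRNAs
    values.index.name = "sample_id"
    values.columns.name = None
    if raw_scale:
        values = np.log2(values.clip(lower=1.0))
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in metadata {meta_path}")
    required = {"patient_id", "tissue"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must declare columns {sorted(required)}")
    return ExpressionMatrix(values=values, meta=meta[["patient_id", "tissue"]])


def write_expression(matrix: ExpressionMatrix, path, meta_path) -> None:
    matrix.values.T.to_csv(path, sep="\t", index_label="mirna_id", float_format="%.6f")
    matrix.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path)
    rename, types = {}, {}
    for col in df.columns:
        if ":" in col:
            name, kind = col.split(":", 1)
            if kind not in COVARIATE_TYPES:
                raise ValueError(f"unknown covariate type {kind!r} in header {col!r}")
            rename[col] = name
            types[name] = kind
    df = df.rename(columns=rename)
    if "patient_id" not in df.columns:
        raise ValueError("clinical table requires a 'patient_id' column")
    df = df.set_index("patient_id")
    return ClinicalTable(data=df, covariate_types=types)


def write_clinical(table: ClinicalTable, path) -> None:
    df = table.data.copy()
    df.columns = [
        f"{c}:{table.covariate_types[c]}" if c in table.covariate_types else c
        for c in df.columns
    ]
    df.to_csv(path, index_label="patient_id")


def write_curve(curve: SurvivalCurve, path) -> None:
    """Two-column TSV: time_days, survival_probability."""
    pd.DataFrame(
        {"time_days": curve.times, "survival_probability": curve.survival}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_curve(path) -> SurvivalCurve:
    df = pd.read_csv(path, sep="\t")
    return SurvivalCurve(
        times=df["time_days"].to_numpy(), survival=df["survival_probability"].to_numpy()
    )
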