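import numpy as np
import pandas as pd
import pytest

import mirecur as mr


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n=73), normalized and assembled."""
    expr, clin, truth = mr.generate_dataset(mr.SimulationDesign(seed=0))
    norm = mr.quantile_normalize(expr)
    kept = mr.filter_expressed(norm)
    feats = mr.assemble_features(norm, kept, clin)
    return {"expr": expr, "norm": norm, "kept": kept, "feats": feats,
            "clin": clin, "truth": truth}


@pytest.fixture
def toy_expression():
    """Two paired patients, two miRNAs."""
    values = pd.DataFrame(
        [[8.0, 6.0], [4.0, 4.0], [6.0, 5.0], [4.0, 4.0]],
        index=pd.Index(["P1-T", "P1-N", "P2-T", "P2-N"], name="sample_id"),
        columns=["miR-a", "miR-b"],
    )
    meta = pd.DataFrame(
        {"patient_id": ["P1", "P1", "P2", "P2"], "tissue": ["T", "N", "T", "N"]},
        index=values.index,
    )
    return mr.ExpressionMatrix(values=values, meta=meta)


@pytest.fixture
def toy_clinical():
    df = pd.DataFrame(
        {"time": [400.0, 900.0], "event": [1, 0], "age": [60.0, 70.0]},
        index=pd.Index(["P1", "P2"], name="patient_id"),
    )
    return mr.ClinicalTable(data=df, covariate_types={"age": "continuous"})


def random_survival_instance(rng, n_max=6, allow_ties=True):
    """Small random survival dataset for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    x = rng.standard_normal(n).round(2)
    if allow_ties:
        t = rng.integers(1, n + 2, size=n).astype(float)
    else:
        t = rng.uniform(1, 10, size=n)
    e = (rng.uniform(size=n) < 0.8).astype(int)
    if e.sum() == 0:
        e[int(rng.integers(0, n))] = 1
    return x, t, e


def flat_risk_curves(risks, horizon=3000.0):
    """Constant-hazard-free step curves whose 1 - S(t) equals `risks` for t >= 1."""
    return {
        pid: mr.SurvivalCurve(times=np.array([0.0, 1.0]), survival=np.array([1.0, 1.0 - r]))
        for pid, r in risks.items()
    }


def clinical_from_arrays(pids, times, events):
    df = pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events, int)},
        index=pd.Index(list(pids), name="patient_id"),
    )
    return mr.ClinicalTable(data=df)
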