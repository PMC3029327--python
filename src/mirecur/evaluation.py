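"""Time-dependent AUROC under censoring and the time-averaged AUROC index.

At evaluation time t, cases are patients with an observed event at or before
t, controls are patients still under observation beyond t (regardless of
eventual status), and patients censored at or before t without an event are
excluded (cumulative-case / dynamic-control convention). The risk score of a
patient is 1 - S_hat(t) from their predicted survival curve. The AUROC(t)
step series changes at distinct observed event times inside the evaluation
window; its time average (ta-AUROC) integrates the step function over the
window, renormalizing over the segments where the AUROC is defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClinicalTable, SurvivalCurve
from .survival import gehan_wilcoxon_test, km_estimate, logrank_test


@dataclass
class AUROCSeries:
    change_times: np.ndarray   # ascending; left edge of each constant segment
    auroc_values: np.ndarray   # may contain NaN where undefined
    window: tuple[float, float]
    ta: float

    def segments(self):
        """(start, end, value) triples covering the window."""
        edges = np.append(self.change_times, self.window[1])
        return [
            (edges[i], edges[i + 1], self.auroc_values[i])
            for i in range(len(self.change_times))
        ]


@dataclass
class RiskStrata:
    assignment: pd.Series   # patient id -> "LOW" | "HIGH"
    statistic: pd.Series    # the per-patient splitting statistic

    def patients(self, group: str) -> pd.Index:
        return self.assignment.index[self.assignment == group]


def _auroc_from_risks(risk: np.ndarray, time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Exhausted over case-control pairs via rank sums; NaN when undefined."""
    cases = (event == 1) & (time <= t)
    controls = time > t
    n1, n0 = cases.sum(), controls.sum()
    if n1 == 0 or n0 == 0:
        return np.nan
    r = stats.rankdata(np.concatenate([risk[cases], risk[controls]]))
    # Mann-Whitney U of cases over controls; ties count 0.5
    u = r[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def auroc_at_time(
    curves: Mapping[str, SurvivalCurve], clinical: ClinicalTable, t: float
) -> float:
    """AUROC at a single time point; NaN when cases or controls are empty."""
    if t <= 0:
        raise ValueError("t must be positive")
    pids = list(clinical.patient_ids)
    risk = np.array([1.0 - curves[p].at(t) for p in pids])
    return _auroc_from_risks(risk, clinical.time, clinical.event, t)


def ta_auroc(
    curves: Mapping[str, SurvivalCurve],
    clinical: ClinicalTable,
    window: tuple[float, float] = (183.0, 1826.0),
) -> AUROCSeries:
    """Piecewise-constant AUROC over the window and its time average.

    Change points are the distinct observed event times inside the window
    (plus the window start); each segment carries the AUROC evaluated at its
    left edge. Segments where the AUROC is undefined are excluded and the
    average renormalized over the remaining time.
    """
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t_start < t_end")
    ev_times = np.unique(clinical.time[clinical.event == 1])
    change = np.concatenate(([t0], ev_times[(ev_times > t0) & (ev_times <= t1)]))
    values = np.array([auroc_at_time(curves, clinical, t) for t in change])
    edges = np.append(change, t1)
    lengths = np.diff(edges)
    defined = ~np.isnan(values)
    total = lengths[defined].sum()
    if total <= 0:
        raise ValueError("AUROC undefined over the entire window")
    ta = float(np.sum(lengths[defined] * values[defined]) / total)
    return AUROCSeries(change_times=change, auroc_values=values, window=window, ta=ta)


def auroc_trend(series: AUROCSeries) -> tuple[float, float]:
    """Length-weighted Pearson correlation of AUROC(t) against segment midpoints.

    Returns (r, p); a constant (or undefined) series yields r = 0, p = 1.
    """
    segs = [(a, b, v) for a, b, v in series.segments() if not np.isnan(v)]
    if len(segs) < 3:
        raise ValueError("trend requires at least 3 defined change points")
    mids = np.array([(a + b) / 2 for a, b, _ in segs])
    vals = np.array([v for _, _, v in segs])
    w = np.array([b - a for a, b, _ in segs])
    w = w / w.sum()
    mx, my = np.sum(w * mids), np.sum(w * vals)
    cov = np.sum(w * (mids - mx) * (vals - my))
    vx, vy = np.sum(w * (mids - mx) ** 2), np.sum(w * (vals - my) ** 2)
    if vx <= 0 or vy <= 0:
        return 0.0, 1.0
    r = float(cov / np.sqrt(vx * vy))
    n = len(segs)
    r_ = min(max(r, -0.999999999), 0.999999999)
    t = r_ * np.sqrt((n - 2) / (1 - r_**2))
    p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return r, p


def stratify_median(
    curves: Mapping[str, SurvivalCurve], window: tuple[float, float] = (183.0, 1826.0)
) -> RiskStrata:
    """Median split on the window-mean predicted survival.

    Patients sorted by mean predicted survival descending (ties broken by
    patient id); the top ceil(n/2) form the LOW-risk group.
    """
    pids = sorted(curves.keys())
    stat = pd.Series({p: curves[p].mean_over(window) for p in pids}).sort_index()
    order = sorted(pids, key=lambda p: (-stat[p], p))
    n = len(order)
    n_low = (n + 1) // 2
    assignment = pd.Series("HIGH", index=stat.index)
    assignment.loc[order[:n_low]] = "LOW"
    return RiskStrata(assignment=assignment, statistic=stat)


def compare_strata(strata: RiskStrata, clinical: ClinicalTable):
    """Kaplan-Meier curves per stratum plus log-rank and Gehan-Wilcoxon tests.

    Returns (km_curves: dict, logrank (chi2, p), wilcoxon (chi2, p)).
    """
    km_curves, groups = {}, {}
    for g in ("LOW", "HIGH"):
        pids = strata.patients(g)
        if len(pids) == 0:
            raise ValueError(f"stratum {g} is empty")
        sub = clinical.data.loc[pids]
        groups[g] = (sub["time"].to_numpy(float), sub["event"].to_numpy(int))
        km_curves[g] = km_estimate(*groups[g])
    lr = logrank_test(*groups["LOW"], *groups["HIGH"])
    wx = gehan_wilcoxon_test(*groups["LOW"], *groups["HIGH"])
    return km_curves, lr, wx
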