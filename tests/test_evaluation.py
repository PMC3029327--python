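import numpy as np
import pandas as pd
import pytest

import mirecur as mr
from mirecur.evaluation import _auroc_from_risks

from conftest import clinical_from_arrays, flat_risk_curves


def auroc_pair_oracle(risk, time, event, t):
    """O(n^2) case-control pair enumeration; ties count one half."""
    cases = np.flatnonzero((event == 1) & (time <= t))
    controls = np.flatnonzero(time > t)
    if len(cases) == 0 or len(controls) == 0:
        return np.nan
    wins = 0.0
    for i in cases:
        for j in controls:
            if risk[i] > risk[j]:
                wins += 1.0
            elif risk[i] == risk[j]:
                wins += 0.5
    return wins / (len(cases) * len(controls))


@pytest.fixture
def four_patients():
    pids = ["P1", "P2", "P3", "P4"]
    clin = clinical_from_arrays(pids, [100, 400, 800, 2000], [1, 1, 0, 1])
    curves = flat_risk_curves(dict(zip(pids, [0.9, 0.5, 0.6, 0.1])))
    return curves, clin


class TestAurocAtTime:
    def test_single_case_beats_all_controls(self, four_patients):
        curves, clin = four_patients
        assert mr.auroc_at_time(curves, clin, 365) == pytest.approx(1.0)

    def test_two_cases_three_of_four_pairs(self, four_patients):
        curves, clin = four_patients
        assert mr.auroc_at_time(curves, clin, 500) == pytest.approx(0.75)

    def test_censored_before_t_excluded(self, four_patients):
        curves, clin = four_patients
        # at t=900: P3 (censored at 800) excluded; cases {P1,P2}, controls {P4}
        assert mr.auroc_at_time(curves, clin, 900) == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        pids = ["A", "B", "C"]
        clin = clinical_from_arrays(pids, [100, 500, 900], [1, 1, 0])
        curves = flat_risk_curves({p: 0.4 for p in pids})
        assert mr.auroc_at_time(curves, clin, 300) == pytest.approx(0.5)

    def test_undefined_when_no_cases(self, four_patients):
        curves, clin = four_patients
        assert np.isnan(mr.auroc_at_time(curves, clin, 50))

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            n = int(rng.integers(4, 12))
            time = rng.uniform(1, 1000, n)
            event = rng.integers(0, 2, n)
            risk = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)  # forces ties
            t = float(rng.uniform(1, 1000))
            ours = _auroc_from_risks(risk, time, event, t)
            ref = auroc_pair_oracle(risk, time, event, t)
            if np.isnan(ref):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(ref, abs=1e-12)


class TestTaAuroc:
    def test_perfect_predictor_ta_one(self):
        # risk order equals event-time order, no in-window censoring
        pids = [f"P{i}" for i in range(6)]
        times = [200, 500, 900, 1300, 2000, 2200]
        events = [1, 1, 1, 1, 0, 0]
        risks = dict(zip(pids, [0.9, 0.8, 0.7, 0.6, 0.2, 0.1]))
        clin = clinical_from_arrays(pids, times, events)
        series = mr.ta_auroc(flat_risk_curves(risks), clin, (183.0, 1826.0))
        assert series.ta == pytest.approx(1.0)

    def test_segment_weighted_average(self):
        # AUROC 1.0 on [183+,1000) then 0.5 on [1000,1826]
        pids = ["P1", "P2", "P3", "P4"]
        clin = clinical_from_arrays(pids, [300, 1000, 2000, 2000], [1, 1, 0, 0])
        curves = flat_risk_curves(dict(zip(pids, [0.9, 0.2, 0.5, 0.5])))
        series = mr.ta_auroc(curves, clin, (183.0, 1826.0))
        # segments: [183,300) undefined; [300,1000) -> 1.0; [1000,1826] -> 0.5
        expected = (700 * 1.0 + 826 * 0.5) / (700 + 826)
        assert series.ta == pytest.approx(expected)
        np.testing.assert_allclose(series.change_times, [183.0, 300.0, 1000.0])

    def test_reversed_risks_complement(self):
        rng = np.random.default_rng(1)
        pids = [f"P{i}" for i in range(20)]
        times = rng.uniform(100, 2500, 20)
        events = rng.integers(0, 2, 20)
        events[0] = 1
        risks = rng.uniform(0.05, 0.95, 20)
        clin = clinical_from_arrays(pids, times, events)
        a = mr.ta_auroc(flat_risk_curves(dict(zip(pids, risks))), clin, (183, 1826))
        b = mr.ta_auroc(flat_risk_curves(dict(zip(pids, 1 - risks))), clin, (183, 1826))
        assert a.ta == pytest.approx(1 - b.ta, abs=1e-12)

    def test_change_points_are_event_times(self):
        pids = ["A", "B", "C", "D"]
        clin = clinical_from_arrays(pids, [250, 600, 700, 2000], [1, 1, 0, 0])
        curves = flat_risk_curves({p: r for p, r in zip(pids, [0.9, 0.7, 0.5, 0.1])})
        series = mr.ta_auroc(curves, clin, (183.0, 1826.0))
        np.testing.assert_allclose(series.change_times, [183.0, 250.0, 600.0])

    def test_undefined_everywhere_rejected(self):
        pids = ["A", "B"]
        clin = clinical_from_arrays(pids, [50, 60], [1, 1])  # no controls in window
        curves = flat_risk_curves({"A": 0.5, "B": 0.4})
        with pytest.raises(ValueError, match="undefined"):
            mr.ta_auroc(curves, clin, (183.0, 1826.0))

    def test_random_scores_average_near_half(self):
        rng = np.random.default_rng(2)
        pids = [f"P{i}" for i in range(40)]
        clin_t = rng.uniform(100, 2800, 40)
        clin_e = (rng.uniform(size=40) < 0.6).astype(int)
        clin_e[0] = 1
        clin = clinical_from_arrays(pids, clin_t, clin_e)
        tas = []
        for _ in range(60):
            risks = dict(zip(pids, rng.uniform(size=40)))
            tas.append(mr.ta_auroc(flat_risk_curves(risks), clin, (183, 1826)).ta)
        assert abs(np.mean(tas) - 0.5) < 0.03

    def test_single_model_risk_order_time_invariant(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 2))
        t = np.maximum(rng.exponential(600 / np.exp(0.8 * X[:, 0])), 1.0)
        e = np.ones(30, dtype=int)
        model = mr.cox_fit_multi(X, t, e)
        curves = [model.predict_curve(x) for x in X]
        risks_a = np.array([1 - c.at(400.0) for c in curves])
        risks_b = np.array([1 - c.at(1500.0) for c in curves])
        assert (np.argsort(risks_a) == np.argsort(risks_b)).all()


class TestAurocTrend:
    def _series(self, values):
        values = np.asarray(values, float)
        change = np.linspace(183, 1700, len(values))
        return mr.AUROCSeries(
            change_times=change, auroc_values=values, window=(183.0, 1826.0), ta=0.5
        )

    def test_decreasing_series_negative(self):
        r, p = mr.auroc_trend(self._series([0.9, 0.8, 0.7, 0.6, 0.5]))
        assert r < 0 and p < 0.05

    def test_increasing_series_positive(self):
        r, p = mr.auroc_trend(self._series([0.5, 0.6, 0.7, 0.8, 0.9]))
        assert r > 0

    def test_constant_series_zero(self):
        r, p = mr.auroc_trend(self._series([0.7, 0.7, 0.7, 0.7]))
        assert r == 0.0 and p == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            mr.auroc_trend(self._series([0.5, 0.6]))


class TestStratification:
    def test_even_split_four_patients(self):
        curves = flat_risk_curves({"A": 0.9, "B": 0.7, "C": 0.3, "D": 0.1})
        strata = mr.stratify_median(curves, (183.0, 1826.0))
        assert list(strata.patients("LOW")) == ["C", "D"]
        assert list(strata.patients("HIGH")) == ["A", "B"]

    def test_odd_cohort_ceil_low(self):
        curves = flat_risk_curves({f"P{i:02d}": i / 10 for i in range(7)})
        strata = mr.stratify_median(curves, (183.0, 1826.0))
        assert (strata.assignment == "LOW").sum() == 4
        assert (strata.assignment == "HIGH").sum() == 3

    def test_all_equal_statistics_split_by_id(self):
        curves = flat_risk_curves({f"P{i:02d}": 0.5 for i in range(5)})
        strata = mr.stratify_median(curves, (183.0, 1826.0))
        assert sorted(strata.patients("LOW")) == ["P00", "P01", "P02"]

    def test_statistic_is_window_mean_survival(self):
        curve = mr.SurvivalCurve(times=[0.0, 1000.0], survival=[1.0, 0.5])
        strata = mr.stratify_median({"A": curve, "B": curve}, (500.0, 1500.0))
        # S = 1 on [500,1000), 0.5 on [1000,1500] -> mean (500*1+500*0.5)/1000
        assert strata.statistic["A"] == pytest.approx(0.75)


class TestCompareStrata:
    def test_identical_groups_null(self):
        pids = [f"P{i}" for i in range(8)]
        times = [100, 200, 300, 400] * 2
        events = [1, 1, 0, 1] * 2
        clin = clinical_from_arrays(pids, times, events)
        assignment = pd.Series(["LOW"] * 4 + ["HIGH"] * 4, index=clin.patient_ids)
        strata = mr.RiskStrata(
            assignment=assignment, statistic=pd.Series(0.5, index=clin.patient_ids)
        )
        km, (lr_chi2, lr_p), (wx_chi2, wx_p) = mr.compare_strata(strata, clin)
        assert lr_p == pytest.approx(1.0)
        assert wx_p == pytest.approx(1.0)
        assert set(km) == {"LOW", "HIGH"}

    def test_separated_groups_significant(self):
        pids = [f"P{i:02d}" for i in range(20)]
        times = list(np.arange(1, 11) * 30) + list(np.arange(1, 11) * 300)
        events = [1] * 10 + [0] * 10
        clin = clinical_from_arrays(pids, times, events)
        assignment = pd.Series(["HIGH"] * 10 + ["LOW"] * 10, index=clin.patient_ids)
        strata = mr.RiskStrata(
            assignment=assignment, statistic=pd.Series(0.0, index=clin.patient_ids)
        )
        _, (_, lr_p), (_, wx_p) = mr.compare_strata(strata, clin)
        assert lr_p < 0.01 and wx_p < 0.01

    def test_empty_stratum_rejected(self):
        pids = ["A", "B"]
        clin = clinical_from_arrays(pids, [10, 20], [1, 1])
        strata = mr.RiskStrata(
            assignment=pd.Series(["LOW", "LOW"], index=clin.patient_ids),
            statistic=pd.Series(0.5, index=clin.patient_ids),
        )
        with pytest.raises(ValueError, match="HIGH"):
            mr.compare_strata(strata, clin)
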