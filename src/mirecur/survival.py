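"""Cox proportional-hazards fitting and two-group survival comparison.

The Cox partial likelihood is maximized by Newton-Raphson with the Efron
tie correction (tolerance 1e-8 on the log-likelihood change, at most 50
iterations). The univariate fitter is vectorized across features because the
screening and cross-validation loops need tens of thousands of single-
covariate fits. The baseline cumulative hazard uses the Breslow estimator
evaluated at the training covariate means, so predicted curves are
S0(t) ** exp(beta . (x - mean)).

Kaplan-Meier estimation and the log-rank / Gehan-Wilcoxon tests delegate to
lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .datatypes import SurvivalCurve

_TOL = 1e-8
_MAX_ITER = 50
_BETA_GUARD = 10.0  # |beta| above this at convergence flags monotone likelihood


@dataclass
class CoxResult:
    beta: float
    hazard_ratio: float
    se: float
    p: float
    converged: bool
    degenerate: bool


@dataclass
class MultiCoxModel:
    """Multivariate Cox fit with everything needed to predict survival curves."""

    betas: np.ndarray
    feature_ids: list[str]
    training_means: np.ndarray
    baseline_curve: SurvivalCurve
    se: np.ndarray
    p: np.ndarray
    converged: bool
    degenerate: np.ndarray
    loglik: float

    def linear_predictor(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != len(self.betas):
            raise ValueError(
                f"covariate dimension {x.shape[-1]} != model dimension {len(self.betas)}"
            )
        return x @ self.betas - self.training_means @ self.betas

    def predict_curve(self, x: np.ndarray) -> SurvivalCurve:
        """S(t | x) = S0(t) ** exp(beta . (x - training_means))."""
        hr = np.exp(self.linear_predictor(x))
        surv = np.clip(self.baseline_curve.survival, 0.0, 1.0) ** hr
        return SurvivalCurve(times=self.baseline_curve.times.copy(), survival=surv)


def _check_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("Cox fitting requires at least one event")
    return time, event


def _event_groups(time_sorted: np.ndarray, event_sorted: np.ndarray):
    """Unique event times (ascending) with risk-set start index and tied-event indices."""
    groups = []
    for t in np.unique(time_sorted[event_sorted == 1]):
        start = np.searchsorted(time_sorted, t, side="left")
        tied = np.flatnonzero((time_sorted == t) & (event_sorted == 1))
        groups.append((start, tied))
    return groups


def cox_univariate_many(X, time, event, tol: float = _TOL, max_iter: int = _MAX_ITER):
    """Fit one univariate Cox model per column of X, vectorized.

    Returns dict of arrays: beta, hazard_ratio, se, p, converged, degenerate,
    each of length m.
    """
    time, event = _check_survival(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    order = np.argsort(time, kind="stable")
    ts, es, Xs = time[order], event[order], X[order]
    Xs = Xs - Xs.mean(axis=0)  # location shift leaves the partial likelihood invariant
    degenerate = np.ptp(Xs, axis=0) == 0
    groups = _event_groups(ts, es)

    beta = np.zeros(m)
    prev_ll = None
    hess_neg = np.zeros(m)
    converged = np.zeros(m, dtype=bool)
    for _ in range(max_iter):
        eta = Xs * beta[None, :]
        eta -= eta.max(axis=0, keepdims=True)  # exact invariance, numeric safety
        w = np.exp(eta)
        xw = Xs * w
        x2w = Xs * xw
        S0 = np.cumsum(w[::-1], axis=0)[::-1]
        S1 = np.cumsum(xw[::-1], axis=0)[::-1]
        S2 = np.cumsum(x2w[::-1], axis=0)[::-1]
        ll = np.zeros(m)
        grad = np.zeros(m)
        hess = np.zeros(m)  # negative Hessian (information), positive for concave ll
        for start, tied in groups:
            d = len(tied)
            s0d, s1d, s2d = w[tied].sum(0), xw[tied].sum(0), x2w[tied].sum(0)
            ll += eta[tied].sum(0)
            grad += Xs[tied].sum(0)
            frac = np.arange(d)[:, None] / d
            phi0 = S0[start][None, :] - frac * s0d[None, :]
            phi1 = S1[start][None, :] - frac * s1d[None, :]
            phi2 = S2[start][None, :] - frac * s2d[None, :]
            ll -= np.log(phi0).sum(0)
            grad -= (phi1 / phi0).sum(0)
            hess += (phi2 / phi0 - (phi1 / phi0) ** 2).sum(0)
        hess_neg = hess
        if prev_ll is not None:
            converged |= ~degenerate & (np.abs(ll - prev_ll) < tol)
        prev_ll = ll
        if np.all(converged | degenerate):
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(hess > 0, grad / hess, 0.0)
        step = np.clip(step, -1.0, 1.0)
        active = ~(converged | degenerate)
        beta = np.where(active, np.clip(beta + step, -15.0, 15.0), beta)
    converged &= np.abs(beta) <= _BETA_GUARD

    beta = np.where(degenerate, 0.0, beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(hess_neg > 0, 1.0 / np.sqrt(hess_neg), np.inf)
    se = np.where(degenerate, np.inf, se)
    z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(degenerate, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    return {
        "beta": beta,
        "hazard_ratio": np.exp(beta),
        "se": se,
        "p": p,
        "converged": converged & ~degenerate,
        "degenerate": degenerate,
    }


def cox_fit_single(x, time, event) -> CoxResult:
    """Univariate Cox fit; thin wrapper over the vectorized solver."""
    r = cox_univariate_many(np.asarray(x, dtype=float)[:, None], time, event)
    return CoxResult(
        beta=float(r["beta"][0]),
        hazard_ratio=float(r["hazard_ratio"][0]),
        se=float(r["se"][0]),
        p=float(r["p"][0]),
        converged=bool(r["converged"][0]),
        degenerate=bool(r["degenerate"][0]),
    )


def _efron_ll_grad_hess(beta, Xs, eta_shiftable, groups):
    """Log-likelihood, gradient and Hessian of the Efron partial likelihood."""
    eta = Xs @ beta
    eta -= eta.max()
    w = np.exp(eta)
    xw = Xs * w[:, None]
    n, p = Xs.shape
    outer = Xs[:, :, None] * xw[:, None, :]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(xw[::-1], axis=0)[::-1]
    S2 = np.cumsum(outer[::-1], axis=0)[::-1]
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for start, tied in groups:
        d = len(tied)
        s0d, s1d, s2d = w[tied].sum(0), xw[tied].sum(0), outer[tied].sum(0)
        ll += eta[tied].sum()
        grad += Xs[tied].sum(0)
        for l in range(d):
            f = l / d
            phi0 = S0[start] - f * s0d
            phi1 = S1[start] - f * s1d
            phi2 = S2[start] - f * s2d
            ll -= np.log(phi0)
            mu = phi1 / phi0
            grad -= mu
            hess -= phi2 / phi0 - np.outer(mu, mu)
    return ll, grad, hess


def cox_fit_multi(
    X, time, event, feature_ids=None, tol: float = _TOL, max_iter: int = _MAX_ITER
) -> MultiCoxModel:
    """Multivariate Cox fit with Breslow baseline survival at mean covariates."""
    time, event = _check_survival(time, event)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least covariates+1 subjects ({p + 1}), got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if feature_ids is None:
        feature_ids = [f"x{j}" for j in range(p)]
    means = X.mean(axis=0)
    Xc = X - means
    degenerate = np.ptp(Xc, axis=0) == 0
    free = np.flatnonzero(~degenerate)

    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    Xs = Xc[order][:, free]
    groups = _event_groups(ts, es)

    beta_free = np.zeros(len(free))
    converged = False
    ll, grad, hess = _efron_ll_grad_hess(beta_free, Xs, None, groups)
    for _ in range(max_iter):
        hess_neg = -hess
        try:
            step = np.linalg.solve(hess_neg, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess_neg, grad, rcond=None)[0]
        # step-halving keeps the ascent monotone
        factor = 1.0
        for _half in range(30):
            cand = beta_free + factor * step
            ll_new, grad_new, hess_new = _efron_ll_grad_hess(cand, Xs, None, groups)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta_free, delta = cand, abs(ll_new - ll)
        ll, grad, hess = ll_new, grad_new, hess_new
        if delta < tol:
            converged = True
            break
    if np.any(np.abs(beta_free) > _BETA_GUARD):
        converged = False

    betas = np.zeros(p)
    betas[free] = beta_free
    se = np.full(p, np.inf)
    pvals = np.ones(p)
    if len(free) > 0:
        try:
            cov = np.linalg.inv(-hess)
            se_free = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se_free = np.full(len(free), np.inf)
        se[free] = np.where(se_free > 0, se_free, np.inf)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(np.isfinite(se[free]), beta_free / se[free], 0.0)
        pvals[free] = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)

    # Breslow baseline cumulative hazard at the training means (eta centered)
    w = np.exp(Xs @ beta_free)
    S0 = np.cumsum(w[::-1])[::-1]
    times, surv = [0.0], [1.0]
    cumhaz = 0.0
    for start, tied in groups:
        cumhaz += len(tied) / S0[start]
        times.append(ts[start])
        surv.append(np.exp(-cumhaz))
    baseline = SurvivalCurve(times=np.array(times), survival=np.array(surv))

    return MultiCoxModel(
        betas=betas,
        feature_ids=list(feature_ids),
        training_means=means,
        baseline_curve=baseline,
        se=se,
        p=pvals,
        converged=converged,
        degenerate=degenerate,
        loglik=float(ll),
    )


def km_estimate(time, event) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) survival estimate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0.0:
        times = np.concatenate(([0.0], times))
        surv = np.concatenate(([1.0], surv))
    return SurvivalCurve(times=times, survival=surv)


def _two_group_test(timeA, eventA, timeB, eventB, weightings=None):
    timeA, timeB = np.asarray(timeA, float), np.asarray(timeB, float)
    eventA, eventB = np.asarray(eventA, int), np.asarray(eventB, int)
    if len(timeA) == 0 or len(timeB) == 0:
        raise ValueError("both groups must be non-empty")
    if eventA.sum() + eventB.sum() == 0:
        warnings.warn("no events in either group; test statistic undefined, p = 1")
        return 0.0, 1.0
    res = _ll_logrank(timeA, timeB, event_observed_A=eventA, event_observed_B=eventB,
                     weightings=weightings)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        warnings.warn("zero variance in two-group test; p = 1")
        return 0.0, 1.0
    return chi2, p


def logrank_test(timeA, eventA, timeB, eventB) -> tuple[float, float]:
    """Standard log-rank test: chi-square statistic (1 df) and p-value."""
    return _two_group_test(timeA, eventA, timeB, eventB, weightings=None)


def gehan_wilcoxon_test(timeA, eventA, timeB, eventB) -> tuple[float, float]:
    """Generalized Wilcoxon (Gehan-Breslow) test: events weighted by number at risk."""
    return _two_group_test(timeA, eventA, timeB, eventB, weightings="wilcoxon")
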