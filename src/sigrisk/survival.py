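"""Censored-survival statistics implemented from first principles.

This module is the numerical engine of the package: the Kaplan-Meier
product-limit estimator, the k-sample log-rank test, Cox
proportional-hazards fitting by Newton-Raphson on the partial likelihood
(Efron or Breslow tie handling), hazard ratios for a two-level grouping,
and Harrell's concordance index.

All functions operate on plain NumPy arrays: ``time`` is a vector of
positive follow-up times, ``event`` an indicator vector (1 = event
observed, 0 = right-censored).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "ConcordanceResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "hazard_ratio",
    "concordance_index",
    "cox_partial_loglik",
    "cox_gradient",
]


class ZeroVarianceError(ValueError):
    """A covariate has zero variance; the partial likelihood is flat in it."""

    def __init__(self, names):
        self.names = list(names)
        super().__init__(f"zero-variance covariate(s): {', '.join(map(str, self.names))}")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate of the survivor function.

    ``survival[i]`` is S(t) for t in ``[event_times[i], event_times[i+1])``;
    S = 1 before the first event time.  ``censor_times`` carries the times of
    censored observations for tick marks on plots.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        """S(t) evaluated at arbitrary times (right-continuous step)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]


def _as_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("empty survival input")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValueError("all times must be positive and finite")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValueError("event indicator must be 0 or 1")
    return time, ev.astype(int)


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    ``d_i`` is the number of events at distinct event time ``t_i`` and
    ``n_i`` the number still at risk (time >= t_i).
    """
    time, event = _as_surv(time, event)
    n = time.size
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]

    uniq, first = np.unique(ts, return_index=True)
    # number at risk just before each distinct time
    at_risk_all = n - first
    d = np.add.reduceat(es, first)

    is_event_time = d > 0
    event_times = uniq[is_event_time]
    n_events = d[is_event_time]
    at_risk = at_risk_all[is_event_time]
    surv = np.cumprod(1.0 - n_events / at_risk)
    censor_times = np.sort(time[event == 0])
    return KMCurve(event_times, surv, at_risk, n_events, censor_times)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(time, event, group) -> LogRankResult:
    """k-sample log-rank chi-square test of equality of survival curves.

    The statistic is (O - E)' V^-1 (O - E) over the first k-1 groups, with
    O the observed event counts, E the expectations under the pooled risk
    sets, and V the summed hypergeometric covariance.  df = k - 1; p from
    the upper chi-square tail.
    """
    time, event = _as_surv(time, event)
    group = np.asarray(group)
    if group.shape != time.shape:
        raise ValueError("group labels must match sample count")
    levels, gidx = np.unique(group, return_inverse=True)
    k = levels.size
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")

    if event.sum() == 0:
        return LogRankResult(0.0, k - 1, 1.0)

    uniq_event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in uniq_event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        died = (time == t) & (event == 1)
        d_t = died.sum()
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[died], minlength=k).astype(float)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            cov = d_t * (n_t - d_t) / (n_t - 1) * (np.diag(frac) - np.outer(frac, frac))
            V += cov

    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        chi2 = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, k - 1)) if chi2 > 0 else 1.0
    return LogRankResult(chi2, k - 1, p)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit.

    ``beta`` are the log-hazard coefficients, ``se`` their standard errors
    from the inverse observed information, ``wald_p`` two-sided Wald
    p-values.  ``names`` carries covariate labels when supplied.
    """

    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    loglik_start: float
    loglik: float
    iterations: int
    converged: bool
    tie_method: str
    names: list = field(default_factory=list)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary_rows(self):
        names = self.names or [f"x{i}" for i in range(self.beta.size)]
        for i, nm in enumerate(names):
            yield nm, self.beta[i], self.se[i], self.wald_p[i]


def _prepare_cox(X, time, event):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time, event = _as_surv(time, event)
    if X.shape[0] != time.size:
        raise ValueError("X rows must match sample count")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values; impute before fitting")
    return X, time, event


def _cox_ll_grad_hess(X, time, event, beta, tie_method, want_hess=True):
    """Partial log-likelihood, gradient, and (optionally) Hessian.

    Samples are sorted by descending time so the risk set at an event time
    is a prefix of the arrays and risk-set sums are cumulative sums.
    """
    n, p = X.shape
    order = np.argsort(-time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]
    eta = Xs @ beta
    shift = eta.max()  # overflow guard; cancels in all ratios and in ll
    theta = np.exp(eta - shift)

    cS0 = np.cumsum(theta)
    cS1 = np.cumsum(theta[:, None] * Xs, axis=0)
    if want_hess:
        outer = theta[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
        cS2 = np.cumsum(outer, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p)) if want_hess else None

    # distinct times, descending; risk set ends at the last index of each block
    uniq, first = np.unique(-ts, return_index=True)
    last = np.append(first[1:], n) - 1
    for b0, b1 in zip(first, last):
        block = slice(b0, b1 + 1)
        ev = es[block] == 1
        d = int(ev.sum())
        if d == 0:
            continue
        rows = np.arange(b0, b1 + 1)[ev]
        S0 = cS0[b1]
        S1 = cS1[b1]
        S2 = cS2[b1] if want_hess else None
        sum_eta = (eta[rows] - shift).sum()

        if tie_method == "breslow" or d == 1:
            ll += sum_eta - d * np.log(S0)
            mu = S1 / S0
            grad += Xs[rows].sum(axis=0) - d * mu
            if want_hess:
                hess -= d * (S2 / S0 - np.outer(mu, mu))
        else:  # efron
            th_d = theta[rows]
            s0d = th_d.sum()
            s1d = (th_d[:, None] * Xs[rows]).sum(axis=0)
            if want_hess:
                s2d = (th_d[:, None, None] * (Xs[rows][:, :, None] * Xs[rows][:, None, :])).sum(axis=0)
            xsum = Xs[rows].sum(axis=0)
            ll += sum_eta
            grad += xsum
            for l in range(d):
                f = l / d
                den = S0 - f * s0d
                ll -= np.log(den)
                mu = (S1 - f * s1d) / den
                grad -= mu
                if want_hess:
                    hess -= (S2 - f * s2d) / den - np.outer(mu, mu)
    return ll, grad, hess


def cox_partial_loglik(X, time, event, beta, tie_method="efron") -> float:
    """Cox partial log-likelihood at ``beta`` (Efron or Breslow ties)."""
    X, time, event = _prepare_cox(X, time, event)
    beta = np.asarray(beta, dtype=float)
    ll, _, _ = _cox_ll_grad_hess(X, time, event, beta, tie_method, want_hess=False)
    return float(ll)


def cox_gradient(X, time, event, beta, tie_method="efron") -> np.ndarray:
    """Analytic gradient of the partial log-likelihood at ``beta``."""
    X, time, event = _prepare_cox(X, time, event)
    beta = np.asarray(beta, dtype=float)
    _, g, _ = _cox_ll_grad_hess(X, time, event, beta, tie_method, want_hess=False)
    return g


def cox_fit(X, time, event, tie_method="efron", names=None,
            max_iter=50, grad_tol=1e-8, loglik_rtol=1e-9) -> CoxFit:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Convergence when the gradient max-norm falls below ``grad_tol`` or the
    relative log-likelihood change falls below ``loglik_rtol``; step-halving
    guards against overshoot.  Zero-variance covariates raise
    :class:`ZeroVarianceError` so the caller can drop them explicitly.
    """
    if tie_method not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method: {tie_method}")
    X, time, event = _prepare_cox(X, time, event)
    n, p = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]

    variances = X.var(axis=0)
    if np.any(variances == 0):
        raise ZeroVarianceError([names[i] for i in np.flatnonzero(variances == 0)])
    if event.sum() == 0:
        raise ValueError("no events observed; Cox model undefined")

    # center covariates: leaves beta unchanged, improves conditioning
    center = X.mean(axis=0)
    Xc = X - center

    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(Xc, time, event, beta, tie_method)
    ll_start = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step-halving: insist on non-decreasing partial likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _cox_ll_grad_hess(Xc, time, event, cand, tie_method)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        rel_change = abs(ll_new - ll) / max(abs(ll_new), 1.0)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.max(np.abs(grad)) < grad_tol or rel_change < loglik_rtol:
            converged = np.max(np.abs(grad)) < grad_tol or rel_change < loglik_rtol
            break

    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood); "
            "coefficients may be unstable", RuntimeWarning, stacklevel=2)

    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxFit(beta=beta, se=se, wald_p=wald_p, loglik_start=ll_start,
                  loglik=ll, iterations=it, converged=bool(converged),
                  tie_method=tie_method, names=names)


def hazard_ratio(time, event, group):
    """Hazard ratio between two groups via a univariate Cox fit.

    Returns ``(hr, (lo, hi), p)`` where the interval is the 95% Wald CI for
    the hazard of the *second* group level (sorted order) relative to the
    first.  With no events in one group the likelihood is monotone: the fit
    is flagged and the CI is unbounded.
    """
    time, event = _as_surv(time, event)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError("hazard_ratio requires exactly 2 group levels")
    if event.sum() < 1:
        raise ValueError("hazard_ratio requires at least one event")
    ind = (group == levels[1]).astype(float)
    events_per = [event[group == lv].sum() for lv in levels]
    monotone = any(e == 0 for e in events_per)
    with warnings.catch_warnings():
        if monotone:
            warnings.simplefilter("ignore", RuntimeWarning)
        fit = cox_fit(ind[:, None], time, event, names=[str(levels[1])])
    if monotone:
        warnings.warn("no events in one group: hazard ratio unbounded "
                      "(monotone likelihood)", RuntimeWarning, stacklevel=2)
        hr = float(np.exp(fit.beta[0]))
        return hr, (0.0, np.inf), 1.0
    b, s = fit.beta[0], fit.se[0]
    with np.errstate(over="ignore"):
        lo = np.exp(b - 1.959963984540054 * s)
        hi = np.exp(b + 1.959963984540054 * s)
    return float(np.exp(b)), (float(lo), float(hi)), float(fit.wald_p[0])


# ---------------------------------------------------------------------------
# Concordance index
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    c_index: float
    comparable_pairs: int
    tied_score_pairs: int


def concordance_index(score, time, event) -> ConcordanceResult:
    """Harrell's C: P(higher score -> earlier event) over comparable pairs.

    A pair (i, j) is comparable when the ordering of their events is
    determinable under censoring: t_i < t_j and subject i had the event.
    Pairs with tied times are not comparable.  Tied scores contribute 1/2.
    """
    score = np.asarray(score, dtype=float)
    time, event = _as_surv(time, event)
    if score.shape != time.shape:
        raise ValueError("score length must match sample count")

    dt = time[:, None] < time[None, :]          # t_i < t_j
    comparable = dt & (event[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs (all censored or all tied)")
    higher = score[:, None] > score[None, :]
    tied = score[:, None] == score[None, :]
    concordant = float((comparable & higher).sum())
    half = float((comparable & tied).sum())
    c = (concordant + 0.5 * half) / n_pairs
    return ConcordanceResult(float(c), n_pairs, int(half))
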