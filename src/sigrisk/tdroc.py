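"""Time-dependent ROC curves for a censored survival marker.

Cumulative-case / dynamic-control estimation: at horizon ``t``, cases are
subjects with an event by ``t`` and controls are subjects event-free past
``t``.  Censoring before ``t`` is handled either with conditional
Kaplan-Meier estimates within marker strata ("km") or with a
nearest-neighbor bivariate survival estimator ("nne"), which yields a
monotone ROC by construction.  The AUC is the trapezoid area under the
curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival import km_estimate

__all__ = ["TdROC", "td_roc", "default_span"]


@dataclass
class TdROC:
    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    estimator: str
    span: float | None = None


def default_span(n: int) -> float:
    """Nearest-neighbor window half-width: 0.25 * n^(-0.2).

    The window covers marker percentiles within +- span of each subject,
    shrinking slowly with sample size.
    """
    return 0.25 * n ** (-0.2)


def _check_inputs(marker, time, event, t):
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if not (marker.shape == time.shape == event.shape):
        raise ValueError("marker, time and event must have equal length")
    if t > time.max():
        raise ValueError(f"horizon {t} beyond last follow-up {time.max()}")
    if not np.any((time <= t) & (event == 1)):
        raise ValueError(f"no events observed by horizon {t}")
    return marker, time, event


def _roc_points_to_auc(sens, spec):
    """Trapezoid area under (1-spec, sens) including the (0,0)/(1,1) corners."""
    fpr = 1.0 - np.asarray(spec, dtype=float)
    tpr = np.asarray(sens, dtype=float)
    order = np.lexsort((tpr, fpr))  # ascending tpr within equal fpr
    fpr, tpr = fpr[order], tpr[order]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def _km_at(time, event, t):
    if time.size == 0:
        return 1.0
    if event.sum() == 0:
        return 1.0
    return float(km_estimate(time, event).survival_at(t)[0])


def _isotonic_cleanup(sens, spec):
    """Enforce a monotone ROC: running maxima along decreasing thresholds.

    The conditional-KM estimator is not guaranteed monotone; clip into
    [0, 1] and take cumulative envelopes so the curve is a valid ROC.
    """
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    # thresholds ascend: sens decreases, spec increases
    sens = np.maximum.accumulate(sens[::-1])[::-1]
    spec = np.maximum.accumulate(spec)
    return sens, spec


def td_roc(marker, time, event, t, estimator="nne", span=None) -> TdROC:
    """Time-dependent ROC of a risk marker at horizon ``t``.

    Higher marker means higher risk.  Thresholds run over the unique marker
    values; sensitivity(c) = P(marker > c | T <= t) and specificity(c) =
    P(marker <= c | T > t).
    """
    marker, time, event = _check_inputs(marker, time, event, t)
    n = marker.size
    thresholds = np.unique(marker)

    if estimator == "km":
        surv_all = _km_at(time, event, t)
        if surv_all >= 1.0:
            raise ValueError("overall survival estimate is 1 at the horizon")
        sens = np.empty(thresholds.size)
        spec = np.empty(thresholds.size)
        for i, c in enumerate(thresholds):
            above = marker > c
            p_above = above.mean()
            s_above = _km_at(time[above], event[above], t) if p_above > 0 else 1.0
            # P(X > c, T <= t) / P(T <= t)
            sens[i] = p_above * (1.0 - s_above) / (1.0 - surv_all)
            # P(X <= c, T > t) / P(T > t)
            spec[i] = (surv_all - p_above * s_above) / surv_all
        sens, spec = _isotonic_cleanup(sens, spec)
    elif estimator == "nne":
        if span is None:
            span = default_span(n)
        sens, spec = _nne_roc(marker, time, event, t, span, thresholds)
    else:
        raise ValueError(f"unknown estimator: {estimator}")

    auc = _roc_points_to_auc(sens, spec)
    return TdROC(float(t), thresholds, sens, spec, auc, estimator,
                 None if estimator == "km" else float(span))


def _nne_roc(marker, time, event, t, span, thresholds):
    """Nearest-neighbor estimator of S(c, t) = P(X > c, T > t).

    For each subject a weighted KM curve is built from neighbors whose
    marker percentile lies within ``span``; S(c, t) averages these
    conditional survival estimates over subjects with marker above c.
    """
    n = marker.size
    # percentile of each subject's marker (average ranks for ties)
    order = np.argsort(marker, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # average tied ranks
    for v in np.unique(marker):
        mask = marker == v
        ranks[mask] = ranks[mask].mean()
    pct = ranks / n

    W = (np.abs(pct[:, None] - pct[None, :]) <= span).astype(float)  # n x n

    ev_times = np.unique(time[event == 1])
    ev_times = ev_times[ev_times <= t]
    atrisk = (time[None, :] >= ev_times[:, None]).astype(float)       # m x n
    deaths = ((time[None, :] == ev_times[:, None]) & (event[None, :] == 1)).astype(float)

    Y = W @ atrisk.T      # n x m: weighted number at risk per subject window
    D = W @ deaths.T      # n x m: weighted deaths
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(Y > 0, D / Y, 0.0)
    frac = np.clip(frac, 0.0, 1.0 - 1e-12)
    # S_i(t) = prod over event times <= t of (1 - dD/Y)
    log_surv = np.log1p(-frac).sum(axis=1)
    S_i = np.exp(log_surv)                             # per-subject S(t | x_i)

    S_t = S_i.mean()                                   # P(T > t)
    if S_t >= 1.0:
        raise ValueError("no event mass by the horizon under the estimator")
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, c in enumerate(thresholds):
        above = marker > c
        S_ct = S_i[above].sum() / n                    # P(X > c, T > t)
        p_above = above.mean()
        sens[i] = (p_above - S_ct) / (1.0 - S_t)
        spec[i] = (S_t - S_ct) / S_t
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    return sens, spec
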