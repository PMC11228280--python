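"""Kaplan-Meier estimation and the g-sample log-rank test.

The log-rank statistic is the quadratic form of the per-group observed minus
expected event counts under the pooled-hazard null, with the multivariate
hypergeometric covariance accumulated over distinct event times; a
generalised inverse handles g > 2 groups (the covariance matrix of all g
group sums is singular by construction). The statistic is asymptotically
chi-squared with g - 1 degrees of freedom.

Ties between events and censorings at the same time follow the standard
convention: events are processed first, so subjects censored at t remain in
the risk set for the events at t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class SurvivalCurve:
    event_times: np.ndarray     # distinct event times, sorted
    survival_probs: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray         # risk-set size just before each event time


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p_value: float


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times < 0) or not np.isin(events, (0, 1)).all():
        raise ValueError("times must be >= 0 and events in {0, 1}")

    event_times = np.unique(times[events == 1])
    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_i = int(np.sum(times >= t))  # censored-at-t subjects still at risk
        d_i = int(np.sum((times == t) & (events == 1)))
        at_risk[i] = n_i
        s *= 1.0 - d_i / n_i
        surv[i] = s
    return SurvivalCurve(event_times, surv, at_risk)


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Step-function evaluation of the estimated survival probability."""
    idx = np.searchsorted(curve.event_times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival_probs[idx - 1])


def logrank_test(times, events, groups) -> LogRankResult:
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    g = labels.size
    if g < 2:
        raise ValueError("need at least two non-empty groups")
    member = groups[:, None] == labels[None, :]  # n x g

    event_times = np.unique(times[events == 1])
    if event_times.size == 0:
        warnings.warn("all subjects censored; log-rank statistic is 0", stacklevel=2)
        return LogRankResult(chi2=0.0, df=g - 1, p_value=1.0)

    observed = np.zeros(g)
    expected = np.zeros(g)
    cov = np.zeros((g, g))
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n_j = member[at_risk].sum(axis=0).astype(float)
        dead = at_risk & (times == t) & (events == 1)
        d = int(dead.sum())
        d_j = member[dead].sum(axis=0).astype(float)
        observed += d_j
        expected += d * n_j / n
        if n > 1:
            frac = n_j / n
            cov += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))

    diff = observed - expected
    # drop one group: the g-vector sums to zero, so its covariance is singular
    sub = slice(0, g - 1)
    v = cov[sub, sub]
    chi2 = float(diff[sub] @ np.linalg.pinv(v) @ diff[sub])
    chi2 = max(chi2, 0.0)
    df = g - 1
    return LogRankResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)))


def curves_to_frame(curves: dict) -> "pd.DataFrame":
    """Stack per-group Kaplan-Meier curves into a tidy (time, survival,
    at_risk, group) table for TSV export."""
    import pandas as pd

    rows = []
    for group, curve in curves.items():
        for t, s, n in zip(curve.event_times, curve.survival_probs, curve.at_risk):
            rows.append({"time": t, "survival": s, "at_risk": n, "group": group})
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk", "group"])


def neg_log10_p(p: float) -> float:
    if not 0.0 < p <= 1.0:
        raise ValueError("p must lie in (0, 1]")
    return float(-np.log10(p))
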