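"""Survival-model evaluation: Kaplan-Meier curves, the log-rank test,
cumulative/dynamic time-dependent ROC with Kaplan-Meier weighting, Youden
cut-point selection and risk stratification.

The time-dependent ROC at horizon t treats subjects with event time <= t as
cases and subjects surviving past t as controls. Under censoring the class
membership of censored-before-t subjects is unknown, so sensitivity and
specificity are estimated through conditional Kaplan-Meier survival within
the groups defined by each score cutpoint:

    Sens(c, t) = [1 - S_{>c}(t)] P(score > c) / [1 - S(t)]
    Spec(c, t) = S_{<=c}(t) P(score <= c) / S(t)

with S the overall KM estimate and S_{>c} / S_{<=c} KM within the score
groups. With no censoring before t this reduces exactly to the empirical
ROC of the binary outcome "event by t". The raw estimates need not be
monotone in c; they are monotonized by running maxima before the
trapezoidal AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi2: float
    p: float


@dataclass
class TimeROC:
    horizon: float
    cutpoints: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float


@dataclass
class RiskStratification:
    """High/low assignment at a score cutoff (high iff score > cutoff)."""

    cutoff: float
    assignments: pd.Series  # "high"/"low" per sample
    n_high: int
    n_low: int


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only times never drop the curve; they only shrink later risk
    sets.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("empty survival data")
    if (time < 0).any():
        raise ValueError("negative survival time")
    event_times = np.unique(time[event == 1])
    surv = np.empty(event_times.size)
    s = 1.0
    at_risk = np.empty(event_times.size)
    n_events = np.empty(event_times.size)
    for i, t in enumerate(event_times):
        n = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n
        at_risk[i] = n
        n_events[i] = d
        surv[i] = s
    return KMCurve(event_times, surv, at_risk, n_events)


def km_survival_at(time, event, t: float) -> float:
    """S(t) by the product-limit formula without building the full curve."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ets, d = np.unique(time[(event == 1) & (time <= t)], return_counts=True)
    if ets.size == 0:
        return 1.0
    sorted_times = np.sort(time)
    n_at_risk = time.size - np.searchsorted(sorted_times, ets, side="left")
    return float(np.prod(1.0 - d / n_at_risk))


def logrank_test(time, event, groups) -> LogRankResult:
    """Two-group log-rank chi-square (1 df, hypergeometric variance)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {labels.size}")
    in1 = groups == labels[1]
    event_times = np.unique(time[event == 1])
    obs_minus_exp = 0.0
    var = 0.0
    for t in event_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & in1).sum()
        deaths = (time == t) & (event == 1)
        d = deaths.sum()
        d1 = (deaths & in1).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(0.0, 1.0)
    chi2 = obs_minus_exp ** 2 / var
    return LogRankResult(float(chi2), float(stats.chi2.sf(chi2, df=1)))


def _monotonize(cutpoints, sens, spec):
    """Running maxima: sens non-increasing and spec non-decreasing in c."""
    sens = np.maximum.accumulate(sens[::-1])[::-1]
    spec = np.maximum.accumulate(spec)
    return sens, spec


def time_dependent_roc(scores, time, event, horizon: float) -> TimeROC:
    """Cumulative/dynamic ROC at ``horizon`` with KM-conditional weighting.

    ``scores``, ``time``, ``event`` are aligned per-sample arrays; the
    horizon shares the unit of ``time``. Cutpoints are the observed unique
    scores; the implicit -inf/+inf endpoints (0,0) and (1,1) enter the AUC
    trapezoid.
    """
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if not ((time <= horizon) & (event == 1)).any():
        raise ValueError("no events before the horizon")
    s_all = km_survival_at(time, event, horizon)
    if s_all >= 1.0:
        raise ValueError("no events before the horizon")
    if s_all <= 0.0:
        raise ValueError("no subjects survive past the horizon")
    cutpoints = np.unique(scores)
    sens = np.empty(cutpoints.size)
    spec = np.empty(cutpoints.size)
    n = scores.size
    for i, c in enumerate(cutpoints):
        hi = scores > c
        p_hi = hi.mean()
        if p_hi > 0:
            s_hi = km_survival_at(time[hi], event[hi], horizon)
            sens[i] = (1.0 - s_hi) * p_hi / (1.0 - s_all)
        else:
            sens[i] = 0.0
        lo = ~hi
        s_lo = km_survival_at(time[lo], event[lo], horizon)
        spec[i] = s_lo * lo.mean() / s_all
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)
    sens, spec = _monotonize(cutpoints, sens, spec)
    # traverse cutpoints from +inf down to -inf: (fpr, sens) then moves
    # monotonically from (0,0) to (1,1) and the trapezoid rule applies
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return TimeROC(horizon, cutpoints, sens, spec, auc)


def youden_cutoff(roc: TimeROC) -> float:
    """Cutpoint maximizing sensitivity + specificity; ties -> smaller cutoff."""
    youden = roc.sens + roc.spec
    best = np.argmax(youden)  # argmax returns the first (smallest) maximizer
    return float(roc.cutpoints[best])


def stratify(scores: pd.Series, cutoff: float) -> RiskStratification:
    """Assign high risk iff score > cutoff (score exactly at cutoff is low)."""
    scores = pd.Series(scores)
    high = scores > cutoff
    assignments = pd.Series(np.where(high, "high", "low"), index=scores.index)
    return RiskStratification(float(cutoff), assignments,
                              int(high.sum()), int((~high).sum()))


def multi_horizon_roc(scores, time, event, horizons) -> list:
    """One TimeROC per horizon (same units as ``time``)."""
    return [time_dependent_roc(scores, time, event, h) for h in horizons]


def covariate_roc_comparison(covariates: pd.DataFrame, time, event,
                             horizon: float) -> pd.DataFrame:
    """AUC at one horizon for each covariate column used as a score.

    Ordinal clinical covariates enter as-is; rows with missing values are
    dropped per covariate. Returns a table of AUC and the n used.
    """
    rows = {}
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    for name in covariates.columns:
        vals = pd.to_numeric(covariates[name], errors="coerce")
        ok = vals.notna().to_numpy()
        roc = time_dependent_roc(vals.to_numpy(float)[ok], time[ok], event[ok],
                                 horizon)
        rows[name] = {"auc": roc.auc, "n": int(ok.sum())}
    return pd.DataFrame.from_dict(rows, orient="index")
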