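"""Cox proportional-hazards fitting on the partial likelihood.

Two fitters live here:

- :func:`cox_fit` — multivariate Newton-Raphson on the partial likelihood
  with Breslow (default) or Efron handling of tied event times. Used for
  the multivariate refit of selected pairs and for clinical independence
  models.
- :func:`unicox_scan` — a batch univariate fitter specialized to binary
  0/1 covariates, vectorized across thousands of pair indicators at once.
  For a binary covariate the risk-set sums reduce to counts, so every pair
  shares one sorted pass over the data.

Wald inference throughout: se from the inverse observed information,
95% CI as coef +/- z(0.975)*se with the exact normal quantile.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pairrisk")

Z975 = stats.norm.ppf(0.975)  # 1.959963984540054, not 1.96

MODEL_COLUMNS = ["Coef", "HR", "HR.95L", "HR.95H", "p value"]


class ConvergenceWarning(UserWarning):
    pass


def _risk_set_layout(time, event):
    """Sort descending by time; return order, distinct event times' slice
    ends (risk-set sizes) and the event membership per distinct time."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    event_times = np.unique(time[event == 1])[::-1]  # descending
    # risk set for event time t = all with time >= t = prefix of sorted arrays
    risk_ends = np.searchsorted(-t_sorted, -event_times, side="right")
    return order, t_sorted, e_sorted, event_times, risk_ends


def cox_loglik(beta, X, time, event, ties="breslow"):
    """Log partial likelihood at ``beta`` (for tests and step control)."""
    ll, _, _ = _loglik_derivs(np.asarray(beta, float), np.asarray(X, float),
                              np.asarray(time, float), np.asarray(event, int),
                              ties, want_derivs=False)
    return ll


def _loglik_derivs(beta, X, time, event, ties, want_derivs=True):
    n, p = X.shape
    order, t_sorted, e_sorted, event_times, risk_ends = _risk_set_layout(time, event)
    Xs = X[order]
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = w[:, None] * Xs
    cw = np.cumsum(w)
    cwX = np.cumsum(wX, axis=0)
    if want_derivs:
        wXX = wX[:, :, None] * Xs[:, None, :]
        cwXX = np.cumsum(wXX, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for t, end in zip(event_times, risk_ends):
        in_time = t_sorted[:end] == t
        deaths = in_time & (e_sorted[:end] == 1)
        d = int(deaths.sum())
        s = Xs[:end][deaths].sum(axis=0)
        ll += float(s @ beta)
        S0 = cw[end - 1]
        S1 = cwX[end - 1]
        S2 = cwXX[end - 1] if want_derivs else None
        if ties == "efron" and d > 1:
            w_d = w[:end][deaths]
            s0d = w_d.sum()
            s1d = wX[:end][deaths].sum(axis=0)
            s2d = wXX[:end][deaths].sum(axis=0) if want_derivs else None
            for l in range(d):
                f = l / d
                a0 = S0 - f * s0d
                ll -= np.log(a0)
                if want_derivs:
                    a1 = S1 - f * s1d
                    a2 = S2 - f * s2d
                    m = a1 / a0
                    grad -= m
                    info += a2 / a0 - np.outer(m, m)
        else:
            ll -= d * np.log(S0)
            if want_derivs:
                m = S1 / S0
                grad -= d * m
                info += d * (S2 / S0 - np.outer(m, m))
    if want_derivs:
        # grad currently holds only the risk-set part; add the event part
        for t, end in zip(event_times, risk_ends):
            deaths = (t_sorted[:end] == t) & (e_sorted[:end] == 1)
            grad += Xs[:end][deaths].sum(axis=0)
    return ll, grad, info


class CoxResult:
    """Container for a fitted multivariate Cox model."""

    def __init__(self, terms, coef, cov, loglik, n, n_events, converged, ties):
        self.terms = list(terms)
        self.coef = pd.Series(coef, index=self.terms, name="coef")
        self.cov = pd.DataFrame(cov, index=self.terms, columns=self.terms)
        self.loglik = loglik
        self.n = n
        self.n_events = n_events
        self.converged = converged
        self.ties = ties

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.terms, name="se")

    def table(self) -> pd.DataFrame:
        """Per-term coefficient table: Coef, HR, 95% CI bounds, Wald p."""
        coef = self.coef.to_numpy()
        se = self.se.to_numpy()
        hr = np.exp(coef)
        lo = np.exp(coef - Z975 * se)
        hi = np.exp(coef + Z975 * se)
        p = 2.0 * stats.norm.sf(np.abs(coef) / se)
        return pd.DataFrame(
            {"Coef": coef, "HR": hr, "HR.95L": lo, "HR.95H": hi, "p value": p},
            index=pd.Index(self.terms, name="Id"))


def _check_collinear(X: pd.DataFrame):
    arr = X.to_numpy(float)
    centered = arr - arr.mean(axis=0)
    const = [c for c, s in zip(X.columns, centered.std(axis=0)) if s == 0]
    if const:
        raise ValueError(f"constant covariates cannot be fit: {const}")
    rank = np.linalg.matrix_rank(centered)
    if rank < X.shape[1]:
        # name an offending dependent subset via QR pivoting
        _, r = np.linalg.qr(centered)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"collinear covariates: {bad or list(X.columns)}")


def cox_fit(X: pd.DataFrame, time, event, ties: str = "breslow",
            tol: float = 1e-9, max_iter: int = 100) -> CoxResult:
    """Multivariate Cox fit; ``X`` is samples x covariates.

    Raises on no events or collinear covariates; warns (and returns the
    last iterate) if Newton-Raphson fails to converge.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < 1:
        raise ValueError("no events: Cox partial likelihood is undefined")
    if (time < 0).any():
        raise ValueError("negative survival time")
    _check_collinear(X)
    arr = X.to_numpy(float)
    n, p = arr.shape
    beta = np.zeros(p)
    ll, grad, info = _loglik_derivs(beta, arr, time, event, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving keeps the partial likelihood monotone
        new_beta = beta + step
        new_ll, new_grad, new_info = _loglik_derivs(new_beta, arr, time, event, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_info = _loglik_derivs(new_beta, arr, time, event, ties)
            halvings += 1
        delta = np.max(np.abs(new_beta - beta))
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("Cox fit did not converge within max_iter",
                      ConvergenceWarning)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return CoxResult(X.columns, beta, cov, ll, n, int(event.sum()), converged, ties)


def unicox_scan(indicators: pd.DataFrame, time, event, ties: str = "breslow",
                tol: float = 1e-9, max_iter: int = 100) -> pd.DataFrame:
    """Univariate Cox fit of each binary 0/1 row of ``indicators``.

    Returns a Table-1-style DataFrame (Coef, HR, CI, p) indexed by pair id.
    Constant and non-converging rows are dropped with a warning. Only the
    Breslow tie convention is available on this fast path; Efron requests
    fall back to per-pair :func:`cox_fit`.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if event.sum() < 2:
        raise ValueError("univariate Cox screen needs >= 2 events")

    frac = indicators.mean(axis=1)
    const = (frac == 0) | (frac == 1)
    if const.any():
        logger.warning("%d constant pairs dropped from uniCox screen",
                       int(const.sum()))
    mat = indicators.loc[~const]
    if ties == "efron":
        rows = []
        for pid in mat.index:
            X = mat.loc[[pid]].T.astype(float)
            res = cox_fit(X, time, event, ties="efron", tol=tol, max_iter=max_iter)
            rows.append(res.table())
        return pd.concat(rows) if rows else pd.DataFrame(columns=MODEL_COLUMNS)

    I = mat.to_numpy(np.float64)  # P x n
    P, n = I.shape
    order, t_sorted, e_sorted, event_times, risk_ends = _risk_set_layout(time, event)
    Is = I[:, order]
    cum1 = np.cumsum(Is, axis=1)  # running count of x=1 in the risk-set prefix
    n1r = cum1[:, risk_ends - 1]            # P x J: x=1 members of each risk set
    nr = risk_ends.astype(float)            # J: risk-set sizes
    # events at each distinct event time: total and with x=1
    J = len(event_times)
    d = np.zeros(J)
    d1 = np.zeros((P, J))
    for j, (t, end) in enumerate(zip(event_times, risk_ends)):
        deaths = (t_sorted[:end] == t) & (e_sorted[:end] == 1)
        d[j] = deaths.sum()
        d1[:, j] = Is[:, :end][:, deaths].sum(axis=1)

    beta = np.zeros(P)
    active = np.ones(P, bool)
    for _ in range(max_iter):
        eb = np.exp(beta)[:, None]
        S0 = (nr[None, :] - n1r) + eb * n1r
        mu = eb * n1r / S0                      # E[x | risk set]
        grad = (d1 - d[None, :] * mu).sum(axis=1)
        info = (d[None, :] * mu * (1.0 - mu)).sum(axis=1)
        ok = info > 1e-12
        step = np.zeros(P)
        step[ok] = grad[ok] / info[ok]
        step = np.clip(step, -2.0, 2.0)  # guard monotone-likelihood blowup
        beta_new = np.where(active, beta + step, beta)
        beta_new = np.clip(beta_new, -30, 30)
        moved = np.abs(beta_new - beta)
        beta = beta_new
        active = moved >= tol
        if not active.any():
            break
    converged = ~active & (np.abs(beta) < 29)
    if (~converged).any():
        logger.warning("%d pairs dropped from uniCox screen (no convergence)",
                       int((~converged).sum()))
    eb = np.exp(beta)[:, None]
    S0 = (nr[None, :] - n1r) + eb * n1r
    mu = eb * n1r / S0
    info = (d[None, :] * mu * (1.0 - mu)).sum(axis=1)
    se = np.full(P, np.nan)
    se[info > 0] = 1.0 / np.sqrt(info[info > 0])
    hr = np.exp(beta)
    out = pd.DataFrame({
        "Coef": beta,
        "HR": hr,
        "HR.95L": np.exp(beta - Z975 * se),
        "HR.95H": np.exp(beta + Z975 * se),
        "p value": 2.0 * stats.norm.sf(np.abs(beta) / se),
    }, index=pd.Index(mat.index, name="Id"))
    return out.loc[converged & np.isfinite(se)]
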