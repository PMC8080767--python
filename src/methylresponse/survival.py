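"""Kaplan-Meier estimation, log-rank testing and Cox proportional hazards.

These are written to the package's fixed conventions — product-limit
estimator with the median as the first event time where S(t) drops to 0.5
or below (reported missing when never reached), the two-group log-rank
statistic with the hypergeometric variance, and a Newton-Raphson fit of
the Breslow partial likelihood with Wald confidence intervals — and are
cross-checked against an independent survival library in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SurvivalCurve", "CoxFit", "km_estimate", "logrank_test", "cox_fit"]


@dataclass
class SurvivalCurve:
    """Product-limit estimate over distinct event times.

    ``table`` has one row per distinct event time with columns
    ``time, at_risk, events, survival``; ``median`` is None when the curve
    never reaches 0.5.
    """

    table: pd.DataFrame
    median: float | None
    n: int

    def survival_at(self, t: float) -> float:
        tab = self.table
        past = tab[tab["time"] <= t]
        return float(past["survival"].iloc[-1]) if len(past) else 1.0


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` are 1 for an observed event and 0 for right-censoring;
    censored-only times enter through the risk sets only.  With no
    censoring the estimate equals the empirical survival function.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not len(t):
        raise ValueError("empty input")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    rows = []
    s = 1.0
    median = None
    for et in event_times:
        at_risk = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append({"time": et, "at_risk": at_risk, "events": d, "survival": s})
        if median is None and s <= 0.5:
            median = float(et)
    table = pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])
    return SurvivalCurve(table=table, median=median, n=len(t))


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p).

    Observed-minus-expected events in group 1 are accumulated over the
    shared risk sets at each distinct event time, with the usual
    hypergeometric variance.  A group with no events still contributes
    through its risk sets.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    in1 = g == labels[1]

    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t[e == 1]):
        at_risk = t >= et
        n = int(at_risk.sum())
        n1 = int((at_risk & in1).sum())
        d = int(((t == et) & (e == 1)).sum())
        d1 = int(((t == et) & (e == 1) & in1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model (Breslow ties).

    ``summary`` has one row per covariate: ``coef, se, hr, hr_lo, hr_hi,
    p`` (Wald, 95% CI).  ``converged`` is False on non-convergence or a
    monotone likelihood; such fits carry no silent estimates — the caller
    must check the flag.
    """

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool
    n: int
    n_events: int


def _cox_loglik(beta, t, e, X):
    """Breslow log partial likelihood with gradient and Hessian."""
    eta = X @ beta
    w = np.exp(eta)
    ll, grad, hess = 0.0, np.zeros(X.shape[1]), np.zeros((X.shape[1],) * 2)
    for et in np.unique(t[e == 1]):
        risk = t >= et
        d_idx = (t == et) & (e == 1)
        d = int(d_idx.sum())
        s0 = w[risk].sum()
        s1 = X[risk].T @ w[risk]
        s2 = (X[risk].T * w[risk]) @ X[risk]
        ll += eta[d_idx].sum() - d * np.log(s0)
        grad += X[d_idx].sum(axis=0) - d * s1 / s0
        hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
    return ll, grad, hess


def cox_fit(
    times, events, covariates: pd.DataFrame, tol: float = 1e-8, max_iter: int = 50
) -> CoxFit:
    """Newton-Raphson maximization of the Breslow partial likelihood.

    Convergence requires the max absolute coefficient change to fall below
    ``tol`` within ``max_iter`` iterations; runaway coefficients (monotone
    likelihood under perfect separation) mark the fit unconverged.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    X = covariates.to_numpy(dtype=float)
    names = list(covariates.columns)
    if any(np.ptp(X[:, j]) == 0 for j in range(X.shape[1])):
        raise ValueError("constant covariate")
    n_events = int(e.sum())
    if n_events < X.shape[1]:
        raise ValueError("fewer events than covariates")
    # center for numerical stability; partial likelihood is shift-invariant
    X = X - X.mean(axis=0)

    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik(beta, t, e, X)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta_new = beta - step
        if np.abs(beta_new).max() > 50:  # monotone likelihood guard
            beta = beta_new
            break
        if np.abs(beta_new - beta).max() < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new

    ll, grad, hess = _cox_loglik(beta, t, e, X)
    with np.errstate(invalid="ignore"):
        cov = np.linalg.inv(-hess) if converged else np.full(hess.shape, np.nan)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    summary = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "hr_lo": np.exp(beta - 1.96 * se),
            "hr_hi": np.exp(beta + 1.96 * se),
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        },
        index=names,
    )
    return CoxFit(
        summary=summary,
        log_likelihood=float(ll),
        converged=converged,
        n=len(t),
        n_events=n_events,
    )
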