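"""Survival and proportion inference, implemented from first principles.

Kaplan-Meier product-limit curves, the (k-group) log-rank test, Cox
proportional-hazards regression with Efron or Breslow tie handling, Pearson
chi-squared tests on contingency tables, and exact (Clopper-Pearson) binomial
confidence intervals. Only scipy distribution functions (chi2, beta, normal
quantiles) are used; all estimators and test statistics are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray  # distinct times with >=1 event, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray = field(default=None)  # Greenwood variance of S(t)
    n_total: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function value S(t), last value carried forward; S=1 before
        the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def median(self) -> Optional[float]:
        """Smallest event time with S(t) <= 0.5, or None if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        if below.size == 0:
            return None
        return float(self.event_times[below[0]])

    def survival_at_ci(self, t: float, level: float = 0.95) -> tuple[float, float, float]:
        """(S(t), lower, upper) with a Greenwood log(-log) interval."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0, 1.0
        s = float(self.survival[idx])
        if s <= 0.0 or s >= 1.0:
            return s, s, s
        # var of S; transform to the log(-log S) scale
        var = float(self.variance[idx])
        se_loglog = math.sqrt(var) / (abs(s * math.log(s)))
        z = sps.norm.ppf(0.5 + level / 2)
        lo = s ** math.exp(z * se_loglog)
        hi = s ** math.exp(-z * se_loglog)
        return s, lo, hi


def km_fit(durations: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are counted in the risk set at that
    time (the standard convention).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != e.shape:
        raise ValueError("durations and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("durations must be positive")

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = t.size

    at_risk = np.empty(event_times.size, dtype=int)
    d = np.empty(event_times.size, dtype=int)
    for i, tt in enumerate(event_times):
        at_risk[i] = int(np.sum(t >= tt))
        d[i] = int(np.sum((t == tt) & e))

    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d / at_risk
    survival = np.cumprod(factors)
    # Greenwood: var(S) = S^2 * cumsum(d / (r (r - d)))
    denom = at_risk * (at_risk - d)
    terms = np.where(denom > 0, d / np.where(denom > 0, denom, 1), np.inf)
    with np.errstate(invalid="ignore"):
        variance = survival**2 * np.cumsum(terms)
    variance = np.where(np.isfinite(variance), variance, 0.0)
    return SurvivalCurve(
        event_times=event_times,
        n_at_risk=at_risk,
        n_events=d,
        survival=survival,
        variance=variance,
        n_total=n,
    )


def logrank(*groups: tuple[Sequence[float], Sequence[bool]]) -> TestResult:
    """Log-rank test for k >= 2 groups (df = k - 1).

    Uses the observed-minus-expected statistic with the hypergeometric
    variance/covariance at each distinct event time; two-sided p-value from
    the chi-squared distribution.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ts, es, gs = [], [], []
    for gi, (dur, ev) in enumerate(groups):
        dur = np.asarray(dur, dtype=float)
        ev = np.asarray(ev, dtype=bool)
        if dur.size == 0:
            raise ValueError(f"group {gi} has zero subjects")
        ts.append(dur)
        es.append(ev)
        gs.append(np.full(dur.size, gi))
    t = np.concatenate(ts)
    e = np.concatenate(es)
    g = np.concatenate(gs)
    if not e.any():
        raise ValueError("no events in any group")

    k = len(groups)
    event_times = np.unique(t[e])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for tt in event_times:
        at_risk_mask = t >= tt
        n_risk = np.array([np.sum(at_risk_mask & (g == j)) for j in range(k)], float)
        d_j = np.array([np.sum((t == tt) & e & (g == j)) for j in range(k)], float)
        big_n = n_risk.sum()
        big_d = d_j.sum()
        if big_n <= 1:
            continue
        observed += d_j
        expected += big_d * n_risk / big_n
        frac = n_risk / big_n
        hyper = big_d * (big_n - big_d) / (big_n - 1)
        cov += hyper * (np.diag(frac) - np.outer(frac, frac))

    diff = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    df = k - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, p_value=p)


@dataclass
class CoxFit:
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    ties: str
    log_likelihood: float
    n_iterations: int
    separation_flag: bool = False
    covariate_names: Optional[list[str]] = None

    def confidence_intervals(self, level: float = 0.95) -> np.ndarray:
        z = sps.norm.ppf(0.5 + level / 2)
        lo = self.coefficients - z * self.standard_errors
        hi = self.coefficients + z * self.standard_errors
        return np.column_stack([lo, hi])


def _cox_loglik_grad_hess(
    beta: np.ndarray,
    x_sorted: np.ndarray,
    event_groups: list[tuple[int, np.ndarray]],
    ties: str,
):
    """Partial log-likelihood, gradient, Hessian for data sorted by
    descending time. ``event_groups`` lists (risk_set_size, tied_event_rows)
    per distinct event time, where risk_set_size counts the leading rows of
    ``x_sorted`` at risk.
    """
    n, p = x_sorted.shape
    eta = x_sorted @ beta
    # clip to keep exp finite under separation; separation is flagged upstream
    w = np.exp(np.clip(eta, -500, 500))
    wx = w[:, None] * x_sorted
    wxx = np.einsum("i,ij,ik->ijk", w, x_sorted, x_sorted)

    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for r_size, rows in event_groups:
        d = rows.size
        s0 = cw[r_size - 1]
        s1 = cwx[r_size - 1]
        s2 = cwxx[r_size - 1]
        xd = x_sorted[rows]
        ll += float(eta[rows].sum())
        if ties == "breslow" or d == 1:
            ll -= d * math.log(s0)
            grad += xd.sum(axis=0) - d * s1 / s0
            hess -= d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        elif ties == "efron":
            wd = w[rows].sum()
            wdx = wx[rows].sum(axis=0)
            wdxx = wxx[rows].sum(axis=0)
            grad += xd.sum(axis=0)
            for ell in range(d):
                c = ell / d
                a0 = s0 - c * wd
                a1 = s1 - c * wdx
                a2 = s2 - c * wdxx
                ll -= math.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return ll, grad, hess


def cox_fit(
    durations: Sequence[float],
    events: Sequence[bool],
    covariates,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
    covariate_names: Optional[list[str]] = None,
) -> CoxFit:
    """Cox proportional-hazards regression by Newton-Raphson maximization of
    the partial likelihood. Default tie handling is Efron; convergence when
    the log-partial-likelihood change falls below ``tol`` (or ``max_iter``).
    Non-convergence and apparent separation are flagged, never silent.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != t.size:
        x = x.T
    if x.shape[0] != t.size:
        raise ValueError("covariate matrix does not match durations")
    if not e.any():
        raise ValueError("no events")
    constant = np.all(x == x[0, :], axis=0)
    if constant.any():
        raise ValueError("covariate constant across all subjects")

    # sort by descending time so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="stable")
    t_s, e_s, x_s = t[order], e[order], x[order]

    event_groups: list[tuple[int, np.ndarray]] = []
    for tt in np.unique(t_s[e_s]):
        rows = np.nonzero((t_s == tt) & e_s)[0]
        r_size = int(np.sum(t_s >= tt))
        event_groups.append((r_size, rows))
    event_groups.sort(key=lambda it: it[0])

    p = x.shape[1]
    beta = np.zeros(p)
    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, grad, hess = _cox_loglik_grad_hess(beta, x_s, event_groups, ties)
        if abs(ll - ll_old) < tol and n_iter > 1:
            converged = True
            break
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        new_beta = beta - step
        new_ll = _cox_loglik_grad_hess(new_beta, x_s, event_groups, ties)[0]
        halvings = 0
        while new_ll < ll and halvings < 20:
            step = step / 2
            new_beta = beta - step
            new_ll = _cox_loglik_grad_hess(new_beta, x_s, event_groups, ties)[0]
            halvings += 1
        beta = new_beta
        ll_old = ll

    ll, grad, hess = _cox_loglik_grad_hess(beta, x_s, event_groups, ties)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    separation = bool(np.any(np.abs(beta) > 15))
    if separation:
        converged = False
    return CoxFit(
        coefficients=beta,
        hazard_ratios=np.exp(beta),
        standard_errors=se,
        converged=converged,
        ties=ties,
        log_likelihood=float(ll),
        n_iterations=n_iter,
        separation_flag=separation,
        covariate_names=list(covariate_names) if covariate_names else None,
    )


def chisq_prop(table) -> TestResult:
    """Pearson chi-squared test on an r x c count table (no continuity
    correction)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal in table")
    expected = np.outer(row, col) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, p_value=p)


def exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval via beta quantiles."""
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n and n > 0")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1 - level
    lower = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper
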