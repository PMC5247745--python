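"""Survival-analysis machinery written from first principles.

Product-limit (Kaplan-Meier) estimation with Greenwood variance,
cumulative incidence, the two-group log-rank test, and univariate Cox
proportional-hazards regression with Efron handling of ties.  All
routines operate on plain arrays of follow-up times and 0/1 event
indicators; at tied times, censoring is taken to occur after events.

Cox fitting maximises the partial likelihood by Newton's method with
step-halving, capped at 50 iterations, declaring convergence when the
update falls below 1e-9.  Monotone likelihoods (complete separation)
are detected and flagged rather than reported as converged estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested estimate."""


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if t.size == 0:
        raise DegenerateDataError("empty input")
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    return t, e


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate on the grid of distinct observed times.

    ``survival`` drops only at event times; ``greenwood_var`` is the
    Greenwood variance of the survival estimate at each grid time.
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first observed time."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def variance_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_var[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "se": np.sqrt(self.greenwood_var),
            }
        )


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    The grid contains every distinct observed time (event or censoring);
    S(t) = prod_{t_j <= t} (1 - d_j / n_j).
    """
    t, e = _as_arrays(times, events)
    grid = np.unique(t)
    n_at_risk = np.array([(t >= u).sum() for u in grid])
    d = np.array([((t == u) & e).sum() for u in grid])
    frac = np.where(n_at_risk > 0, d / n_at_risk, 0.0)
    surv = np.cumprod(1.0 - frac)
    # Greenwood: Var[S] = S^2 * sum d / (n (n - d)); terms where S has
    # already hit zero contribute nothing meaningful -> variance 0 there.
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
    var = surv**2 * np.cumsum(terms)
    var = np.where(surv > 0, var, 0.0)
    return SurvivalCurve(grid, n_at_risk, d, surv, var)


@dataclass(frozen=True)
class CumulativeIncidence:
    """1 - S(t) with a Greenwood-based normal-scale 95% CI."""

    estimate: float
    ci95: tuple[float, float]
    extrapolated: bool


def cumulative_incidence(curve: SurvivalCurve, t: float) -> CumulativeIncidence:
    """Cumulative incidence 1 - S(t) with its 95% confidence interval.

    Beyond the last observed time the last value is returned, flagged as
    extrapolated.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    extrapolated = t > float(curve.event_times[-1])
    tq = min(t, float(curve.event_times[-1]))
    est = 1.0 - curve.survival_at(tq)
    se = float(np.sqrt(curve.variance_at(tq)))
    z = stats.norm.ppf(0.975)
    lo, hi = max(0.0, est - z * se), min(1.0, est + z * se)
    return CumulativeIncidence(est, (lo, hi), extrapolated)


@dataclass(frozen=True)
class LogRankResult:
    """Two-group log-rank test (chi-square, 1 df).

    ``observed`` / ``expected`` are per-group event tallies; the signed
    square root of the statistic carries the sign of (O - E) in the
    first group (positive when group A has more events than expected).
    """

    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def log_rank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Standard two-group log-rank test with hypergeometric variance."""
    ta, ea = _as_arrays(times_a, events_a)
    tb, eb = _as_arrays(times_b, events_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, bool), np.ones(tb.size, bool)])

    event_times = np.unique(t[e])
    o_a = e_a = v = 0.0
    for u in event_times:
        at_risk = t >= u
        n = at_risk.sum()
        n_a = (at_risk & ~g).sum()
        d = ((t == u) & e).sum()
        d_a = ((t == u) & e & ~g).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    o_b = float(e[g].sum())
    e_b = float(e.sum()) - e_a
    if v == 0.0:
        stat = 0.0
    else:
        stat = (o_a - e_a) ** 2 / v
    p = float(stats.chi2.sf(stat, df=1)) if v > 0 else 1.0
    return LogRankResult(float(stat), p, (float(o_a), o_b), (float(e_a), float(e_b)))


@dataclass(frozen=True)
class CoxFit:
    """Univariate Cox proportional-hazards fit (Wald inference)."""

    beta: float
    hr: float
    ci95: tuple[float, float]
    se: float
    p_value: float
    converged: bool = True
    n_events: int = 0
    score_chi2: float = float("nan")
    boundary_direction: int = 0


def _efron_quantities(beta: float, x, t, e):
    """Efron partial log-likelihood, gradient and information (scalar beta).

    Arrays must be sorted by descending time so risk-set sums are prefix
    sums.  Returns (loglik, gradient, information).
    """
    r = np.exp(beta * x)
    cum_r = np.cumsum(r)
    cum_xr = np.cumsum(x * r)
    cum_x2r = np.cumsum(x * x * r)

    # distinct event times and their tied-event groups (descending order)
    is_event = e
    loglik = grad = info = 0.0
    # indices of last occurrence of each distinct time in the descending array
    # risk set for time u = all entries with time >= u = prefix ending at the
    # last index whose time equals u
    uniq, last_idx = _unique_last(t)
    for u, li in zip(uniq, last_idx):
        mask = (t == u) & is_event
        d = int(mask.sum())
        if d == 0:
            continue
        s_r = cum_r[li]
        s_xr = cum_xr[li]
        s_x2r = cum_x2r[li]
        rd = r[mask]
        xd = x[mask]
        sd_r = rd.sum()
        sd_xr = (xd * rd).sum()
        sd_x2r = (xd * xd * rd).sum()
        frac = np.arange(d) / d
        denom = s_r - frac * sd_r
        num1 = s_xr - frac * sd_xr
        num2 = s_x2r - frac * sd_x2r
        loglik += beta * xd.sum() - np.log(denom).sum()
        grad += xd.sum() - (num1 / denom).sum()
        info += (num2 / denom - (num1 / denom) ** 2).sum()
    return loglik, grad, info


def _unique_last(t_desc: np.ndarray):
    """Distinct values of a descending-sorted array with last-index of each."""
    uniq, first = np.unique(t_desc[::-1], return_index=True)
    # first-index in the ascending reversed array -> last index in descending
    last = t_desc.size - 1 - first
    return uniq[::-1], last[::-1]


def cox_univariate(covariate, times, events, *, max_iter: int = 50,
                   tol: float = 1e-9) -> CoxFit:
    """Fit a one-covariate Cox model by Newton's method (Efron ties).

    Raises :class:`DegenerateDataError` when there are no events or the
    covariate is constant.  A monotone partial likelihood (complete
    separation) yields ``converged=False`` with ``boundary_direction``
    giving the sign towards which the estimate diverges.
    """
    t, e = _as_arrays(times, events)
    x = np.asarray(covariate, dtype=float)
    if x.shape != t.shape:
        raise ValueError("covariate length mismatch")
    n_events = int(e.sum())
    if n_events == 0:
        raise DegenerateDataError("no events")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant covariate")

    # centre the covariate: shifts multiply the baseline hazard only
    xc = x - x.mean()
    order = np.argsort(-t, kind="stable")
    xs, ts, es = xc[order], t[order], e[order]

    ll0, g0, i0 = _efron_quantities(0.0, xs, ts, es)
    score_chi2 = g0**2 / i0 if i0 > 0 else float("nan")

    beta, ll, g, info = 0.0, ll0, g0, i0
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = g / info
        new_beta = beta + step
        new_ll, new_g, new_info = _efron_quantities(new_beta, xs, ts, es)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_g, new_info = _efron_quantities(new_beta, xs, ts, es)
            halvings += 1
        delta = new_beta - beta
        beta, ll, g, info = new_beta, new_ll, new_g, new_info
        if abs(delta) < tol:
            converged = True
            break
        if abs(beta) > 25:  # hazard ratio beyond e^25: monotone likelihood
            break

    boundary = 0
    if not converged or abs(beta) > 25 or info <= 0:
        converged = False
        boundary = int(np.sign(beta if beta != 0 else g0))
        se = float("inf")
        return CoxFit(
            beta=float(beta), hr=float(np.exp(np.clip(beta, -700, 700))),
            ci95=(0.0, float("inf")), se=se, p_value=float("nan"),
            converged=False, n_events=n_events, score_chi2=float(score_chi2),
            boundary_direction=boundary,
        )

    se = float(1.0 / np.sqrt(info))
    z = stats.norm.ppf(0.975)
    ci = (float(np.exp(beta - z * se)), float(np.exp(beta + z * se)))
    p = float(2 * stats.norm.sf(abs(beta) / se))
    return CoxFit(
        beta=float(beta), hr=float(np.exp(beta)), ci95=ci, se=se, p_value=p,
        converged=True, n_events=n_events, score_chi2=float(score_chi2),
        boundary_direction=0,
    )
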