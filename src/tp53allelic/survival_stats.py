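"""Self-contained survival estimators and association tests.

Everything here operates on plain arrays: event/censoring times in months,
boolean event indicators (True = death observed), and arbitrary numeric
risk scores or covariates.  The estimators are deliberately small and
explicit — product-limit survival, the k-sample log-rank test, Harrell's
concordance, a univariate Cox fit with Breslow tie handling, and the 2x2
odds ratio — because the cutoff search calls them in tight loops and the
test suite checks each against an independent implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "TestResult",
    "CoxResult",
    "OddsRatioResult",
    "ConvergenceError",
    "km_estimate",
    "median_survival",
    "logrank",
    "logrank_2sample_stat",
    "harrell_c",
    "cox_univariate",
    "odds_ratio",
]


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximisation failed; carries the last iterate."""

    def __init__(self, message: str, last_beta: float):
        super().__init__(message)
        self.last_beta = last_beta


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; ``at_risk[i]``
    counts subjects at risk at that time.  ``median`` is the smallest event
    time with S <= 0.5, or None when survival never falls that far.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: Optional[float]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit: hazard ratio with a Wald 95% CI."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    coef: float
    se: float
    n_iter: int


@dataclass(frozen=True)
class OddsRatioResult:
    """Cross-product odds ratio with a Woolf (log-scale) 95% CI.

    ``corrected`` marks the Haldane–Anscombe 0.5 continuity correction
    (applied when any cell is zero); ``unstable`` marks a zero row or
    column, where the OR is not identified.
    """

    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool
    unstable: bool


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("times must be non-negative and finite")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    With no censoring this reduces exactly to one minus the empirical CDF
    of the event times.
    """
    t, e = _as_arrays(times, events)
    event_times = np.unique(t[e])
    if event_times.size == 0:
        return SurvivalCurve(
            event_times=event_times,
            survival=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
            median=None,
        )
    # at risk at time u: subjects with t >= u; deaths at u: events with t == u
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    deaths = np.array([((t == u) & e).sum() for u in event_times], dtype=int)
    surv = np.cumprod(1.0 - deaths / at_risk)
    median = median_survival(event_times, surv)
    return SurvivalCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=deaths,
        median=median,
    )


def median_survival(event_times: np.ndarray, survival: np.ndarray) -> Optional[float]:
    """Smallest event time with survival <= 0.5, or None if never reached."""
    below = np.nonzero(survival <= 0.5)[0]
    if below.size == 0:
        return None
    return float(event_times[below[0]])


def logrank(times, events, groups) -> TestResult:
    """k-sample log-rank test with a chi-square reference (df = k - 1).

    Observed-minus-expected death counts are accumulated over the pooled
    risk sets; the statistic is the quadratic form in the first k-1 groups
    against the hypergeometric covariance.  Every group must be non-empty.
    """
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    if g.shape != t.shape:
        raise ValueError("groups must have the same length as times")
    labels, g_idx = np.unique(g, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    counts = np.bincount(g_idx, minlength=k)
    if np.any(counts == 0):
        raise ValueError("every group must contain at least one subject")

    event_times = np.unique(t[e])
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for u in event_times:
        at_risk_mask = t >= u
        n = at_risk_mask.sum()
        nj = np.bincount(g_idx[at_risk_mask], minlength=k).astype(float)
        death_mask = (t == u) & e
        d = death_mask.sum()
        dj = np.bincount(g_idx[death_mask], minlength=k).astype(float)
        observed += dj
        expected += d * nj / n
        if n > 1:
            p = nj / n
            cov += d * (n - d) / (n - 1) * (np.diag(p) - np.outer(p, p))

    diff = (observed - expected)[: k - 1]
    v = cov[: k - 1, : k - 1]
    stat = float(diff @ np.linalg.pinv(v) @ diff)
    stat = max(stat, 0.0)
    return TestResult(statistic=stat, df=k - 1, p_value=float(stats.chi2.sf(stat, k - 1)))


def logrank_2sample_stat(times, events, in_group: np.ndarray) -> float:
    """Two-sample log-rank chi-square via the scalar U^2/V form.

    Fast path used by the split search; ``in_group`` is a boolean mask for
    one of the two arms.  Returns 0 when the variance vanishes (e.g. all
    deaths at one time with a single subject at risk).
    """
    t, e = _as_arrays(times, events)
    mask = np.asarray(in_group, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e, mask = t[order], e[order], mask[order]
    n_total = t.size

    # walk distinct times once; risk sets shrink as time advances
    u = 0.0
    v = 0.0
    i = 0
    n = n_total
    n1 = int(mask.sum())
    while i < n_total:
        j = i
        d = 0
        d1 = 0
        while j < n_total and t[j] == t[i]:
            if e[j]:
                d += 1
                d1 += int(mask[j])
            j += 1
        if d > 0:
            u += d1 - d * n1 / n
            if n > 1:
                v += d * (n - d) * n1 * (n - n1) / (n * n * (n - 1))
        # remove all subjects with this time from the risk set
        n -= j - i
        n1 -= int(mask[i:j].sum())
        i = j
    if v <= 0.0:
        return 0.0
    return u * u / v


def harrell_c(times, events, risk_scores) -> float:
    """Harrell's concordance index for censored survival data.

    A pair is comparable when the two times differ and the subject with
    the smaller time had an observed event.  The pair is concordant when
    that shorter-lived subject carries the *higher* risk score; tied risk
    scores count 0.5.  Raises when no pair is comparable.
    """
    t, e = _as_arrays(times, events)
    s = np.asarray(risk_scores, dtype=float)
    if s.shape != t.shape:
        raise ValueError("risk_scores must have the same length as times")
    if t.size < 2:
        raise ValueError("concordance needs at least 2 subjects")

    # pair (i, j) with t_i < t_j and event_i
    ti = t[:, None]
    tj = t[None, :]
    comparable = (ti < tj) & e[:, None]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs: concordance undefined")
    si = s[:, None]
    sj = s[None, :]
    concordant = int((comparable & (si > sj)).sum())
    tied = int((comparable & (si == sj)).sum())
    return (concordant + 0.5 * tied) / n_comp


def cox_univariate(
    times, events, x, max_iter: int = 100, tol: float = 1e-9
) -> CoxResult:
    """Single-covariate Cox proportional-hazards fit.

    Maximises the Breslow partial likelihood by Newton–Raphson from
    beta = 0 and reports the hazard ratio exp(beta) with a Wald 95% CI.
    A constant covariate carries no information and is rejected.
    """
    t, e = _as_arrays(times, events)
    xv = np.asarray(x, dtype=float)
    if xv.shape != t.shape:
        raise ValueError("covariate must have the same length as times")
    if np.ptp(xv) == 0.0:
        raise ValueError("degenerate covariate: no variation")
    if not e.any():
        raise ValueError("no events: partial likelihood is empty")

    # sort descending so risk sets are cumulative prefixes
    order = np.argsort(-t, kind="stable")
    ts, es, xs = t[order], e[order], xv[order]

    # Breslow: tied deaths share the full risk set at their time
    def score_info(beta: float) -> tuple[float, float]:
        w = np.exp(beta * xs)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * xs)
        s2 = np.cumsum(w * xs * xs)
        # risk set for a death at time u is everyone with time >= u,
        # ties included; ts is non-increasing, so that is the prefix up to
        # the rightmost subject sharing the same time
        idx = np.searchsorted(-ts, -ts, side="right") - 1
        score = float(np.sum((xs - s1[idx] / s0[idx])[es]))
        info = float(np.sum((s2[idx] / s0[idx] - (s1[idx] / s0[idx]) ** 2)[es]))
        return score, info

    beta = 0.0
    for it in range(1, max_iter + 1):
        score, info = score_info(beta)
        if info <= 0:
            raise ConvergenceError("non-positive information", beta)
        step = score / info
        beta += step
        if abs(step) < tol:
            se = 1.0 / np.sqrt(info)
            z = stats.norm.ppf(0.975)
            return CoxResult(
                hazard_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - z * se)),
                ci_high=float(np.exp(beta + z * se)),
                coef=float(beta),
                se=float(se),
                n_iter=it,
            )
    raise ConvergenceError(f"no convergence after {max_iter} iterations", beta)


def odds_ratio(table) -> OddsRatioResult:
    """Odds ratio of a 2x2 count table [[a, b], [c, d]].

    Returns the cross-product ratio a*d / (b*c) with a Woolf log-scale 95%
    CI.  When any cell is zero the Haldane–Anscombe correction (add 0.5 to
    every cell) is applied; a zero row or column leaves the OR
    unidentified and the result is flagged unstable.
    """
    m = np.asarray(table, dtype=float)
    if m.shape != (2, 2):
        raise ValueError("odds_ratio expects a 2x2 table")
    if np.any(m < 0) or np.any(m != np.floor(m)):
        raise ValueError("table must hold non-negative integer counts")
    unstable = bool(np.any(m.sum(axis=0) == 0) or np.any(m.sum(axis=1) == 0))
    corrected = bool(np.any(m == 0))
    mm = m + 0.5 if corrected else m
    a, b = mm[0]
    c, d = mm[1]
    or_ = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = stats.norm.ppf(0.975)
    log_or = np.log(or_)
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        corrected=corrected,
        unstable=unstable,
    )
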