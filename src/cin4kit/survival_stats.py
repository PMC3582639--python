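"""Survival and association statistics for cohort reporting.

Implements the product-limit (Kaplan-Meier) estimator with Greenwood
standard errors and restricted mean survival time, the two-group log-rank
test, Cox proportional-hazards regression by Newton-Raphson with Efron
(default) or Breslow handling of tied event times, an interaction test for
pairs of prognostic scores, and the simple association tests (Pearson
chi-squared, OLS trend) used to relate a continuous tumor score to
clinicopathological variables.

The Cox fitter reports the full model-level summary used in clinical
tables: log likelihood, likelihood-ratio / Wald / score statistics,
Harrell's concordance, and the Cox-Snell style R-squared together with its
attainable maximum, ``1 - exp(2 * LL0 / n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KmCurve",
    "CoxFit",
    "LogrankResult",
    "InteractionResult",
    "TrendResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "cox_interaction_test",
    "chi_square_association",
    "linear_trend",
    "CoxConvergenceError",
]


class CoxConvergenceError(RuntimeError):
    """Raised when the partial-likelihood Newton iteration fails to converge."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    """Product-limit survival curve with Greenwood errors.

    ``times`` holds the distinct event times; ``survival[j]`` is S(t) just
    after ``times[j]``. ``restricted_mean`` is the area under the step curve
    up to ``truncation`` (default: largest observed time).
    """

    times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    restricted_mean: float
    restricted_mean_se: float
    truncation: float
    n: int

    def survival_at(self, t: float) -> float:
        """S(t) from the step function (right-continuous)."""
        j = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if j < 0 else float(self.survival[j])


def _clean_survival(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.shape != event.shape:
        raise ValueError("time and event must be 1-d arrays of equal length")
    if np.any(time < 0) or not np.all(np.isfinite(time)):
        raise ValueError("survival times must be finite and non-negative")
    if not np.all(np.isin(event, [0, 1])):
        raise ValueError("event indicators must be 0 or 1")
    return time, event.astype(int)


def km_estimate(time, event, truncation: float | None = None) -> KmCurve:
    """Kaplan-Meier estimate with Greenwood SE and restricted mean survival.

    The restricted mean is the integral of the step curve from 0 to
    ``truncation``; its standard error uses the usual sum over event times of
    ``A_j^2 d_j / (n_j (n_j - d_j))`` where ``A_j`` is the remaining area
    beyond ``t_j``.
    """
    time, event = _clean_survival(time, event)
    n = time.size
    if n == 0:
        raise ValueError("no records")
    if np.all(time == 0):
        raise ValueError("all survival times are zero")

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]

    event_times = np.unique(t_sorted[e_sorted == 1])
    # counts per distinct event time
    n_at_risk = n - np.searchsorted(t_sorted, event_times, side="left")
    d = np.array(
        [int(np.sum((t_sorted == u) & (e_sorted == 1))) for u in event_times]
    )
    frac = 1.0 - d / n_at_risk
    surv = np.cumprod(frac)

    # Greenwood: Var S(t) = S(t)^2 * sum d/(n(n-d)); skip terms where n == d
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0)
    gw = surv * np.sqrt(np.cumsum(terms))

    if truncation is None:
        truncation = float(t_sorted[-1])
    if truncation <= 0:
        raise ValueError("truncation must be positive")

    # area under the step curve up to the truncation time
    knots = np.concatenate(([0.0], event_times, [np.inf]))
    s_steps = np.concatenate(([1.0], surv))
    rmst = 0.0
    for j in range(len(s_steps)):
        lo, hi = knots[j], min(knots[j + 1], truncation)
        if hi <= lo:
            break
        rmst += s_steps[j] * (hi - lo)

    # SE of the restricted mean (Klein & Moeschberger form):
    # A_j = integral of the post-drop step curve from t_j to truncation
    var = 0.0
    m = len(event_times)
    for j, tj in enumerate(event_times):
        if tj >= truncation or n_at_risk[j] == d[j]:
            continue
        a = 0.0
        for k in range(j, m):
            lo = event_times[k]
            hi = event_times[k + 1] if k + 1 < m else np.inf
            hi = min(hi, truncation)
            if hi > lo:
                a += surv[k] * (hi - lo)
        var += a * a * d[j] / (n_at_risk[j] * (n_at_risk[j] - d[j]))

    return KmCurve(
        times=event_times,
        survival=surv,
        greenwood_se=gw,
        n_at_risk=n_at_risk,
        n_events=d,
        restricted_mean=float(rmst),
        restricted_mean_se=float(np.sqrt(var)),
        truncation=float(truncation),
        n=n,
    )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    observed_a: float
    expected_a: float


def logrank_test(time_a, event_a, time_b, event_b) -> LogrankResult:
    """Two-group log-rank test (observed minus expected over pooled times).

    Uses the hypergeometric variance with the finite-population factor
    ``(n_j - d_j)/(n_j - 1)``; with no tied event times this coincides with
    the Cox partial-likelihood score test for group membership.
    """
    ta, ea = _clean_survival(time_a, event_a)
    tb, eb = _clean_survival(time_b, event_b)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank undefined with zero events")

    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    group = np.concatenate([np.ones(ta.size), np.zeros(tb.size)])

    ut = np.unique(time[event == 1])
    ts_a = np.sort(ta)
    ts_all = np.sort(time)
    n_j = ts_all.size - np.searchsorted(ts_all, ut, side="left")
    n1_j = ts_a.size - np.searchsorted(ts_a, ut, side="left")

    uid = np.searchsorted(ut, time)
    ev = event == 1
    d_j = np.bincount(uid[ev], minlength=ut.size)
    d1_j = np.bincount(uid[ev & (group == 1)], minlength=ut.size)

    obs = d1_j.sum()
    exp = np.sum(d_j * n1_j / n_j)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_j = np.where(
            n_j > 1,
            d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1),
            0.0,
        )
    var = v_j.sum()
    if var <= 0:
        stat = 0.0
    else:
        stat = (obs - exp) ** 2 / var
    return LogrankResult(
        statistic=float(stat),
        p_value=float(stats.chi2.sf(stat, 1)),
        df=1,
        observed_a=float(obs),
        expected_a=float(exp),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    names: list
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    loglik_null: float
    lr_stat: float
    lr_p: float
    wald_stat: float
    wald_p: float
    score_stat: float
    score_p: float
    df: int
    concordance: float
    r2: float
    max_r2: float
    n: int
    n_events: int
    ties: str
    n_iter: int
    flags: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p,
            },
            index=self.names,
        )


def _cox_quantities(beta, X, time, event, ties):
    """Partial log-likelihood, score vector and information matrix.

    Rows must be pre-sorted by ascending time. Risk sets are suffixes of the
    sorted arrays; tied event times are handled per ``ties``.
    """
    n, p = X.shape
    eta = X @ beta
    eta = eta - eta.max()  # stabilize exp; cancels in all ratios
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])

    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    U = np.zeros(p)
    Info = np.zeros((p, p))

    ev_idx = np.flatnonzero(event == 1)
    ut = np.unique(time[ev_idx])
    for u in ut:
        f = np.searchsorted(time, u, side="left")
        D = ev_idx[time[ev_idx] == u]
        d = D.size
        ll += eta[D].sum()
        if ties == "breslow" or d == 1:
            s0, s1, s2 = S0[f], S1[f], S2[f]
            ll -= d * np.log(s0)
            U += X[D].sum(axis=0) - d * s1 / s0
            Info += d * (s2 / s0 - np.outer(s1, s1) / s0**2)
        else:  # efron
            s0d = w[D].sum()
            s1d = wx[D].sum(axis=0)
            s2d = wxx[D].sum(axis=0)
            U += X[D].sum(axis=0)
            for l in range(d):
                c = l / d
                s0 = S0[f] - c * s0d
                s1 = S1[f] - c * s1d
                s2 = S2[f] - c * s2d
                ll -= np.log(s0)
                U -= s1 / s0
                Info += s2 / s0 - np.outer(s1, s1) / s0**2
    return ll, U, Info


def concordance_index(time, event, risk) -> float:
    """Harrell's C: fraction of usable pairs correctly ordered by risk.

    A pair is usable when the shorter observed time carries an event (or,
    at exactly tied times, exactly one member has an event). Tied risk
    scores in a usable pair count one half.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk, float)
    n = time.size
    ti = time[:, None]
    tj = time[None, :]
    ei = event[:, None]
    ej = event[None, :]
    usable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    ri = risk[:, None]
    rj = risk[None, :]
    conc = usable & (ri > rj)
    tied = usable & (ri == rj)
    n_usable = usable.sum()
    if n_usable == 0:
        return float("nan")
    return float((conc.sum() + 0.5 * tied.sum()) / n_usable)


def cox_fit(
    X,
    time,
    event,
    ties: str = "efron",
    names: list | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    alpha: float = 0.05,
) -> CoxFit:
    """Cox proportional-hazards fit by Newton-Raphson.

    Parameters
    ----------
    X : (n, p) covariate matrix or DataFrame (column names become labels).
    ties : "efron" (default) or "breslow".
    tol : convergence on the infinity norm of the score vector.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim == 2 and X.shape[0] == 1 and np.asarray(time).size != 1:
        X = X.T
    time, event = _clean_survival(time, event)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if n <= p:
        raise ValueError("need more observations than covariates")
    if event.sum() == 0:
        raise ValueError("no events; partial likelihood undefined")
    for j in range(p):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"covariate {names[j]!r} is constant")

    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    flags: list[str] = []
    beta = np.zeros(p)
    ll0, U0, I0 = _cox_quantities(beta, Xs, ts, es, ties)
    try:
        score_stat = float(U0 @ np.linalg.solve(I0, U0))
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular information matrix at beta=0 (collinear covariates?)"
        )

    ll = ll0
    U, Info = U0, I0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        step = np.linalg.solve(Info, U)
        # step-halving to guarantee likelihood ascent
        factor = 1.0
        for _ in range(30):
            ll_new, U_new, I_new = _cox_quantities(
                beta + factor * step, Xs, ts, es, ties
            )
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        ll, U, Info = ll_new, U_new, I_new
        if np.max(np.abs(U)) < tol:
            break
    else:
        raise CoxConvergenceError(
            f"no convergence in {max_iter} iterations; "
            f"|U|={np.max(np.abs(U)):.3g}, beta={beta}"
        )

    if np.any(np.abs(beta) > 20):
        flags.append("monotone_likelihood_suspected")

    cov = np.linalg.inv(Info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    zq = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(over="ignore"):  # inf CI bound under near-separation is valid
        hr = np.exp(beta)
        ci_low = np.exp(beta - zq * se)
        ci_high = np.exp(beta + zq * se)
    lr = 2 * (ll - ll0)
    wald = float(beta @ Info @ beta)
    r2 = 1 - np.exp(-lr / n)
    max_r2 = 1 - np.exp(2 * ll0 / n)
    c_index = concordance_index(ts, es, Xs @ beta)

    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        loglik=float(ll),
        loglik_null=float(ll0),
        lr_stat=float(lr),
        lr_p=float(stats.chi2.sf(lr, p)),
        wald_stat=wald,
        wald_p=float(stats.chi2.sf(wald, p)),
        score_stat=score_stat,
        score_p=float(stats.chi2.sf(score_stat, p)),
        df=p,
        concordance=c_index,
        r2=float(r2),
        max_r2=float(max_r2),
        n=n,
        n_events=int(es.sum()),
        ties=ties,
        n_iter=n_iter,
        flags=flags,
    )


@dataclass
class InteractionResult:
    coef: float
    se: float
    p_value: float
    fit: CoxFit | None
    flags: list


def cox_interaction_test(score_a, score_b, time, event, ties="efron") -> InteractionResult:
    """Wald test of the product term in ``hazard ~ a + b + a:b``.

    A significant interaction indicates that score ``a`` modifies the
    prognostic effect of score ``b`` (and vice versa) beyond their additive
    contributions. A rank-deficient design (e.g. b identical to a) is
    flagged rather than raised.
    """
    a = np.asarray(score_a, float)
    b = np.asarray(score_b, float)
    design = np.column_stack([a, b, a * b])
    if np.linalg.matrix_rank(design - design.mean(axis=0)) < 3:
        return InteractionResult(
            coef=float("nan"), se=float("nan"), p_value=float("nan"),
            fit=None, flags=["collinear_design"],
        )
    try:
        fit = cox_fit(design, time, event, ties=ties, names=["a", "b", "a:b"])
    except (np.linalg.LinAlgError, CoxConvergenceError) as exc:
        return InteractionResult(
            coef=float("nan"), se=float("nan"), p_value=float("nan"),
            fit=None, flags=[f"fit_failed: {exc}"],
        )
    return InteractionResult(
        coef=float(fit.coef[2]),
        se=float(fit.se[2]),
        p_value=float(fit.p[2]),
        fit=fit,
        flags=list(fit.flags),
    )


# ---------------------------------------------------------------------------
# Simple association tests
# ---------------------------------------------------------------------------

def chi_square_association(cat_a, cat_b, correction: bool = False):
    """Pearson chi-squared test of independence for two categorical vectors.

    Continuity correction is off by default (option for 2x2 tables).
    Returns ``(statistic, df, p_value, table)``.
    """
    a = pd.Series(np.asarray(cat_a))  # positional: ignore any incoming index
    b = pd.Series(np.asarray(cat_b))
    if len(a) != len(b):
        raise ValueError("categorical vectors must have equal length")
    table = pd.crosstab(a, b)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("each variable needs at least two observed levels")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(table.to_numpy(), correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue), table


@dataclass
class TrendResult:
    slope: float
    intercept: float
    r: float
    p_value: float
    stderr: float
    n: int


def linear_trend(x, y) -> TrendResult:
    """Ordinary least squares of y on x with the t-test on the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=int(x.size),
    )
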