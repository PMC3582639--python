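"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain loops, directly from the defining
formulas, and deliberately shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar


# ---------------------------------------------------------------------------
# Nearest-shrunken-centroid oracle
# ---------------------------------------------------------------------------

def nsc_fit_oracle(X, labels, delta, priors=None, s0=None):
    """Shrunken centroids by explicit loops over features and classes."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    p, n = X.shape
    classes = sorted(set(labels.tolist()), key=str)
    K = len(classes)
    nk = [int(np.sum(labels == c)) for c in classes]

    xbar = [sum(X[i]) / n for i in range(p)]
    cent = [[0.0] * K for _ in range(p)]
    for k, c in enumerate(classes):
        idx = [j for j in range(n) if labels[j] == c]
        for i in range(p):
            cent[i][k] = sum(X[i, j] for j in idx) / len(idx)

    s = []
    for i in range(p):
        ss = 0.0
        for k, c in enumerate(classes):
            for j in range(n):
                if labels[j] == c:
                    ss += (X[i, j] - cent[i][k]) ** 2
        s.append(math.sqrt(ss / (n - K)))
    if s0 is None:
        s0 = float(np.median(s))

    mk = [math.sqrt(1.0 / nk[k] - 1.0 / n) for k in range(K)]
    shrunk = [[0.0] * K for _ in range(p)]
    dprime = [[0.0] * K for _ in range(p)]
    for i in range(p):
        for k in range(K):
            d = (cent[i][k] - xbar[i]) / (mk[k] * (s[i] + s0))
            dp = math.copysign(max(abs(d) - delta, 0.0), d)
            dprime[i][k] = dp
            shrunk[i][k] = xbar[i] + mk[k] * (s[i] + s0) * dp

    if priors is None:
        priors = [nk[k] / n for k in range(K)]
    return {
        "classes": classes,
        "xbar": xbar,
        "centroids": cent,
        "shrunken": shrunk,
        "d_shrunk": dprime,
        "s": s,
        "s0": s0,
        "m_k": mk,
        "priors": list(priors),
    }


def nsc_classify_oracle(fit, x):
    """Label of x by explicit evaluation of the discriminant scores."""
    p = len(fit["s"])
    K = len(fit["classes"])
    best, best_score = None, None
    for k in range(K):
        score = 0.0
        for i in range(p):
            score += (x[i] - fit["shrunken"][i][k]) ** 2 / (
                (fit["s"][i] + fit["s0"]) ** 2
            )
        score -= 2.0 * math.log(fit["priors"][k])
        if best_score is None or score < best_score - 1e-12:
            best, best_score = fit["classes"][k], score
    return best


# ---------------------------------------------------------------------------
# Cox partial-likelihood oracle
# ---------------------------------------------------------------------------

def cox_loglik_oracle(beta, x, time, event, ties="efron"):
    """Hand-written single-covariate partial log-likelihood (loops only)."""
    n = len(time)
    ll = 0.0
    for u in sorted(set(time[i] for i in range(n) if event[i] == 1)):
        D = [i for i in range(n) if time[i] == u and event[i] == 1]
        R = [i for i in range(n) if time[i] >= u]
        d = len(D)
        s0 = sum(math.exp(beta * x[i]) for i in R)
        s0d = sum(math.exp(beta * x[i]) for i in D)
        for i in D:
            ll += beta * x[i]
        if ties == "breslow":
            ll -= d * math.log(s0)
        else:  # efron
            for l in range(d):
                ll -= math.log(s0 - (l / d) * s0d)
    return ll


def cox_grid_oracle(x, time, event, ties="efron", span=6.0):
    """Maximize the hand-written partial likelihood: grid then refinement."""
    grid = np.linspace(-span, span, 1201)
    vals = [cox_loglik_oracle(b, x, time, event, ties) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = minimize_scalar(
        lambda b: -cox_loglik_oracle(b, x, time, event, ties),
        bounds=(b0 - 0.02, b0 + 0.02),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# Log-rank oracle (explicit O-E and variance terms)
# ---------------------------------------------------------------------------

def logrank_oracle(time_a, event_a, time_b, event_b):
    times = list(time_a) + list(time_b)
    events = list(event_a) + list(event_b)
    group = [1] * len(time_a) + [0] * len(time_b)
    o, e, v = 0.0, 0.0, 0.0
    for u in sorted(set(t for t, ev in zip(times, events) if ev == 1)):
        nj = sum(1 for t in times if t >= u)
        n1 = sum(1 for t, g in zip(times, group) if t >= u and g == 1)
        dj = sum(1 for t, ev in zip(times, events) if t == u and ev == 1)
        d1 = sum(
            1
            for t, ev, g in zip(times, events, group)
            if t == u and ev == 1 and g == 1
        )
        o += d1
        e += dj * n1 / nj
        if nj > 1:
            v += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    return (o - e) ** 2 / v


# ---------------------------------------------------------------------------
# Standardized nearest-centroid (no shrinkage) oracle
# ---------------------------------------------------------------------------

def standardized_nearest_centroid(X, labels, x, priors=None, s0=None):
    """Classification by raw class centroids standardized by (s_i + s0)."""
    fit = nsc_fit_oracle(X, labels, delta=0.0, priors=priors, s0=s0)
    return nsc_classify_oracle(fit, x)
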