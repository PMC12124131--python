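"""Firth-penalised logistic and Cox regression.

Rare-variant case-control analyses routinely produce separated or nearly
separated designs (e.g. a gene whose carriers are all cases), under which
ordinary maximum likelihood diverges.  Firth's penalty -- adding half the
log-determinant of the information matrix to the (partial) log-likelihood,
equivalently a Jeffreys prior -- guarantees finite estimates and is the
standard sensitivity analysis in this setting.

Logistic regression maximises

    l*(beta) = l(beta) + 0.5 * log |X' W X|,   W = diag(p(1-p)),

by Newton iteration on the hat-matrix-modified score

    U*(beta) = X' (y - p + h (0.5 - p)),

with step-halving whenever a step would decrease the penalised likelihood.
Per-term p-values come from penalised likelihood-ratio tests (the term is
constrained to zero and the remaining terms re-maximised, with the penalty
still computed from the full-model information), and confidence bounds from
the profile penalised likelihood, located by bisection of the signed LR
statistic at the chi-square(1) 95% point.

Cox regression applies the same penalty to the Breslow partial likelihood.
The dimension of these models is small (a handful of covariates), so the
Cox maximiser uses a quasi-Newton optimiser on the exact penalised partial
likelihood rather than a bespoke modified-score iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.optimize import brentq, minimize
from scipy.special import expit
from scipy.stats import chi2

_CHI2_95 = float(chi2.ppf(0.95, df=1))


@dataclass
class FirthFit:
    coefficients: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    converged: bool
    iterations: int
    loglik: float


@dataclass
class SurvivalResult:
    hr: float
    ci: tuple[float, float]
    p: float
    statistic: float | None = None
    n_events: int = 0


# ---------------------------------------------------------------------------
# Firth logistic regression
# ---------------------------------------------------------------------------


def _as_design(X, add_intercept: bool) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        names = [f"x{i + 1}" for i in range(Xm.shape[1])]
    if add_intercept:
        Xm = np.column_stack([np.ones(len(Xm)), Xm])
        names = ["intercept"] + names
    return Xm, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns through pivoted QR
        _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag.max()]
        bad += [names[j] for j in piv[len(diag):]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _penalized_loglik(beta, X, y):
    eta = X @ beta
    # numerically safe log-likelihood
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    XtWX = X.T @ (X * w[:, None])
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _firth_newton(X, y, free, beta0=None, max_iter=25, tol=1e-8):
    """Maximise the Firth-penalised likelihood over the ``free`` coordinates.

    Constrained coordinates stay at their value in ``beta0`` (zero by
    default); the penalty is always computed from the full-model
    information, as in profile-likelihood inference.
    """
    k = X.shape[1]
    beta = np.zeros(k) if beta0 is None else beta0.copy()
    free = np.asarray(free)
    pll = _penalized_loglik(beta, X, y)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        XW = X * w[:, None]
        XtWX = X.T @ XW
        XtWX_inv = np.linalg.inv(XtWX)
        # hat diagonal: h_i = w_i x_i' (X'WX)^-1 x_i
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        u = score[free]
        if np.max(np.abs(u)) < tol:
            converged = True
            break
        info = XtWX[np.ix_(free, free)]
        step = np.linalg.solve(info, u)
        # step-halving on penalised-likelihood decrease
        lam = 1.0
        for _ in range(25):
            cand = beta.copy()
            cand[free] += lam * step
            pll_new = _penalized_loglik(cand, X, y)
            if pll_new >= pll - 1e-12:
                beta, pll = cand, pll_new
                break
            lam *= 0.5
        else:
            break
    return beta, pll, converged, it


def firth_logistic(
    y, X, add_intercept: bool = True, conf: float = 0.95, max_iter: int = 25
) -> FirthFit:
    """Firth-penalised logistic regression with profile-likelihood inference.

    ``y`` is binary (0/1 or bool); ``X`` is an array or DataFrame of
    covariates.  Raises ``ValueError`` on a rank-deficient design, naming
    the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y must be binary (0/1)")
    Xm, names = _as_design(X, add_intercept)
    _check_rank(Xm, names)
    k = Xm.shape[1]
    all_free = np.arange(k)
    beta, pll, converged, its = _firth_newton(Xm, y, all_free, max_iter=max_iter)

    crit = float(chi2.ppf(conf, df=1))
    p_vals, lo, hi = np.empty(k), np.empty(k), np.empty(k)
    for j in range(k):
        other = np.array([i for i in range(k) if i != j])
        b0 = beta.copy()
        b0[j] = 0.0
        if other.size:
            _, pll0, _, _ = _firth_newton(Xm, y, other, beta0=b0, max_iter=max_iter)
        else:
            pll0 = _penalized_loglik(b0, Xm, y)
        p_vals[j] = float(chi2.sf(max(2.0 * (pll - pll0), 0.0), df=1))
        lo[j], hi[j] = _profile_ci(Xm, y, beta, pll, j, crit, max_iter)

    return FirthFit(
        coefficients=pd.Series(beta, index=names),
        ci_low=pd.Series(lo, index=names),
        ci_high=pd.Series(hi, index=names),
        p=pd.Series(p_vals, index=names),
        converged=converged,
        iterations=its,
        loglik=pll,
    )


def _profile_ci(Xm, y, beta, pll, j, crit, max_iter):
    """Profile penalised-likelihood CI bounds for coordinate ``j``."""
    k = Xm.shape[1]
    other = np.array([i for i in range(k) if i != j])

    def deficit(bj):
        b0 = beta.copy()
        b0[j] = bj
        if other.size:
            _, pllc, _, _ = _firth_newton(Xm, y, other, beta0=b0, max_iter=max_iter)
        else:
            pllc = _penalized_loglik(b0, Xm, y)
        return 2.0 * (pll - pllc) - crit

    bounds = []
    for direction in (-1.0, 1.0):
        step = max(0.5, abs(beta[j]) * 0.5)
        a, fa = beta[j], -crit
        b = beta[j]
        fb = fa
        for _ in range(60):
            b = b + direction * step
            fb = deficit(b)
            if fb > 0:
                break
            a, fa = b, fb
            step *= 1.6
        else:
            bounds.append(direction * np.inf)
            continue
        bounds.append(float(brentq(deficit, min(a, b), max(a, b), xtol=1e-6)))
    return bounds[0], bounds[1]


# ---------------------------------------------------------------------------
# Firth-penalised Cox regression (Breslow ties)
# ---------------------------------------------------------------------------


def _cox_quantities(beta, times, events, X):
    """Breslow partial log-likelihood and information at ``beta``."""
    order = np.argsort(-times, kind="mergesort")  # decreasing time
    Xo = X[order]
    to = times[order]
    eo = events[order]
    eta = Xo @ beta
    r = np.exp(eta)
    # cumulative risk-set sums walking down in time
    S0 = np.cumsum(r)
    S1 = np.cumsum(r[:, None] * Xo, axis=0)
    S2 = np.cumsum(r[:, None, None] * (Xo[:, :, None] * Xo[:, None, :]), axis=0)
    # for tied times, the risk set includes everyone with time >= t:
    # map each position to the last position sharing its time
    last = np.empty(len(to), dtype=int)
    i = 0
    while i < len(to):
        jend = i
        while jend + 1 < len(to) and to[jend + 1] == to[i]:
            jend += 1
        last[i : jend + 1] = jend
        i = jend + 1
    ll = 0.0
    k = X.shape[1]
    info = np.zeros((k, k))
    for i in np.flatnonzero(eo):
        j = last[i]
        s0 = S0[j]
        s1 = S1[j]
        s2 = S2[j]
        ll += eta[i] - np.log(s0)
        xbar = s1 / s0
        info += s2 / s0 - np.outer(xbar, xbar)
    return ll, info


def _cox_penalized_ll(beta, times, events, X):
    ll, info = _cox_quantities(beta, times, events, X)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def cox_firth(
    times, events, X, conf: float = 0.95
) -> tuple[FirthFit, SurvivalResult]:
    """Firth-penalised Cox regression (Breslow tie handling).

    Returns the full fit plus a ``SurvivalResult`` summarising the first
    covariate as a hazard ratio (the usual single-exposure use).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    Xm, names = _as_design(X, add_intercept=False)
    _check_rank(Xm, names)
    if events.sum() == 0:
        raise ValueError("no events observed; Cox model undefined")
    k = Xm.shape[1]

    def neg(beta):
        return -_cox_penalized_ll(beta, times, events, Xm)

    res = minimize(neg, np.zeros(k), method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 4000})
    beta = res.x
    pll = -res.fun
    crit = float(chi2.ppf(conf, df=1))

    p_vals, lo, hi = np.empty(k), np.empty(k), np.empty(k)
    for j in range(k):
        p_vals[j] = float(chi2.sf(max(2.0 * (pll - _cox_profile(times, events, Xm, beta, j, 0.0)), 0.0), df=1))
        lo[j], hi[j] = _cox_profile_ci(times, events, Xm, beta, pll, j, crit)

    fit = FirthFit(
        coefficients=pd.Series(beta, index=names),
        ci_low=pd.Series(lo, index=names),
        ci_high=pd.Series(hi, index=names),
        p=pd.Series(p_vals, index=names),
        converged=bool(res.success),
        iterations=int(res.nit),
        loglik=pll,
    )
    summary = SurvivalResult(
        hr=float(np.exp(beta[0])),
        ci=(float(np.exp(lo[0])), float(np.exp(hi[0]))),
        p=float(p_vals[0]),
        statistic=None,
        n_events=int(events.sum()),
    )
    return fit, summary


def _cox_profile(times, events, Xm, beta, j, value):
    """Penalised partial likelihood profiled over the other coordinates."""
    k = Xm.shape[1]
    if k == 1:
        b = np.array([value])
        return _cox_penalized_ll(b, times, events, Xm)
    other = [i for i in range(k) if i != j]

    def neg(bo):
        b = np.empty(k)
        b[j] = value
        b[other] = bo
        return -_cox_penalized_ll(b, times, events, Xm)

    res = minimize(neg, beta[other], method="Nelder-Mead",
                   options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 2000})
    return -res.fun


def _cox_profile_ci(times, events, Xm, beta, pll, j, crit):
    def deficit(bj):
        return 2.0 * (pll - _cox_profile(times, events, Xm, beta, j, bj)) - crit

    bounds = []
    for direction in (-1.0, 1.0):
        step = max(0.5, abs(beta[j]) * 0.5)
        a = beta[j]
        b = a
        for _ in range(60):
            b = b + direction * step
            if deficit(b) > 0:
                break
            a = b
            step *= 1.6
        else:
            bounds.append(direction * np.inf)
            continue
        bounds.append(float(brentq(deficit, min(a, b), max(a, b), xtol=1e-6)))
    return bounds[0], bounds[1]
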