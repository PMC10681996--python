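"""Cox proportional-hazards partial-likelihood solver (Efron ties).

A compact Newton-Raphson maximizer of the Cox partial likelihood for a
small number of covariates, with Wald standard errors from the observed
information.  A dedicated fast path handles the single binary covariate
case, which the minimum-p cutpoint scan calls thousands of times: there
``exp(beta * x)`` takes only two values, so the risk-set sums reduce to
suffix counts per group and every Newton iteration is a handful of
vectorized operations over the event times.

Separation (monotone likelihood) is detected by coefficient divergence
and reported via a flag rather than a silent estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["CoxFit", "cox_newton"]

_MAX_ABS_BETA = 15.0  # |beta| beyond this on a standardized scale => separation
_TOL = 1e-10
_MAX_ITER = 60


@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit.

    ``hr``/``ci_low``/``ci_high``/``p`` are per-covariate Wald quantities;
    ``flags`` collects diagnostics (``separation``, ``no_convergence``).
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    n: int
    n_events: int
    loglik: float
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags

    def row(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "covariate": name,
            "coef": float(self.coef[i]),
            "hr": float(self.hr[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p": float(self.p[i]),
            "n": self.n,
            "n_events": self.n_events,
            "flags": ";".join(self.flags),
        }


def _prepare(time: np.ndarray, event: np.ndarray, x: np.ndarray):
    order = np.argsort(time, kind="stable")
    t, d, xs = time[order], event[order].astype(bool), x[order]
    # risk set at an event time t* = everyone with t >= t*; group rows by
    # unique time, record group start indices for suffix sums
    uniq, start = np.unique(t, return_index=True)
    return t, d, xs, uniq, start


def _efron_terms(t, d, xs, uniq, start, beta):
    """Log-likelihood, gradient and information for sorted data."""
    n, p = xs.shape
    eta = xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * xs
    wxx = w[:, None, None] * (xs[:, :, None] * xs[:, None, :])

    # suffix sums evaluated at each unique-time group start
    c0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    c1 = np.concatenate([np.cumsum(wx[::-1], axis=0)[::-1], np.zeros((1, p))])
    c2 = np.concatenate([np.cumsum(wxx[::-1], axis=0)[::-1], np.zeros((1, p, p))])

    loglik = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    ends = np.append(start[1:], n)
    for k in range(len(uniq)):
        lo, hi = start[k], ends[k]
        dd = d[lo:hi]
        m = int(dd.sum())
        if m == 0:
            continue
        idx = np.arange(lo, hi)[dd]
        s0r, s1r, s2r = c0[lo], c1[lo], c2[lo]
        s0d, s1d, s2d = w[idx].sum(), wx[idx].sum(axis=0), wxx[idx].sum(axis=0)
        loglik += float(eta[idx].sum())
        grad += xs[idx].sum(axis=0)
        frac = np.arange(m) / m
        for f in frac:
            a0 = s0r - f * s0d
            a1 = s1r - f * s1d
            a2 = s2r - f * s2d
            loglik -= np.log(a0)
            grad -= a1 / a0
            info += a2 / a0 - np.outer(a1, a1) / a0**2
    return loglik, grad, info


def cox_newton(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    alpha: float = 0.05,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with Efron tie handling."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.shape[0]:
        X = X.T
    n, p = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    n_events = int(np.asarray(event, dtype=bool).sum())
    flags: list[str] = []
    if n_events < 2:
        raise ValueError("Cox fit requires at least 2 events")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [names[i] for i in range(p) if sd[i] == 0]
        raise ValueError(f"constant covariate(s): {bad}")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")

    # standardize for numerical stability; back-transform at the end
    mu = X.mean(axis=0)
    Z = (X - mu) / sd
    t, dvec, zs, uniq, start = _prepare(time, event, Z)

    beta = np.zeros(p)
    loglik, grad, info = _efron_terms(t, dvec, zs, uniq, start, beta)
    converged = False
    for _ in range(_MAX_ITER):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            flags.append("separation")
            break
        # step-halving line search on the partial likelihood
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, i_new = _efron_terms(t, dvec, zs, uniq, start, cand)
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                break
            scale *= 0.5
        beta, delta_ll = cand, ll_new - loglik
        loglik, grad, info = ll_new, g_new, i_new
        if np.max(np.abs(beta)) > _MAX_ABS_BETA:
            flags.append("separation")
            break
        if np.max(np.abs(grad)) < _TOL or abs(delta_ll) < _TOL:
            converged = True
            break
    if not converged and "separation" not in flags:
        flags.append("no_convergence")

    try:
        cov = np.linalg.inv(info)
        se_z = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_z = np.full(p, np.nan)
        if "separation" not in flags:
            flags.append("separation")

    coef = beta / sd
    se = se_z / sd
    zcrit = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(over="ignore", invalid="ignore"):
        hr = np.exp(coef)
        ci_low = np.exp(coef - zcrit * se)
        ci_high = np.exp(coef + zcrit * se)
        zval = np.where(se > 0, coef / se, np.nan)
        pval = 2.0 * stats.norm.sf(np.abs(zval))
    pval = np.where(np.isnan(pval), 1.0, np.maximum(pval, np.finfo(float).tiny))
    return CoxFit(names, coef, se, hr, ci_low, ci_high, pval, n, n_events, float(loglik), flags)


# ---------------------------------------------------------------------------
# Fast single-binary-covariate path (used by the cutpoint scan)
# ---------------------------------------------------------------------------


class BinaryCoxScanner:
    """Repeated Cox fits of a single binary covariate on fixed (time, event).

    Precomputes the sorted event structure once; each call to
    :meth:`fit_indicator` runs a scalar Newton iteration where all
    risk-set sums are suffix counts of the two groups.  Matches
    :func:`cox_newton` on the same data to solver tolerance.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=bool)
        self.order = np.argsort(time, kind="stable")
        self.t = time[self.order]
        self.d = event[self.order]
        self.n = len(time)
        self.n_events = int(event.sum())
        uniq, start = np.unique(self.t, return_index=True)
        ends = np.append(start[1:], self.n)
        # keep only unique times with events
        keep = []
        for k in range(len(uniq)):
            if self.d[start[k]:ends[k]].any():
                keep.append(k)
        self.start = start[keep]
        self.ends = ends[keep]
        self.mvec = np.array([int(self.d[lo:hi].sum()) for lo, hi in zip(self.start, self.ends)])
        # Efron fractions flattened over all event times
        self.flat_group = np.repeat(np.arange(len(self.mvec)), self.mvec)
        self.frac = np.concatenate([np.arange(m) / m for m in self.mvec]) if len(self.mvec) else np.array([])

    def fit_indicator(self, x: np.ndarray, alpha: float = 0.05) -> CoxFit:
        """Fit ``h(t) = h0(t) exp(beta * x)`` for binary ``x`` (0/1)."""
        x = np.asarray(x, dtype=float)[self.order]
        if x.std() == 0:
            raise ValueError("constant covariate(s): ['indicator']")
        n1_suffix = np.concatenate([np.cumsum(x[::-1])[::-1], [0.0]])
        n_suffix = np.concatenate([np.arange(self.n, 0, -1.0), [0.0]])
        n1_r = n1_suffix[self.start]
        n0_r = n_suffix[self.start] - n1_r
        d1 = np.array([x[lo:hi][self.d[lo:hi]].sum() for lo, hi in zip(self.start, self.ends)])
        d0 = self.mvec - d1
        sum_xd = float(d1.sum())

        g = self.flat_group
        fr = self.frac
        n1_rf = n1_r[g] - fr * d1[g]
        n0_rf = n0_r[g] - fr * d0[g]

        beta = 0.0
        flags: list[str] = []
        converged = False
        for _ in range(_MAX_ITER):
            eb = np.exp(beta)
            a0 = n0_rf + eb * n1_rf
            a1 = eb * n1_rf
            grad = sum_xd - float((a1 / a0).sum())
            info = float((a1 / a0 * (1.0 - a1 / a0)).sum())
            if info <= 0:
                flags.append("separation")
                break
            step = grad / info
            beta += step
            if abs(beta) > _MAX_ABS_BETA:
                flags.append("separation")
                break
            if abs(step) < 1e-9 or abs(grad) < _TOL:
                converged = True
                break
        if not converged and "separation" not in flags:
            flags.append("no_convergence")

        eb = np.exp(beta)
        a0 = n0_rf + eb * n1_rf
        a1 = eb * n1_rf
        loglik = beta * sum_xd - float(np.log(a0).sum())
        info = float((a1 / a0 * (1.0 - a1 / a0)).sum())
        se = 1.0 / np.sqrt(info) if info > 0 else np.nan
        zcrit = stats.norm.ppf(1 - alpha / 2)
        if np.isfinite(se) and se > 0:
            pval = 2.0 * stats.norm.sf(abs(beta / se))
        else:
            pval = 1.0
        arr = lambda v: np.array([v], dtype=float)  # noqa: E731
        exp_clip = lambda v: np.exp(min(v, 700.0)) if np.isfinite(v) else np.nan  # noqa: E731
        return CoxFit(
            ["indicator"],
            arr(beta),
            arr(se),
            arr(np.exp(beta)),
            arr(exp_clip(beta - zcrit * se) if np.isfinite(se) else np.nan),
            arr(exp_clip(beta + zcrit * se) if np.isfinite(se) else np.nan),
            arr(max(pval, np.finfo(float).tiny)),
            self.n,
            self.n_events,
            loglik,
            flags,
        )
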