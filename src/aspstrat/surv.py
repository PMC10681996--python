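"""Endpoint derivation, Kaplan-Meier, Cox regression and cutpoint search.

Endpoints follow the surgical-cohort conventions: PFS events at the first
recurrence (any site) or death; OS events at death; LRC and FFDM are
cause-specific (events at loco-regional / distant recurrence, death
without that recurrence censored at death); otherwise censoring at last
follow-up.

The optimal-cutpoint search dichotomizes a marker at every unique observed
value inside its interquartile range and picks the threshold whose
binarized Cox model has the smallest Wald p-value.  Minimum-p scanning
inflates type-I error; a permutation-adjusted p-value (min-p null
distribution over marker permutations) is provided, and the full
candidate trace is kept for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test

from ._cox import BinaryCoxScanner, CoxFit, cox_newton

__all__ = [
    "ENDPOINTS",
    "CutpointResult",
    "derive_endpoint",
    "km_estimate",
    "cox_fit",
    "optimal_cutpoint",
    "validate_fixed_cutoff",
    "logrank",
]

log = logging.getLogger(__name__)

ENDPOINTS = ("PFS", "OS", "LRC", "FFDM")

_EVENT_COLS = ("locoregional_months", "distant_months", "death_months", "last_followup_months")


def derive_endpoint(cohort: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Per-patient ``(time, event)`` records for one endpoint.

    Accepts either precomputed ``<endpoint>_time`` / ``<endpoint>_event``
    columns (lower-case endpoint name) or the event-history columns
    ``locoregional_months``, ``distant_months``, ``death_months`` and
    ``last_followup_months`` (NaN = not observed).  Records with
    non-positive follow-up are dropped with their ids logged.
    """
    endpoint = endpoint.upper()
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")
    tcol, ecol = f"{endpoint.lower()}_time", f"{endpoint.lower()}_event"
    if tcol in cohort.columns and ecol in cohort.columns:
        out = cohort[["patient_id", tcol, ecol]].rename(columns={tcol: "time", ecol: "event"})
    else:
        missing = [c for c in _EVENT_COLS if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort lacks event-history columns {missing} and {tcol}/{ecol}")
        lr = cohort["locoregional_months"].to_numpy(dtype=float)
        dm = cohort["distant_months"].to_numpy(dtype=float)
        death = cohort["death_months"].to_numpy(dtype=float)
        last = cohort["last_followup_months"].to_numpy(dtype=float)
        first_rec = np.fmin(lr, dm)
        if endpoint == "PFS":
            t_event = np.fmin(first_rec, death)
        elif endpoint == "OS":
            t_event = death
        elif endpoint == "LRC":
            t_event = lr
        else:  # FFDM
            t_event = dm
        event = ~np.isnan(t_event)
        if endpoint in ("LRC", "FFDM"):
            # death without the endpoint recurrence censors at death
            censor_at = np.fmin(death, last)
        else:
            censor_at = last
        time = np.where(event, t_event, np.where(np.isnan(censor_at), last, censor_at))
        out = pd.DataFrame(
            {"patient_id": cohort["patient_id"], "time": time, "event": event.astype(int)}
        )
    bad = ~(out["time"] > 0) | ~np.isfinite(out["time"])
    if bad.any():
        log.warning(
            "dropping %d records with non-positive follow-up: %s",
            int(bad.sum()),
            out.loc[bad, "patient_id"].tolist(),
        )
        out = out[~bad]
    out = out.reset_index(drop=True)
    out["event"] = out["event"].astype(int)
    return out


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit step table.

    Returns one row per distinct observed time with columns ``time``,
    ``at_risk``, ``events``, ``censored`` and ``survival``; ties are
    handled by simultaneous multiplication at the tied time.
    """
    if len(records) == 0:
        raise ValueError("no records")
    t = records["time"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times, start = np.unique(t, return_index=True)
    ends = np.append(start[1:], len(t))
    n = len(t)
    rows = []
    surv = 1.0
    for tt, lo, hi in zip(times, start, ends):
        at_risk = n - lo
        d = int(e[lo:hi].sum())
        c = (hi - lo) - d
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append((tt, at_risk, d, c, surv))
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "censored", "survival"])


def km_median(records: pd.DataFrame) -> float:
    """Median survival time (first time S(t) <= 0.5; NaN if never reached)."""
    km = km_estimate(records)
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("nan")


def cox_fit(
    records: pd.DataFrame,
    covariates: pd.DataFrame | pd.Series | np.ndarray,
    names: list[str] | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit of ``records`` on ``covariates``.

    ``records`` needs ``time`` and ``event`` columns aligned row-wise with
    the covariates.  Metric and binarized (0/1) codings are both
    supported; a single binary covariate takes the dedicated fast path.
    Separation or non-convergence is flagged on the result, never silent.
    """
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    if isinstance(covariates, pd.DataFrame):
        names = names or list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    elif isinstance(covariates, pd.Series):
        names = names or [covariates.name or "x0"]
        X = covariates.to_numpy(dtype=float)[:, None]
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    if X.ndim != 2 or X.shape[0] != len(time):
        raise ValueError("covariates must align row-wise with the records")
    if X.shape[1] == 1 and set(np.unique(X[:, 0])) <= {0.0, 1.0}:
        fit = BinaryCoxScanner(time, event).fit_indicator(X[:, 0])
        if names:
            fit.names = list(names)
        return fit
    return cox_newton(time, event, X, names=names)


@dataclass
class CutpointResult:
    """Outcome of the IQR-restricted minimum-p cutpoint search."""

    marker: str
    endpoint: str
    cutoff: float
    fit: CoxFit
    iqr: tuple[float, float]
    n_candidates: int
    trace: pd.DataFrame = field(repr=False, default=None)
    p_adjusted: float | None = None


def _iqr_candidates(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    q1, q3 = np.quantile(values, [0.25, 0.75], method="median_unbiased")
    uniq = np.unique(values)
    cand = uniq[(uniq >= q1) & (uniq <= q3)]
    # a cutoff equal to the overall maximum leaves the high group empty
    cand = cand[cand < uniq[-1]]
    return cand, (float(q1), float(q3))


def optimal_cutpoint(
    marker: pd.Series | np.ndarray,
    records: pd.DataFrame,
    marker_name: str = "marker",
    endpoint: str = "PFS",
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutpointResult:
    """Minimum-p dichotomization threshold restricted to the marker's IQR.

    Every unique observed marker value v with Q1 <= v <= Q3 (median-unbiased
    quartiles, bounds inclusive) is a candidate; for each, a Cox model on
    ``indicator(marker > v)`` is fitted and the candidate with the smallest
    Wald p is selected, ties broken toward the smaller cutoff.  Candidates
    whose fit flags separation are recorded in the trace but not selected
    unless no clean candidate exists.  With ``n_permutations`` > 0 a
    min-p-adjusted p-value is computed by permuting the marker against the
    survival records.
    """
    values = np.asarray(marker, dtype=float)
    if len(values) != len(records):
        raise ValueError("marker and records must align")
    if len(records) < 10 or int(records["event"].sum()) < 3:
        raise ValueError("cutpoint search requires >= 10 patients and >= 3 events")
    if np.unique(values).size < 2:
        raise ValueError("marker is constant; no candidate cutoffs")
    cand, iqr = _iqr_candidates(values)
    if cand.size == 0:
        raise ValueError("no candidate cutoffs inside the interquartile range")

    scanner = BinaryCoxScanner(
        records["time"].to_numpy(dtype=float), records["event"].to_numpy(dtype=int)
    )

    def scan(vals: np.ndarray):
        rows = []
        best = None
        for c in cand:
            x = (vals > c).astype(float)
            if x.std() == 0:
                continue
            fit = scanner.fit_indicator(x)
            rows.append((float(c), float(fit.hr[0]), float(fit.p[0]), ";".join(fit.flags)))
            clean = fit.ok
            if best is None:
                best = (c, fit, clean)
            else:
                _, bfit, bclean = best
                if (clean, -fit.p[0]) > (bclean, -bfit.p[0]):
                    # prefer clean fits; among equal cleanliness, smaller p;
                    # ties in p keep the earlier (smaller) cutoff
                    if clean != bclean or fit.p[0] < bfit.p[0]:
                        best = (c, fit, clean)
        return best, rows

    best, rows = scan(values)
    if best is None:
        raise ValueError("no candidate produced two nonempty groups")
    cutoff, fit, _ = best
    trace = pd.DataFrame(rows, columns=["cutoff", "hr", "p", "flags"])

    p_adj = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng(0)
        observed = float(fit.p[0])
        hits = 1
        for _ in range(n_permutations):
            perm = rng.permutation(values)
            pbest, _ = scan(perm)
            if pbest is not None and float(pbest[1].p[0]) <= observed:
                hits += 1
        p_adj = hits / (n_permutations + 1)

    if not fit.ok:
        log.warning("selected cutpoint fit flagged: %s", fit.flags)
    return CutpointResult(marker_name, endpoint, float(cutoff), fit, iqr, int(cand.size), trace, p_adj)


def validate_fixed_cutoff(
    marker: pd.Series | np.ndarray,
    records: pd.DataFrame,
    cutoff: float,
    marker_name: str = "asp",
) -> dict:
    """Binarize at a prespecified cutoff (no optimization) and test it.

    Returns the Cox fit of ``indicator(marker > cutoff)``, per-group KM
    step tables, group sizes and the log-rank p-value.  The shipped
    default for ASP validation is 19.5 (percent scale).
    """
    values = np.asarray(marker, dtype=float)
    high = values > cutoff
    n_high, n_low = int(high.sum()), int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError(
            f"cutoff {cutoff} leaves an empty group (low n={n_low}, high n={n_high})"
        )
    fit = cox_fit(records, high.astype(float)[:, None], names=[f"{marker_name} > {cutoff}"])
    km_low = km_estimate(records[~high])
    km_high = km_estimate(records[high])
    stat, p = logrank(records, pd.Series(np.where(high, "high", "low")))
    return {
        "fit": fit,
        "cutoff": float(cutoff),
        "n_low": n_low,
        "n_high": n_high,
        "km_low": km_low,
        "km_high": km_high,
        "logrank_stat": stat,
        "logrank_p": p,
    }


def logrank(records: pd.DataFrame, groups: pd.Series | np.ndarray) -> tuple[float, float]:
    """Two-or-more-sample log-rank test; returns (chi-square, p)."""
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("log-rank requires >= 2 nonempty groups")
    res = multivariate_logrank_test(
        records["time"].to_numpy(dtype=float), groups, records["event"].to_numpy(dtype=int)
    )
    return float(res.test_statistic), float(res.p_value)
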