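"""Survival statistics computed from (reconstructed) individual patient data.

Provides the three summaries usually compared against a publication:
survival probability at given times, median survival, and the two-arm
hazard ratio -- each with a 95% confidence interval.

The product-limit estimate uses Greenwood's variance with the confidence
interval on the log-survival scale by default (the convention of the R
``survival`` package's ``survfit``); a complementary log-log variant is
available via ``conf_type="loglog"``.  The hazard ratio comes from the
partial likelihood of a proportional-hazards model with a single binary
arm covariate, maximized by Newton's method with Efron's correction for
tied event times (Breslow available for cross-checks).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .types import IPDRecord

__all__ = [
    "KMCurve",
    "km_curve",
    "surv_prob_at",
    "median_survival",
    "cox_hr",
    "SurvivalEstimate",
    "MedianEstimate",
    "HazardRatio",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class SurvivalEstimate(NamedTuple):
    estimate: float
    lo95: float
    hi95: float
    truncated: bool = False


class MedianEstimate(NamedTuple):
    estimate: Optional[float]
    lo95: Optional[float]
    hi95: Optional[float]


class HazardRatio(NamedTuple):
    hr: float
    lo95: float
    hi95: float
    se_log_hr: float


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate with Greenwood variance at each event time."""

    event_times: np.ndarray  # distinct times with >= 1 event, increasing
    n_risk: np.ndarray  # at risk just before each event time
    n_events: np.ndarray
    surv: np.ndarray  # S(t) at each event time
    var_log_surv: np.ndarray  # Greenwood sum: var of log S
    max_follow_up: float
    conf_type: str = "log"

    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        """95% CI bounds for S at each event time."""
        s = self.surv
        se = np.sqrt(self.var_log_surv)
        with np.errstate(divide="ignore", invalid="ignore"):
            if self.conf_type == "log":
                lo = np.where(s > 0, s * np.exp(-Z95 * se), 0.0)
                hi = np.where(s > 0, np.minimum(s * np.exp(Z95 * se), 1.0), 0.0)
            elif self.conf_type == "loglog":
                # CI on log(-log S); se(log(-log S)) = se(log S)/|log S|
                logs = np.log(s)
                theta = np.exp(np.where(logs < 0, Z95 * se / np.abs(logs), 0.0))
                lo = np.where((s > 0) & (s < 1), s ** theta, s)
                hi = np.where((s > 0) & (s < 1), s ** (1.0 / theta), s)
            else:
                raise ValueError(f"unknown conf_type {self.conf_type!r}")
        return lo, hi


def _as_arrays(ipd: Sequence[IPDRecord] | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ipd, pd.DataFrame):
        t = ipd["time"].to_numpy(dtype=float)
        e = ipd["event"].to_numpy(dtype=int)
    else:
        t = np.array([r.time for r in ipd], dtype=float)
        e = np.array([r.event for r in ipd], dtype=int)
    if t.size == 0:
        raise ValueError("need at least one record")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t, e


def km_curve(ipd: Sequence[IPDRecord] | pd.DataFrame, conf_type: str = "log") -> KMCurve:
    """Product-limit estimator from IPD records (or a time/event frame).

    Censorings tied with an event time are counted as still at risk at that
    time (events before censorings, the standard convention).  With no
    events the curve is constant at 1.
    """
    t, e = _as_arrays(ipd)
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    n = t.size
    ev_times, idx = np.unique(t[e == 1], return_inverse=True)
    d = np.bincount(idx, minlength=ev_times.size).astype(int)
    # at risk just before each event time: observed time >= event time
    n_risk = n - np.searchsorted(t, ev_times, side="left")
    frac = 1.0 - d / n_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
    var_log = np.cumsum(term)
    return KMCurve(
        event_times=ev_times,
        n_risk=n_risk.astype(int),
        n_events=d,
        surv=surv,
        var_log_surv=var_log,
        max_follow_up=float(t.max()),
        conf_type=conf_type,
    )


def surv_prob_at(curve: KMCurve, t: float) -> SurvivalEstimate:
    """Evaluate the (right-continuous) survival step function at time t.

    Beyond the last follow-up time the last available estimate is returned
    with ``truncated=True``.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    truncated = t > curve.max_follow_up
    j = int(np.searchsorted(curve.event_times, min(t, curve.max_follow_up),
                            side="right")) - 1
    if j < 0:
        return SurvivalEstimate(1.0, 1.0, 1.0, truncated)
    lo, hi = curve.ci()
    return SurvivalEstimate(
        float(curve.surv[j]), float(lo[j]), float(hi[j]), truncated
    )


def median_survival(curve: KMCurve) -> MedianEstimate:
    """Median survival: smallest event time with S <= 0.5.

    CI endpoints are the smallest event times at which the survival CI
    bounds drop to 0.5 or below (the usual confidence set for quantiles of
    a product-limit curve); an endpoint the bands never reach is ``None``,
    as is the median itself when S never falls to 0.5.
    """
    lo_band, hi_band = curve.ci()

    def first_leq(values: np.ndarray) -> Optional[float]:
        hits = np.nonzero(values <= 0.5 + 1e-12)[0]
        return float(curve.event_times[hits[0]]) if hits.size else None

    return MedianEstimate(
        estimate=first_leq(curve.surv),
        lo95=first_leq(lo_band),
        hi95=first_leq(hi_band),
    )


# ---------------------------------------------------------------------------
# Two-arm proportional hazards fit


def _tie_groups(t: np.ndarray, e: np.ndarray, z: np.ndarray):
    """Per distinct event time: (d0, d1, r0, r1) event and risk-set counts."""
    ev_times = np.unique(t[e == 1])
    t0 = np.sort(t[z == 0])
    t1 = np.sort(t[z == 1])
    r0 = t0.size - np.searchsorted(t0, ev_times, side="left")
    r1 = t1.size - np.searchsorted(t1, ev_times, side="left")

    def _counts(mask: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(ev_times, t[mask])
        return np.bincount(idx, minlength=ev_times.size)

    d0 = _counts((e == 1) & (z == 0))
    d1 = _counts((e == 1) & (z == 1))
    return list(zip(d0.tolist(), d1.tolist(), r0.tolist(), r1.tolist()))


def _pl_parts(beta: float, groups, ties: str) -> tuple[float, float, float]:
    """Partial log-likelihood, gradient and negative Hessian at beta."""
    eb = math.exp(beta)
    ll = 0.0
    grad = 0.0
    info = 0.0
    for d0, d1, r0, r1 in groups:
        d = d0 + d1
        s0_r = r0 + r1 * eb  # sum of exp(beta z) over risk set
        s1_r = r1 * eb  # sum of z exp(beta z)
        ll += d1 * beta
        if ties == "breslow":
            js = [0.0] * d
        else:  # efron
            js = [j / d for j in range(d)]
        for frac in js:
            a0 = s0_r - frac * (d0 + d1 * eb)
            a1 = s1_r - frac * (d1 * eb)
            ll -= math.log(a0)
            mu = a1 / a0
            grad -= mu
            info += mu * (1.0 - mu)
    grad += sum(g[1] for g in groups)
    return ll, grad, info


def partial_loglik(
    beta: float,
    ipd_a: Sequence[IPDRecord] | pd.DataFrame,
    ipd_b: Sequence[IPDRecord] | pd.DataFrame,
    ties: str = "efron",
) -> float:
    """Partial log-likelihood of the two-arm PH model at log-HR ``beta``."""
    groups = _groups_from_arms(ipd_a, ipd_b)
    return _pl_parts(beta, groups, ties)[0]


def _groups_from_arms(ipd_a, ipd_b):
    ta, ea = _as_arrays(ipd_a)
    tb, eb_ = _as_arrays(ipd_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb_])
    z = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    return _tie_groups(t, e, z)


def cox_hr(
    ipd_a: Sequence[IPDRecord] | pd.DataFrame,
    ipd_b: Sequence[IPDRecord] | pd.DataFrame,
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 50,
) -> HazardRatio:
    """Hazard ratio of arm b relative to arm a with 95% CI and SE of log HR.

    Newton's method on the partial likelihood starting from 0, with step
    halving; the SE comes from the observed information at the maximum.
    When one arm carries all the events the maximizer diverges; the estimate
    is then reported as unbounded (``inf`` or 0) with infinite SE and a
    warning.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    groups = _groups_from_arms(ipd_a, ipd_b)
    if not groups:
        raise ValueError("no events in either arm: hazard ratio undefined")
    d0_tot = sum(g[0] for g in groups)
    d1_tot = sum(g[1] for g in groups)
    if d0_tot == 0 or d1_tot == 0:
        warnings.warn(
            "all events fall in one arm: the partial-likelihood maximizer "
            "diverges and the hazard ratio is unbounded",
            UserWarning,
            stacklevel=2,
        )
        hr = math.inf if d1_tot > 0 else 0.0
        return HazardRatio(hr, 0.0, math.inf, math.inf)

    beta = 0.0
    ll, grad, info = _pl_parts(beta, groups, ties)
    for _ in range(max_iter):
        if abs(grad) < tol:
            break
        if info <= 0:
            break
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _pl_parts(new_beta, groups, ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _pl_parts(new_beta, groups, ties)
            halvings += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
    se = math.sqrt(1.0 / info) if info > 0 else math.inf
    safe_exp = lambda x: float(np.exp(np.clip(x, -745, 709)))
    return HazardRatio(
        hr=safe_exp(beta),
        lo95=safe_exp(beta - Z95 * se) if math.isfinite(se) else 0.0,
        hi95=safe_exp(beta + Z95 * se) if math.isfinite(se) else math.inf,
        se_log_hr=se,
    )
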