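"""Simulated trials and perfectly digitized inputs.

The reconstruction can only be validated end-to-end against data whose
truth is known.  This module simulates two-arm (or k-arm) time-to-event
trials with parametric event times and independent censoring, renders the
*exact* digitization a perfect observer would produce from each arm's KM
plot, derives the published-style risk table and event total, and can
perturb coordinates to emulate click error.

All randomness flows from the single seed in :class:`TrialSpec` (plus the
explicit seed of :func:`perturb_curve`), so every artifact is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .io import validate_and_repair
from .survstats import km_curve
from .types import DigitizedCurve, RiskTable

__all__ = [
    "EventDist",
    "CensorDist",
    "TrialSpec",
    "DigitizationNoise",
    "Trial",
    "simulate_trial",
    "exact_digitize",
    "perturb_curve",
    "make_risk_table",
    "pick_risk_times",
]


@dataclass(frozen=True)
class EventDist:
    """Parametric event-time distribution: exponential(rate) or weibull(shape, scale)."""

    kind: str  # 'exponential' | 'weibull'
    rate: Optional[float] = None
    shape: Optional[float] = None
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "exponential":
            if self.rate is None or self.rate <= 0:
                raise ValueError("exponential event distribution needs rate > 0")
        elif self.kind == "weibull":
            if not (self.shape and self.scale) or self.shape <= 0 or self.scale <= 0:
                raise ValueError("weibull event distribution needs shape, scale > 0")
        else:
            raise ValueError(f"unknown event distribution {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "exponential":
            return rng.exponential(1.0 / self.rate, size=n)
        return self.scale * rng.weibull(self.shape, size=n)

    @classmethod
    def exponential(cls, rate: float) -> "EventDist":
        return cls("exponential", rate=rate)

    @classmethod
    def weibull(cls, shape: float, scale: float) -> "EventDist":
        return cls("weibull", shape=shape, scale=scale)


@dataclass(frozen=True)
class CensorDist:
    """Independent censoring: none, uniform(0, c_max) or exponential(rate)."""

    kind: str = "none"  # 'none' | 'uniform' | 'exponential'
    c_max: Optional[float] = None
    rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind == "uniform" and (self.c_max is None or self.c_max <= 0):
            raise ValueError("uniform censoring needs c_max > 0")
        if self.kind == "exponential" and (self.rate is None or self.rate <= 0):
            raise ValueError("exponential censoring needs rate > 0")
        if self.kind not in ("none", "uniform", "exponential"):
            raise ValueError(f"unknown censoring distribution {self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "none":
            return np.full(n, np.inf)
        if self.kind == "uniform":
            return rng.uniform(0.0, self.c_max, size=n)
        return rng.exponential(1.0 / self.rate, size=n)

    @classmethod
    def none(cls) -> "CensorDist":
        return cls("none")

    @classmethod
    def uniform(cls, c_max: float) -> "CensorDist":
        return cls("uniform", c_max=c_max)

    @classmethod
    def exponential(cls, rate: float) -> "CensorDist":
        return cls("exponential", rate=rate)


@dataclass(frozen=True)
class TrialSpec:
    """Design of one simulated trial."""

    n_per_arm: int
    arms: Mapping[str, EventDist]
    censor: CensorDist = field(default_factory=CensorDist.none)
    admin_cutoff: float = np.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be at least 2")
        if not self.arms:
            raise ValueError("at least one arm is required")
        if self.admin_cutoff <= 0:
            raise ValueError("admin_cutoff must be positive")


@dataclass(frozen=True)
class DigitizationNoise:
    """Gaussian jitter plus step dropping, emulating imperfect clicking.

    This is an explicit stand-in for human digitization error -- the real
    process has no published noise model -- and is off (all zero) by default.
    """

    time_jitter_sd: float = 0.0
    prob_jitter_sd: float = 0.0
    drop_step_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.time_jitter_sd < 0 or self.prob_jitter_sd < 0:
            raise ValueError("jitter SDs must be non-negative")
        if not (0 <= self.drop_step_prob < 1):
            raise ValueError("drop_step_prob must be in [0, 1)")

    @property
    def is_null(self) -> bool:
        return (
            self.time_jitter_sd == 0
            and self.prob_jitter_sd == 0
            and self.drop_step_prob == 0
        )


@dataclass(frozen=True)
class Trial:
    """Simulated trial: true IPD plus the spec that generated it."""

    spec: TrialSpec
    ipd: pd.DataFrame  # columns time, event, arm

    @property
    def arm_labels(self) -> list[str]:
        return list(self.spec.arms.keys())

    def arm_ipd(self, arm: str) -> pd.DataFrame:
        out = self.ipd[self.ipd["arm"] == arm].reset_index(drop=True)
        if out.empty:
            raise KeyError(f"no arm {arm!r} in trial")
        return out

    def event_counts(self, arm: str) -> pd.DataFrame:
        """True events and censorings per distinct observed time, one arm."""
        sub = self.arm_ipd(arm)
        g = sub.groupby("time")["event"]
        return pd.DataFrame(
            {
                "time": g.sum().index.to_numpy(),
                "events": g.sum().to_numpy(dtype=int),
                "censored": (g.count() - g.sum()).to_numpy(dtype=int),
            }
        )


def simulate_trial(spec: TrialSpec) -> Trial:
    """Draw event and censoring times and apply the administrative cutoff.

    Observed time is ``min(event, censor, admin_cutoff)`` with event
    indicator 1 iff the event time is the minimum (ties resolved in favour
    of the event).
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for arm, dist in spec.arms.items():
        ev = dist.sample(rng, spec.n_per_arm)
        cz = spec.censor.sample(rng, spec.n_per_arm)
        limit = np.minimum(cz, spec.admin_cutoff)
        obs = np.minimum(ev, limit)
        ind = (ev <= limit).astype(int)
        frames.append(pd.DataFrame({"time": obs, "event": ind, "arm": arm}))
    return Trial(spec=spec, ipd=pd.concat(frames, ignore_index=True))


def exact_digitize(ipd: pd.DataFrame, arm_label: str = "") -> DigitizedCurve:
    """The coordinates a perfect digitizer would click off the arm's KM plot.

    One coordinate at t = 0 with S = 1, one at every distinct event time
    with the exact product-limit value, and -- if follow-up extends beyond
    the last event -- a final coordinate at the largest observed time where
    the curve's right edge ends (the plot is drawn out to that point).
    """
    if ipd.empty:
        raise ValueError("cannot digitize an empty arm")
    arm_label = arm_label or str(ipd["arm"].iloc[0]) if "arm" in ipd else arm_label
    curve = km_curve(ipd)
    times = [0.0]
    surv = [1.0]
    times.extend(curve.event_times.tolist())
    surv.extend(curve.surv.tolist())
    if curve.max_follow_up > (times[-1] if len(times) > 1 else 0.0):
        times.append(curve.max_follow_up)
        surv.append(surv[-1])
    if len(times) < 2:  # no events, no follow-up spread: duplicate the origin
        times.append(0.0)
        surv.append(1.0)
    return DigitizedCurve(arm_label=arm_label, times=np.array(times),
                          surv=np.array(surv))


def perturb_curve(
    curve: DigitizedCurve,
    noise: DigitizationNoise,
    seed: int,
    protect_times: Sequence[float] = (),
) -> DigitizedCurve:
    """Jitter and thin a curve's coordinates, emulating click error.

    The t = 0 coordinate is never perturbed or dropped, and neither is any
    coordinate whose time appears in ``protect_times`` (published risk times
    must survive digitization exactly).  Jittered coordinates are re-sorted
    in time and survival anomalies are clamped via
    :func:`kmrecon.io.validate_and_repair`.  Zero noise returns the curve
    unchanged.
    """
    if noise.is_null:
        return curve
    rng = np.random.default_rng(seed)
    t = curve.times.copy()
    s = curve.surv.copy()
    n = t.size
    protected = np.zeros(n, dtype=bool)
    protected[0] = True
    protected[-1] = True  # keep the curve's right edge
    for pt in protect_times:
        protected |= np.isclose(t, pt)
    keep = (rng.uniform(size=n) >= noise.drop_step_prob) | protected
    t, s, protected = t[keep], s[keep], protected[keep]
    jitter_t = rng.normal(0.0, noise.time_jitter_sd, size=t.size)
    jitter_s = rng.normal(0.0, noise.prob_jitter_sd, size=t.size)
    t = np.where(protected, t, np.maximum(t + jitter_t, 0.0))
    s = np.where(protected, s, np.clip(s + jitter_s, 0.0, 1.0))
    order = np.argsort(t, kind="mergesort")
    t, s = t[order], s[order]
    s[0] = 1.0
    raw = DigitizedCurve(curve.arm_label, t, s)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        repaired, _ = validate_and_repair(raw)
    return repaired


def pick_risk_times(curve: DigitizedCurve, n_intervals: int = 5) -> list[float]:
    """Choose published-style risk times among the curve's coordinates.

    Targets ``n_intervals`` equally spaced times over follow-up (as real
    publications print four or five), snapping each to the latest coordinate
    at or before it; duplicates collapse, so fewer intervals may result.
    The final coordinate is never chosen (the last interval needs room).
    """
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    t = curve.times
    targets = np.linspace(0.0, t[-1], n_intervals + 1)[:-1]
    rows = np.searchsorted(t, targets, side="right") - 1
    rows = np.unique(np.clip(rows, 0, t.size - 2))
    chosen = []
    for r in rows:
        if not chosen or t[r] > chosen[-1]:
            chosen.append(float(t[r]))
    return chosen


def make_risk_table(
    ipd: pd.DataFrame,
    times: Sequence[float],
    curve: DigitizedCurve,
) -> tuple[RiskTable, int]:
    """Derive the published-style risk table and event total for one arm.

    ``nrisk_i`` counts subjects with observed time >= ``trisk_i`` (at risk
    just before that time); row bounds follow the input-table convention:
    interval i runs from the coordinate at ``trisk_i`` up to the last
    coordinate before ``trisk_{i+1}``.  Each requested time must be one of
    the curve's coordinates.
    """
    times = list(times)
    if not times or times[0] != 0.0:
        raise ValueError("risk times must start at 0")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("risk times must be strictly increasing")
    t_curve = curve.times
    lower = []
    for tt in times:
        hits = np.nonzero(t_curve == tt)[0]
        if hits.size == 0:
            raise ConsistencyError(
                f"risk time {tt:g} is not a curve coordinate; include it among "
                f"the digitized points (published risk times must be clicked)"
            )
        lower.append(int(hits[0]) + 1)
    upper = [lo - 1 for lo in lower[1:]] + [curve.n_points]
    obs = ipd["time"].to_numpy(dtype=float)
    nrisk = [int(np.sum(obs >= tt)) for tt in times]
    table = RiskTable(
        trisk=np.array(times), lower=np.array(lower),
        upper=np.array(upper), nrisk=np.array(nrisk),
    )
    totevents = int(ipd["event"].sum())
    return table, totevents
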