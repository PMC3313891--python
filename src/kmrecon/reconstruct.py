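"""Reconstruction of Kaplan-Meier data from digitized curve coordinates.

The published KM plot is a pictorial encoding of the underlying life-table
counts.  Given the clicked coordinates (T_k, S_k), the numbers at risk
printed beneath the plot, and (when reported) the total number of events,
this module inverts the product-limit equations numerically:

1.  guess the number censored on each inter-risk-time interval from the
    drop in survival versus the drop in the published at-risk count;
2.  spread those censorings uniformly over the interval (constant-rate,
    non-informative censoring assumption) and bin them between clicks;
3.  walk the coordinates, converting each survival drop into an integer
    event count via the inverted product-limit step
    ``d_k = round(n_k * (1 - S_k / S_last))`` and propagating the at-risk
    count ``n_{k+1} = n_k - d_k - c_k``;
4.  iterate the censoring count until the propagated at-risk number at the
    next published risk time equals the published value;
5.  handle the last interval (no risk number at its end) by carrying the
    average censoring rate forward, and finally re-adjust its censoring
    until the total event count matches the published total, if reported.

Four information levels are supported, from ``all_information`` down to
``neither`` (no risk numbers beyond time 0 and no event total, in which
case censoring is assumed absent).  The whole procedure is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConsistencyError, ReconstructionWarning
from .types import (
    CensorPlan,
    DigitizedCurve,
    InfoLevel,
    IPDRecord,
    KMData,
    ReconstructionInput,
    RiskTable,
)

__all__ = [
    "round_half_even",
    "initial_censor_guess",
    "place_censor_times",
    "bin_censor_counts",
    "propagate_interval",
    "fit_interval",
    "process_last_interval",
    "match_total_events",
    "reconstruct",
    "derive_ipd",
    "EntryState",
    "ReconstructionResult",
]

#: Cap on the censoring re-adjustment loops (steps 4 and 8).  The update is
#: integer-valued and usually converges in a handful of passes; the cap plus
#: cycle detection guard against oscillation on inconsistent inputs.
MAX_FIT_ITERATIONS = 1000


def round_half_even(x) -> int:
    """Round to the nearest integer, ties to even.

    Every "rounded to the nearest integer" in the reconstruction goes through
    this single helper so the tie-break convention is stated once.
    """
    return int(np.rint(x))


@dataclass(frozen=True)
class EntryState:
    """Propagation state at the entry of a coordinate range.

    ``n_entry`` is the at-risk count just before the first coordinate of the
    range; ``last_k`` is the 1-based row of the most recent coordinate with
    an event and ``s_km_last`` the KM estimate there (1.0 at the start).
    """

    n_entry: int
    last_k: int = 1
    s_km_last: float = 1.0


@dataclass(frozen=True)
class IntervalSlice:
    """Per-coordinate output of propagating one coordinate range."""

    k_lo: int  # 1-based, inclusive
    k_hi: int  # 1-based, inclusive
    d: np.ndarray
    cen: np.ndarray
    n: np.ndarray  # at-risk at each coordinate of the range
    s_km: np.ndarray
    exit_state: EntryState  # n_entry = at-risk after coordinate k_hi


@dataclass
class Diagnostics:
    """Iteration counts and unresolved discrepancies of a reconstruction."""

    iterations: list[int] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    residuals: list[int] = field(default_factory=list)
    total_events_iterations: int = 0
    total_events_matched: Optional[bool] = None
    messages: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ReconstructionResult:
    km: KMData
    plan: CensorPlan
    diagnostics: Diagnostics


def initial_censor_guess(
    nrisk_i: int, s_next: float, s_cur: float, nrisk_next: int
) -> int:
    """Initial censoring count for an interval (step 1).

    Under no censoring the at-risk count at the next published risk time
    would be ``round(nrisk_i * s_next / s_cur)``; the shortfall of the
    published ``nrisk_next`` against that is attributed to censoring.
    Negative raw values (published risk number *larger* than explicable) are
    floored at 0 with a warning, since a risk set cannot grow.
    """
    if s_cur <= 0:
        raise ConsistencyError(
            "survival at the interval start is 0: the curve is degenerate and "
            "the censoring guess is undefined"
        )
    no_censor = round_half_even(nrisk_i * s_next / s_cur)
    guess = no_censor - nrisk_next
    if guess < 0:
        warnings.warn(
            f"initial censoring guess {guess} is negative (published number at "
            f"risk larger than the survival drop allows); floored at 0",
            ReconstructionWarning,
            stacklevel=2,
        )
        return 0
    return guess


def place_censor_times(ncensor: int, t_lo: float, t_hi: float) -> np.ndarray:
    """Spread ``ncensor`` censoring times evenly over (t_lo, t_hi) (step 2).

    Times are ``t_lo + c * (t_hi - t_lo) / (ncensor + 1)`` for c = 1..ncensor,
    strictly inside the interval.  ``ncensor = 0`` returns an empty array even
    on a zero-width interval (needed for degenerate final intervals).
    """
    if ncensor < 0:
        raise ValueError("ncensor must be non-negative")
    if ncensor == 0:
        return np.empty(0)
    if t_hi <= t_lo:
        raise ValueError(
            f"cannot place {ncensor} censor times on the empty interval "
            f"[{t_lo:g}, {t_hi:g}]"
        )
    c = np.arange(1, ncensor + 1, dtype=float)
    return t_lo + c * (t_hi - t_lo) / (ncensor + 1)


def bin_censor_counts(
    cen_times: Sequence[float], curve: DigitizedCurve, k_lo: int, k_hi: int
) -> np.ndarray:
    """Count censor times falling between consecutive coordinates (step 2).

    Returns, for each coordinate k = k_lo..k_hi (1-based), the number of
    censor times in the half-open bin [T_k, T_{k+1}); half-open so a time on
    a shared boundary is counted once.  Requires k_hi < N so the right edge
    T_{k_hi + 1} exists.
    """
    t = curve.times
    if not (1 <= k_lo <= k_hi < curve.n_points):
        raise ValueError(f"coordinate range {k_lo}..{k_hi} invalid for curve of "
                         f"{curve.n_points} points (need k_hi < N)")
    edges = t[k_lo - 1 : k_hi + 1]  # T_{k_lo} .. T_{k_hi + 1}
    times = np.asarray(cen_times, dtype=float)
    counts = np.zeros(k_hi - k_lo + 1, dtype=int)
    if times.size == 0:
        return counts
    # side='right' makes each bin [T_k, T_{k+1}) half-open on the right
    idx = np.searchsorted(edges, times, side="right") - 1
    idx = np.clip(idx, 0, counts.size - 1)
    np.add.at(counts, idx, 1)
    return counts


def propagate_interval(
    curve: DigitizedCurve,
    k_lo: int,
    k_hi: int,
    state: EntryState,
    cen_counts: np.ndarray,
) -> IntervalSlice:
    """Convert survival drops into integer event counts over k_lo..k_hi (step 3).

    For each coordinate the inverted product-limit step gives
    ``d_k = round(n_k * (1 - S_k / S_last))`` where ``S_last`` is the KM
    estimate at the most recent coordinate with an event; the at-risk count
    then propagates by ``n_{k+1} = n_k - d_k - c_k``.  Event counts are
    clamped to [0, n_k]; censor counts are reduced if they would drive the
    risk set negative; once the risk set or the KM estimate hits 0, further
    event counts are forced to 0 (with a warning if the digitized curve still
    decreases).
    """
    m = k_hi - k_lo + 1
    if len(cen_counts) != m:
        raise ValueError("cen_counts must have one entry per coordinate in range")
    s = curve.surv
    d = np.zeros(m, dtype=int)
    cen = np.asarray(cen_counts, dtype=int).copy()
    n = np.zeros(m + 1, dtype=int)
    s_km = np.zeros(m, dtype=float)
    n_cur = int(state.n_entry)
    last_k = state.last_k
    s_last = state.s_km_last
    warned_exhausted = False
    for j, k in enumerate(range(k_lo, k_hi + 1)):
        n[j] = n_cur
        sk = s[k - 1]
        if k == 1:
            dk = 0
            s_km[j] = 1.0
        elif n_cur <= 0 or s_last <= 0:
            dk = 0
            s_km[j] = s_last if s_last > 0 else 0.0
            if sk < s[k - 2] - 1e-12 and not warned_exhausted:
                warnings.warn(
                    f"risk set exhausted at row {k} while the digitized curve "
                    f"still decreases; remaining events forced to 0",
                    ReconstructionWarning,
                    stacklevel=2,
                )
                warned_exhausted = True
        else:
            dk = round_half_even(n_cur * (1.0 - sk / s_last))
            dk = min(max(dk, 0), n_cur)
            s_km[j] = s_last * (1.0 - dk / n_cur)
        if dk > 0:
            last_k = k
            s_last = s_km[j]
        ck = cen[j]
        if n_cur - dk - ck < 0:
            ck = n_cur - dk  # a risk set cannot go negative
            cen[j] = ck
        n_cur = n_cur - dk - ck
        d[j] = dk
    n[m] = n_cur
    return IntervalSlice(
        k_lo=k_lo,
        k_hi=k_hi,
        d=d,
        cen=cen,
        n=n,
        s_km=s_km,
        exit_state=EntryState(n_entry=n_cur, last_k=last_k, s_km_last=s_last),
    )


def _fit_censoring(
    curve: DigitizedCurve,
    k_lo: int,
    k_hi: int,
    t_hi: float,
    state: EntryState,
    ncensor0: int,
    target: int,
) -> tuple[IntervalSlice, int, np.ndarray, int, bool]:
    """Iterate steps 2-3, adjusting the censoring count until the propagated
    at-risk count after ``k_hi`` hits ``target`` (step 4 / step 8 inner loop).

    Returns (slice, ncensor, cen_times, iterations, converged).  Stops early
    when the target is unreachable (undershoot with zero censoring), on a
    repeated censoring count (cycle) or at the iteration cap, returning the
    best state visited.
    """
    t_lo = curve.times[k_lo - 1]
    span_empty = t_hi <= t_lo
    ncensor = max(int(ncensor0), 0)
    if span_empty:
        ncensor = 0

    def run(nc: int) -> tuple[IntervalSlice, np.ndarray]:
        times = place_censor_times(nc, t_lo, t_hi) if nc else np.empty(0)
        counts = bin_censor_counts(times, curve, k_lo, k_hi) if times.size \
            else np.zeros(k_hi - k_lo + 1, dtype=int)
        return propagate_interval(curve, k_lo, k_hi, state, counts), times

    seen: set[int] = set()
    best: Optional[tuple[int, int]] = None  # (|residual|, ncensor)
    iterations = 0
    converged = False
    # candidate states are explored silently; only the accepted state below
    # may emit user-facing warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ReconstructionWarning)
        while True:
            iterations += 1
            sl, _ = run(ncensor)
            residual = sl.exit_state.n_entry - target
            if residual == 0:
                converged = True
                break
            if best is None or abs(residual) < best[0]:
                best = (abs(residual), ncensor)
            if ncensor in seen or iterations >= MAX_FIT_ITERATIONS or span_empty:
                ncensor = best[1]
                break
            seen.add(ncensor)
            if residual < 0 and ncensor == 0:
                break  # undershoot with no censoring left to remove: unattainable
            ncensor = max(ncensor + residual, 0)
    sl, times = run(ncensor)
    return sl, ncensor, times, iterations, converged


def fit_interval(
    curve: DigitizedCurve,
    risk: RiskTable,
    i: int,
    state: EntryState,
) -> tuple[IntervalSlice, int, np.ndarray, int, bool]:
    """Fit one inner risk interval i (1-based, i < nint): steps 1-4.

    Returns (slice, ncensor_i, cen_times_i, iterations, converged).  On
    non-convergence a warning reports the residual discrepancy and the best
    state visited is returned; the caller then chains the next interval off
    the *propagated* at-risk count so the life-table identity stays exact.
    """
    if not (1 <= i < risk.n_intervals):
        raise ValueError("fit_interval applies to intervals before the last")
    k_lo = int(risk.lower[i - 1])
    k_hi = int(risk.upper[i - 1])
    k_next = int(risk.lower[i])  # first row of interval i+1; T there = trisk_{i+1}
    target = int(risk.nrisk[i])
    s = curve.surv
    guess = initial_censor_guess(
        state.n_entry, s[k_next - 1], s[k_lo - 1], target
    )
    sl, ncensor, times, iterations, converged = _fit_censoring(
        curve, k_lo, k_hi, curve.times[k_next - 1], state, guess, target
    )
    if not converged:
        warnings.warn(
            f"interval {i}: censoring adjustment did not reach the published "
            f"number at risk {target} (got {sl.exit_state.n_entry} after "
            f"{iterations} passes); continuing from the propagated count",
            ReconstructionWarning,
            stacklevel=2,
        )
    return sl, ncensor, times, iterations, converged


def process_last_interval(
    curve: DigitizedCurve,
    risk: RiskTable,
    state: EntryState,
    prior_ncensor: Sequence[int],
) -> tuple[IntervalSlice, int, np.ndarray]:
    """Steps 2-3 on the final interval with a carried-forward censoring rate.

    No number at risk is published at the end of the last interval, so its
    censoring count is the total censored so far scaled by the span of the
    last interval relative to the time already elapsed, capped at the number
    still at risk.  With a single interval (no prior censoring information)
    the count is 0.
    """
    nint = risk.n_intervals
    k_lo = int(risk.lower[nint - 1])
    k_hi = int(risk.upper[nint - 1])
    t = curve.times
    if nint == 1 or len(prior_ncensor) == 0:
        ncensor = 0
    else:
        elapsed = t[k_lo - 2] - t[0]  # T_{upper_{nint-1}} - T_{lower_1}
        span = t[k_hi - 1] - t[k_lo - 1]
        if elapsed <= 0:
            ncensor = 0
        else:
            ncensor = min(
                round_half_even(span / elapsed * sum(prior_ncensor)),
                int(risk.nrisk[nint - 1]),
            )
        ncensor = max(ncensor, 0)
    times = _place_last_interval(curve, k_lo, k_hi, ncensor)
    counts = _bin_last_interval(curve, k_lo, k_hi, times)
    sl = propagate_interval(curve, k_lo, k_hi, state, counts)
    return sl, ncensor, times


def _place_last_interval(
    curve: DigitizedCurve, k_lo: int, k_hi: int, ncensor: int
) -> np.ndarray:
    """Censor times for the last interval are spread over [T_{k_lo}, T_{k_hi}]."""
    t = curve.times
    if k_hi == k_lo or t[k_hi - 1] <= t[k_lo - 1]:
        return np.empty(0)
    return place_censor_times(ncensor, t[k_lo - 1], t[k_hi - 1])


def _bin_last_interval(
    curve: DigitizedCurve, k_lo: int, k_hi: int, times: np.ndarray
) -> np.ndarray:
    """Bin last-interval censor times; the final coordinate gets none."""
    counts = np.zeros(k_hi - k_lo + 1, dtype=int)
    if times.size and k_hi > k_lo:
        counts[:-1] = bin_censor_counts(times, curve, k_lo, k_hi - 1)
    return counts


def match_total_events(
    curve: DigitizedCurve,
    risk: RiskTable,
    totevents: int,
    entry: EntryState,
    events_before_last: int,
    last_slice: IntervalSlice,
    ncensor_last: int,
    diagnostics: Diagnostics,
) -> tuple[IntervalSlice, int, np.ndarray]:
    """Steps 7-8: re-adjust last-interval censoring to hit the event total.

    If the events accrued before the last interval already reach the
    published total, the last interval is frozen (no further events or
    censorings).  Otherwise the last-interval censoring count is shifted by
    the running surplus of events until the total matches or the censoring
    count reaches zero.
    """
    if totevents < 0:
        raise ValueError("totevents must be non-negative")
    nint = risk.n_intervals
    k_lo = int(risk.lower[nint - 1])
    k_hi = int(risk.upper[nint - 1])
    if nint > 1 and events_before_last >= totevents:
        m = k_hi - k_lo + 1
        frozen = IntervalSlice(
            k_lo=k_lo,
            k_hi=k_hi,
            d=np.zeros(m, dtype=int),
            cen=np.zeros(m, dtype=int),
            n=np.full(m + 1, entry.n_entry, dtype=int),
            s_km=np.full(m, entry.s_km_last, dtype=float),
            exit_state=entry,
        )
        diagnostics.total_events_matched = events_before_last == totevents
        if events_before_last > totevents:
            warnings.warn(
                f"events accrued before the last interval ({events_before_last}) "
                f"already exceed the published total ({totevents}); the last "
                f"interval is frozen",
                ReconstructionWarning,
                stacklevel=2,
            )
        return frozen, 0, np.empty(0)

    t = curve.times
    span_empty = k_hi == k_lo or t[k_hi - 1] <= t[k_lo - 1]

    def run(nc: int) -> tuple[IntervalSlice, np.ndarray]:
        times = _place_last_interval(curve, k_lo, k_hi, nc)
        counts = _bin_last_interval(curve, k_lo, k_hi, times)
        return propagate_interval(curve, k_lo, k_hi, entry, counts), times

    sl = last_slice
    ncensor = ncensor_last
    seen: set[int] = set()
    best: Optional[tuple[int, int]] = None
    iterations = 0
    stalled = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ReconstructionWarning)
        while True:
            sumd = events_before_last + int(sl.d.sum())
            residual = sumd - totevents
            if residual == 0 or (residual < 0 and ncensor == 0):
                break
            if best is None or abs(residual) < best[0]:
                best = (abs(residual), ncensor)
            if ncensor in seen or iterations >= MAX_FIT_ITERATIONS or span_empty:
                ncensor = best[1]
                stalled = True
                break
            seen.add(ncensor)
            iterations += 1
            ncensor = max(ncensor + residual, 0)
            sl, _ = run(ncensor)
    sl, times = run(ncensor)
    if stalled:
        warnings.warn(
            f"event-total adjustment stalled with "
            f"{events_before_last + int(sl.d.sum())} events against a published "
            f"total of {totevents}",
            ReconstructionWarning,
            stacklevel=2,
        )
    diagnostics.total_events_iterations = iterations
    diagnostics.total_events_matched = (
        events_before_last + int(sl.d.sum()) == totevents
    )
    return sl, ncensor, times


def reconstruct(inp: ReconstructionInput) -> ReconstructionResult:
    """Run the full reconstruction for one arm at its information level.

    Orchestrates the steps according to ``inp.info_level``:

    * ``all_information``: iterate censoring per risk interval, carry the
      censoring rate into the last interval, then match the event total;
    * ``no_total_events``: the same without the final event-total adjustment;
    * ``no_numbers_at_risk``: one interval, censoring starts at 0 and is
      adjusted against the event total only;
    * ``neither``: no censoring anywhere, a single inversion pass.
    """
    curve = inp.curve
    risk = inp.risk
    level = inp.info_level
    n_pts = curve.n_points
    nint = risk.n_intervals
    diag = Diagnostics()

    d = np.zeros(n_pts, dtype=int)
    cen = np.zeros(n_pts, dtype=int)
    n_hat = np.zeros(n_pts + 1, dtype=int)
    s_km = np.ones(n_pts, dtype=float)

    state = EntryState(n_entry=int(risk.nrisk[0]), last_k=1, s_km_last=1.0)
    plan_counts: list[int] = []
    plan_times: list[np.ndarray] = []

    def paste(sl: IntervalSlice) -> None:
        lo, hi = sl.k_lo - 1, sl.k_hi
        d[lo:hi] = sl.d
        cen[lo:hi] = sl.cen
        n_hat[lo:hi] = sl.n[:-1]
        n_hat[hi] = sl.n[-1]
        s_km[lo:hi] = sl.s_km

    if level is InfoLevel.NEITHER:
        sl = propagate_interval(curve, 1, n_pts, state, np.zeros(n_pts, dtype=int))
        paste(sl)
        plan_counts.append(0)
        plan_times.append(np.empty(0))
        state = sl.exit_state
    else:
        for i in range(1, nint):
            sl, nc, times, iters, ok = fit_interval(curve, risk, i, state)
            paste(sl)
            plan_counts.append(nc)
            plan_times.append(times)
            diag.iterations.append(iters)
            diag.converged.append(ok)
            diag.residuals.append(sl.exit_state.n_entry - int(risk.nrisk[i]))
            state = sl.exit_state

        entry_last = state
        refit_against_total = level in (
            InfoLevel.ALL_INFORMATION, InfoLevel.NO_NUMBERS_AT_RISK
        )
        with warnings.catch_warnings():
            if refit_against_total:
                # provisional pass: step 7/8 will re-fit the last interval
                warnings.simplefilter("ignore", ReconstructionWarning)
            sl, nc_last, times_last = process_last_interval(
                curve, risk, entry_last, plan_counts
            )
        if refit_against_total:
            events_before = int(d[: int(risk.lower[nint - 1]) - 1].sum())
            sl, nc_last, times_last = match_total_events(
                curve,
                risk,
                int(inp.totevents),  # type: ignore[arg-type]
                entry_last,
                events_before,
                sl,
                nc_last,
                diag,
            )
        paste(sl)
        plan_counts.append(int(sl.cen.sum()))
        plan_times.append(times_last)
        state = sl.exit_state

    km = KMData(
        times=curve.times.copy(),
        d_hat=d,
        cen_hat=cen,
        n_hat=n_hat,
        s_km=s_km,
        last_k=state.last_k,
    )
    plan = _consistent_plan(plan_counts, plan_times, km, risk)
    return ReconstructionResult(km=km, plan=plan, diagnostics=diag)


def _consistent_plan(
    counts: list[int], times: list[np.ndarray], km: KMData, risk: RiskTable
) -> CensorPlan:
    """Reconcile planned censor times with the per-coordinate counts.

    Propagation can trim censorings that would overdraw the risk set, so the
    plan is rebuilt from the realized ``cen_hat`` totals, truncating the
    placed times where needed.
    """
    out_counts: list[int] = []
    out_times: list[np.ndarray] = []
    for i in range(risk.n_intervals if len(counts) == risk.n_intervals else len(counts)):
        if len(counts) == risk.n_intervals:
            lo, hi = int(risk.lower[i]) - 1, int(risk.upper[i])
        else:  # 'neither': a single pseudo-interval spanning the curve
            lo, hi = 0, km.n_points
        realized = int(km.cen_hat[lo:hi].sum())
        t = np.asarray(times[i], dtype=float)[:realized] if realized else np.empty(0)
        if t.size < realized:  # pad at the interval midpoint as a fallback
            mid = (km.times[lo] + km.times[hi - 1]) / 2.0
            t = np.concatenate([t, np.full(realized - t.size, mid)])
        out_counts.append(realized)
        out_times.append(t)
    return CensorPlan(ncensor=tuple(out_counts), cen_times=tuple(out_times))


def derive_ipd(
    km: KMData,
    plan: CensorPlan,
    curve: DigitizedCurve,
    arm: str = "",
) -> list[IPDRecord]:
    """Turn reconstructed KM data into approximate individual patient data.

    Each estimated event at coordinate k contributes a record (T_k, 1); each
    estimated censoring contributes a record at its placed censor time with
    indicator 0.  Subjects still at risk after the final coordinate leave the
    data censored at T_N, so the record count always equals the initial
    number at risk.
    """
    arm = arm or curve.arm_label
    records: list[IPDRecord] = []
    t = km.times
    n = km.n_points
    for k in range(n):
        records.extend([IPDRecord(float(t[k]), 1, arm)] * int(km.d_hat[k]))
    # censor records at their planned times, matched per coordinate bin
    pool = np.sort(np.concatenate([np.asarray(ts) for ts in plan.cen_times])) \
        if plan.cen_times else np.empty(0)
    used = 0
    for k in range(n):
        c = int(km.cen_hat[k])
        if c == 0:
            continue
        lo_t = t[k]
        hi_t = t[k + 1] if k + 1 < n else np.inf
        in_bin = pool[(pool >= lo_t) & (pool < hi_t)] if pool.size else np.empty(0)
        take = in_bin[:c]
        used += take.size
        for tc in take:
            records.append(IPDRecord(float(tc), 0, arm))
        for _ in range(c - take.size):  # fallback: midpoint of the bin
            mid = (lo_t + (t[k + 1] if k + 1 < n else lo_t)) / 2.0
            records.append(IPDRecord(float(mid), 0, arm))
    for _ in range(km.n_after_final):
        records.append(IPDRecord(float(t[-1]), 0, arm))
    return records
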