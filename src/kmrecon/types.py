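"""Core domain types.

The reconstruction works with four kinds of object:

* :class:`DigitizedCurve` -- the (time, survival) coordinates clicked off a
  published Kaplan-Meier plot, one curve per treatment arm;
* :class:`RiskTable` -- the numbers at risk printed beneath the plot,
  together with the coordinate rows that each risk interval spans;
* :class:`KMData` -- the reconstructed per-coordinate counts (events,
  censorings, at-risk) and the product-limit estimate they imply;
* :class:`IPDRecord` -- one (time, event indicator, arm) row per subject of
  the approximate individual patient data derived from :class:`KMData`.

Coordinate rows are 1-based throughout the public interface, matching the
layout of the input tables; internal arrays are plain 0-based numpy arrays.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError, InputFormatError

__all__ = [
    "DigitizedCurve",
    "RiskTable",
    "InfoLevel",
    "ReconstructionInput",
    "KMData",
    "CensorPlan",
    "IPDRecord",
    "ipd_to_frame",
    "ipd_from_frame",
]


class IPDRecord(NamedTuple):
    """One subject of the reconstructed individual patient data."""

    time: float
    event: int  # 1 = event, 0 = censored
    arm: str


def ipd_to_frame(records: Sequence[IPDRecord]) -> pd.DataFrame:
    """Convert IPD records to a ``time, event, arm`` data frame."""
    return pd.DataFrame(records, columns=["time", "event", "arm"])


def ipd_from_frame(frame: pd.DataFrame) -> list[IPDRecord]:
    """Convert a ``time, event, arm`` data frame to IPD records."""
    return [
        IPDRecord(float(t), int(e), str(a))
        for t, e, a in zip(frame["time"], frame["event"], frame["arm"])
    ]


@dataclass(frozen=True)
class DigitizedCurve:
    """Ordered (T_k, S_k) coordinates read off one published KM curve.

    Parameters
    ----------
    arm_label:
        Name of the treatment arm the curve belongs to.
    times:
        x-axis coordinates T_k (k = 1..N), non-decreasing, T_1 = 0.
    surv:
        y-axis coordinates S_k, survival probabilities with S_1 = 1.
        Monotonicity of ``surv`` is *not* enforced here: click error can
        produce small inversions which :func:`kmrecon.io.validate_and_repair`
        clamps away.
    """

    arm_label: str
    times: np.ndarray
    surv: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.surv, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "surv", s)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise InputFormatError("times and surv must be 1-d arrays of equal length")
        if t.size < 2:
            raise InputFormatError("a digitized curve needs at least 2 coordinates")
        if t[0] != 0.0:
            raise InputFormatError(
                f"first coordinate must be at time 0 (convention T_1 = 0), got {t[0]!r}"
            )
        if s[0] != 1.0:
            raise InputFormatError(
                f"first coordinate must have survival 1 (convention S_1 = 1), got {s[0]!r}"
            )
        if np.any(np.diff(t) < 0):
            k = int(np.argmax(np.diff(t) < 0)) + 2
            raise InputFormatError(f"times must be non-decreasing; violated at row {k}")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:
        return self.n_points

    def is_monotone(self) -> bool:
        """True if S_k is non-increasing (i.e. no repair is needed)."""
        return bool(np.all(np.diff(self.surv) <= 0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": np.arange(1, self.n_points + 1),
                "time": self.times,
                "surv": self.surv,
            }
        )


@dataclass(frozen=True)
class RiskTable:
    """Published numbers at risk plus the coordinate rows each interval spans.

    ``lower`` and ``upper`` are 1-based coordinate rows of the companion
    :class:`DigitizedCurve`: interval i starts at row ``lower[i]`` (whose time
    equals ``trisk[i]``) and ends at the last row before the next published
    risk time.
    """

    trisk: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    nrisk: np.ndarray

    def __post_init__(self) -> None:
        tr = np.asarray(self.trisk, dtype=float)
        lo = np.asarray(self.lower, dtype=int)
        up = np.asarray(self.upper, dtype=int)
        nr = np.asarray(self.nrisk, dtype=int)
        for name, arr in (("trisk", tr), ("lower", lo), ("upper", up), ("nrisk", nr)):
            if arr.ndim != 1 or arr.size != tr.size:
                raise InputFormatError(f"risk-table column {name!r} has wrong shape")
        if tr.size < 1:
            raise InputFormatError("risk table needs at least one interval")
        object.__setattr__(self, "trisk", tr)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        object.__setattr__(self, "nrisk", nr)
        if tr[0] != 0.0:
            raise ConsistencyError("first risk interval must start at time 0")
        if lo[0] != 1:
            raise ConsistencyError("first risk interval must start at coordinate row 1")
        if np.any(lo > up):
            i = int(np.argmax(lo > up)) + 1
            raise ConsistencyError(f"interval {i}: lower row exceeds upper row")
        if np.any(lo[1:] != up[:-1] + 1):
            i = int(np.argmax(lo[1:] != up[:-1] + 1)) + 2
            raise ConsistencyError(
                f"interval {i}: rows are not contiguous (lower must be previous upper + 1)"
            )
        if np.any(np.diff(tr) <= 0):
            raise ConsistencyError("risk times must be strictly increasing")
        if np.any(nr <= 0):
            raise ConsistencyError("number at risk must be strictly positive")
        if np.any(np.diff(nr) > 0):
            raise ConsistencyError("number at risk must be non-increasing")

    @property
    def n_intervals(self) -> int:
        return int(self.trisk.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": np.arange(1, self.n_intervals + 1),
                "trisk": self.trisk,
                "lower": self.lower,
                "upper": self.upper,
                "nrisk": self.nrisk,
            }
        )


class InfoLevel(str, enum.Enum):
    """Which published auxiliaries accompany the digitized curve."""

    ALL_INFORMATION = "all_information"
    NO_NUMBERS_AT_RISK = "no_numbers_at_risk"
    NO_TOTAL_EVENTS = "no_total_events"
    NEITHER = "neither"


@dataclass(frozen=True)
class ReconstructionInput:
    """A validated bundle of everything the reconstruction needs for one arm."""

    curve: DigitizedCurve
    risk: RiskTable
    totevents: Optional[int] = None
    info_level: InfoLevel = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        level = self.info_level
        if level is None:
            level = self.infer_level(self.risk, self.totevents)
        else:
            level = InfoLevel(level)
        object.__setattr__(self, "info_level", level)
        if self.totevents is not None and self.totevents < 0:
            raise ConfigurationError("totevents must be non-negative")
        nint = self.risk.n_intervals
        has_tot = self.totevents is not None
        if level is InfoLevel.ALL_INFORMATION and (nint < 2 or not has_tot):
            raise ConfigurationError(
                "'all_information' requires numbers at risk beyond time 0 "
                "(>= 2 risk intervals) and a total event count"
            )
        if level is InfoLevel.NO_NUMBERS_AT_RISK and (nint != 1 or not has_tot):
            raise ConfigurationError(
                "'no_numbers_at_risk' requires a single risk interval and a total event count"
            )
        if level is InfoLevel.NO_TOTAL_EVENTS and nint < 2:
            raise ConfigurationError(
                "'no_total_events' requires numbers at risk beyond time 0"
            )
        if level is InfoLevel.NEITHER and nint != 1:
            raise ConfigurationError(
                "'neither' uses only the time-0 number at risk; collapse the risk "
                "table to a single interval (see ReconstructionInput.at_level)"
            )
        up = self.risk.upper
        if up[-1] != self.curve.n_points:
            raise ConsistencyError(
                f"last risk interval must end at the final coordinate row "
                f"{self.curve.n_points}, got {int(up[-1])}"
            )

    @staticmethod
    def infer_level(risk: RiskTable, totevents: Optional[int]) -> InfoLevel:
        multi = risk.n_intervals >= 2
        has_tot = totevents is not None
        if multi and has_tot:
            return InfoLevel.ALL_INFORMATION
        if not multi and has_tot:
            return InfoLevel.NO_NUMBERS_AT_RISK
        if multi:
            return InfoLevel.NO_TOTAL_EVENTS
        return InfoLevel.NEITHER

    def at_level(self, level: InfoLevel | str) -> "ReconstructionInput":
        """Return a copy degraded to a (possibly) poorer information level.

        Collapses the risk table to a single time-0 interval and/or drops the
        total event count as required by ``level``.  Used to study how the
        reconstruction deteriorates when publications omit auxiliaries.
        """
        level = InfoLevel(level)
        risk = self.risk
        tot = self.totevents
        if level in (InfoLevel.NO_NUMBERS_AT_RISK, InfoLevel.NEITHER):
            risk = RiskTable(
                trisk=[0.0],
                lower=[1],
                upper=[self.curve.n_points],
                nrisk=[int(self.risk.nrisk[0])],
            )
        if level in (InfoLevel.NO_TOTAL_EVENTS, InfoLevel.NEITHER):
            tot = None
        return ReconstructionInput(self.curve, risk, tot, level)


@dataclass(frozen=True)
class KMData:
    """Reconstructed Kaplan-Meier data for one arm.

    Arrays are indexed by coordinate k = 1..N (0-based internally).  ``n_hat``
    has length N + 1: ``n_hat[N]`` is the number of subjects still at risk
    after the final coordinate (they leave the study event-free).
    """

    times: np.ndarray
    d_hat: np.ndarray
    cen_hat: np.ndarray
    n_hat: np.ndarray
    s_km: np.ndarray
    last_k: int  # 1-based row of the most recent coordinate with an event

    def __post_init__(self) -> None:
        n = self.times.size
        if not (self.d_hat.size == self.cen_hat.size == self.s_km.size == n):
            raise ValueError("KMData arrays have inconsistent lengths")
        if self.n_hat.size != n + 1:
            raise ValueError("n_hat must have one entry per coordinate plus the exit count")

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def n_after_final(self) -> int:
        """Subjects still at risk after the last coordinate."""
        return int(self.n_hat[-1])

    @property
    def total_events(self) -> int:
        return int(self.d_hat.sum())

    @property
    def total_censored(self) -> int:
        return int(self.cen_hat.sum())

    def to_frame(self) -> pd.DataFrame:
        n = self.n_points
        return pd.DataFrame(
            {
                "k": np.arange(1, n + 1),
                "time": self.times,
                "n_hat": self.n_hat[:n],
                "d_hat": self.d_hat,
                "cen_hat": self.cen_hat,
                "S_km": self.s_km,
            }
        )


@dataclass(frozen=True)
class CensorPlan:
    """Estimated censoring pattern: count and times per risk-table interval."""

    ncensor: tuple[int, ...]
    cen_times: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.ncensor) != len(self.cen_times):
            raise ValueError("ncensor and cen_times must align per interval")
        for n, t in zip(self.ncensor, self.cen_times):
            if len(t) != n:
                raise ValueError("cen_times length must equal ncensor for every interval")

    @property
    def total(self) -> int:
        return int(sum(self.ncensor))
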