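"""Reading, validating and writing the delimited-text formats.

Two inputs drive a reconstruction:

* a *curve file*: the (time, survival) coordinates exported by graph-reading
  software, two numeric columns with an optional leading row-index column;
* a *risk file*: five columns ``i, trisk, lower, upper, nrisk`` giving, for
  each interval between published risk times, the time, the coordinate rows
  it spans and the published number at risk at its start.

Both accept comma- or tab-delimited text (auto-detected) with an optional
header row; outputs are always comma-delimited with a header.
"""

from __future__ import annotations

import csv
import os
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputFormatError, RepairWarning
from .types import DigitizedCurve, IPDRecord, KMData, RiskTable, ipd_to_frame

__all__ = [
    "read_curve",
    "read_risk_table",
    "validate_and_repair",
    "write_ipd",
    "read_ipd",
    "write_km_data",
]

#: Tolerance for matching a published risk time against a curve coordinate:
#: absolute + relative slack, since digitized times are never exact.
TIME_ATOL = 1e-6
TIME_RTOL = 1e-4


def _read_table(path: str) -> pd.DataFrame:
    """Read a comma- or tab-delimited numeric table, skipping a header row."""
    with open(path, "r", newline="") as fh:
        sample = fh.read(4096)
    if not sample.strip():
        raise InputFormatError(f"{path}: file is empty")
    delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
    df = pd.read_csv(path, sep=delimiter, header=None, comment="#",
                     skip_blank_lines=True)
    # A non-numeric first row is a header; anything non-numeric later is an error.
    first = df.iloc[0]
    if not all(_is_number(v) for v in first):
        df = df.iloc[1:].reset_index(drop=True)
    for r in range(len(df)):
        for c in range(df.shape[1]):
            if not _is_number(df.iat[r, c]):
                raise InputFormatError(
                    f"{path}: non-numeric value {df.iat[r, c]!r} in data row {r + 1}"
                )
    return df.astype(float)


def _is_number(v) -> bool:
    try:
        float(v)
    except (TypeError, ValueError):
        return False
    return True


def read_curve(path: str, arm_label: str = "") -> DigitizedCurve:
    """Read a digitized-curve file into a :class:`DigitizedCurve`.

    The file must have two numeric columns (time, survival); a leading
    row-index column is detected by column count and discarded.  The first
    data row must be ``(0, 1)``; anomalies elsewhere (non-monotone survival)
    are deliberately left in place for :func:`validate_and_repair`.
    """
    df = _read_table(path)
    if df.shape[1] == 3:
        df = df.iloc[:, 1:]
    elif df.shape[1] != 2:
        raise InputFormatError(
            f"{path}: expected 2 columns (time, survival), optionally preceded "
            f"by a row index; found {df.shape[1]}"
        )
    if len(df) < 2:
        raise InputFormatError(f"{path}: a curve needs at least 2 coordinate rows")
    t = df.iloc[:, 0].to_numpy()
    s = df.iloc[:, 1].to_numpy()
    if t[0] != 0.0 or s[0] != 1.0:
        raise InputFormatError(
            f"{path}: row 1 must be (0, 1) -- by convention the curve starts at "
            f"time 0 with survival 1; got ({t[0]!r}, {s[0]!r})"
        )
    return DigitizedCurve(arm_label=arm_label, times=t, surv=s)


def read_risk_table(path: str) -> RiskTable:
    """Read a five-column risk file ``i, trisk, lower, upper, nrisk``."""
    df = _read_table(path)
    if df.shape[1] != 5:
        raise InputFormatError(
            f"{path}: expected 5 columns (i, trisk, lower, upper, nrisk), "
            f"found {df.shape[1]}"
        )
    df = df.sort_values(df.columns[0]).reset_index(drop=True)
    try:
        return RiskTable(
            trisk=df.iloc[:, 1].to_numpy(),
            lower=df.iloc[:, 2].to_numpy().astype(int),
            upper=df.iloc[:, 3].to_numpy().astype(int),
            nrisk=df.iloc[:, 4].to_numpy().astype(int),
        )
    except (ConsistencyError, InputFormatError) as exc:
        raise type(exc)(f"{path}: {exc}") from None


def validate_and_repair(
    curve: DigitizedCurve,
    risk: Optional[RiskTable] = None,
    *,
    strict: bool = False,
) -> tuple[DigitizedCurve, list[str]]:
    """Clamp digitization anomalies and cross-check curve against risk table.

    Survival values that *increase* from one coordinate to the next -- click
    error, per the input conventions -- are clamped down to the running
    minimum and logged; values outside [0, 1] are clipped.  With
    ``strict=True`` any such anomaly raises instead.  If a risk table is
    given, every ``trisk_i`` must match ``T_{lower_i}`` within a small
    absolute+relative tolerance and all rows must lie inside the curve.

    Returns the repaired curve and the list of repair messages (empty when
    the curve was already consistent).  Idempotent: repairing a repaired
    curve is the identity.
    """
    log: list[str] = []
    s = curve.surv.copy()
    clipped = np.clip(s, 0.0, 1.0)
    for k in np.nonzero(clipped != s)[0]:
        log.append(f"row {k + 1}: survival {s[k]:g} outside [0, 1], clipped")
    s = clipped
    for k in range(1, s.size):
        if s[k] > s[k - 1]:
            log.append(
                f"row {k + 1}: survival {s[k]:g} exceeds previous value "
                f"{s[k - 1]:g}, clamped (monotonicity repair)"
            )
            s[k] = s[k - 1]
    if log:
        if strict:
            raise InputFormatError(
                "curve anomalies in strict mode: " + "; ".join(log)
            )
        for msg in log:
            warnings.warn(msg, RepairWarning, stacklevel=2)
    repaired = DigitizedCurve(curve.arm_label, curve.times, s)

    if risk is not None:
        n = curve.n_points
        if np.any(risk.lower < 1) or np.any(risk.upper > n):
            raise ConsistencyError(
                f"risk-table rows must lie within coordinate rows 1..{n}"
            )
        for i in range(risk.n_intervals):
            t_curve = curve.times[risk.lower[i] - 1]
            tol = TIME_ATOL + TIME_RTOL * abs(risk.trisk[i])
            if abs(t_curve - risk.trisk[i]) > tol:
                raise ConsistencyError(
                    f"interval {i + 1}: published risk time {risk.trisk[i]:g} does "
                    f"not match curve time {t_curve:g} at row {int(risk.lower[i])}; "
                    f"the digitized coordinates must include every published risk time"
                )
    return repaired, log


def write_ipd(records: Sequence[IPDRecord], path: str) -> None:
    """Write IPD records as comma-delimited text with header ``time,event,arm``.

    Rows are sorted by time then event indicator so output is canonical;
    re-reading with :func:`read_ipd` reproduces the records exactly.
    """
    if len(records) == 0:
        raise InputFormatError("refusing to write an empty IPD file")
    frame = ipd_to_frame(records).sort_values(
        ["time", "event", "arm"], kind="mergesort"
    )
    frame.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)


def read_ipd(path: str) -> list[IPDRecord]:
    """Read an IPD file written by :func:`write_ipd`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time", "event", "arm"} - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing IPD columns {sorted(missing)}")
    return [
        IPDRecord(float(t), int(e), str(a))
        for t, e, a in zip(df["time"], df["event"], df["arm"])
    ]


def write_km_data(km: KMData, path: str) -> None:
    """Write reconstructed KM data as ``k,time,n_hat,d_hat,cen_hat,S_km``."""
    km.to_frame().to_csv(path, index=False)


def ensure_parent(path: str) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
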