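"""Built-in worked example.

The package ships the digitized coordinates of one published Kaplan-Meier
curve: locoregional control in the radiotherapy arm of a head-and-neck
cancer trial, clicked between 0 and 10 months (31 coordinates), together
with the first rows of its published number-at-risk table (213 patients at
risk at month 0, 122 at month 10).  This is the standard first-interval
example for exercising the reconstruction on real digitized input without
any external file.
"""

from __future__ import annotations

import numpy as np

from .types import DigitizedCurve, ReconstructionInput, RiskTable

__all__ = ["load_example_curve", "load_example_risk_table", "load_example_input"]

# (time in months, locoregional control probability), 31 digitized clicks
_EXAMPLE_COORDS = [
    (0.0, 1.0),
    (0.18, 0.994),
    (0.42, 0.989),
    (0.91, 0.979),
    (1.39, 0.974),
    (1.88, 0.969),
    (2.6, 0.964),
    (2.85, 0.959),
    (3.33, 0.933),
    (3.34, 0.923),
    (3.58, 0.901),
    (3.83, 0.865),
    (4.07, 0.85),
    (4.56, 0.828),
    (4.8, 0.817),
    (5.29, 0.777),
    (5.54, 0.767),
    (5.78, 0.759),
    (6.02, 0.749),
    (6.51, 0.716),
    (6.75, 0.711),
    (7.73, 0.671),
    (7.97, 0.661),
    (8.21, 0.651),
    (8.46, 0.638),
    (8.7, 0.628),
    (8.7, 0.626),
    (8.95, 0.621),
    (9.43, 0.616),
    (9.92, 0.61),
    (10.0, 0.608),
]

# risk-table rows covering those coordinates: interval 1 spans rows 1-30
# (month 0, 213 at risk); interval 2 begins at row 31 (month 10, 122 at risk)
_EXAMPLE_RISK = [
    (0.0, 1, 30, 213),
    (10.0, 31, 31, 122),
]


def load_example_curve() -> DigitizedCurve:
    """The 31 digitized coordinates of the radiotherapy-arm example curve."""
    t, s = zip(*_EXAMPLE_COORDS)
    return DigitizedCurve(arm_label="radiotherapy", times=np.array(t),
                          surv=np.array(s))


def load_example_risk_table() -> RiskTable:
    """The matching number-at-risk rows (months 0 and 10)."""
    tr, lo, up, nr = zip(*_EXAMPLE_RISK)
    return RiskTable(trisk=np.array(tr), lower=np.array(lo),
                     upper=np.array(up), nrisk=np.array(nr))


def load_example_input() -> ReconstructionInput:
    """Curve + risk table bundled for reconstruction.

    The source publication reported no total number of events, so the
    information level is ``no_total_events``.
    """
    return ReconstructionInput(
        curve=load_example_curve(),
        risk=load_example_risk_table(),
        totevents=None,
    )
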