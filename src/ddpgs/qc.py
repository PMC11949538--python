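"""Johnson–Bickel bounce criterion for non-systematic discounting data.

A reversal is an indifference point (from the second delay onward) that
exceeds the preceding one by strictly more than 20% of the delayed amount —
value increasing with delay rather than decreasing.  Two sensitivity
filters are supported: lenient (drop subjects with more than one reversal)
and conservative (drop subjects with any reversal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import IndifferenceProfile

QC_MODES = ("none", "lenient", "conservative")


@dataclass
class QCResult:
    subject_id: str
    n_reversals: int
    pass_lenient: bool
    pass_conservative: bool


def count_reversals(profile: IndifferenceProfile, threshold_frac: float = 0.20) -> int:
    """Number of increases IP_d - IP_{d-1} strictly greater than
    threshold_frac * delayed_amount, over ascending delays."""
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    ips = profile.indifference_points
    jumps = np.diff(ips)
    return int(np.sum(jumps > threshold_frac * profile.delayed_amount))


def qc_profile(profile: IndifferenceProfile, threshold_frac: float = 0.20) -> QCResult:
    n = count_reversals(profile, threshold_frac)
    return QCResult(
        subject_id=profile.subject_id,
        n_reversals=n,
        pass_lenient=n <= 1,
        pass_conservative=n == 0,
    )


def qc_table(profiles, threshold_frac: float = 0.20) -> pd.DataFrame:
    rows = [qc_profile(p, threshold_frac).__dict__ for p in profiles]
    return pd.DataFrame(
        rows, columns=["subject_id", "n_reversals", "pass_lenient", "pass_conservative"]
    )


def filter_cohort(qc: pd.DataFrame, mode: str) -> list[str]:
    """Subject ids retained under a QC mode.

    none -> all; lenient -> n_reversals <= 1; conservative -> n_reversals == 0.
    """
    if mode not in QC_MODES:
        raise ValueError(f"unknown QC mode {mode!r}; expected one of {QC_MODES}")
    if mode == "none":
        keep = np.ones(len(qc), dtype=bool)
    elif mode == "lenient":
        keep = qc["n_reversals"].to_numpy() <= 1
    else:
        keep = qc["n_reversals"].to_numpy() == 0
    return qc.loc[keep, "subject_id"].astype(str).tolist()
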