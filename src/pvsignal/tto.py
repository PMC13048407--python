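"""Time-to-onset (TTO) analysis.

TTO is the number of days from the start of the focal drug to the onset of
the adverse event.  One TTO per report: the earliest event onset minus the
drug start date.  Reports with a missing start or onset date, or a negative
difference, are excluded with a reason code collected in an audit (exclusion
is a result of the analysis, not an error).  The distribution is summarized
as interval counts/percentages, median with interquartile range, and an
empirical cumulative curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .icsr import ICSRReport, proportion

#: Default onset intervals in days: [0,30], (30,60], (60,90], (90,180],
#: (180,360], (360, inf).  Day 0 (onset on the start date) is valid and
#: falls in the first bin.
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 180.0, 360.0, math.inf)


@dataclass(frozen=True)
class TTORecord:
    case_id: str
    days: int

    def __post_init__(self) -> None:
        if self.days < 0:
            raise ValueError("days must be nonnegative")


@dataclass(frozen=True)
class TTOExclusion:
    case_id: str
    reason: str  # missing_start | missing_onset | negative_tto | drug_absent


@dataclass
class TTOSummary:
    n_valid: int = 0
    median_days: float | None = None
    iqr_low: float | None = None
    iqr_high: float | None = None
    bin_labels: list[str] = field(default_factory=list)
    bin_counts: list[int] = field(default_factory=list)
    bin_percentages: list[float] = field(default_factory=list)
    ecdf: list[tuple[int, float]] = field(default_factory=list)


def compute_tto(report: ICSRReport, drug_name: str) -> TTORecord | TTOExclusion:
    """Days from focal-drug start to earliest event onset for one report.

    The drug start date is the earliest reported start among the report's
    entries for ``drug_name``; the event onset is the earliest reported onset
    across events.  Missing dates or a negative difference exclude the report
    with a reason code.
    """
    starts = [d.start_date for d in report.drugs if d.drug_name == drug_name]
    if not starts:
        return TTOExclusion(report.case_id, "drug_absent")
    known_starts = [s for s in starts if s is not None]
    if not known_starts:
        return TTOExclusion(report.case_id, "missing_start")
    onsets = [e.onset_date for e in report.events if e.onset_date is not None]
    if not onsets:
        return TTOExclusion(report.case_id, "missing_onset")
    days = (min(onsets) - min(known_starts)).days
    if days < 0:
        return TTOExclusion(report.case_id, "negative_tto")
    return TTORecord(report.case_id, days)


def collect_tto(
    reports: Sequence[ICSRReport], drug_name: str
) -> tuple[list[TTORecord], list[TTOExclusion]]:
    """Apply :func:`compute_tto` to every report; split records from the
    exclusion audit."""
    records, audit = [], []
    for rep in reports:
        res = compute_tto(rep, drug_name)
        if isinstance(res, TTORecord):
            records.append(res)
        else:
            audit.append(res)
    return records, audit


def _bin_label(lo: float, hi: float, first: bool) -> str:
    if math.isinf(hi):
        return f">{lo:g}"
    return f"{lo:g}-{hi:g}" if first else f"{lo:g}<d<={hi:g}"


def tto_distribution(
    records: Sequence[TTORecord],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> TTOSummary:
    """Interval counts and two-decimal percentages of onset days.

    ``bin_edges`` must be strictly increasing, start at 0 and end at
    infinity; the first interval is closed on both ends, the rest are
    left-open.
    """
    edges = list(bin_edges)
    if edges[0] != 0 or not math.isinf(edges[-1]) or sorted(edges) != edges:
        raise ValueError("bin edges must increase from 0 to inf")
    summary = TTOSummary(n_valid=len(records))
    days = np.array([r.days for r in records], dtype=float)
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if i == 0:
            count = int(np.sum((days >= lo) & (days <= hi)))
        else:
            count = int(np.sum((days > lo) & (days <= hi)))
        summary.bin_labels.append(_bin_label(lo, hi, first=i == 0))
        summary.bin_counts.append(count)
        summary.bin_percentages.append(
            proportion(count, len(records)) if records else 0.0
        )
    return summary


def tto_summary(
    records: Sequence[TTORecord],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> TTOSummary:
    """Median, interquartile range, interval distribution and empirical CDF.

    Quantiles use linear interpolation between order statistics (the default
    numpy rule, quantile type 7).
    """
    if not records:
        raise ValueError("tto_summary requires at least one record")
    summary = tto_distribution(records, bin_edges)
    days = np.array([r.days for r in records], dtype=float)
    q25, q50, q75 = np.percentile(days, [25, 50, 75])
    summary.median_days = float(q50)
    summary.iqr_low = float(q25)
    summary.iqr_high = float(q75)
    distinct = np.unique(days)
    n = len(days)
    summary.ecdf = [
        (int(v), float(np.sum(days <= v) / n)) for v in distinct
    ]
    return summary


def summary_to_frames(summary: TTOSummary) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interval table and ECDF table for TSV export."""
    bins = pd.DataFrame(
        {
            "interval_days": summary.bin_labels,
            "count": summary.bin_counts,
            "percentage": summary.bin_percentages,
        }
    )
    ecdf = pd.DataFrame(summary.ecdf, columns=["days", "cumulative_fraction"])
    return bins, ecdf


def audit_to_frame(audit: Sequence[TTOExclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"case_id": x.case_id, "reason": x.reason} for x in audit],
        columns=["case_id", "reason"],
    )
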