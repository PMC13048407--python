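"""2x2 contingency tables for drug-event pairs.

For a focal drug and one event (a MedDRA preferred term, or all preferred
terms of one system organ class) the table counts deduplicated reports:

              event   no event
    drug        a        b
    no drug     c        d

The counting unit is the report, not the drug-event row: a report listing the
same preferred term twice, or several terms of one organ class, contributes 1
to `a`.  The comparator is every other report in the database.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .icsr import ICSRReport, SUSPECT_ROLES

Level = Literal["pt", "soc"]

#: Tables with fewer than this many exposed-event reports are flagged
#: low-count (computed but interpreted with caution), per common
#: pharmacovigilance practice.
DEFAULT_MIN_COUNT = 3

UNMAPPED_BUCKET = "UNMAPPED"


class UnmappedPTError(KeyError):
    """A preferred-term code has no system-organ-class mapping."""


@dataclass
class MedDRAMap:
    """User-supplied preferred-term to system-organ-class mapping.

    The MedDRA dictionary is licensed and never bundled; users provide a
    two-column delimited file (pt_code, soc_name).  Multi-axial terms must
    already be resolved to their primary organ class.
    """

    pt_to_soc: dict[str, str]
    pt_label: dict[str, str] | None = None

    @classmethod
    def from_file(cls, path: str | Path, sep: str = "\t") -> "MedDRAMap":
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
        cols = list(df.columns)
        if len(cols) < 2:
            raise ValueError(f"{path}: expected at least 2 columns, got {cols}")
        mapping = dict(zip(df[cols[0]], df[cols[1]]))
        labels = dict(zip(df[cols[0]], df[cols[2]])) if len(cols) > 2 else None
        return cls(pt_to_soc=mapping, pt_label=labels)

    def to_file(self, path: str | Path, sep: str = "\t") -> None:
        rows = sorted(self.pt_to_soc.items())
        df = pd.DataFrame(rows, columns=["pt_code", "soc_name"])
        if self.pt_label:
            df["pt_label"] = [self.pt_label.get(pt, "") for pt, _ in rows]
        df.to_csv(path, sep=sep, index=False)

    def socs(self) -> frozenset[str]:
        return frozenset(self.pt_to_soc.values())


def map_pt_to_soc(
    pt_code: str,
    meddra_map: MedDRAMap,
    on_unmapped: Literal["error", "bucket"] = "error",
) -> str:
    """Resolve a preferred term to its (primary) system organ class.

    Unmapped codes raise by default; with ``on_unmapped="bucket"`` they are
    collected under a sentinel UNMAPPED class instead.
    """
    soc = meddra_map.pt_to_soc.get(pt_code)
    if soc is None:
        if on_unmapped == "bucket":
            return UNMAPPED_BUCKET
        raise UnmappedPTError(f"PT code {pt_code!r} has no SOC mapping")
    return soc


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts for one drug-event pair, plus the label and level."""

    a: int
    b: int
    c: int
    d: int
    label: str = ""
    level: Level = "pt"
    low_count: bool = False

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def n(self) -> int:
        """Total reports in the database."""
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _event_labels(
    report: ICSRReport, level: Level, meddra_map: MedDRAMap | None,
    on_unmapped: Literal["error", "bucket"] = "error",
) -> frozenset[str]:
    pts = report.pt_codes()
    if level == "pt":
        return pts
    if meddra_map is None:
        raise ValueError("SOC-level counting requires a MedDRA map")
    return frozenset(map_pt_to_soc(pt, meddra_map, on_unmapped) for pt in pts)


def _is_exposed(report: ICSRReport, drug_name: str) -> bool:
    # role filtering happens upstream; any remaining mention counts as exposure
    return any(d.drug_name == drug_name for d in report.drugs)


def build_table(
    reports: Sequence[ICSRReport],
    drug_name: str,
    target: str,
    level: Level = "pt",
    meddra_map: MedDRAMap | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> ContingencyTable:
    """Count the 2x2 table for ``drug_name`` against ``target``.

    ``target`` is a preferred-term code at PT level or an organ-class name at
    SOC level.  A report contributes once to the event side if any of its
    events matches, however many matching events it lists.  Reports must
    already be deduplicated and role-filtered.
    """
    a = b = c = d = 0
    for rep in reports:
        exposed = _is_exposed(rep, drug_name)
        has_event = target in _event_labels(rep, level, meddra_map)
        if exposed and has_event:
            a += 1
        elif exposed:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(
        a=a, b=b, c=c, d=d, label=target, level=level, low_count=a < min_count
    )


def build_all_tables(
    reports: Sequence[ICSRReport],
    drug_name: str,
    level: Level = "pt",
    meddra_map: MedDRAMap | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
    on_unmapped: Literal["error", "bucket"] = "error",
) -> list[ContingencyTable]:
    """One table per distinct event label among the focal drug's reports.

    A single pass tallies, per label, the exposed-with-event count and the
    overall with-event count; marginals then fix b, c, d.  Labels are emitted
    in sorted order.  Tables with a < ``min_count`` are flagged ``low_count``
    but never dropped.
    """
    n = len(reports)
    n_drug = 0
    a_counts: Counter[str] = Counter()
    event_counts: Counter[str] = Counter()
    for rep in reports:
        labels = _event_labels(rep, level, meddra_map, on_unmapped)
        exposed = _is_exposed(rep, drug_name)
        if exposed:
            n_drug += 1
        for lab in labels:
            event_counts[lab] += 1
            if exposed:
                a_counts[lab] += 1
    tables = []
    for lab in sorted(a_counts):
        a = a_counts[lab]
        c = event_counts[lab] - a
        b = n_drug - a
        d = n - n_drug - c
        tables.append(
            ContingencyTable(
                a=a, b=b, c=c, d=d, label=lab, level=level, low_count=a < min_count
            )
        )
    return tables


def tables_to_frame(tables: Sequence[ContingencyTable]) -> pd.DataFrame:
    """Flatten tables into a DataFrame (columns level,label,a,b,c,d,N)."""
    return pd.DataFrame(
        [
            {
                "level": t.level,
                "label": t.label,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "N": t.n,
                "low_count": t.low_count,
            }
            for t in tables
        ]
    )
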