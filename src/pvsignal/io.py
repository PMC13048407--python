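"""Delimited readers/writers for report tables and result exports.

Reports are exchanged as one table per entity, joined on case id, in the
style of FAERS quarterly ASCII extracts:

* ``demo``  — case_id, report_date, sex, age_years, country, reporter, serious
* ``drug``  — case_id, drug_name, role, start_date
* ``reac``  — case_id, pt_code, onset_date
* ``outc``  — case_id, outcome

Two dialects: ``csv`` (comma-separated, ``.csv``) and ``faers``
("$"-delimited, ``.txt``).  Dates are written ISO-8601 and parsed as either
ISO-8601 or compact YYYYMMDD; two-digit years are rejected.  Malformed rows
are rejected with line-numbered diagnostics rather than aborting the load.

Result exports carry a provenance header (version, seed, config hash) as
``#`` comment lines, and two columns per statistic: a display column rounded
half-up to two decimals and a full-precision column.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Mapping, Sequence

import math

import pandas as pd

from . import __version__
from .icsr import (
    DemographicSummary,
    DrugEntry,
    DrugRole,
    EventEntry,
    ICSRReport,
    Outcome,
    Reporter,
    Sex,
)
from .stats import ScanResult, SignalStats

logger = logging.getLogger(__name__)

Dialect = Literal["csv", "faers"]

_DIALECT_SEP = {"csv": ",", "faers": "$"}
_DIALECT_EXT = {"csv": "csv", "faers": "txt"}

ENTITY_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "demo": ("case_id", "report_date", "sex", "age_years", "country",
             "reporter", "serious"),
    "drug": ("case_id", "drug_name", "role", "start_date"),
    "reac": ("case_id", "pt_code", "onset_date"),
    "outc": ("case_id", "outcome"),
}

_COMPACT_DATE = re.compile(r"^\d{8}$")


class DataFormatError(ValueError):
    """A report table could not be interpreted (bad dialect, missing column)."""


def parse_date(value: object) -> date | None:
    """ISO-8601 or compact YYYYMMDD date; empty/NaN means missing.

    Two-digit years (and any other form) are rejected with ValueError.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() == "nan":
        return None
    if _COMPACT_DATE.match(s):
        return datetime.strptime(s, "%Y%m%d").date()
    try:
        parsed = date.fromisoformat(s)
    except ValueError as exc:
        raise ValueError(f"unparseable date {s!r}") from exc
    if parsed.year < 1000:
        raise ValueError(f"two-digit or truncated year in date {s!r}")
    return parsed


def format_half_up(x: float | None, decimals: int = 2) -> str:
    """Half-up fixed-point display, matching the table convention; blank for
    missing/NaN."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class LoadDiagnostics:
    """Line-numbered rejection messages collected while reading tables."""

    messages: list[str] = field(default_factory=list)

    def reject(self, entity: str, line: int, reason: str) -> None:
        msg = f"{entity} line {line}: {reason}"
        self.messages.append(msg)
        logger.warning("rejected %s", msg)

    @property
    def n_rejected(self) -> int:
        return len(self.messages)


def _entity_path(directory: Path, entity: str, dialect: Dialect) -> Path:
    return directory / f"{entity}.{_DIALECT_EXT[dialect]}"


def write_reports(
    reports: Sequence[ICSRReport],
    directory: str | Path,
    dialect: Dialect = "csv",
) -> dict[str, Path]:
    """Write the four entity tables; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sep = _DIALECT_SEP[dialect]

    demo_rows, drug_rows, reac_rows, outc_rows = [], [], [], []
    for r in reports:
        demo_rows.append(
            {
                "case_id": r.case_id,
                "report_date": r.report_date.isoformat(),
                "sex": r.sex.value,
                "age_years": "" if r.age_years is None else r.age_years,
                "country": r.country or "",
                "reporter": r.reporter.value,
                "serious": int(r.serious),
            }
        )
        for d in r.drugs:
            drug_rows.append(
                {
                    "case_id": r.case_id,
                    "drug_name": d.drug_name,
                    "role": d.role.value,
                    "start_date": d.start_date.isoformat() if d.start_date else "",
                }
            )
        for e in r.events:
            reac_rows.append(
                {
                    "case_id": r.case_id,
                    "pt_code": e.pt_code,
                    "onset_date": e.onset_date.isoformat() if e.onset_date else "",
                }
            )
        for o in sorted(o.value for o in r.outcomes):
            outc_rows.append({"case_id": r.case_id, "outcome": o})

    paths = {}
    for entity, rows in [("demo", demo_rows), ("drug", drug_rows),
                         ("reac", reac_rows), ("outc", outc_rows)]:
        path = _entity_path(directory, entity, dialect)
        pd.DataFrame(rows, columns=ENTITY_COLUMNS[entity]).to_csv(
            path, sep=sep, index=False
        )
        paths[entity] = path
    return paths


def _load_table(
    directory: Path,
    entity: str,
    dialect: Dialect,
    column_map: Mapping[str, Mapping[str, str]] | None,
) -> pd.DataFrame:
    if dialect not in _DIALECT_SEP:
        raise DataFormatError(f"unknown dialect {dialect!r}")
    path = _entity_path(directory, entity, dialect)
    if not path.exists():
        raise DataFormatError(f"missing table {path}")
    df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], dtype=str,
                     keep_default_na=False)
    if column_map and entity in column_map:
        df = df.rename(columns={v: k for k, v in column_map[entity].items()})
    missing = set(ENTITY_COLUMNS[entity]) - set(df.columns)
    if missing:
        raise DataFormatError(f"{path}: missing mandatory columns {sorted(missing)}")
    return df


def read_reports(
    directory: str | Path,
    dialect: Dialect = "csv",
    column_map: Mapping[str, Mapping[str, str]] | None = None,
    diagnostics: LoadDiagnostics | None = None,
) -> list[ICSRReport]:
    """Load and validate reports from entity tables.

    Malformed rows are rejected with line-numbered diagnostics (collected in
    ``diagnostics`` when given, always logged); a rejected demo row drops the
    case, a rejected drug/reac/outc row drops only that row.
    """
    directory = Path(directory)
    diag = diagnostics if diagnostics is not None else LoadDiagnostics()
    demo = _load_table(directory, "demo", dialect, column_map)
    drug = _load_table(directory, "drug", dialect, column_map)
    reac = _load_table(directory, "reac", dialect, column_map)
    outc = _load_table(directory, "outc", dialect, column_map)

    drugs_by_case: dict[str, list[DrugEntry]] = {}
    for i, row in enumerate(drug.itertuples(index=False), start=2):
        try:
            entry = DrugEntry(
                drug_name=row.drug_name,
                role=DrugRole(row.role),
                start_date=parse_date(row.start_date),
            )
        except ValueError as exc:
            diag.reject("drug", i, f"case {row.case_id}: {exc}")
            continue
        drugs_by_case.setdefault(row.case_id, []).append(entry)

    events_by_case: dict[str, list[EventEntry]] = {}
    for i, row in enumerate(reac.itertuples(index=False), start=2):
        try:
            entry = EventEntry(
                pt_code=row.pt_code, onset_date=parse_date(row.onset_date)
            )
        except ValueError as exc:
            diag.reject("reac", i, f"case {row.case_id}: {exc}")
            continue
        events_by_case.setdefault(row.case_id, []).append(entry)

    outcomes_by_case: dict[str, set[Outcome]] = {}
    for i, row in enumerate(outc.itertuples(index=False), start=2):
        try:
            outcomes_by_case.setdefault(row.case_id, set()).add(
                Outcome(row.outcome)
            )
        except ValueError as exc:
            diag.reject("outc", i, f"case {row.case_id}: {exc}")

    reports: list[ICSRReport] = []
    for i, row in enumerate(demo.itertuples(index=False), start=2):
        case_id = row.case_id
        try:
            report_date = parse_date(row.report_date)
            if report_date is None:
                raise ValueError("missing report_date")
            serious = str(row.serious).strip().lower() in {"1", "true", "yes"}
            reports.append(
                ICSRReport(
                    case_id=case_id,
                    report_date=report_date,
                    sex=Sex(row.sex) if row.sex else Sex.MISSING,
                    age_years=float(row.age_years) if row.age_years else None,
                    country=row.country or None,
                    reporter=Reporter(row.reporter) if row.reporter
                    else Reporter.MISSING,
                    serious=serious,
                    outcomes=frozenset(outcomes_by_case.get(case_id, set()))
                    if serious
                    else frozenset(),
                    drugs=drugs_by_case.get(case_id, []),
                    events=events_by_case.get(case_id, []),
                )
            )
        except ValueError as exc:
            diag.reject("demo", i, f"case {case_id}: {exc}")
    if diag.n_rejected:
        logger.info("rejected %d malformed rows while loading %s",
                    diag.n_rejected, directory)
    return reports


# ---------------------------------------------------------------------------
# result exports


def provenance_header(seed: int | None, config: Mapping[str, object]) -> list[str]:
    """Comment lines recording version, seed, and a config digest."""
    digest = hashlib.sha256(
        json.dumps({k: str(v) for k, v in sorted(config.items())}).encode()
    ).hexdigest()[:12]
    return [
        f"# pvsignal {__version__}",
        f"# seed={'' if seed is None else seed}",
        f"# config_hash={digest}",
    ]


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def scan_to_frame(result: ScanResult) -> pd.DataFrame:
    """Result table mirroring the standard scan layout: display columns
    (half-up, 2 decimals) alongside full-precision columns and flags."""

    def row(s: SignalStats) -> dict:
        return {
            "level": s.level,
            "label": s.label,
            "n": s.n,
            "expected": format_half_up(s.expected),
            "ROR": format_half_up(s.ror),
            "ROR_95CI": f"({format_half_up(s.ror_low)},{format_half_up(s.ror_high)})",
            "PRR": format_half_up(s.prr),
            "PRR_95CI": f"({format_half_up(s.prr_low)},{format_half_up(s.prr_high)})",
            "chi_square": format_half_up(s.chi2),
            "IC": format_half_up(s.ic),
            "IC025": format_half_up(s.ic025),
            "EBGM": format_half_up(s.ebgm),
            "EBGM05": format_half_up(s.ebgm05),
            "ror_sig": s.ror_sig,
            "prr_sig": s.prr_sig,
            "bcpnn_sig": s.bcpnn_sig,
            "mgps_sig": s.mgps_sig,
            "overall_sig": s.overall_sig,
            "haldane_applied": s.haldane_applied,
            "low_count": s.low_count,
            "raw_expected": s.expected,
            "raw_ror": s.ror,
            "raw_ror_low": s.ror_low,
            "raw_ror_high": s.ror_high,
            "raw_prr": s.prr,
            "raw_prr_low": s.prr_low,
            "raw_prr_high": s.prr_high,
            "raw_chi2": s.chi2,
            "raw_ic": s.ic,
            "raw_ic025": s.ic025,
            "raw_ebgm": s.ebgm,
            "raw_ebgm05": s.ebgm05,
        }

    return pd.DataFrame([row(s) for s in result.stats])


def demographics_to_frame(summary: DemographicSummary) -> pd.DataFrame:
    rows = [{"category": "total", "value": "reports", "count": summary.total,
             "percentage": ""}]
    for cat, table in summary.categories().items():
        for value, (count, pct) in table.items():
            rows.append(
                {"category": cat, "value": value, "count": count,
                 "percentage": format_half_up(pct)}
            )
    return pd.DataFrame(rows, columns=["category", "value", "count", "percentage"])


def demographics_to_json(summary: DemographicSummary) -> dict:
    return {
        "total": summary.total,
        **{
            cat: {v: {"count": c, "percentage": p} for v, (c, p) in table.items()}
            for cat, table in summary.categories().items()
        },
    }


def read_keyvalue_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config file; ``#`` starts a comment."""
    out: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise DataFormatError(f"{path} line {i}: expected key=value")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_column_map(path: str | Path) -> dict[str, dict[str, str]]:
    """Column mapping config: ``entity.standard_name = actual_column``."""
    flat = read_keyvalue_config(path)
    out: dict[str, dict[str, str]] = {}
    for key, value in flat.items():
        if "." not in key:
            raise DataFormatError(f"bad column-map key {key!r}")
        entity, name = key.split(".", 1)
        out.setdefault(entity, {})[name] = value
    return out
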