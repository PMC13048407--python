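"""Individual case safety reports: data model, deduplication, descriptives.

An ICSR (individual case safety report) is one spontaneous report of suspected
adverse drug reactions, as collected by systems such as FAERS or VigiBase.  A
case may be reported several times (follow-up versions share the case id); the
convention used here keeps the version with the most recent report date.
Reports in which the focal drug appears only as a concomitant or interacting
medication are excluded from signal detection to limit confounding.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    MISSING = "missing"


class Reporter(str, Enum):
    CONSUMER = "consumer"
    PHARMACIST = "pharmacist"
    PHYSICIAN = "physician"
    LAWYER = "lawyer"
    OTHER_HEALTH_PROFESSIONAL = "other_health_professional"
    MISSING = "missing"


class Outcome(str, Enum):
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    DEATH = "death"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    REQUIRED_INTERVENTION = "required_intervention"
    OTHER_SERIOUS = "other_serious"


class DrugRole(str, Enum):
    PRIMARY_SUSPECT = "primary_suspect"
    SECONDARY_SUSPECT = "secondary_suspect"
    CONCOMITANT = "concomitant"
    INTERACTING = "interacting"


#: Roles under which a report counts as exposed for signal detection.
SUSPECT_ROLES = frozenset({DrugRole.PRIMARY_SUSPECT, DrugRole.SECONDARY_SUSPECT})

#: Age bands used for demographic stratification; lower bound inclusive.
AGE_BANDS: tuple[tuple[str, float, float], ...] = (
    ("<18", 0.0, 18.0),
    ("18-44", 18.0, 45.0),
    ("45-64", 45.0, 65.0),
    (">=65", 65.0, float("inf")),
)


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report, with its reported causal role."""

    drug_name: str
    role: DrugRole
    start_date: date | None = None

    def __post_init__(self) -> None:
        if not self.drug_name:
            raise ValueError("drug_name must be nonempty")


@dataclass(frozen=True)
class EventEntry:
    """One adverse event on a report, coded as a MedDRA preferred term."""

    pt_code: str
    onset_date: date | None = None

    def __post_init__(self) -> None:
        if not self.pt_code:
            raise ValueError("pt_code must be nonempty")


@dataclass
class ICSRReport:
    """One safety report (one version of a case).

    ``report_date`` is the versioning date (FDA_DT semantics in FAERS): when a
    case is reported more than once, the most recent ``report_date`` wins at
    deduplication.  ``outcomes`` must be empty for non-serious reports; the
    outcome categories are not mutually exclusive.
    """

    case_id: str
    report_date: date
    sex: Sex = Sex.MISSING
    age_years: float | None = None
    country: str | None = None
    reporter: Reporter = Reporter.MISSING
    serious: bool = False
    outcomes: frozenset[Outcome] = frozenset()
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[EventEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be nonempty")
        if not self.serious and self.outcomes:
            raise ValueError(
                f"case {self.case_id}: outcomes given but serious is False"
            )
        if not self.events:
            raise ValueError(f"case {self.case_id}: events must be nonempty")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError(f"case {self.case_id}: negative age")
        self.outcomes = frozenset(self.outcomes)

    def pt_codes(self) -> frozenset[str]:
        """Distinct preferred-term codes on this report."""
        return frozenset(e.pt_code for e in self.events)

    def drug_roles(self, drug_name: str) -> frozenset[DrugRole]:
        """All roles under which ``drug_name`` appears on this report."""
        return frozenset(d.role for d in self.drugs if d.drug_name == drug_name)


def deduplicate_reports(reports: Sequence[ICSRReport]) -> list[ICSRReport]:
    """Keep one version per case id: the one with the latest report date.

    Ties on report date keep the record appearing last in input order (a
    warning is logged).  The relative input order of surviving reports is
    preserved.  Idempotent.
    """
    best: dict[str, tuple[int, ICSRReport]] = {}
    for idx, rep in enumerate(reports):
        prev = best.get(rep.case_id)
        if prev is None:
            best[rep.case_id] = (idx, rep)
            continue
        if rep.report_date > prev[1].report_date:
            best[rep.case_id] = (idx, rep)
        elif rep.report_date == prev[1].report_date:
            logger.warning(
                "case %s: duplicate with identical report_date %s; "
                "keeping last occurrence",
                rep.case_id,
                rep.report_date,
            )
            best[rep.case_id] = (idx, rep)
    # preserve the surviving records' original positions
    return [rep for _, rep in sorted(best.values(), key=lambda t: t[0])]


def filter_by_drug_role(
    reports: Sequence[ICSRReport],
    drug_name: str,
    allowed_roles: Iterable[DrugRole] = SUSPECT_ROLES,
) -> list[ICSRReport]:
    """Drop reports that mention ``drug_name`` only in disallowed roles.

    Reports not mentioning the drug at all are retained unchanged: they form
    the comparator population for disproportionality analysis.
    """
    allowed = frozenset(allowed_roles)
    if not allowed:
        raise ValueError("allowed_roles must be nonempty")
    kept = []
    for rep in reports:
        roles = rep.drug_roles(drug_name)
        if roles and not (roles & allowed):
            continue
        kept.append(rep)
    return kept


def proportion(count: int, total: int) -> float:
    """Percentage 100*count/total, half-up rounded to 2 decimals.

    ``count > total`` is tolerated because spontaneous-report outcome
    categories overlap (one report may list several outcomes), so outcome
    percentages are conventionally taken against total reports.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class DemographicSummary:
    """Per-category counts and percentages of a deduplicated report set.

    Partition categories (sex, age band, reporter, seriousness, year) sum to
    ``total``.  Outcomes overlap and therefore do not; their percentages are
    taken against total reports.  Missing values are counted in explicit
    ``missing`` buckets — stratified analyses exclude them, totals do not.
    """

    total: int
    sex: dict[str, tuple[int, float]] = field(default_factory=dict)
    age: dict[str, tuple[int, float]] = field(default_factory=dict)
    country: dict[str, tuple[int, float]] = field(default_factory=dict)
    reporter: dict[str, tuple[int, float]] = field(default_factory=dict)
    seriousness: dict[str, tuple[int, float]] = field(default_factory=dict)
    outcomes: dict[str, tuple[int, float]] = field(default_factory=dict)
    year: dict[str, tuple[int, float]] = field(default_factory=dict)

    def categories(self) -> Mapping[str, dict[str, tuple[int, float]]]:
        return {
            "sex": self.sex,
            "age": self.age,
            "country": self.country,
            "reporter": self.reporter,
            "seriousness": self.seriousness,
            "outcomes": self.outcomes,
            "year": self.year,
        }


def summarize_demographics(
    reports: Sequence[ICSRReport], top_countries: int = 6
) -> DemographicSummary:
    """Tabulate sex, age bands, countries, reporter, seriousness, outcomes
    and report year with two-decimal percentages of the report total."""
    total = len(reports)
    summary = DemographicSummary(total=total)
    if total == 0:
        return summary

    def tab(counter: Counter[str], order: Sequence[str]) -> dict[str, tuple[int, float]]:
        return {k: (counter[k], proportion(counter[k], total)) for k in order}

    sex_c: Counter[str] = Counter(r.sex.value for r in reports)
    summary.sex = tab(sex_c, [s.value for s in Sex])

    age_c: Counter[str] = Counter()
    for r in reports:
        if r.age_years is None:
            age_c["missing"] += 1
        else:
            for label, lo, hi in AGE_BANDS:
                if lo <= r.age_years < hi:
                    age_c[label] += 1
                    break
    summary.age = tab(age_c, [b[0] for b in AGE_BANDS] + ["missing"])

    country_c: Counter[str] = Counter(
        r.country if r.country else "missing" for r in reports
    )
    top = [c for c, _ in country_c.most_common() if c != "missing"][:top_countries]
    order = top + (["missing"] if "missing" in country_c else [])
    summary.country = tab(country_c, order)

    rep_c: Counter[str] = Counter(r.reporter.value for r in reports)
    summary.reporter = tab(rep_c, [r.value for r in Reporter])

    ser_c: Counter[str] = Counter(
        "serious" if r.serious else "non_serious" for r in reports
    )
    summary.seriousness = tab(ser_c, ["non_serious", "serious"])

    out_c: Counter[str] = Counter()
    for r in reports:
        for o in r.outcomes:
            out_c[o.value] += 1
    summary.outcomes = tab(out_c, [o.value for o in Outcome])

    year_c: Counter[str] = Counter(str(r.report_date.year) for r in reports)
    summary.year = tab(year_c, sorted(year_c))

    return summary
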