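"""Synthetic spontaneous-reporting-system generator with known ground truth.

Emulates the shape of a FAERS-style extract — a large report universe with
one focal drug at low prevalence, per-PT background reporting frequencies,
optional planted drug-event signals with specified reporting risk ratios,
demographic strata, and a bimodal onset-time distribution (an early
exponential mode within the first weeks plus a long late tail beyond a year)
— so that every pipeline stage is testable without access to the licensed
databases.

The generative model, per report: drug exposure ~ Bernoulli(prevalence);
each preferred term occurs independently with probability
background_rate * (risk ratio if exposed else 1); reports with no event are
redrawn.  PT independence within a report is a deliberate simplification —
it is exactly the null model the disproportionality estimators assume, so
planted risk ratios are recoverable and un-planted terms are true nulls.
One onset episode per report: every event of a report carries the same onset
date, drawn from the two-component mixture.

A single root seed governs generation; each aspect (exposure, events,
demographics, dates, missingness) draws from its own derived stream, so
adding a field never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import NamedTuple, Sequence

import numpy as np

from .contingency import MedDRAMap
from .icsr import (
    DrugEntry,
    DrugRole,
    EventEntry,
    ICSRReport,
    Outcome,
    Reporter,
    Sex,
)


class PTSpec(NamedTuple):
    """One preferred term of the synthetic catalog."""

    pt_code: str
    soc_name: str
    background_rate: float


_DEFAULT_SOCS = (
    "Cardiac disorders",
    "Investigations",
    "Metabolism and nutrition disorders",
    "Nervous system disorders",
    "Renal and urinary disorders",
    "Vascular disorders",
)


def default_pt_catalog(
    n_pts: int = 30,
    rate_low: float = 0.002,
    rate_high: float = 0.03,
    socs: Sequence[str] = _DEFAULT_SOCS,
) -> list[PTSpec]:
    """Deterministic catalog: log-spaced background rates, round-robin SOCs."""
    rates = np.geomspace(rate_low, rate_high, n_pts)
    return [
        PTSpec(f"PT{i + 1:04d}", socs[i % len(socs)], float(rates[i]))
        for i in range(n_pts)
    ]


@dataclass(frozen=True)
class OnsetModel:
    """Two-component onset-day mixture: with probability ``early_weight`` an
    exponential of scale ``early_scale`` days (acute reactions), otherwise
    ``late_location`` plus an exponential of scale ``late_scale`` days (the
    long tail of chronic toxicity)."""

    early_weight: float = 0.55
    early_scale: float = 35.0
    late_location: float = 60.0
    late_scale: float = 400.0

    def cdf(self, x: float) -> float:
        """Analytic mixture CDF (ground truth for sampled onsets)."""
        early = 1.0 - np.exp(-x / self.early_scale) if x >= 0 else 0.0
        late = (
            1.0 - np.exp(-(x - self.late_location) / self.late_scale)
            if x >= self.late_location
            else 0.0
        )
        return self.early_weight * early + (1.0 - self.early_weight) * late

    def quantile(self, q: float, hi: float = 1e7) -> float:
        """Numeric inverse of :meth:`cdf` by bisection."""
        lo, up = 0.0, hi
        for _ in range(200):
            mid = (lo + up) / 2
            if self.cdf(mid) < q:
                lo = mid
            else:
                up = mid
        return (lo + up) / 2


# demographic strata typical of an antihypertensive's report profile:
# female-majority reporting, an elderly-skewed age distribution with roughly
# half of ages missing, physician-dominated reporters, ~20% serious
_SEX_P = {Sex.FEMALE: 0.4827, Sex.MALE: 0.4342, Sex.MISSING: 0.0831}
_AGE_P = {"<18": 0.0011, "18-44": 0.0248, "45-64": 0.1687, ">=65": 0.3122,
          "missing": 0.4932}
_AGE_RANGE = {"<18": (1.0, 18.0), "18-44": (18.0, 45.0), "45-64": (45.0, 65.0),
              ">=65": (65.0, 95.0)}
_REPORTER_P = {
    Reporter.CONSUMER: 0.3061,
    Reporter.PHARMACIST: 0.0441,
    Reporter.PHYSICIAN: 0.5216,
    Reporter.LAWYER: 0.0043,
    Reporter.OTHER_HEALTH_PROFESSIONAL: 0.0924,
    Reporter.MISSING: 0.0315,
}
_COUNTRY_P = {"US": 0.3726, "DE": 0.1278, "JP": 0.0740, "CA": 0.0618,
              "FR": 0.0575, "BR": 0.0447, "OTHER": 0.2616}
_SERIOUS_P = 0.1853
_OUTCOME_W = {
    Outcome.LIFE_THREATENING: 277,
    Outcome.HOSPITALIZATION: 1735,
    Outcome.DISABILITY: 98,
    Outcome.DEATH: 548,
    Outcome.CONGENITAL_ANOMALY: 8,
    Outcome.REQUIRED_INTERVENTION: 4,
    Outcome.OTHER_SERIOUS: 3080,
}

_OTHER_DRUGS = tuple(f"comparator_drug_{i:02d}" for i in range(1, 21))


@dataclass
class SyntheticConfig:
    """Generative parameters of the synthetic reporting system."""

    n_reports: int = 100_000
    drug_name: str = "focaldrug"
    drug_prevalence: float = 0.02
    pt_catalog: list[PTSpec] = field(default_factory=default_pt_catalog)
    planted_signals: dict[str, float] = field(default_factory=dict)
    onset_model: OnsetModel = field(default_factory=OnsetModel)
    #: fraction of focal-drug reports in which the drug is listed only as
    #: concomitant (removed by role filtering)
    concomitant_fraction: float = 0.05
    p_missing_start: float = 0.45
    p_missing_onset: float = 0.25
    #: fraction of reports with a data-entry error placing onset before start
    p_negative_onset: float = 0.02
    first_year: int = 2005
    n_years: int = 20
    year_decay: float = 0.87
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        probs = [
            self.drug_prevalence,
            self.concomitant_fraction,
            self.p_missing_start,
            self.p_missing_onset,
            self.p_negative_onset,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        codes = [p.pt_code for p in self.pt_catalog]
        if len(set(codes)) != len(codes):
            raise ValueError("pt_codes in the catalog must be unique")
        rates = {p.pt_code: p.background_rate for p in self.pt_catalog}
        if any(not 0.0 < r < 1.0 for r in rates.values()):
            raise ValueError("background rates must lie in (0, 1)")
        for pt, rr in self.planted_signals.items():
            if pt not in rates:
                raise ValueError(f"planted signal for unknown pt {pt!r}")
            if rr < 0:
                raise ValueError("risk ratios must be nonnegative")
            if rates[pt] * max(rr, 1.0) >= 1.0:
                raise ValueError(
                    f"background_rate * risk ratio must stay below 1 ({pt})"
                )

    def meddra_map(self) -> MedDRAMap:
        return MedDRAMap(
            pt_to_soc={p.pt_code: p.soc_name for p in self.pt_catalog}
        )

    def truth(self) -> dict[str, float]:
        """Ground-truth reporting risk ratio of every catalog PT."""
        return {
            p.pt_code: float(self.planted_signals.get(p.pt_code, 1.0))
            for p in self.pt_catalog
        }


def _choice(rng: np.random.Generator, table: dict, n: int) -> list:
    keys = list(table.keys())
    p = np.array([table[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=n, p=p)
    return [keys[i] for i in idx]


def _sample_events(
    rng: np.random.Generator,
    exposed: np.ndarray,
    p_exposed: np.ndarray,
    p_base: np.ndarray,
    chunk: int = 20_000,
) -> list[np.ndarray]:
    """Per-report boolean PT indicators; zero-event reports are redrawn."""
    n = exposed.size
    npts = p_base.size
    out: list[np.ndarray] = []
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        probs = np.where(exposed[start:stop, None], p_exposed[None, :],
                         p_base[None, :])
        mat = rng.random((stop - start, npts)) < probs
        empty = ~mat.any(axis=1)
        while empty.any():
            redraw = rng.random((int(empty.sum()), npts)) < probs[empty]
            mat[empty] = redraw
            empty_idx = np.flatnonzero(empty)
            empty[empty_idx] = ~redraw.any(axis=1)
        out.extend(np.flatnonzero(row) for row in mat)
    return out


def generate_reports(
    config: SyntheticConfig,
) -> tuple[list[ICSRReport], dict[str, float]]:
    """Draw a full synthetic report set; returns (reports, ground truth).

    Fully reproducible: the same config (including seed) yields an identical
    report list.
    """
    config.validate()
    n = config.n_reports
    root = np.random.SeedSequence(config.seed)
    (s_exp, s_evt, s_demo, s_date, s_onset, s_miss) = [
        np.random.default_rng(s) for s in root.spawn(6)
    ]

    exposed = s_exp.random(n) < config.drug_prevalence
    concomitant_only = exposed & (s_exp.random(n) < config.concomitant_fraction)

    truth = config.truth()
    p_base = np.array([p.background_rate for p in config.pt_catalog])
    rr = np.array([truth[p.pt_code] for p in config.pt_catalog])
    p_exposed = np.clip(p_base * rr, 0.0, 0.999)
    event_idx = _sample_events(s_evt, exposed, p_exposed, p_base)

    sexes = _choice(s_demo, _SEX_P, n)
    bands = _choice(s_demo, _AGE_P, n)
    band_u = s_demo.random(n)
    reporters = _choice(s_demo, _REPORTER_P, n)
    countries = _choice(s_demo, _COUNTRY_P, n)
    serious = s_demo.random(n) < _SERIOUS_P
    outcome_draw = _choice(s_demo, _OUTCOME_W, n)

    years = np.array(
        _choice(
            s_date,
            {config.first_year + k: config.year_decay**k
             for k in range(config.n_years)},
            n,
        )
    )
    day_offsets = s_date.integers(0, 365, size=n)
    report_delays = s_date.integers(0, 91, size=n)
    comed_counts = s_date.integers(0, 3, size=n)

    w = config.onset_model.early_weight
    use_early = s_onset.random(n) < w
    early = s_onset.exponential(config.onset_model.early_scale, size=n)
    late = config.onset_model.late_location + s_onset.exponential(
        config.onset_model.late_scale, size=n
    )
    onset_days = np.rint(np.where(use_early, early, late)).astype(int)

    miss_start = s_miss.random(n) < config.p_missing_start
    miss_onset = s_miss.random(n) < config.p_missing_onset
    neg_onset = s_miss.random(n) < config.p_negative_onset
    neg_days = s_miss.integers(1, 31, size=n)

    pt_codes = [p.pt_code for p in config.pt_catalog]
    reports: list[ICSRReport] = []
    for i in range(n):
        start_date = date(int(years[i]), 1, 1) + timedelta(days=int(day_offsets[i]))
        if neg_onset[i]:
            onset = start_date - timedelta(days=int(neg_days[i]))
        else:
            onset = start_date + timedelta(days=int(onset_days[i]))
        report_date = max(onset, start_date) + timedelta(days=int(report_delays[i]))

        drugs: list[DrugEntry] = []
        if exposed[i]:
            role = (
                DrugRole.CONCOMITANT
                if concomitant_only[i]
                else DrugRole.PRIMARY_SUSPECT
            )
            drugs.append(
                DrugEntry(
                    config.drug_name,
                    role,
                    None if miss_start[i] else start_date,
                )
            )
        for k in range(int(comed_counts[i]) + (0 if exposed[i] else 1)):
            name = _OTHER_DRUGS[(i + k * 7) % len(_OTHER_DRUGS)]
            role = DrugRole.PRIMARY_SUSPECT if (not exposed[i] and k == 0) \
                else DrugRole.CONCOMITANT
            drugs.append(DrugEntry(name, role, start_date))

        events = [
            EventEntry(pt_codes[j], None if miss_onset[i] else onset)
            for j in event_idx[i]
        ]

        band = bands[i]
        if band == "missing":
            age = None
        else:
            lo, hi = _AGE_RANGE[band]
            age = round(lo + band_u[i] * (hi - lo), 1)

        reports.append(
            ICSRReport(
                case_id=f"CASE{i + 1:07d}",
                report_date=report_date,
                sex=sexes[i],
                age_years=age,
                country=countries[i],
                reporter=reporters[i],
                serious=bool(serious[i]),
                outcomes=frozenset({outcome_draw[i]}) if serious[i] else frozenset(),
                drugs=drugs,
                events=events,
            )
        )
    return reports, truth


def inject_duplicates(
    reports: Sequence[ICSRReport], fraction: float, seed: int = 0
) -> list[ICSRReport]:
    """Append later-dated follow-up versions for a random subset of cases.

    ``round(fraction * len(reports))`` cases gain one extra version with a
    strictly later report date and a perturbed record, appended after the
    originals.  Deduplication recovers exactly the later versions.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    k = round(fraction * len(reports))
    if k == 0:
        return list(reports)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reports), size=k, replace=False)
    delays = rng.integers(1, 181, size=k)
    out = list(reports)
    for j, i in enumerate(sorted(int(x) for x in idx)):
        orig = reports[i]
        out.append(
            dataclasses.replace(
                orig,
                report_date=orig.report_date + timedelta(days=int(delays[j])),
                reporter=Reporter.PHYSICIAN,
            )
        )
    return out
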