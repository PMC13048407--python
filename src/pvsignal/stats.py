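"""Disproportionality estimators and the signal-criteria engine.

Four estimators are computed on each 2x2 table (cells a, b, c, d; N total;
E = (a+b)(a+c)/N the expected exposed-event count under independence):

* ROR — reporting odds ratio ad/(bc), Woolf log-scale 95% interval.
* PRR — proportional reporting ratio [a/(a+b)] / [c/(c+d)], log-scale
  interval, with a companion Pearson chi-square (Yates-corrected by default).
* BCPNN IC — information component log2(observed/expected).  ``plain`` mode
  is log2(a/E) with a delta-method interval on the log scale; ``shrunk`` mode
  applies the 0.5/0.5 credibility shrinkage with the standard posterior
  approximation for the 2.5th percentile.
* EBGM — empirical Bayes geometric mean of the observed/expected ratio.
  ``plain`` mode is a/E with a log-scale lower 5th percentile; ``mgps`` mode
  shrinks a/E under the two-component gamma mixture prior fitted across all
  tables of a scan (see :mod:`pvsignal.mgps`).

In plain mode IC == log2(EBGM) exactly, the convention of OpenVigil-style
scan outputs; the shrunk/mgps modes are the literature-standard Bayesian
variants.  A pair is flagged a signal when all four criteria hold:
ROR lower 95% bound > 1; PRR >= 2 with chi-square >= 4; IC025 > 0; EBGM > 2.

Zero cells make the ROR/PRR intervals degenerate; the Haldane correction
(add 0.5 to every cell) is applied automatically in that case and recorded.
Statistics that remain non-estimable (e.g. plain IC at a = 0 and no exposed
reports at all) are returned as NaN with a reason code, and evaluate to
non-significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from scipy.stats import norm

from .contingency import (
    ContingencyTable,
    Level,
    MedDRAMap,
    build_all_tables,
)
from .icsr import ICSRReport
from . import mgps as _mgps

_Z975 = float(norm.ppf(0.975))
_Z95 = float(norm.ppf(0.95))
_LN2 = math.log(2.0)

HaldaneMode = Literal["auto", "always", "none"]
ICMode = Literal["plain", "shrunk"]
EBGMMode = Literal["plain", "mgps"]

NAN = float("nan")


def expected_count(table: ContingencyTable) -> float:
    """Expected exposed-event count under independence: (a+b)(a+c)/N."""
    n = table.n
    if n == 0:
        raise ValueError("empty table: N = 0")
    return table.n_drug * table.n_event / n


def _corrected(table: ContingencyTable, haldane: HaldaneMode) -> tuple[
    float, float, float, float, bool
]:
    cells = table.cells()
    apply = haldane == "always" or (haldane == "auto" and 0 in cells)
    if apply:
        return tuple(x + 0.5 for x in cells) + (True,)  # type: ignore[return-value]
    return tuple(float(x) for x in cells) + (False,)  # type: ignore[return-value]


def ror(
    table: ContingencyTable,
    alpha: float = 0.05,
    haldane: HaldaneMode = "auto",
) -> tuple[float, float, float]:
    """Reporting odds ratio ad/(bc) with Woolf (1-alpha) interval.

    With a zero cell and ``haldane="none"`` the estimate is non-estimable
    and NaNs are returned.
    """
    a, b, c, d, _ = _corrected(table, haldane)
    if min(a, b, c, d) <= 0:
        return (NAN, NAN, NAN)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(1 - alpha / 2))
    return (est, est * math.exp(-z * se), est * math.exp(z * se))


def prr(
    table: ContingencyTable,
    alpha: float = 0.05,
    haldane: HaldaneMode = "auto",
) -> tuple[float, float, float]:
    """Proportional reporting ratio with log-scale (1-alpha) interval.

    PRR = [a/(a+b)] / [c/(c+d)];
    SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)).
    """
    a, b, c, d, _ = _corrected(table, haldane)
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return (NAN, NAN, NAN)
    est = (a / (a + b)) / (c / (c + d))
    var = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(var, 0.0))
    z = float(norm.ppf(1 - alpha / 2))
    return (est, est * math.exp(-z * se), est * math.exp(z * se))


def chi_square(table: ContingencyTable, yates: bool = True) -> float:
    """Pearson chi-square of the 2x2 table.

    With Yates continuity correction the per-cell deviation |O-E| is reduced
    by 0.5 and clamped at zero.  Non-estimable (NaN) when a marginal is zero.
    """
    a, b, c, d = (float(x) for x in table.cells())
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if n == 0 or 0 in margins:
        return NAN
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2, 0.0)
    num = n * dev * dev
    den = margins[0] * margins[1] * margins[2] * margins[3]
    return num / den


def ic_from_counts(
    a: float,
    expected: float,
    n_total: float | None = None,
    mode: ICMode = "plain",
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Information component from an observed count and its expectation.

    plain:  IC = log2(a/E); IC025 = IC - z * sqrt(1/a - 1/N) / ln 2
            (log-scale delta method; non-estimable at a = 0).
    shrunk: IC = log2((a+0.5)/(E+0.5));
            IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2 (a+0.5)^(-3/2).

    ``n_total`` (the database size) only sharpens the plain-mode interval;
    when omitted the 1/N term is dropped.
    """
    if mode == "plain":
        if a <= 0 or expected <= 0:
            return (NAN, NAN)
        val = math.log2(a / expected)
        inv_n = 0.0 if not n_total else 1.0 / n_total
        se = math.sqrt(max(1 / a - inv_n, 0.0)) / _LN2
        z = float(norm.ppf(1 - alpha / 2))
        return (val, val - z * se)
    if mode == "shrunk":
        if expected < 0:
            return (NAN, NAN)
        val = math.log2((a + 0.5) / (expected + 0.5))
        low = val - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
        return (val, low)
    raise ValueError(f"unknown IC mode {mode!r}")


def ic(
    table: ContingencyTable,
    mode: ICMode = "plain",
    alpha: float = 0.05,
) -> tuple[float, float]:
    """BCPNN information component and its lower credibility bound
    (see :func:`ic_from_counts` for the two modes)."""
    n = table.n
    if n == 0:
        return (NAN, NAN)
    return ic_from_counts(table.a, expected_count(table), n, mode=mode, alpha=alpha)


def ebgm_from_counts(
    a: float,
    expected: float,
    n_total: float | None = None,
    mode: EBGMMode = "plain",
    prior: "_mgps.MGPSPrior | None" = None,
) -> tuple[float, float]:
    """Observed/expected shrinkage estimate from an observed count and its
    expectation.

    plain: EBGM = a/E, EBGM05 = exp(ln(a/E) - z05 * sqrt(1/a - 1/N))
           (one-sided log-scale bound); non-estimable at a = 0 or E = 0.
    mgps:  gamma-mixture posterior shrinkage under ``prior``
           (see :func:`pvsignal.mgps.posterior_ebgm`).
    """
    if expected <= 0:
        return (NAN, NAN)
    if mode == "plain":
        if a <= 0:
            return (NAN, NAN)
        val = a / expected
        inv_n = 0.0 if not n_total else 1.0 / n_total
        se = math.sqrt(max(1 / a - inv_n, 0.0))
        return (val, val * math.exp(-_Z95 * se))
    if mode == "mgps":
        if prior is None:
            raise ValueError("mgps mode requires a fitted MGPSPrior")
        return _mgps.posterior_ebgm(a, expected, prior)
    raise ValueError(f"unknown EBGM mode {mode!r}")


def ebgm(
    table: ContingencyTable,
    mode: EBGMMode = "plain",
    prior: "_mgps.MGPSPrior | None" = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Empirical Bayes geometric mean of observed/expected and its 5th
    percentile (see :func:`ebgm_from_counts` for the two modes)."""
    n = table.n
    if n == 0:
        return (NAN, NAN)
    return ebgm_from_counts(
        table.a, expected_count(table), n, mode=mode, prior=prior
    )


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds of the four-criterion signal rule.

    Defaults: ROR lower 95% bound > 1; PRR >= 2 and chi-square >= 4;
    IC025 > 0; EBGM > 2.  ``min_cases`` optionally also requires n = a at or
    above a floor before any flag can be raised (off by default).
    """

    ror_ci_low_gt: float = 1.0
    prr_ge: float = 2.0
    chi2_ge: float = 4.0
    ic025_gt: float = 0.0
    ebgm_gt: float = 2.0
    min_cases: int | None = None


@dataclass(frozen=True)
class AnalysisConfig:
    """Estimator settings for a scan."""

    alpha: float = 0.05
    ic_mode: ICMode = "plain"
    ebgm_mode: EBGMMode = "plain"
    yates: bool = True
    haldane: HaldaneMode = "auto"
    min_count: int = 3
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)


@dataclass
class SignalStats:
    """All four estimators with intervals for one drug-event pair."""

    label: str
    level: Level = "pt"
    n: int = 0
    expected: float = NAN
    ror: float = NAN
    ror_low: float = NAN
    ror_high: float = NAN
    prr: float = NAN
    prr_low: float = NAN
    prr_high: float = NAN
    chi2: float = NAN
    ic: float = NAN
    ic025: float = NAN
    ebgm: float = NAN
    ebgm05: float = NAN
    ror_sig: bool = False
    prr_sig: bool = False
    bcpnn_sig: bool = False
    mgps_sig: bool = False
    overall_sig: bool = False
    haldane_applied: bool = False
    low_count: bool = False
    notes: tuple[str, ...] = ()


def evaluate_criteria(
    stats: SignalStats, config: CriteriaConfig | None = None
) -> SignalStats:
    """Fill the per-algorithm and overall significance flags.

    NaN statistics (non-estimable) never satisfy a criterion.  Returns a new
    SignalStats; the input is not mutated.
    """
    cfg = config or CriteriaConfig()
    ror_sig = stats.ror_low > cfg.ror_ci_low_gt
    prr_sig = stats.prr >= cfg.prr_ge and stats.chi2 >= cfg.chi2_ge
    bcpnn_sig = stats.ic025 > cfg.ic025_gt
    mgps_sig = stats.ebgm > cfg.ebgm_gt
    if cfg.min_cases is not None and stats.n < cfg.min_cases:
        ror_sig = prr_sig = bcpnn_sig = mgps_sig = False
    return replace(
        stats,
        ror_sig=bool(ror_sig),
        prr_sig=bool(prr_sig),
        bcpnn_sig=bool(bcpnn_sig),
        mgps_sig=bool(mgps_sig),
        overall_sig=bool(ror_sig and prr_sig and bcpnn_sig and mgps_sig),
    )


def compute_signal_stats(
    table: ContingencyTable,
    config: AnalysisConfig | None = None,
    prior: "_mgps.MGPSPrior | None" = None,
) -> SignalStats:
    """All four estimators plus flags for one contingency table."""
    cfg = config or AnalysisConfig()
    notes: list[str] = []
    e = expected_count(table) if table.n > 0 else NAN
    r, r_lo, r_hi = ror(table, alpha=cfg.alpha, haldane=cfg.haldane)
    p, p_lo, p_hi = prr(table, alpha=cfg.alpha, haldane=cfg.haldane)
    x2 = chi_square(table, yates=cfg.yates)
    ic_val, ic_lo = ic(table, mode=cfg.ic_mode, alpha=cfg.alpha)
    eb, eb_lo = ebgm(table, mode=cfg.ebgm_mode, prior=prior, alpha=cfg.alpha)
    haldane_applied = cfg.haldane == "always" or (
        cfg.haldane == "auto" and 0 in table.cells()
    )
    if math.isnan(r):
        notes.append("ror_non_estimable")
    if math.isnan(ic_val):
        notes.append("ic_non_estimable")
    if math.isnan(eb):
        notes.append("ebgm_non_estimable")
    stats = SignalStats(
        label=table.label,
        level=table.level,
        n=table.a,
        expected=e,
        ror=r,
        ror_low=r_lo,
        ror_high=r_hi,
        prr=p,
        prr_low=p_lo,
        prr_high=p_hi,
        chi2=x2,
        ic=ic_val,
        ic025=ic_lo,
        ebgm=eb,
        ebgm05=eb_lo,
        haldane_applied=haldane_applied,
        low_count=table.low_count,
        notes=tuple(notes),
    )
    return evaluate_criteria(stats, cfg.criteria)


@dataclass
class ScanResult:
    """Signal statistics for every event label of one scan."""

    stats: list[SignalStats]
    prior: "_mgps.MGPSPrior | None" = None

    def ranked_by_n(self) -> list[SignalStats]:
        """Most frequently reported first; ties broken by label."""
        return sorted(self.stats, key=lambda s: (-s.n, s.label))

    def ranked_by_ror(self) -> list[SignalStats]:
        """Strongest odds-ratio signal first; NaN last; ties by label."""
        def key(s: SignalStats):
            r = s.ror
            return (math.isnan(r), -(r if not math.isnan(r) else 0.0), s.label)
        return sorted(self.stats, key=key)

    def significant(self) -> list[SignalStats]:
        return [s for s in self.stats if s.overall_sig]


def run_signal_scan(
    reports: Sequence[ICSRReport],
    drug_name: str,
    level: Level = "pt",
    meddra_map: MedDRAMap | None = None,
    config: AnalysisConfig | None = None,
) -> ScanResult:
    """Scan every event label of the focal drug for disproportionality.

    Reports must already be deduplicated and role-filtered.  In ``mgps`` EBGM
    mode the gamma-mixture prior is fitted once across all tables of the scan
    before per-table shrinkage.
    """
    cfg = config or AnalysisConfig()
    tables = build_all_tables(
        reports, drug_name, level=level, meddra_map=meddra_map,
        min_count=cfg.min_count,
    )
    prior = None
    if cfg.ebgm_mode == "mgps" and tables:
        counts = [t.a for t in tables]
        expected = [expected_count(t) for t in tables]
        prior = _mgps.fit_prior(counts, expected).prior
    stats = [compute_signal_stats(t, cfg, prior=prior) for t in tables]
    stats.sort(key=lambda s: s.label)
    return ScanResult(stats=stats, prior=prior)
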