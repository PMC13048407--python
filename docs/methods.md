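# Methods

## The analysis problem

Spontaneous reporting systems (FAERS, VigiBase) accumulate individual case
safety reports (ICSRs): one case may be reported repeatedly (follow-up
versions share a case id), a drug may appear on a report as primary/secondary
suspect or merely as concomitant/interacting medication, and events are coded
as MedDRA preferred terms (PTs) that roll up to system organ classes (SOCs).
Disproportionality analysis asks, for a focal drug and each event, whether
the drug–event pair is reported more often than the rest of the database
would predict. There is no denominator of exposed patients; everything is
relative reporting frequency, so the output is a screening signal, not a
causal effect estimate.

## Pipeline conventions

- **Deduplication** keeps, per case id, the version with the latest report
  date. Ties keep the record appearing last in input order and log a
  warning — a deterministic, order-stable rule for a situation the data
  standard leaves open.
- **Role filtering** removes reports that name the focal drug *only* as
  concomitant or interacting; reports not naming it at all are retained as
  the comparator. A report with mixed roles counts as exposed.
- **Counting unit is the deduplicated report**, never the drug–event row: a
  report listing the same PT twice, or several PTs of one SOC, contributes 1
  to the exposed-event cell. This choice propagates into every statistic and
  is therefore fixed package-wide.
- **Comparator** is all other reports in the database (no active-comparator
  restriction).
- Multi-axial PTs must be resolved to a primary SOC by the user-supplied
  mapping; the MedDRA dictionary is licensed and is never bundled.
- Tables with fewer than 3 exposed-event cases are flagged `low_count` but
  computed and reported (common practice: such estimates are wildly
  unstable; dropping them silently would bias scans).

## Estimators

With cells a, b, c, d; N = a+b+c+d; E = (a+b)(a+c)/N:

| statistic | point estimate | interval |
|---|---|---|
| ROR | ad/(bc) | exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)) (Woolf) |
| PRR | [a/(a+b)]/[c/(c+d)] | exp(ln PRR ± z·√(1/a − 1/(a+b) + 1/c − 1/(c+d))) |
| χ² | Pearson on the 2×2 | Yates correction by default: deviation \|O−E\|−0.5 clamped at 0 |
| IC (plain) | log₂(a/E) | IC025 = IC − z·√(1/a − 1/N)/ln 2 (delta method) |
| IC (shrunk) | log₂((a+0.5)/(E+0.5)) | IC025 = IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2) |
| EBGM (plain) | a/E | EBGM05 = exp(ln(a/E) − 1.645·√(1/a − 1/N)) |
| EBGM (mgps) | exp(E[ln λ \| a]) | EBGM05 = posterior 5th percentile |

Mode choices, and why both exist: published SOC-level scan tables from
OpenVigil-style tooling satisfy IC = log₂(EBGM) with EBGM equal to the raw
observed/expected ratio — i.e. point estimates without Bayesian shrinkage.
`plain` mode reproduces that convention and is the default; `shrunk` (IC)
and `mgps` (EBGM) are the literature-standard Bayesian variants and are
first-class options. The plain IC025 formula is a documented package choice
(log-scale delta method); published tables do not print their interval
formula, so no claim of interval-level agreement is made, and the χ²
convention (Yates) likewise cannot be verified against printed values
without the raw marginals.

Degenerate inputs: a zero cell makes ROR/PRR non-estimable, so the Haldane
correction (add 0.5 to every cell) is applied automatically exactly when a
zero cell is present (`haldane="auto"`, recorded in the output row);
`always`/`none` are available. Plain IC/EBGM are non-estimable at a = 0
(returned as NaN with a reason code; NaN never satisfies a significance
criterion). E = 0 (an empty margin) marks every statistic non-estimable.

## The signal rule

All four criteria must hold: ROR lower 95% bound > 1; PRR ≥ 2 **and**
χ² ≥ 4; IC025 > 0; EBGM > 2. Thresholds live in `CriteriaConfig` and are
configurable; an optional minimum-case floor (commonly n ≥ 3) is available
but off by default, since the conjunction rule is usually applied without
it. No multiple-testing adjustment is applied — the four-criterion
conjunction is itself the conventional guard — and none is claimed.

## MGPS prior fitting

The two-gamma mixture prior λ ~ P·Gamma(α₁,β₁) + (1−P)·Gamma(α₂,β₂)
(shape/rate) makes the marginal of each observed count a mixture of
negative binomials. The five parameters are fitted by EM over all cells of
a scan:

- E-step: component responsibilities from the two NB likelihoods.
- M-step: mixture weight in closed form; each component's (α, β) by
  Nelder–Mead on (log α, log β), warm-started at the current value and
  rejected if it would lower the weighted likelihood — this preserves the
  EM guarantee that the observed-data log likelihood never decreases, which
  the tests assert on every fixture.
- Initialization θ₀ = (0.2, 0.1, 2, 4, 1/3); 5 restarts from multiplicative
  log-normal jitter (σ = 0.3) of θ₀, seeded; best final likelihood wins.
- Convergence: relative log-likelihood change < 1e−6, cap 1000 iterations.
- The mixture weight is clipped to [1e−6, 1−1e−6] to keep log P finite.
- Degenerate input (all counts zero, or fewer than 2 cells with E > 0)
  fails with a diagnostic rather than returning a boundary fit.

A caveat found while validating: when every cell is generated from a single
gamma component, the over-specified mixture does not push P to a boundary —
the minority component lingers with small weight near the same parameters.
The collapse test therefore asserts what actually characterizes collapse:
the dominant component approximates the generating gamma and the minority
weight falls well below its initial value.

Posterior per cell: Gamma(α_k + a, β_k + E) components with responsibilities
as weights; EBGM = exp(Σ w_k(ψ(α_k+a) − ln(β_k+E))); EBGM05 by Brent
root-finding on the mixture CDF between the two component 5th percentiles,
relative tolerance 1e−8. Shrinkage vanishes as a, E → ∞ at fixed a/E
(asserted within 1% at a = 10,000).

## Time to onset

TTO = earliest event onset date − earliest focal-drug start date, one value
per report (day 0, onset on the start date, is valid). Reports with a
missing start, missing onset, or negative difference are excluded with a
reason code into an audit table — exclusions are results, not errors.
Quantiles use linear interpolation between order statistics (numpy default,
type 7); the convention is stated because published medians/IQRs rarely
state theirs. Default bins [0,30], (30,60], (60,90], (90,180], (180,360],
(360,∞) days: only the first-month and beyond-a-year cut points are
standard in onset reporting; the intermediate cuts are a package choice and
fully configurable. The cumulative curve is a plain empirical CDF — there
is no censoring model, so this is not a Kaplan–Meier estimate and must not
be read as one.

## Synthetic reporting system

What it emulates: a 100,000-report universe (the default study scale used
throughout testing) with one focal drug at 2% prevalence; a catalog of PTs
with background per-report reporting rates (default 30 PTs, log-spaced
0.002–0.03 across six organ classes); planted signals acting
multiplicatively on the per-PT reporting probability of exposed reports
(reporting-rate semantics — exactly what disproportionality estimates);
demographics drawn from strata typical of an elderly-skewed
antihypertensive profile (48% female, ~49% missing age, physician-majority
reporters, 18.5% serious, year weights decaying from 2005); 5% of exposed
reports listing the drug only as concomitant (exercising the role filter);
missingness of start (45%) and onset (25%) dates plus a 2% onset-precedes-
start error rate (exercising the TTO audit; jointly they reproduce the
roughly 40% TTO-eligible fraction seen in real extracts); and a bimodal
onset mixture — 0.55·Exp(35 d) + 0.45·(60 d + Exp(400 d)) — giving ~32% of
onsets within 30 days and ~21% beyond 360 days, the early-acute/late-
chronic pattern of onset analyses. `OnsetModel.cdf/quantile` expose the
analytic truth the sample tests compare against.

What it deliberately does not emulate: PTs occur independently within a
report (real ICSRs correlate events — this *is* the null model the
estimators assume, which is what makes planted risk ratios recoverable and
nulls honest); every event of a report shares one onset episode; no
signal masking/competition, no under-reporting dynamics over calendar time,
no drug–drug interaction signals. Passing tests therefore demonstrate
correctness of the estimators and calibration under the estimators' own
model, not robustness to the correlation structure of real reporting data.

Reproducibility: one root seed; each aspect (exposure, events,
demographics, dates, onsets, missingness) draws from its own spawned
stream, so extending the generator never perturbs earlier draws. The same
config yields an identical report list.

Duplicate injection appends one later-dated, perturbed follow-up version
for a chosen fraction of cases, so deduplication can be validated by exact
bookkeeping (n·(1+f) records in, n out, later versions retained).

## Calibration and validation sizes

The null-calibration check scans 400 null PTs (rates 0.004–0.04) in a
100,000-report database: the fraction of PTs whose ROR lower bound exceeds
1 is compared to the nominal one-sided 2.5% of the Woolf interval (observed
≈ 3% — the Woolf interval is mildly anticonservative at moderate counts).
The planted-recovery check uses one PT at background 0.01 with risk ratio
5: ~2,000 exposed reports give ~100–300 exposed-event cases, enough for the
ROR to land in [4, 6] and the pair to pass all four criteria. MGPS recovery
uses 5,000 simulated cells. These sizes keep the full suite and the
acceptance script in the tens of seconds while leaving Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

- Disproportionality is hypothesis-generating: estimates are reporting
  ratios, not risks; no stratified (age/sex-adjusted) MGPS and no multi-item
  itemset mode is provided.
- Printed intervals/χ² of external scan tables cannot be re-derived without
  raw marginals; agreement is claimed (and tested) only for the point-value
  conventions (IC = log₂(EBGM) = log₂(a/E)) and the criteria logic.
- The BCPNN credibility interval exists in several published variants; the
  two implemented (delta-method plain, shrunk approximation) are stated
  choices, not claims about any particular external tool.
- The report reader validates row-by-row and rejects malformed rows; it is
  not a general FAERS ETL (no quarterly-file stitching, no drug-name
  normalization dictionary).
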