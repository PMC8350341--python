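# Methods

## Data model

The package operates on the JADER relational layout: DEMO (one row per
report: sex, 10-year age band, reporting year), DRUG (reported drugs with
an involvement code — suspected / concomitant / interacting — route, and
administration start/end dates), HIST (primary illness), REAC (adverse
events as MedDRA preferred terms, with onset date and one of six outcome
categories). Tables link on `report_id`; rows whose `report_id` has no
DEMO entry are dropped at load and counted in the load report, as are
duplicate DEMO keys, invalid involvement codes and unknown outcomes.
Duplicate (report, PT) event rows are deduplicated to the earliest
complete onset date and counted.

Dates are partial: `YYYYMMDD`, `YYYYMM`, or `YYYY`. Partiality is
retained at load — only the time-to-onset extraction demands complete
dates — and unparseable or calendar-impossible values become missing
fields on retained rows. Drug names are normalized by NFKC folding
(unifying full-width/half-width forms), whitespace collapsing and
case-folding; matching is exact on normalized names, with an opt-in
substring mode for brand and salt variants.

The counting unit for all association analyses is the report: a drug
listed twice in a report, or an event coded under two matching PTs,
contributes one.

## Case definitions

Cases are defined by substring queries over the narrow-scope PT lists of
three gastrointestinal SMQs (20000104, 20000105, 20000107). The standard
queries are the nine-substring composite (ileus, stenosis, obstruction,
obstructive, impaction, perforation, perforated, hypomotility,
intussusception) and its obstruction / perforation / ileus restrictions.
Matching is case-insensitive substring on the PT name as supplied in the
dictionary file; no MedDRA hierarchy traversal is attempted. MedDRA is
licensed, so the dictionary is always user-supplied (CSV: smq_id,
smq_name, scope, pt_name); the packaged
`data/synthetic_smq_fixture.csv` is a small synthetic stand-in used by
the tests, and PT-count properties of the real SMQ lists are therefore
not unit-test assertions.

## Disproportionality

ROR = a·d/(b·c) with the Woolf interval
`exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`. Choices:

- **No continuity correction.** Recomputing published rows from their
  printed marginals matches the printed values only without a
  Haldane–Anscombe correction; zero-cell tables are reported as not
  estimable instead.
- **1.96**, not a higher-precision 0.975 quantile — the field convention,
  and it matches printed intervals to their rounding.
- **Two flags, not one.** `estimable` (all cells positive, a ≥ 2) and
  `signal` (estimable and lower bound > 1) are reported separately;
  published tables conflate them in a single "-"/footnote convention.
- Report output rounds half-up to one decimal; internal values keep full
  precision.
- No multiple-testing adjustment: the ROR screen is a rough ranking
  device, not an inferential family.

## Time-to-onset

Latency = onset date − earliest complete administration **start** date of
that drug in that report, per (report, drug, PT), retained when
0 ≤ days ≤ 90. The window length, the quantile rule and the anchor are
config options; `anchor="end"` (last administration date) implements the
alternative reading of "time since last prescription". Exclusions
(incomplete date, negative, beyond window) are tallied, never silently
dropped.

Summaries use linear interpolation between order statistics (the common
"type 7" rule) — the original analysis software is unknown, so the rule
is explicit and configurable.

The Weibull fit maximizes the two-parameter likelihood in (ln α, ln β)
with an analytic gradient (L-BFGS-B, Gumbel-moment initialization). Wald
95% intervals come from the observed information matrix on the log scale,
guaranteeing positive bounds; a seeded percentile bootstrap is available
as an option. Zero-day latencies enter the likelihood as 0.5 day (the
half-day convention for same-day onset at day resolution) but keep their
raw zeros in medians and quartiles. Samples with n < 3 or fewer than two
distinct values are reported unfitted. Hazard classification uses only β
and its CI: increasing if the lower bound exceeds 1, decreasing if the
upper bound is below 1, otherwise compatible with constant.

Simulation calibration (in the test suite): over β ∈ {0.7, 1, 1.5, 2.5} ×
α ∈ {3, 20, 40} days with n = 500 per fit and 150 replicates per cell,
the median relative bias of β̂ is below 5% in every cell and the pooled
empirical CI coverage lies in [92%, 98%]. Multiplying a latency sample by
k multiplies α̂ by k and leaves β̂ unchanged (asserted to optimizer
tolerance); shifting all latencies changes β̂, which is why the zero-shift
is applied to zeros only.

## Outcomes

One outcome per (report, stratum) by worst severity (death >
with_sequelae > not_recovered > convalescent > recovery > others);
missing outcomes pool into "others" so stratum totals equal case counts.
Strata are drug groups or age bands. The mosaic export encodes stratum
widths proportional to case totals and rectangle heights proportional to
within-stratum outcome proportions; rendering is a thin optional
matplotlib layer. The death-flag helper lists strata whose death share
strictly exceeds a threshold (default 10%).

## Synthetic generator

The generator emulates the statistical structure the analyses assume,
with every quantity recoverable:

- **Association.** A report's case odds are the background odds
  `p0/(1−p0)` multiplied by θ_d for every drug held as a *suspected*
  exposure (exposures drawn independently per drug). Because the analysis
  keeps suspected drugs only, the population ROR for drug d is exactly
  θ_d, making `expected_ror` an identity and the generator an estimator
  oracle. Conditional-on-other-drugs and marginal odds ratios coincide
  here only because exposures are independent and rare.
- **Latency.** Each case anchors to one uniformly chosen suspected drug;
  its latency is drawn from that drug's Weibull(α, β), rounded half-up to
  whole days (JADER stores day resolution) and truncated at the study
  window end. Non-anchored cases and non-cases get uniform onset dates.
- **Dates.** Start, end and onset dates are independently degraded with
  probability `date_missing_prob`, half to fully missing and half to
  year-month precision, so the completeness of a (start, onset) pair is
  (1−p)².
- **Outcomes** draw from per-drug six-category mixtures (anchored cases)
  or a common background mixture.
- One DIG event per case by default; `multi_pt_prob` adds second PTs to
  exercise report-level dedup paths.

Ground truth records the per-drug report-level 2×2, suspected/exposed
report sets, drawn latencies, and the count of complete, in-window
(report, drug, event) pairings — computed from the generator's internal
arrays, not by running the analysis code, so the equality
`build_contingency == truth` is a genuine cross-module oracle.

What the generator does **not** emulate: reporting dynamics (Weber
effect, notoriety bias), correlated polypharmacy, indication
confounding, within-report drug duplicates, or free-text name noise.
Passing tests therefore demonstrate estimator correctness under the
stated sampling model, not robustness to real-world reporting artifacts.

### Default and study conditions

The default world is a scaled-down SRS: 20,000 reports, background case
probability 0.017 (the composite-case share of the real database), four
drugs spanning strong/short-latency, strong/long-latency, moderate and
null profiles, 8% date missingness, suspected fraction 0.6, study window
April 2004 – November 2020. The null-calibration study uses one null
drug (θ = 1) with exposure probability 0.2 and background event
probability 0.08 at n = 5,000 — chosen once so all four expected cells
are large enough (≳ 45) for the Woolf interval's nominal level to be the
quantity under test rather than small-count artifacts; observed coverage
over 2,000 replicates must lie within 95% ± 2%.

## Problem sizes

Test simulations use 3,000–60,000 reports per database, 150 replicates
per Weibull grid cell, and 2,000 null replicates; these sizes put Monte
Carlo error comfortably inside every asserted tolerance while keeping
the default suite around two minutes.

## Known limitations

- The ROR is a reporting association, not a risk estimate; no covariate
  adjustment (reporting year, age) is implemented.
- No censoring-aware survival modelling; latencies beyond the window are
  discarded, not censored.
- Weibull Wald intervals are first-order; for very small n (≲ 10) their
  coverage degrades — the bootstrap option is preferable there.
- The 79/23/34/8 PT-count properties of the real composite and
  sub-queries can only be checked by users holding a MedDRA license.
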