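# Methods

## Problem setting

Spontaneous reporting databases (FAERS and its analogues) are
numerator-only: each record is a suspected drug–adverse-event report
with demographics, drug roles, reaction terms coded as MedDRA Preferred
Terms (PTs), receipt and therapy dates — but there is no count of
exposed, unaffected patients. Signal detection therefore compares each
drug–event pair's reporting rate against the background formed by all
other pairs in the same universe. `pvsignal` implements that workflow
for a single target event defined by a PT set (the bundled default is
retinal vein occlusion, PT 10038907), from raw quarterly files to
ranked signals and onset-time summaries.

## Ingestion and deduplication

Quarterly tables (DEMO/DRUG/REAC/THER) are `$`-delimited text with one
header line, read as Latin-1 with replacement of undecodable bytes
(legacy quarters are not valid UTF-8). Rows with a field count that
does not match the header, or non-numeric identifiers, are excluded and
counted per file — the malformed/orphan counters plus the output rows
always account for every input line. Dates come in three dialects
(YYYY, YYYYMM, YYYYMMDD) and are kept at their stated precision;
invalid strings are treated as absent.

A case may appear as several report versions. Per FDA deduplication
practice the pipeline keeps, for each CASEID, the report with the
latest receipt date (FDA_DT), breaking ties by the numerically highest
PRIMARYID. Partial dates are compared through a total-order key in
which unknown components rank earliest: a year-only date never outranks
a fully dated report from the same year, and a record with no receipt
date survives only when no dated sibling exists. Deduplication is
idempotent and independent of input order, and its output is sorted by
CASEID.

Selection then proceeds in a fixed order: deduplicate → standardize
drug names through the synonym table → keep healthcare-professional
reporters → partition into event / non-event cases → admit drugs with
at least `min_reports_per_drug` (default 3, boundary inclusive) event
cases in a kept role (default: primary suspect only). "Healthcare
professional" maps to the occupation codes MD, PH and OT; this is
configurable, as is everything else in `FilterConfig`. Each stage
writes its counts into the provenance map.

The denominator universe for the b/c/d cells is the deduplicated,
reporter-filtered case universe — the same population whose event cases
supply `a`. Using the full unfiltered report stream instead is
supported by running with `reporters_kept` covering all occupations;
the restricted universe is the default because the analysis elsewhere
(report floor, onset cohort) is defined on professional-reported cases.

## Contingency tables and the four statistics

One case counts once per drug, even with several matching reaction PTs;
a multi-suspect case contributes to every suspect drug's table, so the
sum of `a` across drugs may exceed the event-case total while `a + c`
is the same for every drug. If any cell of a table is zero when a
statistic is requested, a Haldane continuity correction (+0.5 to all
four cells) is applied for that computation and the result is flagged.
(The correction is stated for zero b/c/d in the usual rule; it is
applied for `a = 0` as well, since the Wald and log formulas are equally
undefined there. Flagged results are excluded from the algebraic-identity
tests, which require uncorrected integer tables.)

The four statistics are computed exactly as defined in the README. Two
points deserve emphasis:

- **Crude EBGM, not a DuMouchel fit.** `EBGM = aN/((a+b)(a+c))` is the
  maximum-likelihood observed/expected reporting ratio, and
  `EBGM05` is a one-sided normal-approximation bound using the same
  `√(1/a+1/b+1/c+1/d)` standard error as the ROR. A full gamma-Poisson
  mixture (empirical-Bayes hyperparameter estimation with shrinkage)
  would shrink small-count cells toward the prior; it is deliberately
  not implemented, and `ebgm_stats` is the single extension point where
  a shrinkage estimator could be substituted.
- **Crude IC as the headline BCPNN value.** Under the crude
  definitions `IC = log2(EBGM)` identically, and the headline "BCPNN
  value" reported by the pipeline is this crude IC. The prior-based
  posterior moments E(IC), V(IC) (Dirichlet prior counts
  α₁ = β₁ = γ₁₁ = 1, α = β = 2) are always computed alongside, and the
  signal bound IC025 = E(IC) − 2√V(IC) always uses them. As all cells
  grow proportionally E(IC) → IC and V(IC) → 0, which the tests assert
  at scale factors 10² and 10⁴.

The χ² statistic attached to the PRR defaults to the Yates-corrected
variant — the common convention for sparse 2×2 pharmacovigilance
tables — with plain Pearson available; both are cross-checked against
`scipy.stats.chi2_contingency`. The 1.96 and 1.64 multipliers are
fixed constants of the method (two-sided and one-sided 95%), not
configuration.

Joint positivity is the conjunction of the four published criteria
(a ≥ 3 and ROR lower bound > 1; a ≥ 3 and PRR lower bound > 1;
IC025 > 0; EBGM05 > 2 and a > 0); being a conjunction it is
conservative, which the null-calibration experiment quantifies.
Ranking is by descending IC025, ties by descending ROR then name.
Report tables round half-up to 3 decimals.

A useful algebraic fact, asserted over random tables: for any table
with ROR > 1, `ROR ≥ PRR ≥ EBGM`, with equality exactly at
independence (ad = bc), and the ordering reverses when ROR < 1.

## Bundled reference statistics

The package ships a published study's per-drug signal table (25
RVO-associated drugs with ROR/CI, PRR/χ², EBGM/EBGM05, IC and its
printed lower bound) plus its outcome, sex and country counts. These
are inputs for identity checks — the printed upper CI bound must follow
from the estimate and lower bound by Wald log-symmetry
(`ci_high = ROR²/ci_low`), the printed EBGM05 from the printed EBGM and
the SE recovered from the ROR CI, and the printed IC column equals
log2 of the printed EBGM column — never outputs of this package. One
internal inconsistency exists in that source: the drospirenone row's
IC (3.431) differs from log2 of its EBGM (3.443) by more than printed
rounding; all other 24 rows agree to 3 decimals. The printed IC025
column of that table is *not* reproducible from the documented variance
formula (the printed IC − IC025 gap is constant across rows, which no
posterior-variance expression produces), so the pipeline computes IC025
from the formulas above and does not imitate the printed bounds.

## Time to onset

Onset is `event_date − therapy_start` in days, computed only for event
cases of signal drugs where both dates are day-precise; year-month
dates can be imputed to day 15 behind an opt-in flag (default:
excluded), and negative differences are excluded. All exclusions are
counted, and on synthetic data the counters must match the generator's
bookkeeping exactly.

There is no censoring — a spontaneous report exists only because the
event occurred — so every onset is an observed event and the
Kaplan-Meier estimate (computed via `lifelines.KaplanMeierFitter`)
coincides with the empirical survival function, which the tests assert.
Class comparisons use the k-sample log-rank test
(`lifelines.statistics.multivariate_logrank_test`, χ² with k−1 df).
Summary quantiles use linear interpolation at position 1 + (n−1)p
(numpy's default); class-level medians are medians of the pooled
per-case onsets under the same convention, not means of per-drug
medians.

## Synthetic universe

The generator is the package's ground-truth instrument. Per case it
draws one primary-suspect drug from exposure margins summing to 1, a
target-event indicator with probability `min(1, lift · p0)` (lift 1 =
null), 1–3 filler reaction PTs, demographics (age ~ N(58.8, 16.9),
weight ~ N(70.5, 21.2), sex / country / outcome frequencies from the
bundled published cohort mix), a reporter occupation, and day-precise
therapy/event/receipt dates; for event cases the onset is drawn from
the drug's configured model (exponential, lognormal or Weibull,
parametrized by the median), rounded to whole days and floored at 1.
A configured fraction of cases is emitted twice — the follow-up shares
the CASEID with a later receipt date and higher PRIMARYID — and a
configured fraction has a date dropped or degraded to month precision.
Ground truth records the exact per-drug (a, b, c, d) after ideal
deduplication, the true onset models and per-drug complete/degraded
onset counts, so every stage can be checked against bookkeeping.

The default desk-scale spec is 50,000 cases over 205 drugs: the 25
bundled signal drugs carry planted lifts log-graded from 80 down to 4
(the span of the published effect sizes) at exposure 0.004 each, 180
null filler drugs share the remaining margin, baseline event rate
p0 = 0.005, 20% duplicate reports, 25% degraded dates; planted drugs
inherit their ATC class's published median onset (lognormal, σ = 1) and
fillers are exponential with median 180 days. Spec validation rejects
any planted drug whose expected `a` falls below 1. A population-scale
factory (~460k cases, event cohort near 2,300) exists for larger runs;
tests and the acceptance script use the desk scale so the default suite
finishes in well under a minute.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: drug co-prescription structure and
masking/competition bias, stimulated-reporting waves, misspelled or
free-text drug names beyond the synonym table, indication confounding,
and real FAERS quirks such as cross-quarter case migration. The
planted-lift model also makes exposure and event independence exact for
null drugs, which real databases never guarantee.

## Calibration experiments

- **Null calibration**: 200 universes with every lift at 1; each of the
  205 drugs per universe is one test, and the joint criterion's flag
  rate stays well under 5% (conjunction of four thresholds plus the
  a ≥ 3 floor is conservative at these cell sizes).
- **Coverage**: one drug planted at lift 50 (exposure 0.01,
  p0 = 0.005, implying a true odds ratio of 66.3); across 100
  replicates the ROR 95% CI must cover the true value at least 90
  times.
- **Onset separation**: two exponential groups with a 4-fold rate
  difference at n = 200 each give log-rank p < 10⁻⁴; KM median
  recovery is assessed as the mean over 10 replicate draws of n = 500,
  since a single sample median at that n has ~9% sampling SD.

## Known limitations

- The crude EBGM/IC carry no shrinkage; small-count signals are noisier
  than a fitted gamma-Poisson or full Bayesian IC would be.
- No stratification (age/sex/year) and no multiplicity correction
  across drugs, matching standard first-pass practice.
- The onset analysis treats one onset per (case, drug) pair and ignores
  dechallenge/rechallenge information.
- Only the four core quarterly tables are consumed; the outcome field
  is carried on the demographic table rather than a separate outcomes
  table.
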