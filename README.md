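# pvsignal

Disproportionality signal detection and time-to-onset analysis for
spontaneous adverse-event reports, built around the workflow used in
FAERS pharmacovigilance studies of drug-induced retinal vein occlusion
(RVO, MedDRA PT 10038907).

Spontaneous reporting systems such as the FDA Adverse Event Reporting
System collect millions of suspected drug–event reports but have no
denominator of exposed patients. Disproportionality analysis asks
instead whether a drug–event pair is reported *more often than expected*
relative to the rest of the database. `pvsignal` is aimed at
pharmacoepidemiologists who want that workflow — quarterly-file
ingestion, FDA-rule deduplication, case selection, four signal
algorithms, risk tiers, and onset-time analysis — as a tested,
reproducible pipeline, exercisable end to end on synthetic report
universes with known ground truth.

## The statistics

For each drug the deduplicated case universe is collapsed to a 2×2
table: `a` cases with the drug and the event, `b` with the drug only,
`c` with the event only, `d` with neither, and `N = a+b+c+d`.

- **ROR** (reporting odds ratio): `ROR = ad/bc`, with Wald interval
  `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
- **PRR** (proportional reporting ratio):
  `PRR = [a/(a+b)] / [c/(c+d)]`, Wald interval with
  `SE = √(1/a − 1/(a+b) + 1/c − 1/(c+d))`, plus the 2×2 χ² statistic
  (Yates-corrected by default).
- **BCPNN information component**: crude
  `IC = log2[aN / ((a+b)(a+c))]`; with Dirichlet priors
  (α₁ = β₁ = γ₁₁ = 1, α = β = 2) the posterior moments E(IC) and V(IC)
  give the lower bound `IC025 = E(IC) − 2√V(IC)`.
- **EBGM** (crude observed/expected ratio): `EBGM = aN/((a+b)(a+c))`
  with `EBGM05 = exp(ln EBGM − 1.64·√(1/a+1/b+1/c+1/d))`.

A drug is a **joint signal** when all four criteria hold at once:
`a ≥ 3` with ROR and PRR lower 95% bounds > 1, `IC025 > 0`, and
`EBGM05 > 2` with `a > 0`. IC025 also grades risk:
(0, 1.5] low, (1.5, 3] medium, > 3 high. For joint-signal drugs the
time from therapy start to the event is summarized per drug and per ATC
class (median, quartiles, Kaplan-Meier curves, k-sample log-rank test;
no censoring, since spontaneous reports carry no follow-up).

## Worked example

All four statistics for one table, from the command line:

```text
$ pvsignal stats --table 10,90,100,9900
a=10 b=90 c=100 d=9900 N=10100
ROR   11.0 (5.56-21.764)
PRR   10.0 (5.382-18.58), chi2 66.327
IC    3.199  E(IC) 2.382  IC025 1.427
EBGM  9.182  EBGM05 5.187
joint signal: True  tier: low
```

The event is ~10× over-reported for this drug (ROR 11.0, EBGM 9.18);
every criterion clears its threshold, so the pair is a joint signal,
and IC025 = 1.43 places it in the low-risk tier.

A full synthetic study runs through the numbered drivers:

```bash
python analysis/01_simulate_reports.py --seed 1   # FAERS-dialect quarter
python analysis/02_ingest_and_dedup.py            # join, dedup, filters
python analysis/03_signal_detection.py            # four algorithms + tiers
python analysis/04_time_to_onset.py               # KM curves, log-rank
python analysis/05_descriptive_report.py          # cohort summary, export
```

With seed 1 the simulated universe holds 60,000 reports that collapse
to 50,000 unique cases (the 10,000 planted duplicate reports are all
removed); 34 drugs clear the three-event-case floor, 15 of the 25
planted signal drugs are recovered as joint signals with zero false
positives among the 180 null drugs, and the log-rank test separates the
drug classes' onset distributions at p ≈ 8×10⁻⁹. Tables land in
`results/`.

The same pipeline runs on real quarterly extracts via
`pvsignal run --quarters <dir> --config <file> --out <dir>`.

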