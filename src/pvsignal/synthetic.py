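"""Synthetic spontaneous-report universes with exact ground truth.

The generator emulates the structure of a FAERS quarterly extract at
case level: each synthetic case carries one primary-suspect drug drawn
from configured exposure margins, a Bernoulli target-event indicator
whose probability is the baseline reporting rate ``p0`` inflated by the
drug's planted lift (lift 1 = null, no association), one to three filler
reaction PTs, demographics and reporter occupation, therapy-start /
event / FDA-receipt dates in the FAERS partial-date dialects, and —
for a configured fraction of cases — a second report sharing the CASEID
(a follow-up version with a later receipt date and higher PRIMARYID),
which the deduplication stage must collapse.

Alongside the reports the generator returns :class:`GroundTruth`: the
exact per-drug (a, b, c, d) after ideal deduplication, the true onset
distributions, and per-drug counts of onsets hidden by degraded dates.
Every pipeline stage can therefore be checked against bookkeeping
rather than against itself.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np

from .contingency import ContingencyTable
from .faers_io import DrugEntry, PartialDate, ReportRecord, copy_record
from .reference import (
    REFERENCE_COUNTRY_COUNTS,
    REFERENCE_SEX_COUNTS,
    TARGET_PT,
    load_class_map,
    reference_signals,
)

FILLER_PTS = (
    "10019211", "10028813", "10012378", "10047700", "10016558",
    "10013573", "10037175", "10046735",
)

#: Published per-class median onset days used for the default onset models.
CLASS_ONSET_MEDIANS = {
    "Sensory Organ Drugs": 532.01,
    "Antiparasitic Drugs": 362.77,
    "Nervous System Drugs": 265.52,
    "Urogenital System and Sex Hormone Drugs": 210.39,
    "Antitumor and Immunomodulating Drugs": 200.70,
    "Musculoskeletal System Drugs": 179.83,
}

DEFAULT_REPORTER_MIX = {
    "physician": 0.40,
    "pharmacist": 0.12,
    "other_health_professional": 0.13,
    "consumer": 0.22,
    "lawyer": 0.01,
    "unknown": 0.12,
}


@dataclass(frozen=True)
class DrugSpec:
    name: str
    exposure: float              # marginal P(case's primary suspect = drug)
    lift: float = 1.0            # multiplies p0 for the target event
    onset_family: str = "exponential"   # exponential | lognormal | weibull
    onset_median: float = 180.0
    onset_shape: float = 1.0     # lognormal sigma / weibull shape


@dataclass
class SyntheticSpec:
    n_cases: int
    drugs: list[DrugSpec]
    p0: float = 0.005
    duplicate_rate: float = 0.2
    reporter_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REPORTER_MIX)
    )
    missing_date_rate: float = 0.25
    date_window: tuple[str, str] = ("20040101", "20231231")
    seed: int = 0

    def validate(self) -> None:
        probs = [d.exposure for d in self.drugs] + [
            self.p0, self.duplicate_rate, self.missing_date_rate
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(d.exposure for d in self.drugs) - 1.0) > 1e-9:
            raise ValueError("drug exposure margins must sum to 1")
        for d in self.drugs:
            if d.lift < 0:
                raise ValueError(f"{d.name}: lift must be >= 0")
            if d.lift != 1.0:
                expected_a = (
                    self.n_cases * d.exposure * min(1.0, d.lift * self.p0)
                )
                if expected_a < 1.0:
                    raise ValueError(
                        f"infeasible spec: expected a = {expected_a:.2f} < 1 "
                        f"for planted drug {d.name}"
                    )


@dataclass
class GroundTruth:
    n_cases: int
    tables: dict[str, tuple[int, int, int, int]]
    event_total: int
    onset_models: dict[str, tuple[str, float, float]]
    onset_missing_by_drug: dict[str, int] = field(default_factory=dict)
    onset_complete_by_drug: dict[str, int] = field(default_factory=dict)
    n_duplicate_reports: int = 0

    def true_odds_ratio(self, spec: SyntheticSpec, drug: str) -> float:
        """Population odds ratio implied by the planted lift."""
        d = next(x for x in spec.drugs if x.name == drug)
        p1 = min(1.0, d.lift * spec.p0)
        p0 = spec.p0
        return (p1 / (1 - p1)) / (p0 / (1 - p0))


@dataclass
class Universe:
    """Vectorized case-level draw (before report materialization)."""

    spec: SyntheticSpec
    drug_idx: np.ndarray
    event: np.ndarray
    onset_days: np.ndarray        # 0 where not an event
    truth: GroundTruth


def sample_universe(spec: SyntheticSpec, rng: np.random.Generator) -> Universe:
    """Draw the case-level universe and derive exact ground truth."""
    spec.validate()
    names = [d.name for d in spec.drugs]
    exposure = np.array([d.exposure for d in spec.drugs])
    lifts = np.array([d.lift for d in spec.drugs])
    n = spec.n_cases

    drug_idx = rng.choice(len(names), size=n, p=exposure)
    p_event = np.minimum(1.0, lifts[drug_idx] * spec.p0)
    event = rng.random(n) < p_event

    onset = np.zeros(n)
    for i, d in enumerate(spec.drugs):
        mask = event & (drug_idx == i)
        k = int(mask.sum())
        if k == 0:
            continue
        if d.onset_family == "exponential":
            raw = rng.exponential(d.onset_median / math.log(2.0), size=k)
        elif d.onset_family == "lognormal":
            raw = rng.lognormal(math.log(d.onset_median), d.onset_shape, size=k)
        elif d.onset_family == "weibull":
            scale = d.onset_median / math.log(2.0) ** (1.0 / d.onset_shape)
            raw = scale * rng.weibull(d.onset_shape, size=k)
        else:
            raise ValueError(f"unknown onset family: {d.onset_family!r}")
        onset[mask] = np.maximum(1, np.round(raw))

    event_total = int(event.sum())
    tables: dict[str, tuple[int, int, int, int]] = {}
    for i, name in enumerate(names):
        a = int((event & (drug_idx == i)).sum())
        b = int((~event & (drug_idx == i)).sum())
        c = event_total - a
        d_cell = n - a - b - c
        tables[name] = (a, b, c, d_cell)

    truth = GroundTruth(
        n_cases=n,
        tables=tables,
        event_total=event_total,
        onset_models={
            d.name: (d.onset_family, d.onset_median, d.onset_shape)
            for d in spec.drugs
        },
    )
    return Universe(spec, drug_idx, event, onset, truth)


def ground_truth_tables(truth: GroundTruth) -> list[ContingencyTable]:
    """Exact tables for oracle comparison, sorted by descending a then name."""
    tables = [
        ContingencyTable(name, *cells) for name, cells in truth.tables.items()
    ]
    tables.sort(key=lambda t: (-t.a, t.drug))
    return tables


def _ordinal_range(window: tuple[str, str]) -> tuple[int, int]:
    start = _dt.datetime.strptime(window[0], "%Y%m%d").date().toordinal()
    end = _dt.datetime.strptime(window[1], "%Y%m%d").date().toordinal()
    return start, end


def _full_date(ordinal: int) -> PartialDate:
    d = _dt.date.fromordinal(int(ordinal))
    return PartialDate(d.year, d.month, d.day)


def generate(
    spec: SyntheticSpec, seed: int | None = None
) -> tuple[list[ReportRecord], GroundTruth]:
    """Materialize the universe as FAERS-style report records.

    Reports are shuffled (duplicates interleaved) so the deduplication
    stage cannot rely on input order.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    uni = sample_universe(spec, rng)
    truth = uni.truth
    names = [d.name for d in spec.drugs]
    n = spec.n_cases
    lo, hi = _ordinal_range(spec.date_window)

    occ_names = list(spec.reporter_mix)
    occ_probs = np.array([spec.reporter_mix[o] for o in occ_names])
    occ_probs = occ_probs / occ_probs.sum()
    occupations = rng.choice(len(occ_names), size=n, p=occ_probs)

    sex_names = list(REFERENCE_SEX_COUNTS)
    sex_probs = np.array(list(REFERENCE_SEX_COUNTS.values()), dtype=float)
    sexes = rng.choice(len(sex_names), size=n, p=sex_probs / sex_probs.sum())

    country_names = list(REFERENCE_COUNTRY_COUNTS)
    country_probs = np.array(
        list(REFERENCE_COUNTRY_COUNTS.values()), dtype=float
    )
    countries = rng.choice(
        len(country_names), size=n, p=country_probs / country_probs.sum()
    )

    ages = np.clip(rng.normal(58.8, 16.9, size=n), 0, 110)
    weights = np.clip(rng.normal(70.5, 21.2, size=n), 2, 250)
    outcome_pool = np.array(
        ["other_serious", "disability", "hospitalization", "death",
         "life_threatening"]
    )
    outcome_probs = np.array([2062, 361, 316, 30, 20], dtype=float)
    outcomes = rng.choice(
        len(outcome_pool), size=n, p=outcome_probs / outcome_probs.sum()
    )

    starts = rng.integers(lo, hi - 400, size=n)
    fda_lag = rng.integers(5, 200, size=n)
    degrade = rng.random(n) < spec.missing_date_rate
    degrade_kind = rng.integers(0, 3, size=n)  # 0 drop start, 1 drop event, 2 month-precision
    n_fillers = rng.integers(1, 4, size=n)

    records: list[ReportRecord] = []
    missing_by_drug: dict[str, int] = {}
    complete_by_drug: dict[str, int] = {}
    for i in range(n):
        name = names[uni.drug_idx[i]]
        caseid = str(10_000_000 + i)
        is_event = bool(uni.event[i])
        start_ord = int(starts[i])
        if is_event:
            event_ord = start_ord + int(uni.onset_days[i])
        else:
            event_ord = start_ord + int(rng.integers(1, 300))
        therapy_start: PartialDate | None = _full_date(start_ord)
        event_date: PartialDate | None = _full_date(event_ord)
        if degrade[i]:
            if degrade_kind[i] == 0:
                therapy_start = None
            elif degrade_kind[i] == 1:
                event_date = None
            else:
                therapy_start = PartialDate(
                    therapy_start.year, therapy_start.month
                )
        if is_event:
            if degrade[i]:
                missing_by_drug[name] = missing_by_drug.get(name, 0) + 1
            else:
                complete_by_drug[name] = complete_by_drug.get(name, 0) + 1

        reactions = list(
            rng.choice(FILLER_PTS, size=int(n_fillers[i]), replace=False)
        )
        if is_event:
            reactions.insert(0, TARGET_PT)
        records.append(
            ReportRecord(
                primaryid=caseid + "1",
                caseid=caseid,
                fda_date=_full_date(event_ord + int(fda_lag[i])),
                event_date=event_date,
                reporter_occupation=occ_names[occupations[i]],
                sex=sex_names[sexes[i]],
                age_years=round(float(ages[i]), 1),
                weight_kg=round(float(weights[i]), 1),
                country=country_names[countries[i]],
                drugs=[
                    DrugEntry(name=name, role="primary_suspect",
                              therapy_start=therapy_start, seq="1")
                ],
                reactions=reactions,
                outcome=str(outcome_pool[outcomes[i]]),
            )
        )

    truth.onset_missing_by_drug = missing_by_drug
    truth.onset_complete_by_drug = complete_by_drug

    n_dup = int(math.floor(spec.duplicate_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False)
    duplicates = []
    for i in dup_idx:
        orig = records[i]
        fda = orig.fda_date.to_date().toordinal() + int(rng.integers(10, 120))
        duplicates.append(
            copy_record(
                orig,
                primaryid=orig.caseid + "2",
                fda_date=_full_date(fda),
            )
        )
    truth.n_duplicate_reports = n_dup

    all_records = records + duplicates
    order = rng.permutation(len(all_records))
    return [all_records[int(k)] for k in order], truth


# ---------------------------------------------------------------------------
# Bundled study specs
# ---------------------------------------------------------------------------

def desk_spec(
    seed: int = 0,
    n_cases: int = 50_000,
    null: bool = False,
    duplicate_rate: float = 0.2,
    missing_date_rate: float = 0.25,
    planted_exposure: float = 0.004,
) -> SyntheticSpec:
    """Desk-scale universe: 205 drugs, 25 planted lifts graded 80 -> 4.

    The 25 planted drugs are the published signal drugs; each inherits
    its class's published median onset time (lognormal, sigma = 1).
    ``null=True`` sets every lift to 1 (calibration universes).
    """
    ref = reference_signals().sort_values("ror", ascending=False)
    class_map = load_class_map()
    planted_names = list(ref.drug)
    lifts = np.geomspace(80.0, 4.0, len(planted_names))
    n_filler = 180
    filler_exposure = (1.0 - planted_exposure * len(planted_names)) / n_filler

    drugs = []
    for name, lift in zip(planted_names, lifts):
        atc = class_map[name][0]
        drugs.append(
            DrugSpec(
                name=name,
                exposure=planted_exposure,
                lift=1.0 if null else float(lift),
                onset_family="lognormal",
                onset_median=CLASS_ONSET_MEDIANS.get(atc, 180.0),
                onset_shape=1.0,
            )
        )
    for k in range(n_filler):
        drugs.append(
            DrugSpec(
                name=f"filler_{k:04d}",
                exposure=filler_exposure,
                lift=1.0,
                onset_family="exponential",
                onset_median=180.0,
            )
        )
    return SyntheticSpec(
        n_cases=n_cases,
        drugs=drugs,
        p0=0.005,
        duplicate_rate=duplicate_rate,
        missing_date_rate=missing_date_rate,
        seed=seed,
    )


def single_drug_spec(
    lift: float = 50.0,
    exposure: float = 0.01,
    p0: float = 0.005,
    n_cases: int = 50_000,
    seed: int = 0,
) -> SyntheticSpec:
    """One planted drug among 100 null fillers (coverage experiments)."""
    n_filler = 100
    filler_exposure = (1.0 - exposure) / n_filler
    drugs = [DrugSpec("planted", exposure, lift)] + [
        DrugSpec(f"filler_{k:04d}", filler_exposure, 1.0)
        for k in range(n_filler)
    ]
    return SyntheticSpec(
        n_cases=n_cases, drugs=drugs, p0=p0,
        duplicate_rate=0.0, missing_date_rate=0.0, seed=seed,
    )


def population_scale_spec(seed: int = 0) -> SyntheticSpec:
    """Population-scale variant: ~460k professional-reported-case
    equivalent with p0 tuned so event cases land near 2,300."""
    spec = desk_spec(seed=seed, n_cases=460_000)
    spec.p0 = 2300 / (460_000 * 1.1)  # ~10% of events come from planted lifts
    return spec
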