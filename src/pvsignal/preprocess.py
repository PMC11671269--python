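"""Case deduplication and selection filters.

Spontaneous-report databases contain follow-up versions of the same
case.  Per FDA guidance the pipeline keeps, for each CASEID, the report
with the most recent FDA receipt date, breaking receipt-date ties by the
numerically highest PRIMARYID.  Downstream counting is case-level:
the deduplicated universe defines N, and the analysis is then restricted
to healthcare-professional reporters, the event is defined by a set of
MedDRA Preferred Terms, and only drugs linked (in a suspect role) to a
minimum number of event cases enter disproportionality testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .faers_io import ReportRecord, compare_partial_dates

HEALTHCARE_PROFESSIONALS = frozenset(
    {"physician", "pharmacist", "other_health_professional"}
)


@dataclass
class FilterConfig:
    """Selection parameters for one analysis run."""

    target_pts: frozenset[str]
    roles_kept: frozenset[str] = frozenset({"primary_suspect"})
    reporters_kept: frozenset[str] = HEALTHCARE_PROFESSIONALS
    min_reports_per_drug: int = 3

    def __post_init__(self):
        self.target_pts = frozenset(str(pt) for pt in self.target_pts)
        self.roles_kept = frozenset(self.roles_kept)
        self.reporters_kept = frozenset(self.reporters_kept)
        if self.min_reports_per_drug < 1:
            raise ValueError("min_reports_per_drug must be >= 1")


@dataclass
class CaseSet:
    """Deduplicated cases plus per-stage provenance counts.

    ``event_caseids`` is populated by :func:`select_event_cases`; both
    event and non-event cases stay in ``cases`` because the non-event
    side supplies the b and d cells of every contingency table.
    """

    cases: list[ReportRecord]
    provenance: dict[str, int] = field(default_factory=dict)
    event_caseids: frozenset[str] = frozenset()

    @property
    def universe_size(self) -> int:
        return len(self.cases)

    @property
    def event_cases(self) -> list[ReportRecord]:
        return [c for c in self.cases if c.caseid in self.event_caseids]


def _dedup_key(rec: ReportRecord) -> tuple:
    date_key = rec.fda_date.sort_key() if rec.fda_date else (0, 0, 0)
    try:
        pid = int(rec.primaryid)
    except ValueError:
        pid = -1
    return (*date_key, pid)


def deduplicate(records: list[ReportRecord]) -> CaseSet:
    """Collapse reports to unique cases.

    Keep, per CASEID, the record with the latest FDA date; ties on the
    date (compared at the coarsest common precision, via the sort key in
    which unknown components rank earliest) go to the numerically
    largest PRIMARYID.  A record with no FDA date is treated as earliest
    possible, so it survives only when no dated sibling exists.  Output
    is sorted by CASEID — deterministic and independent of input order.
    """
    best: dict[str, ReportRecord] = {}
    for rec in records:
        cur = best.get(rec.caseid)
        if cur is None or _dedup_key(rec) > _dedup_key(cur):
            best[rec.caseid] = rec
    cases = [best[cid] for cid in sorted(best)]
    return CaseSet(
        cases=cases,
        provenance={
            "input_reports": len(records),
            "unique_cases": len(cases),
            "duplicates_removed": len(records) - len(cases),
        },
    )


def select_event_cases(case_set: CaseSet, config: FilterConfig) -> CaseSet:
    """Partition the universe into event / non-event cases.

    A case is an event case when at least one of its reaction PTs is in
    ``config.target_pts``.  Both partitions are retained.
    """
    if not config.target_pts:
        raise ValueError("target_pts must be non-empty")
    event_ids = frozenset(
        c.caseid for c in case_set.cases if c.has_reaction(set(config.target_pts))
    )
    provenance = dict(case_set.provenance)
    provenance["event_cases"] = len(event_ids)
    provenance["non_event_cases"] = case_set.universe_size - len(event_ids)
    return replace(case_set, provenance=provenance, event_caseids=event_ids)


def apply_report_filters(
    case_set: CaseSet, config: FilterConfig
) -> tuple[CaseSet, list[str]]:
    """Keep professional-reported cases; find drugs meeting the report floor.

    Drug eligibility counts *event* cases in which the drug appears in a
    kept role; a drug with at least ``min_reports_per_drug`` such cases
    enters the analysis.  The event partition is recomputed on the kept
    cases so provenance stays sum-consistent.
    """
    kept = [
        c for c in case_set.cases if c.reporter_occupation in config.reporters_kept
    ]
    provenance = dict(case_set.provenance)
    provenance["reporter_filtered_cases"] = len(kept)
    provenance["reporter_removed_cases"] = case_set.universe_size - len(kept)
    filtered = select_event_cases(
        CaseSet(cases=kept, provenance=provenance), config
    )

    counts: dict[str, int] = {}
    roles = set(config.roles_kept)
    for case in filtered.cases:
        if case.caseid not in filtered.event_caseids:
            continue
        for name in case.drug_names(roles):
            counts[name] = counts.get(name, 0) + 1
    eligible = sorted(
        (d for d, n in counts.items() if n >= config.min_reports_per_drug),
        key=lambda d: (-counts[d], d),
    )
    filtered.provenance["eligible_drugs"] = len(eligible)
    return filtered, eligible


def standardize_drug_names(
    case_set: CaseSet, synonym_map: dict[str, str]
) -> tuple[CaseSet, int]:
    """Map verbatim drug names to canonical generics.

    Lookup is case-insensitive on trimmed names; unmapped names pass
    through verbatim and are counted (second return value).
    """
    lowered = {k.strip().lower(): v for k, v in synonym_map.items()}
    unmapped = 0
    new_cases = []
    for case in case_set.cases:
        drugs = []
        for d in case.drugs:
            canon = lowered.get(d.name.strip().lower())
            if canon is None:
                unmapped += 1
                canon = d.name
            drugs.append(replace(d, name=canon))
        new_cases.append(replace(case, drugs=drugs))
    return replace(case_set, cases=new_cases), unmapped


def prepare_cases(
    records: list[ReportRecord],
    config: FilterConfig,
    synonym_map: dict[str, str] | None = None,
) -> tuple[CaseSet, list[str]]:
    """Canonical pipeline order: dedup -> standardize -> reporter filter ->
    event partition -> drug eligibility."""
    case_set = deduplicate(records)
    if synonym_map:
        case_set, _ = standardize_drug_names(case_set, synonym_map)
    case_set = select_event_cases(case_set, config)
    return apply_report_filters(case_set, config)
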