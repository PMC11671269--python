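"""End-to-end driver tying the stages together.

Order of operations: read/join (or accept in-memory records) ->
deduplicate -> standardize names -> reporter filter -> event partition
-> drug eligibility -> 2x2 tables -> four statistics + classification ->
ranking -> time-to-onset for joint-signal drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import timing
from .contingency import build_all_tables
from .faers_io import ReportRecord, join_records, read_quarter
from .grouping_report import (
    DescriptiveSummary,
    assign_classes,
    summarize_cases,
)
from .preprocess import CaseSet, FilterConfig, prepare_cases
from .reference import TARGET_PT, load_class_map, load_synonym_map
from .signal_stats import (
    DEFAULT_CRITERIA,
    DEFAULT_PRIORS,
    SignalResult,
    compute_signal,
    rank_signals,
)


def default_config() -> FilterConfig:
    return FilterConfig(target_pts=frozenset({TARGET_PT}))


@dataclass
class RunResult:
    case_set: CaseSet
    eligible_drugs: list[str]
    results: list[SignalResult]
    ranked: list[SignalResult]          # joint-signal drugs, ranked
    classes: pd.DataFrame
    onset_samples: list[timing.OnsetSample] = field(default_factory=list)
    onset_counters: timing.OnsetCounters | None = None
    onset_by_drug: pd.DataFrame | None = None
    onset_by_class: pd.DataFrame | None = None
    km_curves: dict = field(default_factory=dict)
    logrank: tuple[float, float] | None = None
    summary: DescriptiveSummary | None = None


def run_analysis(
    records: list[ReportRecord],
    config: FilterConfig | None = None,
    synonym_map: dict[str, str] | None = None,
    class_map: dict[str, tuple[str, str]] | None = None,
    chi2_variant: str = "yates",
    ic_mode: str = "crude",
) -> RunResult:
    """Run the full analysis on joined report records."""
    config = config or default_config()
    synonym_map = load_synonym_map() if synonym_map is None else synonym_map
    class_map = load_class_map() if class_map is None else class_map

    case_set, eligible = prepare_cases(records, config, synonym_map)
    tables = build_all_tables(case_set, eligible, config)
    results = [
        compute_signal(t, DEFAULT_PRIORS, chi2_variant, ic_mode,
                       DEFAULT_CRITERIA)
        for t in tables
    ]
    joint = [r for r in results if r.joint_signal]
    ranked = rank_signals(joint)
    classes = assign_classes([r.drug for r in ranked], class_map)

    out = RunResult(
        case_set=case_set,
        eligible_drugs=eligible,
        results=results,
        ranked=ranked,
        classes=classes,
        summary=summarize_cases(case_set),
    )

    if ranked:
        atc_only = {d: c[0] for d, c in class_map.items()}
        samples, counters = timing.compute_onsets(
            case_set, [r.drug for r in ranked], config, class_map=atc_only
        )
        out.onset_samples = samples
        out.onset_counters = counters
        if samples:
            out.onset_by_drug = timing.onset_summary(samples, by="drug")
            out.onset_by_class = timing.onset_summary(samples, by="class")
            out.km_curves = timing.km_estimate(samples, by="class")
            groups: dict[str, list[float]] = {}
            for s in samples:
                groups.setdefault(s.drug_class, []).append(s.onset_days)
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
            if len(groups) >= 2:
                out.logrank = timing.logrank_test(groups)
    return out


def run_from_quarters(
    paths: list[str],
    config: FilterConfig | None = None,
    **kwargs,
) -> RunResult:
    """Read quarterly table files, join, then :func:`run_analysis`."""
    read = read_quarter(paths)
    joined = join_records(read.rows)
    return run_analysis(joined.records, config, **kwargs)
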