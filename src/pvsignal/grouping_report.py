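"""Drug-class annotation, descriptive cohort summary and result export.

Percentages in the descriptive summary follow the reporting conventions
of published FAERS cohort tables: sex and country shares use the case
count as denominator, while outcome shares use the total number of
outcome entries (a case can in principle carry several outcomes, so the
outcome block reconciles only under its own denominator).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CaseSet
from .signal_stats import SignalResult, round_half_up
from .timing import SurvivalCurve


@dataclass
class DescriptiveSummary:
    n_cases: int
    age: dict = field(default_factory=dict)       # mean/sd/median/q1/q3/n
    weight: dict = field(default_factory=dict)
    sex: dict = field(default_factory=dict)       # label -> (count, pct)
    outcome: dict = field(default_factory=dict)
    country: dict = field(default_factory=dict)
    reporter: dict = field(default_factory=dict)  # label -> count
    yearly_by_sex: dict = field(default_factory=dict)  # year -> {F, M, unknown}


def assign_classes(
    drugs: list[str], class_map: dict[str, tuple[str, str]]
) -> pd.DataFrame:
    """Annotate drugs with (ATC class, target class); unresolved ->
    'unclassified' (listed, never dropped)."""
    rows = [
        {
            "drug": d,
            "atc_class": class_map.get(d, ("unclassified", "unclassified"))[0],
            "target_class": class_map.get(d, ("unclassified", "unclassified"))[1],
        }
        for d in drugs
    ]
    return pd.DataFrame(rows, columns=["drug", "atc_class", "target_class"])


def _numeric_block(values: list[float]) -> dict:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if len(arr) == 0:
        return {"n": 0}
    return {
        "n": int(len(arr)),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "median": float(np.quantile(arr, 0.5)),
        "q1": float(np.quantile(arr, 0.25)),
        "q3": float(np.quantile(arr, 0.75)),
    }


def _count_block(counts: dict[str, int], denominator: int) -> dict:
    return {
        label: {
            "count": int(n),
            "pct": 100.0 * n / denominator if denominator else 0.0,
        }
        for label, n in sorted(counts.items(), key=lambda kv: -kv[1])
    }


def summarize_cases(case_set: CaseSet) -> DescriptiveSummary:
    """Demographic / outcome / reporter / country / yearly summary of the
    event cohort (runs on whatever cases the given CaseSet holds)."""
    cases = case_set.event_cases if case_set.event_caseids else case_set.cases
    sex_counts: dict[str, int] = {}
    outcome_counts: dict[str, int] = {}
    country_counts: dict[str, int] = {}
    reporter_counts: dict[str, int] = {}
    yearly: dict[int, dict[str, int]] = {}
    for case in cases:
        sex_counts[case.sex] = sex_counts.get(case.sex, 0) + 1
        if case.outcome != "unknown":
            outcome_counts[case.outcome] = outcome_counts.get(case.outcome, 0) + 1
        label = case.country or "unknown"
        country_counts[label] = country_counts.get(label, 0) + 1
        reporter_counts[case.reporter_occupation] = (
            reporter_counts.get(case.reporter_occupation, 0) + 1
        )
        if case.fda_date is not None:
            y = yearly.setdefault(case.fda_date.year, {})
            y[case.sex] = y.get(case.sex, 0) + 1
    outcome_total = sum(outcome_counts.values())
    return DescriptiveSummary(
        n_cases=len(cases),
        age=_numeric_block([c.age_years for c in cases]),
        weight=_numeric_block([c.weight_kg for c in cases]),
        sex=_count_block(sex_counts, len(cases)),
        outcome=_count_block(outcome_counts, outcome_total),
        country=_count_block(country_counts, len(cases)),
        reporter=dict(sorted(reporter_counts.items(), key=lambda kv: -kv[1])),
        yearly_by_sex={y: yearly[y] for y in sorted(yearly)},
    )


# ---------------------------------------------------------------------------
# Tables and files
# ---------------------------------------------------------------------------

def signal_table(
    results: list[SignalResult],
    classes: pd.DataFrame | None = None,
    joint_only: bool = True,
) -> pd.DataFrame:
    """Report-style signal table (one row per drug, 3-dp half-up rounding)."""
    atc = (
        dict(zip(classes.drug, classes.atc_class))
        if classes is not None else {}
    )
    rows = []
    for r in results:
        if joint_only and not r.joint_signal:
            continue
        rows.append(
            {
                "drug": r.drug,
                "number": r.a,
                "classification": atc.get(r.drug, "unclassified"),
                "ror": round_half_up(r.ror),
                "ror_ci_low": round_half_up(r.ror_ci_low),
                "ror_ci_high": round_half_up(r.ror_ci_high),
                "prr": round_half_up(r.prr),
                "chi2": round_half_up(r.chi2),
                "ebgm": round_half_up(r.ebgm),
                "ebgm05": round_half_up(r.ebgm05),
                "ic": round_half_up(r.ic),
                "ic_025": round_half_up(r.ic_025),
                "tier": r.tier,
                "corrected": r.corrected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "number", "classification", "ror", "ror_ci_low",
            "ror_ci_high", "prr", "chi2", "ebgm", "ebgm05", "ic", "ic_025",
            "tier", "corrected",
        ],
    )


def forest_table(results: list[SignalResult]) -> pd.DataFrame:
    """Forest-plot-ready (estimate, low, high) per drug, ROR scale."""
    return pd.DataFrame(
        [
            {
                "drug": r.drug,
                "estimate": round_half_up(r.ror),
                "low": round_half_up(r.ror_ci_low),
                "high": round_half_up(r.ror_ci_high),
            }
            for r in results
        ],
        columns=["drug", "estimate", "low", "high"],
    )


def km_table(curves: dict[str, SurvivalCurve]) -> pd.DataFrame:
    rows = []
    for group, curve in sorted(curves.items()):
        for t, s, r in zip(curve.times, curve.survival, curve.at_risk):
            rows.append(
                {"group": group, "time": float(t),
                 "survival": float(s), "at_risk": int(r)}
            )
    return pd.DataFrame(rows, columns=["group", "time", "survival", "at_risk"])


def export_results(
    out_dir: str,
    signals: pd.DataFrame,
    onsets: pd.DataFrame,
    summary: DescriptiveSummary,
    forest: pd.DataFrame,
    km: pd.DataFrame,
    manifest: dict,
) -> dict[str, str]:
    """Write all result files; deterministic given identical inputs.

    Raises before any partial write when the target is not writable.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise PermissionError(f"output directory not writable: {out_dir}")
    paths = {
        "signals": os.path.join(out_dir, "signal_table.csv"),
        "onsets": os.path.join(out_dir, "onset_summary.csv"),
        "summary": os.path.join(out_dir, "descriptive_summary.json"),
        "forest": os.path.join(out_dir, "forest_plot.csv"),
        "km": os.path.join(out_dir, "km_curves.csv"),
        "manifest": os.path.join(out_dir, "run_manifest.json"),
    }
    signals.to_csv(paths["signals"], index=False)
    onsets.to_csv(paths["onsets"], index=False)
    with open(paths["summary"], "w") as fh:
        json.dump(asdict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    forest.to_csv(paths["forest"], index=False)
    km.to_csv(paths["km"], index=False)
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
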