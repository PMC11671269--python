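"""Time-to-onset analysis for signal-positive drugs.

Onset is the number of days from therapy start to the adverse event,
computed only when both dates are known to day precision (year-month
dates may be imputed to mid-month behind an opt-in flag; the default is
to exclude and count them).  Spontaneous reports carry no follow-up, so
there is no censoring: every onset is an observed event and the
Kaplan-Meier estimate coincides with the empirical survival function.

Summaries use median and quartiles with linear interpolation between
order statistics (position 1 + (n-1)p), the numpy default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .faers_io import PartialDate
from .preprocess import CaseSet, FilterConfig


@dataclass(frozen=True)
class OnsetSample:
    caseid: str
    drug: str
    drug_class: str
    onset_days: float


@dataclass
class OnsetCounters:
    computed: int = 0
    missing_date: int = 0    # either date absent or not day-precise
    negative: int = 0        # event before therapy start


@dataclass
class SurvivalCurve:
    times: np.ndarray        # increasing event times
    survival: np.ndarray     # non-increasing, starts at 1.0 (time 0)
    at_risk: np.ndarray


def _day_precise(date: PartialDate | None, impute_mid_month: bool):
    if date is None:
        return None
    if date.precision == "day":
        return date.to_date()
    if date.precision == "month" and impute_mid_month:
        return PartialDate(date.year, date.month, 15).to_date()
    return None


def compute_onsets(
    case_set: CaseSet,
    drugs: list[str],
    config: FilterConfig,
    class_map: dict[str, str] | None = None,
    impute_mid_month: bool = False,
) -> tuple[list[OnsetSample], OnsetCounters]:
    """Per-case onset days for event cases exposed to the given drugs.

    Exclusions are never silent: samples dropped for missing/partial
    dates or negative differences are tallied in the counters.
    """
    wanted = set(drugs)
    roles = set(config.roles_kept)
    class_map = class_map or {}
    samples: list[OnsetSample] = []
    counters = OnsetCounters()
    for case in case_set.cases:
        if case.caseid not in case_set.event_caseids:
            continue
        event = _day_precise(case.event_date, impute_mid_month)
        for entry in case.drugs:
            if entry.role not in roles or entry.name not in wanted:
                continue
            start = _day_precise(entry.therapy_start, impute_mid_month)
            if event is None or start is None:
                counters.missing_date += 1
                continue
            days = (event - start).days
            if days < 0:
                counters.negative += 1
                continue
            counters.computed += 1
            samples.append(
                OnsetSample(
                    caseid=case.caseid,
                    drug=entry.name,
                    drug_class=class_map.get(entry.name, "unclassified"),
                    onset_days=float(days),
                )
            )
    return samples, counters


def _group_key(by: str):
    if by == "drug":
        return lambda s: s.drug
    if by == "class":
        return lambda s: s.drug_class
    raise ValueError(f"unknown grouping: {by!r}")


def onset_summary(samples: list[OnsetSample], by: str = "drug") -> pd.DataFrame:
    """Median/Q1/Q3/n per group, sorted by descending median.

    Quantiles interpolate linearly at position 1 + (n-1)p.  Empty input
    yields an empty frame.
    """
    key = _group_key(by)
    rows = []
    groups: dict[str, list[float]] = {}
    for s in samples:
        groups.setdefault(key(s), []).append(s.onset_days)
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        rows.append(
            {
                by: name,
                "n": len(arr),
                "median": float(np.quantile(arr, 0.5)),
                "q1": float(np.quantile(arr, 0.25)),
                "q3": float(np.quantile(arr, 0.75)),
            }
        )
    frame = pd.DataFrame(rows, columns=[by, "n", "median", "q1", "q3"])
    if len(frame):
        frame = frame.sort_values(
            ["median", by], ascending=[False, True]
        ).reset_index(drop=True)
    return frame


def km_estimate(
    samples: list[OnsetSample], by: str = "class"
) -> dict[str, SurvivalCurve]:
    """Product-limit curves per group (all observed, no censoring)."""
    key = _group_key(by)
    groups: dict[str, list[float]] = {}
    for s in samples:
        groups.setdefault(key(s), []).append(s.onset_days)
    curves: dict[str, SurvivalCurve] = {}
    for name, values in sorted(groups.items()):
        durations = np.asarray(values, dtype=float)
        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=np.ones_like(durations))
        times = np.asarray(sorted(set(durations)))
        surv = (
            kmf.survival_function_.reindex(times)["KM_estimate"].to_numpy()
        )
        at_risk = np.array([(durations >= t).sum() for t in times])
        curves[name] = SurvivalCurve(times=times, survival=surv, at_risk=at_risk)
    return curves


def km_median(curve: SurvivalCurve) -> float:
    """First time at which survival drops to 0.5 or below."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if len(below) else float("inf")


def logrank_test(groups: dict[str, list[float]]) -> tuple[float, float]:
    """k-sample log-rank test; chi-square reference with k-1 df.

    Degenerate all-tied input (every observation equal across groups)
    returns (0.0, 1.0) by exchangeability.
    """
    names = [n for n, v in groups.items() if len(v)]
    if len(names) < 2:
        raise ValueError("log-rank test needs >= 2 non-empty groups")
    durations, labels = [], []
    for name in names:
        durations.extend(groups[name])
        labels.extend([name] * len(groups[name]))
    durations = np.asarray(durations, dtype=float)
    if len(set(durations.tolist())) == 1:
        return 0.0, 1.0
    res = multivariate_logrank_test(
        durations, np.asarray(labels), np.ones_like(durations)
    )
    return float(res.test_statistic), float(res.p_value)


def samples_frame(samples: list[OnsetSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "caseid": s.caseid,
                "drug": s.drug,
                "drug_class": s.drug_class,
                "onset_days": s.onset_days,
            }
            for s in samples
        ],
        columns=["caseid", "drug", "drug_class", "onset_days"],
    )
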