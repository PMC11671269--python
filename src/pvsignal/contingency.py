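"""Per-drug 2x2 contingency tables over the case universe.

For drug D and the target event E over a universe of N cases:

    a = cases with D (in a kept role) and E      b = cases with D, not E
    c = cases with E, without D                  d = neither

One case can contribute to several drugs' tables (multi-suspect
reports) but is counted once per drug; cases with several target-PT
reactions count once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .preprocess import CaseSet, FilterConfig


@dataclass(frozen=True)
class ContingencyTable:
    drug: str
    a: int
    b: int
    c: int
    d: int
    corrected: bool = False   # Haldane +0.5 applied (cells then half-integer)
    flagged: bool = False     # drug absent from universe, or correction used

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def with_haldane(self) -> "ContingencyTable":
        """Add 0.5 to every cell (applied when any cell is zero).

        Keeps the Wald-type formulas finite; results computed from a
        corrected table carry ``flagged=True`` so report consumers can
        tell them apart.
        """
        return ContingencyTable(
            self.drug, self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5,
            corrected=True, flagged=True,
        )

    def for_statistics(self) -> "ContingencyTable":
        if self.n == 0:
            raise ValueError(f"degenerate table for {self.drug}: N=0")
        if min(self.cells) == 0 and not self.corrected:
            return self.with_haldane()
        return self


def build_table(
    case_set: CaseSet, drug: str, config: FilterConfig
) -> ContingencyTable:
    """Build the 2x2 table for one drug; requires the event partition."""
    roles = set(config.roles_kept)
    a = b = 0
    n_event = len(case_set.event_caseids)
    for case in case_set.cases:
        if drug not in case.drug_names(roles):
            continue
        if case.caseid in case_set.event_caseids:
            a += 1
        else:
            b += 1
    c = n_event - a
    d = case_set.universe_size - a - b - c
    return ContingencyTable(drug, a, b, c, d, flagged=(a + b == 0))


def build_all_tables(
    case_set: CaseSet, eligible_drugs: list[str], config: FilterConfig
) -> list[ContingencyTable]:
    """One table per eligible drug, sorted by descending a then name.

    Single pass over cases: drug membership is re-derived per case, so
    tables reconcile with :func:`build_table` exactly.
    """
    roles = set(config.roles_kept)
    wanted = set(eligible_drugs)
    a_counts = {d: 0 for d in eligible_drugs}
    b_counts = {d: 0 for d in eligible_drugs}
    n_event = len(case_set.event_caseids)
    n_total = case_set.universe_size
    for case in case_set.cases:
        is_event = case.caseid in case_set.event_caseids
        for name in case.drug_names(roles) & wanted:
            if is_event:
                a_counts[name] += 1
            else:
                b_counts[name] += 1
    tables = [
        ContingencyTable(
            d, a_counts[d], b_counts[d],
            n_event - a_counts[d],
            n_total - a_counts[d] - b_counts[d] - (n_event - a_counts[d]),
            flagged=(a_counts[d] + b_counts[d] == 0),
        )
        for d in eligible_drugs
    ]
    tables.sort(key=lambda t: (-t.a, t.drug))
    return tables
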