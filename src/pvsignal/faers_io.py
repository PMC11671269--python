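"""Reading, writing and joining FAERS-style quarterly ASCII tables.

The public FAERS quarterly extract ships four core tables per quarter
(DEMO, DRUG, REAC, THER) as ``$``-delimited text with one header line.
This module parses that dialect into :class:`RawTableRow` objects, joins
them by report identifier into :class:`ReportRecord` objects, and writes
the same dialect back out (used by the synthetic-data generator, so that
every downstream stage is exercised through the real file path).

Dates in FAERS are "partial": an 8-digit ``YYYYMMDD``, a 6-digit
``YYYYMM`` or a bare 4-digit year, depending on what the reporter knew.
:class:`PartialDate` keeps the stated precision; comparisons used for
deduplication are done at the coarsest common precision so that a bare
year never outranks a fully-dated report from the same year.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import logging
import os
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

DELIMITER = "$"
ENCODING = "latin-1"  # legacy quarters contain non-UTF-8 bytes

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "THER")

#: Minimal column sets each table must provide (superset columns pass through).
TABLE_COLUMNS = {
    "DEMO": [
        "PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
        "WT", "WT_COD", "SEX", "OCCP_COD", "REPORTER_COUNTRY", "OUTC_COD",
    ],
    "DRUG": ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"],
    "REAC": ["PRIMARYID", "CASEID", "PT"],
    "THER": ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"],
}

MANDATORY_COLUMNS = ("PRIMARYID", "CASEID")

ROLE_CODES = {
    "PS": "primary_suspect",
    "SS": "secondary_suspect",
    "C": "concomitant",
    "I": "interacting",
}
ROLE_TO_CODE = {v: k for k, v in ROLE_CODES.items()}

OCCUPATION_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other_health_professional",
    "CN": "consumer",
    "LW": "lawyer",
}
OCCUPATION_TO_CODE = {v: k for k, v in OCCUPATION_CODES.items()}

OUTCOME_CODES = {
    "DE": "death",
    "LT": "life_threatening",
    "HO": "hospitalization",
    "DS": "disability",
    "OT": "other_serious",
}
OUTCOME_TO_CODE = {v: k for k, v in OUTCOME_CODES.items()}


# ---------------------------------------------------------------------------
# Partial dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date known to year, month or day precision."""

    year: int
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> tuple[int, int, int]:
        """Total-order key: unknown components sort before any known one.

        Under this key a year-only date never compares *later* than a
        fully-dated report of the same year, which is the property the
        deduplication rule needs.
        """
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> _dt.date:
        if self.precision != "day":
            raise ValueError(f"{self} is not day-precise")
        return _dt.date(self.year, self.month, self.day)

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def parse_partial_date(raw: str | None) -> PartialDate | None:
    """Parse a FAERS date string (``YYYY``, ``YYYYMM`` or ``YYYYMMDD``).

    Lenient by contract: anything unparseable (wrong length, month 13,
    Feb 30, non-digits, empty) returns ``None``.  Callers that need to
    account for discarded values keep their own warning counters.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    if not raw.isdigit() or len(raw) not in (4, 6, 8):
        return None
    year = int(raw[:4])
    if year < 1900 or year > 2200:
        return None
    if len(raw) == 4:
        return PartialDate(year)
    month = int(raw[4:6])
    if not 1 <= month <= 12:
        return None
    if len(raw) == 6:
        return PartialDate(year, month)
    day = int(raw[6:8])
    if not 1 <= day <= calendar.monthrange(year, month)[1]:
        return None
    return PartialDate(year, month, day)


def compare_partial_dates(x: PartialDate | None, y: PartialDate | None) -> int:
    """Compare at the coarsest common precision; absent sorts earliest.

    Returns -1, 0 or +1.  Two dates that agree on every component they
    both state compare equal ("tie"), which defers the deduplication
    decision to the report identifier.
    """
    if x is None and y is None:
        return 0
    if x is None:
        return -1
    if y is None:
        return 1
    for xc, yc in ((x.year, y.year), (x.month, y.month), (x.day, y.day)):
        if xc is None or yc is None:
            return 0
        if xc != yc:
            return -1 if xc < yc else 1
    return 0


# ---------------------------------------------------------------------------
# Raw rows and joined records
# ---------------------------------------------------------------------------

@dataclass
class RawTableRow:
    table_name: str              # DEMO | DRUG | REAC | THER
    primaryid: str
    caseid: str
    payload: dict[str, str]      # ordered field-name -> value, incl. ids


@dataclass
class DrugEntry:
    name: str
    role: str                    # primary_suspect | secondary_suspect | ...
    therapy_start: PartialDate | None = None
    seq: str = "1"


@dataclass
class ReportRecord:
    """One spontaneous report, joined across the four quarterly tables."""

    primaryid: str
    caseid: str
    fda_date: PartialDate | None = None
    event_date: PartialDate | None = None
    reporter_occupation: str = "unknown"
    sex: str = "unknown"
    age_years: float | None = None
    weight_kg: float | None = None
    country: str = ""
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[str] = field(default_factory=list)
    outcome: str = "unknown"

    def has_reaction(self, pts: set[str]) -> bool:
        return any(pt in pts for pt in self.reactions)

    def drug_names(self, roles: set[str] | None = None) -> set[str]:
        return {
            d.name for d in self.drugs
            if roles is None or d.role in roles
        }


@dataclass
class ReadResult:
    rows: list[RawTableRow]
    malformed: dict[str, int] = field(default_factory=dict)

    @property
    def malformed_total(self) -> int:
        return sum(self.malformed.values())


@dataclass
class JoinResult:
    records: list[ReportRecord]
    orphans: int = 0             # DRUG/REAC/THER rows with no DEMO parent
    duplicate_demo: int = 0      # repeated PRIMARYID within DEMO (first kept)


class MissingColumnError(ValueError):
    """A mandatory column (PRIMARYID/CASEID) is absent from a table file."""


def _infer_table_name(path: str) -> str:
    base = os.path.basename(path).upper()
    for name in TABLE_NAMES:
        if base.startswith(name):
            return name
    raise ValueError(f"cannot infer table type from file name: {path!r}")


def read_quarter(
    paths: list[str],
    delimiter: str = DELIMITER,
    encoding: str = ENCODING,
) -> ReadResult:
    """Read one quarter's table files into raw rows.

    Each file must carry a one-line header.  Rows whose field count does
    not match the header are counted per file in ``malformed`` and
    logged — never silently dropped.  An empty file contributes no rows
    (warning logged).  A file lacking PRIMARYID or CASEID raises
    :class:`MissingColumnError` naming file and column.
    """
    rows: list[RawTableRow] = []
    malformed: dict[str, int] = {}
    for path in paths:
        table = _infer_table_name(path)
        with open(path, encoding=encoding, errors="replace") as fh:
            header_line = fh.readline().rstrip("\r\n")
            if not header_line:
                logger.warning("empty table file: %s", path)
                malformed[path] = 0
                continue
            header = header_line.split(delimiter)
            for col in MANDATORY_COLUMNS:
                if col not in header:
                    raise MissingColumnError(
                        f"{path}: mandatory column {col} missing from header"
                    )
            pid_i = header.index("PRIMARYID")
            cid_i = header.index("CASEID")
            bad = 0
            for line in fh:
                fields = line.rstrip("\r\n").split(delimiter)
                if len(fields) != len(header):
                    bad += 1
                    continue
                payload = dict(zip(header, fields))
                pid, cid = fields[pid_i].strip(), fields[cid_i].strip()
                if not (pid.isdigit() and cid.isdigit()):
                    bad += 1
                    continue
                rows.append(RawTableRow(table, pid, cid, payload))
            malformed[path] = bad
            if bad:
                logger.warning("%s: %d malformed row(s) excluded", path, bad)
    return ReadResult(rows, malformed)


def _parse_number(raw: str | None) -> float | None:
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    try:
        value = float(raw)
    except ValueError:
        return None
    return value if value >= 0 else None


def join_records(rows: list[RawTableRow]) -> JoinResult:
    """Join raw rows into one :class:`ReportRecord` per DEMO row.

    DRUG/REAC/THER rows attach by PRIMARYID.  A therapy-start date
    attaches to the drug whose sequence number matches its
    ``DSG_DRUG_SEQ``; if no drug matches, it falls back to the record's
    primary-suspect drug.  Child rows with a PRIMARYID absent from DEMO
    are counted as orphans and excluded.  Repeated DEMO PRIMARYIDs keep
    the first occurrence (counted).
    """
    records: dict[str, ReportRecord] = {}
    duplicate_demo = 0
    for row in rows:
        if row.table_name != "DEMO":
            continue
        if row.primaryid in records:
            duplicate_demo += 1
            continue
        p = row.payload
        age = _parse_number(p.get("AGE"))
        age_cod = (p.get("AGE_COD") or "YR").strip().upper()
        if age is not None and age_cod == "MON":
            age /= 12.0
        elif age is not None and age_cod == "DY":
            age /= 365.25
        weight = _parse_number(p.get("WT"))
        wt_cod = (p.get("WT_COD") or "KG").strip().upper()
        if weight is not None and wt_cod == "LBS":
            weight *= 0.45359237
        sex = (p.get("SEX") or "").strip().upper()
        records[row.primaryid] = ReportRecord(
            primaryid=row.primaryid,
            caseid=row.caseid,
            fda_date=parse_partial_date(p.get("FDA_DT")),
            event_date=parse_partial_date(p.get("EVENT_DT")),
            reporter_occupation=OCCUPATION_CODES.get(
                (p.get("OCCP_COD") or "").strip().upper(), "unknown"
            ),
            sex=sex if sex in ("F", "M") else "unknown",
            age_years=age,
            weight_kg=weight,
            country=(p.get("REPORTER_COUNTRY") or "").strip(),
            outcome=OUTCOME_CODES.get(
                (p.get("OUTC_COD") or "").strip().upper(), "unknown"
            ),
        )

    orphans = 0
    pending_ther: list[RawTableRow] = []
    for row in rows:
        if row.table_name == "DEMO":
            continue
        rec = records.get(row.primaryid)
        if rec is None:
            orphans += 1
            continue
        if row.table_name == "DRUG":
            role = ROLE_CODES.get(
                (row.payload.get("ROLE_COD") or "").strip().upper(), "concomitant"
            )
            rec.drugs.append(
                DrugEntry(
                    name=(row.payload.get("DRUGNAME") or "").strip(),
                    role=role,
                    seq=(row.payload.get("DRUG_SEQ") or "1").strip(),
                )
            )
        elif row.table_name == "REAC":
            pt = (row.payload.get("PT") or "").strip()
            if pt:
                rec.reactions.append(pt)
        elif row.table_name == "THER":
            pending_ther.append(row)

    # THER after DRUG so sequence matching sees all drugs of the record
    for row in pending_ther:
        rec = records[row.primaryid]
        start = parse_partial_date(row.payload.get("START_DT"))
        if start is None:
            continue
        seq = (row.payload.get("DSG_DRUG_SEQ") or "").strip()
        target = next((d for d in rec.drugs if d.seq == seq), None)
        if target is None:
            target = next(
                (d for d in rec.drugs if d.role == "primary_suspect"), None
            )
        if target is not None and target.therapy_start is None:
            target.therapy_start = start

    return JoinResult(list(records.values()), orphans, duplicate_demo)


# ---------------------------------------------------------------------------
# Writing (synthetic quarters and round-trip tests)
# ---------------------------------------------------------------------------

def write_quarter(
    records: list[ReportRecord],
    out_dir: str,
    quarter_label: str = "24Q1",
    delimiter: str = DELIMITER,
    encoding: str = ENCODING,
) -> dict[str, str]:
    """Write records as one FAERS-dialect quarter; returns table->path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        name: os.path.join(out_dir, f"{name}{quarter_label}.txt")
        for name in TABLE_NAMES
    }
    handles = {
        name: open(path, "w", encoding=encoding, newline="\n")
        for name, path in paths.items()
    }
    try:
        for name in TABLE_NAMES:
            handles[name].write(delimiter.join(TABLE_COLUMNS[name]) + "\n")
        for rec in records:
            demo = [
                rec.primaryid,
                rec.caseid,
                str(rec.fda_date) if rec.fda_date else "",
                str(rec.event_date) if rec.event_date else "",
                "" if rec.age_years is None else f"{rec.age_years:g}",
                "YR",
                "" if rec.weight_kg is None else f"{rec.weight_kg:g}",
                "KG",
                rec.sex if rec.sex in ("F", "M") else "",
                OCCUPATION_TO_CODE.get(rec.reporter_occupation, ""),
                rec.country,
                OUTCOME_TO_CODE.get(rec.outcome, ""),
            ]
            handles["DEMO"].write(delimiter.join(demo) + "\n")
            for drug in rec.drugs:
                handles["DRUG"].write(
                    delimiter.join(
                        [
                            rec.primaryid,
                            rec.caseid,
                            drug.seq,
                            ROLE_TO_CODE.get(drug.role, "C"),
                            drug.name,
                        ]
                    )
                    + "\n"
                )
                if drug.therapy_start is not None:
                    handles["THER"].write(
                        delimiter.join(
                            [
                                rec.primaryid,
                                rec.caseid,
                                drug.seq,
                                str(drug.therapy_start),
                            ]
                        )
                        + "\n"
                    )
            for pt in rec.reactions:
                handles["REAC"].write(
                    delimiter.join([rec.primaryid, rec.caseid, pt]) + "\n"
                )
    finally:
        for fh in handles.values():
            fh.close()
    return paths


def copy_record(rec: ReportRecord, **changes) -> ReportRecord:
    """Deep-ish copy helper used by the generator when emitting duplicates."""
    new = replace(
        rec,
        drugs=[replace(d) for d in rec.drugs],
        reactions=list(rec.reactions),
    )
    for key, value in changes.items():
        setattr(new, key, value)
    return new
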