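"""Validation issues, reports, and the closed issue-code table.

Two disjoint code families implement the two validation levels: level 1
(does each raw value constrain to its declared data type?) and level 2
(does the metadata structure conform to the template?).  A third, small
family covers workbook parse problems.  Severities are fixed per code:
unexpected *extra* information is a warning, everything else an error —
arbitrary key/value pairs are a feature of the capture model, not a fault.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

ERROR = "error"
WARNING = "warning"
INFO = "info"

# -- level 1: value vs data type ------------------------------------------
NOT_INTEGER = "not_integer"
NOT_DECIMAL = "not_decimal"
NOT_ISO_DATE = "not_iso_date"
NOT_ISO_TIME = "not_iso_time"
NOT_ISO_DATETIME = "not_iso_datetime"
OUT_OF_RANGE = "out_of_range"
BAD_URL = "bad_url"
BAD_EMAIL = "bad_email"
CV_VIOLATION = "cv_violation"
PATTERN_MISMATCH = "pattern_mismatch"

LEVEL1_CODES = frozenset(
    {
        NOT_INTEGER,
        NOT_DECIMAL,
        NOT_ISO_DATE,
        NOT_ISO_TIME,
        NOT_ISO_DATETIME,
        OUT_OF_RANGE,
        BAD_URL,
        BAD_EMAIL,
        CV_VIOLATION,
        PATTERN_MISMATCH,
    }
)

# -- level 2: structure vs template ---------------------------------------
MISSING_REQUIRED = "missing_required"
UNKNOWN_KEY = "unknown_key"
NO_SAMPLES = "no_samples"
MISSING_EP = "missing_ep"
EXTRA_EP = "extra_ep"
BROKEN_LINK = "broken_link"

LEVEL2_CODES = frozenset(
    {MISSING_REQUIRED, UNKNOWN_KEY, NO_SAMPLES, MISSING_EP, EXTRA_EP, BROKEN_LINK}
)

# -- workbook parse level --------------------------------------------------
UNKNOWN_SHEET = "unknown_sheet"
DUPLICATE_HEADER = "duplicate_header"
BLANK_ID = "blank_id"
DUPLICATE_ID = "duplicate_id"

PARSE_CODES = frozenset({UNKNOWN_SHEET, DUPLICATE_HEADER, BLANK_ID, DUPLICATE_ID})

ALL_CODES = LEVEL1_CODES | LEVEL2_CODES | PARSE_CODES

#: severity is a pure function of the code
SEVERITY: dict[str, str] = {code: ERROR for code in ALL_CODES}
SEVERITY[UNKNOWN_KEY] = WARNING
SEVERITY[UNKNOWN_SHEET] = WARNING


@dataclass(frozen=True)
class Location:
    """Where an issue was found.

    ``entity_id`` and ``collection`` are always set for validation issues;
    ``sheet``/``row``/``column`` are filled when the issue originates from
    (or can be traced back to) a workbook cell.  ``row`` is 1-based and
    counts the physical spreadsheet row (header is row 1).
    """

    entity_id: str
    collection: str
    key: str | None = None
    sheet: str | None = None
    row: int | None = None
    column: str | None = None

    def triple(self) -> tuple[str, str, str | None]:
        return (self.entity_id, self.collection, self.key)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str
    code: str
    location: Location
    message: str

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown issue code: {self.code!r}")

    def sort_key(self) -> tuple:
        loc = self.location
        return (loc.collection, loc.entity_id, loc.key or "", self.code)


_TSV_COLUMNS = (
    "severity",
    "code",
    "entity",
    "collection",
    "key",
    "sheet",
    "row",
    "column",
    "message",
)


@dataclass
class ValidationReport:
    """An ordered list of issues plus the derived validity verdict."""

    issues: list[ValidationIssue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.issues = sorted(self.issues, key=ValidationIssue.sort_key)

    @property
    def is_valid(self) -> bool:
        return not any(i.severity == ERROR for i in self.issues)

    @property
    def error_count(self) -> int:
        return sum(1 for i in self.issues if i.severity == ERROR)

    def codes(self) -> list[str]:
        return [i.code for i in self.issues]

    def pairs(self) -> set[tuple[str, str, str | None, str]]:
        """(entity, collection, key, code) tuples — the oracle currency."""
        return {(*i.location.triple(), i.code) for i in self.issues}

    def merged(self, other: "ValidationReport") -> "ValidationReport":
        return ValidationReport(self.issues + other.issues)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        w.writerow(_TSV_COLUMNS)
        for i in self.issues:
            loc = i.location
            w.writerow(
                [
                    i.severity,
                    i.code,
                    loc.entity_id,
                    loc.collection,
                    loc.key or "",
                    loc.sheet or "",
                    "" if loc.row is None else loc.row,
                    loc.column or "",
                    i.message,
                ]
            )
        return buf.getvalue()

    def to_text(self) -> str:
        if not self.issues:
            return "OK: no issues found\n"
        lines = []
        for i in self.issues:
            loc = i.location
            where = f"{loc.collection}:{loc.entity_id}"
            if loc.key:
                where += f".{loc.key}"
            if loc.sheet:
                cell = loc.sheet
                if loc.row is not None:
                    cell += f" row {loc.row}"
                if loc.column:
                    cell += f" col {loc.column}"
                where += f" ({cell})"
            lines.append(f"{i.severity.upper():7s} {i.code:18s} {where}: {i.message}")
        verdict = "INVALID" if not self.is_valid else "VALID (warnings only)"
        lines.append(f"{verdict}: {self.error_count} error(s), "
                     f"{len(self.issues) - self.error_count} warning(s)")
        return "\n".join(lines) + "\n"


def issue(code: str, location: Location, message: str) -> ValidationIssue:
    """Create an issue with the severity mandated by the code table."""
    return ValidationIssue(SEVERITY[code], code, location, message)
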