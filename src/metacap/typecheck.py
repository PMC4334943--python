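"""Level-1 validation: does a raw value constrain to its declared data type?

Every check is total (no exceptions on arbitrary printable input) and
deterministic.  Leading/trailing whitespace is trimmed before all checks;
internal whitespace is significant.  An empty (or all-whitespace) value
yields neither a typed value nor an issue — whether emptiness is a
problem depends on the required flag and is decided at level 2, keeping
the two validation levels disjoint.

Date/time rules follow a single ISO 8601 profile: extended format only
(``YYYY-MM-DD``, ``HH:MM[:SS]``, date ``T`` time with an optional
``Z``/``±HH:MM`` zone offset), with real calendar validity — no basic
format, no fractional seconds, years 0001–9999.  Calendar validity
(month lengths, Gregorian leap rule) is computed here rather than
delegated, so the profile is exactly what this module says it is.

Coordinates are decimal degrees (WGS84 assumed), range-checked to
[-90, 90] / [-180, 180]; sexagesimal (DMS) strings are rejected.  Regex
gatekeepers are full-string anchored: controlled syntax means the whole
value conforms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any
from urllib.parse import urlsplit

from . import report as rpt
from .errors import ConfigurationError
from .report import Location, ValidationIssue, issue
from .template import FieldDefinition
from .vocab import ControlledVocabulary, resolve_term

_INT_RE = re.compile(r"[+-]?\d+")
_DEC_RE = re.compile(r"[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?")
_DATE_RE = re.compile(r"(\d{4})-(\d{2})-(\d{2})")
_TIME_RE = re.compile(r"(\d{2}):(\d{2})(?::(\d{2}))?")
_OFFSET_RE = re.compile(r"Z|[+-]\d{2}:\d{2}")
_EMAIL_RE = re.compile(r"[^@\s]+@[^@\s]+")

_MONTH_DAYS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

#: issue code raised when a value of the given tag fails its check
TAG_CODES: dict[str, str] = {
    "integer": rpt.NOT_INTEGER,
    "decimal": rpt.NOT_DECIMAL,
    "date": rpt.NOT_ISO_DATE,
    "time": rpt.NOT_ISO_TIME,
    "datetime": rpt.NOT_ISO_DATETIME,
    "latitude": rpt.NOT_DECIMAL,
    "longitude": rpt.NOT_DECIMAL,
    "url": rpt.BAD_URL,
    "email": rpt.BAD_EMAIL,
    "cv_term": rpt.CV_VIOLATION,
    "pattern": rpt.PATTERN_MISMATCH,
}


@dataclass(frozen=True)
class TypedValue:
    """A raw string together with its normalized interpretation."""

    raw: str
    tag: str
    parsed: Any


def _is_leap(year: int) -> bool:
    return year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)


def _check_date(s: str) -> tuple[int, int, int] | None:
    m = _DATE_RE.fullmatch(s)
    if not m:
        return None
    y, mo, d = (int(g) for g in m.groups())
    if y < 1 or not 1 <= mo <= 12:
        return None
    days = _MONTH_DAYS[mo - 1] + (1 if mo == 2 and _is_leap(y) else 0)
    if not 1 <= d <= days:
        return None
    return (y, mo, d)


def _check_time(s: str) -> tuple[int, int, int] | None:
    m = _TIME_RE.fullmatch(s)
    if not m:
        return None
    h, mi = int(m.group(1)), int(m.group(2))
    sec = int(m.group(3)) if m.group(3) is not None else 0
    if h > 23 or mi > 59 or sec > 59:
        return None
    return (h, mi, sec)


def _check_datetime(s: str) -> tuple | None:
    if "T" not in s:
        return None
    date_part, rest = s.split("T", 1)
    offset = ""
    m = _OFFSET_RE.search(rest)
    if m and m.end() == len(rest):
        offset = rest[m.start() :]
        rest = rest[: m.start()]
    d = _check_date(date_part)
    t = _check_time(rest)
    if d is None or t is None:
        return None
    if offset and offset != "Z":
        oh, om = int(offset[1:3]), int(offset[4:6])
        if oh > 23 or om > 59:
            return None
    return (*d, *t, offset)


def check_gatekeeper(pattern: str, raw: str) -> bool:
    """Full-string regex match (implicit anchoring).

    Pattern compilability is a template-load-time concern; a bad pattern
    reaching this point is a configuration error.
    """
    try:
        compiled = re.compile(pattern)
    except re.error as exc:
        raise ConfigurationError(f"gatekeeper regex does not compile: {exc}") from exc
    return compiled.fullmatch(raw) is not None


def validate_value(
    field: FieldDefinition,
    raw: str,
    vocabs: dict[str, ControlledVocabulary] | None = None,
    location: Location | None = None,
) -> tuple[TypedValue | None, list[ValidationIssue]]:
    """Check one raw value against its field's data type.

    Returns ``(typed, issues)`` with exactly one of the two populated —
    except for empty input, which yields ``(None, [])``.
    """
    loc = location or Location(entity_id="", collection="", key=field.key)
    s = raw.strip()
    if not s:
        return None, []

    def bad(code: str, message: str):
        return None, [issue(code, loc, message)]

    tag = field.data_type
    if tag == "text":
        return TypedValue(raw, tag, s), []
    if tag == "integer":
        if _INT_RE.fullmatch(s):
            return TypedValue(raw, tag, int(s)), []
        return bad(rpt.NOT_INTEGER, f"{s!r} is not an integer")
    if tag == "decimal":
        if _DEC_RE.fullmatch(s):
            return TypedValue(raw, tag, float(s)), []
        return bad(rpt.NOT_DECIMAL, f"{s!r} is not a decimal number")
    if tag in ("latitude", "longitude"):
        if not _DEC_RE.fullmatch(s):
            return bad(rpt.NOT_DECIMAL, f"{s!r} is not a decimal coordinate")
        value = float(s)
        bound = 90.0 if tag == "latitude" else 180.0
        if not -bound <= value <= bound:
            return bad(
                rpt.OUT_OF_RANGE,
                f"{tag} {s} outside [-{bound:g}, {bound:g}] decimal degrees",
            )
        return TypedValue(raw, tag, value), []
    if tag == "date":
        parsed = _check_date(s)
        if parsed is None:
            return bad(rpt.NOT_ISO_DATE, f"{s!r} is not an ISO 8601 date (YYYY-MM-DD)")
        return TypedValue(raw, tag, parsed), []
    if tag == "time":
        parsed = _check_time(s)
        if parsed is None:
            return bad(rpt.NOT_ISO_TIME, f"{s!r} is not a 24-hour HH:MM[:SS] time")
        return TypedValue(raw, tag, parsed), []
    if tag == "datetime":
        parsed = _check_datetime(s)
        if parsed is None:
            return bad(
                rpt.NOT_ISO_DATETIME,
                f"{s!r} is not an ISO 8601 datetime (date'T'time[offset])",
            )
        return TypedValue(raw, tag, parsed), []
    if tag == "url":
        parts = urlsplit(s)
        if parts.scheme and parts.netloc and " " not in s:
            return TypedValue(raw, tag, s), []
        return bad(rpt.BAD_URL, f"{s!r} is not a scheme://authority URL")
    if tag == "email":
        if _EMAIL_RE.fullmatch(s):
            return TypedValue(raw, tag, s), []
        return bad(rpt.BAD_EMAIL, f"{s!r} is not a local@domain address")
    if tag == "cv_term":
        if vocabs is None or field.vocab_ref not in vocabs:
            raise ConfigurationError(
                f"field {field.key!r} needs vocabulary {field.vocab_ref!r}, "
                "which is not registered"
            )
        term = resolve_term(vocabs[field.vocab_ref], s)
        if term is None:
            return bad(
                rpt.CV_VIOLATION,
                f"{s!r} is not a term of the {field.vocab_ref!r} vocabulary",
            )
        return TypedValue(raw, tag, term), []
    if tag == "pattern":
        if check_gatekeeper(field.pattern, s):
            return TypedValue(raw, tag, s), []
        return bad(
            rpt.PATTERN_MISMATCH,
            f"{s!r} does not match the required syntax /{field.pattern}/",
        )
    raise ConfigurationError(f"unknown data type tag {tag!r}")  # pragma: no cover
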