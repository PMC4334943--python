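"""Level-1 typing rules: ISO 8601 profile, numerics, coordinates, gatekeepers.

The date/time grammar tests compare this package's own calendar logic
against an independent reference: a regex shape gate (the documented
extended-format profile) plus the standard library's calendar-validating
constructors.
"""

import datetime
import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metacap as mc
from metacap.report import (
    BAD_EMAIL,
    BAD_URL,
    CV_VIOLATION,
    NOT_DECIMAL,
    NOT_INTEGER,
    NOT_ISO_DATE,
    NOT_ISO_DATETIME,
    NOT_ISO_TIME,
    OUT_OF_RANGE,
    PATTERN_MISMATCH,
)

F = mc.FieldDefinition


def _codes(field, raw, vocabs=None):
    typed, issues = mc.validate_value(field, raw, vocabs)
    return typed, [i.code for i in issues]


@pytest.mark.parametrize(
    "field, raw, expect_codes",
    [
        # dates: extended ISO only, real calendar days
        (F("d", "d", "date"), "2014-12-08", []),
        (F("d", "d", "date"), "12/08/2014", [NOT_ISO_DATE]),
        (F("d", "d", "date"), "2013-02-29", [NOT_ISO_DATE]),
        (F("d", "d", "date"), "2016-02-29", []),
        (F("d", "d", "date"), "20141208", [NOT_ISO_DATE]),
        (F("d", "d", "date"), "2014-13-01", [NOT_ISO_DATE]),
        # times and datetimes
        (F("t", "t", "time"), "14:30", []),
        (F("t", "t", "time"), "14:30:59", []),
        (F("t", "t", "time"), "24:00", [NOT_ISO_TIME]),
        (F("t", "t", "time"), "7 pm", [NOT_ISO_TIME]),
        (F("dt", "dt", "datetime"), "2014-12-08T14:30:00", []),
        (F("dt", "dt", "datetime"), "2014-12-08T14:30:00Z", []),
        (F("dt", "dt", "datetime"), "2014-12-08T14:30:00+02:00", []),
        (F("dt", "dt", "datetime"), "2014-12-08 14:30:00", [NOT_ISO_DATETIME]),
        (F("dt", "dt", "datetime"), "2014-12-08T25:00:00", [NOT_ISO_DATETIME]),
        # numerics: no locale parsing, no comma decimals
        (F("i", "i", "integer"), "-42", []),
        (F("i", "i", "integer"), "3.5", [NOT_INTEGER]),
        (F("x", "x", "decimal"), "1.5e-3", []),
        (F("x", "x", "decimal"), "1,5", [NOT_DECIMAL]),
        # coordinates: decimal degrees, range-checked, DMS rejected
        (F("lat", "lat", "latitude"), "43.6532", []),
        (F("lat", "lat", "latitude"), "91.0", [OUT_OF_RANGE]),
        (F("lat", "lat", "latitude"), "-90", []),
        (F("lat", "lat", "latitude"), "43°39'", [NOT_DECIMAL]),
        (F("lon", "lon", "longitude"), "-180.0", []),
        (F("lon", "lon", "longitude"), "181", [OUT_OF_RANGE]),
        # urls and emails: structural minimum only
        (F("u", "u", "url"), "https://example.org/x", []),
        (F("u", "u", "url"), "example.org", [BAD_URL]),
        (F("e", "e", "email"), "pi@example.org", []),
        (F("e", "e", "email"), "nobody", [BAD_EMAIL]),
        # text is always valid after trimming
        (F("s", "s", "text"), "  anything at all  ", []),
    ],
)
def test_typing_rules(field, raw, expect_codes):
    typed, codes = _codes(field, raw)
    assert codes == expect_codes
    assert (typed is not None) == (not expect_codes)


def test_empty_value_yields_neither_issue_nor_typed_value():
    typed, codes = _codes(F("d", "d", "date"), "   ")
    assert typed is None and codes == []


def test_whitespace_trimmed_before_checks():
    typed, codes = _codes(F("i", "i", "integer"), " 42 ")
    assert codes == [] and typed.parsed == 42


def test_cv_term_resolves_through_vocabulary(vocabs):
    f = F("biome", "Biome", "cv_term", vocab_ref="biome")
    typed, codes = _codes(f, "Marine Biome", vocabs)
    assert codes == [] and typed.parsed.term_id == "ENVO:00000447"
    _, codes = _codes(f, "lava biome", vocabs)
    assert codes == [CV_VIOLATION]


def test_unregistered_vocabulary_is_configuration_error():
    f = F("biome", "Biome", "cv_term", vocab_ref="biome")
    with pytest.raises(mc.ConfigurationError):
        mc.validate_value(f, "marine biome", {})


class TestGatekeeper:
    def test_full_match_passes(self):
        assert mc.check_gatekeeper("[A-Z]{2}[0-9]{4}", "AB1234")

    def test_partial_match_fails_by_implicit_anchoring(self):
        assert not mc.check_gatekeeper("[A-Z]{2}[0-9]{4}", "AB12345")

    def test_dot_star_accepts_empty(self):
        assert mc.check_gatekeeper(".*", "")

    def test_pattern_field_reports_mismatch(self):
        f = F("c", "c", "pattern", pattern="[A-Z]{2}[0-9]{4}")
        _, codes = _codes(f, "ab1234")
        assert codes == [PATTERN_MISMATCH]


# -------------------------------------------------------------------------
# grammar agreement with an independent calendar oracle
# -------------------------------------------------------------------------

_DATE_SHAPE = re.compile(r"(\d{4})-(\d{2})-(\d{2})")


def _oracle_date(s: str) -> bool:
    m = _DATE_SHAPE.fullmatch(s)
    if not m:
        return False
    try:
        datetime.date(*(int(g) for g in m.groups()))
        return True
    except ValueError:
        return False


def date_grammar():
    """A few thousand date-like strings, valid and invalid."""
    years = ("0000", "1900", "2000", "2013", "2014", "2016", "2100")
    months = ("00", "01", "02", "04", "11", "12", "13", "2")
    days = ("00", "01", "09", "28", "29", "30", "31", "32", "8")
    for y in years:
        for mo in months:
            for d in days:
                yield f"{y}-{mo}-{d}"
                yield f"{y}/{mo}/{d}"
                yield f"{y}{mo}{d}"
    yield from ("", "2014-12", "2014-12-08T00:00", "yesterday", "2014--08")


def test_date_acceptance_matches_reference_calendar():
    f = F("d", "d", "date")
    accept = lambda s: not mc.validate_value(f, s)[1] and s.strip() != ""
    disagreements = [
        s for s in date_grammar()
        if (mc.validate_value(f, s)[0] is not None) != _oracle_date(s)
    ]
    assert disagreements == []
    assert accept("2016-02-29") and not accept("1900-02-29")


@settings(max_examples=300, derandomize=True)
@given(st.text(alphabet=st.characters(codec="ascii"), max_size=30))
def test_totality_no_tag_ever_raises_on_printable_input(s):
    """validate_value is total: arbitrary input yields issues, not exceptions."""
    for tag in ("integer", "decimal", "date", "time", "datetime",
                "latitude", "longitude", "url", "email", "text"):
        typed, issues = mc.validate_value(F("k", "k", tag), s)
        assert (typed is None) == (bool(issues) or not s.strip())


@settings(max_examples=200, derandomize=True)
@given(st.sampled_from(["date", "time", "datetime", "integer", "decimal"]),
       st.text(max_size=20))
def test_determinism_identical_inputs_identical_codes(tag, s):
    f = F("k", "k", tag)
    first = [i.code for i in mc.validate_value(f, s)[1]]
    second = [i.code for i in mc.validate_value(f, s)[1]]
    assert first == second
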