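"""Exception hierarchy.

Configuration problems (bad templates, unknown vocabularies, infeasible
corruption requests) are exceptions; problems with *metadata values* are
never exceptions — they become :class:`~metacap.report.ValidationIssue`
entries so that a workbook full of mistakes still yields a complete report.
"""


class MetacapError(Exception):
    """Base class for all package-specific errors."""


class TemplateParseError(MetacapError):
    """Malformed template/package/vocabulary file (syntax level)."""

    def __init__(self, message: str, *, path: str | None = None, line: int | None = None):
        loc = ""
        if path:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class SchemaError(MetacapError):
    """Well-formed file violating a structural invariant (duplicate keys,
    unresolved vocabulary references, dangling parents, ...)."""


class ConflictError(MetacapError):
    """Attempt to create something that already exists (duplicate package,
    duplicate sample id, ...)."""


class NotFoundError(MetacapError, LookupError):
    """Unknown collection, package, sample or vocabulary name."""


class ConfigurationError(MetacapError):
    """The caller wired components together inconsistently (e.g. a cv_term
    field whose vocabulary is not registered)."""


class CorruptionError(MetacapError, ValueError):
    """An error-injection request that cannot be satisfied by the bundle
    (e.g. more missing_required defects than required fields)."""
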