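"""metacap: checklist-driven metadata capture and validation for metagenomics.

The package models a minimum-information checklist (plus pluggable
environmental packages) as data files, stores captured metadata as
``id | collection | key | value`` records, validates it on two levels
(value-vs-datatype and structure-vs-template, with controlled-vocabulary
enforcement), and round-trips whole projects through editable multi-sheet
workbooks.
"""

from importlib import resources

from .bundle import (
    ProjectBundle,
    add_library,
    add_sample,
    from_store,
    new_bundle,
    prefill_project,
    to_records,
    to_store,
)
from .errors import (
    ConfigurationError,
    ConflictError,
    CorruptionError,
    MetacapError,
    NotFoundError,
    SchemaError,
    TemplateParseError,
)
from .kvstore import ABSENT, Entity, KVRecord, KVStore
from .report import Location, ValidationIssue, ValidationReport
from .spreadsheet import blank_workbook, read_workbook, write_workbook
from .synthetic import (
    CorruptionLedger,
    inject_errors,
    make_valid_bundle,
    random_corruption_trial,
)
from .template import (
    CollectionSpec,
    FieldDefinition,
    MetadataTemplate,
    attach_package,
    detach_package,
    load_package,
    load_template,
    required_fields,
    write_template,
)
from .typecheck import TypedValue, check_gatekeeper, validate_value
from .validate import validate_bundle, validate_structure, validate_values
from .vocab import (
    ControlledVocabulary,
    Term,
    load_obo,
    load_vocabulary,
    resolve_term,
    search_terms,
)

__version__ = "0.1.0"


def example_template_path():
    """Path to the bundled example template (a MIxS-style illustration)."""
    return resources.files(__package__) / "data" / "template.yaml"


def example_package_path(name: str):
    """Path to a bundled standalone environmental-package document."""
    return resources.files(__package__) / "data" / "packages" / f"{name}.yaml"


__all__ = [name for name in dir() if not name.startswith("_")]
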