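"""Workbook generation and round trip: the download / edit / re-validate loop.

Layout (this package's own dialect, documented in docs/template-format.md):
one sheet per collection in force, named ``project``, ``sample``,
``library <subtype>`` and ``ep <package>``.  Row 1 holds canonical keys
(first column is the reserved entity-id column ``id``), row 2 is a human
annotation row (labels, units, a ``*`` marking required keys), and every
row from 3 on is one entity.  Libraries and ep blocks carry their
``sample_name`` link as an ordinary cell.

Two dialects share the layout: ``xlsx`` (Office Open XML, the format
users download and edit) and ``tsv-dir`` (a directory with one UTF-8 TSV
per sheet, spaces in sheet names becoming underscores) whose output is
byte-deterministic and diffable.  All cells are read back as text — no
spreadsheet-native date or number coercion is ever applied, so nothing
gets silently mangled before level-1 validation sees it.
"""

from __future__ import annotations

import csv
import datetime
from pathlib import Path

import openpyxl
from openpyxl.styles import Font
from openpyxl.utils import get_column_letter

from .bundle import ProjectBundle
from .errors import SchemaError
from .kvstore import Entity
from .report import (
    BLANK_ID,
    DUPLICATE_HEADER,
    DUPLICATE_ID,
    UNKNOWN_SHEET,
    Location,
    ValidationIssue,
    issue,
)
from .template import CollectionSpec, MetadataTemplate

DIALECTS = ("xlsx", "tsv-dir")

ID_COLUMN = "id"
ID_LABEL = "Entity ID"


def sheet_name(spec: CollectionSpec) -> str:
    return f"{spec.name} {spec.subtype}" if spec.subtype else spec.name


def _file_stem(spec: CollectionSpec) -> str:
    return sheet_name(spec).replace(" ", "_")


def _annotation(fdef) -> str:
    label = fdef.label
    if fdef.units:
        label += f" ({fdef.units})"
    if fdef.required:
        label += " *"
    return label


def _sheet_rows(
    spec: CollectionSpec, entities: list[Entity]
) -> tuple[list[str], list[str], list[list[str]]]:
    """Header, annotation and data rows for one sheet."""
    keys = spec.keys()
    extras = sorted({k for e in entities for k in e.values if k not in keys})
    header = [ID_COLUMN, *keys, *extras]
    annotation = [ID_LABEL, *(_annotation(f) for f in spec.fields), *extras]
    data = []
    for e in entities:
        row = [e.id]
        for k in [*keys, *extras]:
            v = e.values.get(k, "")
            row.append("|".join(v) if isinstance(v, tuple) else v)
        data.append(row)
    return header, annotation, data


def _collect(bundle: ProjectBundle, spec: CollectionSpec) -> list[Entity]:
    if spec.name == "project":
        return [bundle.project]
    if spec.name == "sample":
        return bundle.samples
    pool = bundle.libraries if spec.name == "library" else bundle.ep_blocks
    return [e for e in pool if e.collection == spec.ident]


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _write(
    template: MetadataTemplate,
    sheets: dict[str, tuple[list[str], list[str], list[list[str]]]],
    path: Path,
    dialect: str,
) -> None:
    if dialect == "tsv-dir":
        path.mkdir(parents=True, exist_ok=True)
        for spec in template.collections:
            header, annotation, data = sheets[spec.ident]
            with open(
                path / f"{_file_stem(spec)}.tsv", "w", encoding="utf-8", newline=""
            ) as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(header)
                w.writerow(annotation)
                w.writerows(data)
        return
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    bold = Font(bold=True)
    for spec in template.collections:
        header, annotation, data = sheets[spec.ident]
        ws = wb.create_sheet(title=sheet_name(spec))
        ws.append(header)
        ws.append(annotation)
        for row in data:
            ws.append(row)
        required = {f.key for f in spec.fields if f.required}
        for col, key in enumerate(header, start=1):
            ws.cell(row=1, column=col).font = bold
            if key in required:
                ws.cell(row=2, column=col).font = bold
        # everything is text: stop spreadsheet tools from "helping"
        for row in ws.iter_rows():
            for cell in row:
                cell.number_format = "@"
    wb.save(path)


def blank_workbook(
    template: MetadataTemplate, path: str | Path, dialect: str = "xlsx"
) -> None:
    """Write an empty capture workbook: all sheets, headers, no data rows."""
    _check_dialect(dialect)
    sheets = {
        spec.ident: _sheet_rows(spec, []) for spec in template.collections
    }
    _write(template, sheets, Path(path), dialect)


def write_workbook(
    bundle: ProjectBundle,
    template: MetadataTemplate | None = None,
    path: str | Path = "metadata.xlsx",
    dialect: str = "xlsx",
) -> None:
    """Write a filled workbook, one entity per row on its collection's sheet."""
    _check_dialect(dialect)
    template = template or bundle.template
    known = {spec.ident for spec in template.collections}
    for ent in bundle.entities():
        if ent.collection not in known:
            raise SchemaError(
                f"bundle entity {ent.id!r} has collection {ent.collection!r} "
                "unknown to the template"
            )
    sheets = {
        spec.ident: _sheet_rows(spec, _collect(bundle, spec))
        for spec in template.collections
    }
    _write(template, sheets, Path(path), dialect)


# -------------------------------------------------------------------------
# reading
# -------------------------------------------------------------------------


def _cell_str(value) -> str:
    """Coerce a spreadsheet cell to text without locale tricks."""
    if value is None:
        return ""
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    if isinstance(value, (datetime.datetime, datetime.date, datetime.time)):
        return value.isoformat()
    return str(value)


def _read_sheet_grid(path: Path, dialect: str) -> dict[str, list[list[str]]]:
    grids: dict[str, list[list[str]]] = {}
    if dialect == "tsv-dir":
        for tsv in sorted(path.glob("*.tsv")):
            with open(tsv, encoding="utf-8", newline="") as fh:
                grids[tsv.stem] = [list(r) for r in csv.reader(fh, delimiter="\t")]
    else:
        wb = openpyxl.load_workbook(path, data_only=True)
        for ws in wb.worksheets:
            rows = [[_cell_str(c) for c in row] for row in ws.iter_rows(values_only=True)]
            grids[ws.title.replace(" ", "_")] = rows
    return grids


def _parse_sheet(
    spec: CollectionSpec, rows: list[list[str]], sheet: str, issues: list
) -> list[Entity]:
    if not rows:
        return []
    raw_header = [h.strip() for h in rows[0]]
    columns: list[tuple[int, str]] = []  # (index, key); duplicates dropped
    seen: set[str] = set()
    for idx, key in enumerate(raw_header):
        if not key:
            continue
        if key in seen:
            issues.append(
                issue(
                    DUPLICATE_HEADER,
                    Location(
                        "", spec.ident, key, sheet=sheet, row=1,
                        column=get_column_letter(idx + 1),
                    ),
                    f"duplicate header key {key!r}; column ignored",
                )
            )
            continue
        seen.add(key)
        columns.append((idx, key))
    if not columns or columns[0][1] != ID_COLUMN:
        issues.append(
            issue(
                DUPLICATE_HEADER,
                Location("", spec.ident, ID_COLUMN, sheet=sheet, row=1, column="A"),
                f"first column of sheet {sheet!r} must be {ID_COLUMN!r}",
            )
        )
        return []
    known = set(spec.keys())
    entities: list[Entity] = []
    ids: set[str] = set()
    for rownum, row in enumerate(rows[2:], start=3):
        if all(not c.strip() for c in row):
            continue
        cell = lambda i: row[i].strip() if i < len(row) else ""
        ent_id = cell(columns[0][0])
        if not ent_id:
            issues.append(
                issue(
                    BLANK_ID,
                    Location("", spec.ident, ID_COLUMN, sheet=sheet, row=rownum,
                             column="A"),
                    "row has no entity id; row skipped",
                )
            )
            continue
        if ent_id in ids:
            issues.append(
                issue(
                    DUPLICATE_ID,
                    Location(ent_id, spec.ident, ID_COLUMN, sheet=sheet, row=rownum,
                             column="A"),
                    f"duplicate entity id {ent_id!r}; first row wins, this row skipped",
                )
            )
            continue
        ids.add(ent_id)
        values: dict[str, str] = {}
        for idx, key in columns[1:]:
            v = cell(idx)
            if key in known or v:
                values[key] = v
        entities.append(Entity(id=ent_id, collection=spec.ident, values=values))
    return entities


def read_workbook(
    path: str | Path,
    template: MetadataTemplate,
    dialect: str | None = None,
) -> tuple[ProjectBundle, list[ValidationIssue]]:
    """Read an edited workbook back into a bundle, best-effort.

    The dialect is inferred from the path (directory = tsv-dir) unless
    given.  Recoverable problems — an unknown sheet, a duplicated header
    key, rows with blank or duplicate entity ids — are returned as
    located parse issues, not raised; an unreadable or corrupt file is an
    :class:`OSError`.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv-dir" if path.is_dir() else "xlsx"
    _check_dialect(dialect)
    if not path.exists():
        raise FileNotFoundError(f"no workbook at {path}")
    grids = _read_sheet_grid(path, dialect)
    by_stem = {_file_stem(spec): spec for spec in template.collections}
    issues: list[ValidationIssue] = []
    parsed: dict[str, list[Entity]] = {}
    for stem, rows in grids.items():
        spec = by_stem.get(stem)
        if spec is None:
            issues.append(
                issue(
                    UNKNOWN_SHEET,
                    Location("", stem, sheet=stem.replace("_", " "), row=1, column="A"),
                    f"sheet {stem.replace('_', ' ')!r} matches no template collection; "
                    "ignored",
                )
            )
            continue
        parsed[spec.ident] = _parse_sheet(
            spec, rows, sheet_name(spec), issues
        )
    projects = parsed.get("project", [])
    if len(projects) > 1:
        for extra in projects[1:]:
            issues.append(
                issue(
                    DUPLICATE_ID,
                    Location(extra.id, "project", ID_COLUMN,
                             sheet="project", column="A"),
                    "project sheet must hold exactly one row; extra row ignored",
                )
            )
    project = projects[0] if projects else Entity(id="", collection="project")
    bundle = ProjectBundle(template=template, project=project)
    for spec in template.collections:
        ents = parsed.get(spec.ident, [])
        if spec.name == "sample":
            bundle.samples.extend(ents)
        elif spec.name == "library":
            bundle.libraries.extend(ents)
        elif spec.name == "ep":
            bundle.ep_blocks.extend(ents)
    return bundle, issues
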