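"""Metadata checklists and environmental packages as data.

A :class:`MetadataTemplate` is the machine-readable form of a
minimum-information checklist: one ``project`` collection, one ``sample``
collection, at least one ``library`` collection (per library type) and at
least one environmental package (``ep``) collection per package name.
Templates live in YAML documents shipped alongside the code, not inside
it, so a community standard can be updated — or a lab-specific subset
created — without touching the software.  See ``docs/template-format.md``
for the file schema.

Each field declaration carries a canonical machine key (lowercase,
underscore-separated), a display label, a data-type tag, a required flag,
and where applicable a controlled-vocabulary reference, a regex
gatekeeper, units and an example value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import ConflictError, NotFoundError, SchemaError, TemplateParseError
from .vocab import ControlledVocabulary, Term, load_vocabulary

#: the closed set of data-type tags a field may declare
DATA_TYPE_TAGS = frozenset(
    {
        "text",
        "integer",
        "decimal",
        "date",
        "time",
        "datetime",
        "latitude",
        "longitude",
        "url",
        "email",
        "cv_term",
        "pattern",
    }
)

COLLECTION_NAMES = ("project", "sample", "library", "ep")

#: reserved key linking a library or ep entity to its sample
LINK_KEY = "sample_name"

_KEY_RE = re.compile(r"[a-z][a-z0-9_]*")


@dataclass(frozen=True)
class FieldDefinition:
    """One checklist term: canonical key, display label, typing contract."""

    key: str
    label: str
    data_type: str = "text"
    required: bool = False
    definition: str = ""
    vocab_ref: str = ""
    pattern: str = ""
    units: str = ""
    example: str = ""

    def __post_init__(self) -> None:
        if not _KEY_RE.fullmatch(self.key):
            raise SchemaError(
                f"field key {self.key!r} is not canonical "
                "(lowercase, underscore-separated)"
            )
        if self.data_type not in DATA_TYPE_TAGS:
            raise SchemaError(
                f"field {self.key!r}: unknown data type {self.data_type!r}"
            )
        if (self.data_type == "cv_term") != bool(self.vocab_ref):
            raise SchemaError(
                f"field {self.key!r}: vocab_ref must be set iff data_type is cv_term"
            )
        if self.data_type == "pattern":
            if not self.pattern:
                raise SchemaError(f"field {self.key!r}: pattern data type needs a regex")
            try:
                re.compile(self.pattern)
            except re.error as exc:
                raise SchemaError(
                    f"field {self.key!r}: regex does not compile: {exc}"
                ) from exc
        elif self.pattern:
            raise SchemaError(f"field {self.key!r}: pattern set but data_type is not pattern")


@dataclass(frozen=True)
class CollectionSpec:
    """An ordered field contract for one collection (tier) of a template."""

    name: str
    fields: tuple[FieldDefinition, ...]
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.name not in COLLECTION_NAMES:
            raise SchemaError(f"unknown collection name {self.name!r}")
        if self.name == "ep" and not self.subtype:
            raise SchemaError("ep collections must carry a package name as subtype")
        seen: set[str] = set()
        for f in self.fields:
            if f.key in seen:
                raise SchemaError(
                    f"collection {self.ident!r}: duplicate field key {f.key!r}"
                )
            seen.add(f.key)

    @property
    def ident(self) -> str:
        """Stable collection identity, e.g. ``sample`` or ``ep/water``."""
        return f"{self.name}/{self.subtype}" if self.subtype else self.name

    def keys(self) -> list[str]:
        return [f.key for f in self.fields]

    def field(self, key: str) -> FieldDefinition | None:
        for f in self.fields:
            if f.key == key:
                return f
        return None


@dataclass(frozen=True)
class MetadataTemplate:
    """A named, versioned set of collection contracts plus their vocabularies."""

    name: str
    version: str
    collections: tuple[CollectionSpec, ...]
    vocabularies: dict[str, ControlledVocabulary] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idents = [c.ident for c in self.collections]
        for ident in idents:
            if idents.count(ident) > 1:
                raise SchemaError(f"duplicate collection {ident!r} in template")
        counts = {name: 0 for name in COLLECTION_NAMES}
        for c in self.collections:
            counts[c.name] += 1
        if counts["project"] != 1 or counts["sample"] != 1:
            raise SchemaError(
                "template needs exactly one project and one sample collection"
            )
        if counts["library"] < 1 or counts["ep"] < 1:
            raise SchemaError(
                "template needs at least one library and one ep collection"
            )
        for c in self.collections:
            for f in c.fields:
                if f.vocab_ref and f.vocab_ref not in self.vocabularies:
                    raise SchemaError(
                        f"field {f.key!r} in {c.ident!r} references unregistered "
                        f"vocabulary {f.vocab_ref!r}"
                    )

    def collection(self, ident: str) -> CollectionSpec:
        for c in self.collections:
            if c.ident == ident:
                return c
        raise NotFoundError(f"no collection {ident!r} in template {self.name!r}")

    def has_collection(self, ident: str) -> bool:
        return any(c.ident == ident for c in self.collections)

    @property
    def packages(self) -> list[CollectionSpec]:
        return [c for c in self.collections if c.name == "ep"]

    @property
    def libraries(self) -> list[CollectionSpec]:
        return [c for c in self.collections if c.name == "library"]


def required_fields(template: MetadataTemplate, collection: str) -> list[str]:
    """Keys flagged required in a collection, in declaration order."""
    return [f.key for f in template.collection(collection).fields if f.required]


def attach_package(
    template: MetadataTemplate,
    package: CollectionSpec,
    vocabularies: dict[str, ControlledVocabulary] | None = None,
) -> MetadataTemplate:
    """Return a new template with an environmental package plugged in.

    The input template is never modified.  Any vocabularies the package
    fields reference must already be registered or supplied here.
    """
    if package.name != "ep":
        raise SchemaError("only ep collections can be attached as packages")
    if template.has_collection(package.ident):
        raise ConflictError(f"package {package.ident!r} already present")
    vocabs = dict(template.vocabularies)
    vocabs.update(vocabularies or {})
    return MetadataTemplate(
        name=template.name,
        version=template.version,
        collections=template.collections + (package,),
        vocabularies=vocabs,
    )


def detach_package(template: MetadataTemplate, subtype: str) -> MetadataTemplate:
    """Return a new template without the named environmental package."""
    ident = f"ep/{subtype}"
    if not template.has_collection(ident):
        raise NotFoundError(f"no package {ident!r} in template")
    return replace(
        template,
        collections=tuple(c for c in template.collections if c.ident != ident),
    )


# -------------------------------------------------------------------------
# YAML (de)serialization
# -------------------------------------------------------------------------

_FIELD_KEYS = {
    "key",
    "label",
    "type",
    "required",
    "definition",
    "vocab",
    "pattern",
    "units",
    "example",
}


def _parse_field(raw: object, where: str, path: str) -> FieldDefinition:
    if not isinstance(raw, dict):
        raise TemplateParseError(f"{where}: field entry must be a mapping", path=path)
    unknown = set(raw) - _FIELD_KEYS
    if unknown:
        raise TemplateParseError(
            f"{where}: unknown field attribute(s) {sorted(unknown)}", path=path
        )
    if "key" not in raw:
        raise TemplateParseError(f"{where}: field entry missing 'key'", path=path)
    key = str(raw["key"])
    try:
        return FieldDefinition(
            key=key,
            label=str(raw.get("label", key)),
            data_type=str(raw.get("type", "text")),
            required=bool(raw.get("required", False)),
            definition=str(raw.get("definition", "") or ""),
            vocab_ref=str(raw.get("vocab", "") or ""),
            pattern=str(raw.get("pattern", "") or ""),
            units=str(raw.get("units", "") or ""),
            example=str(raw.get("example", "") or ""),
        )
    except SchemaError:
        raise


def _parse_collection(raw: object, path: str) -> CollectionSpec:
    if not isinstance(raw, dict) or "name" not in raw:
        raise TemplateParseError("collection entry must be a mapping with 'name'", path=path)
    name = str(raw["name"])
    subtype = str(raw.get("subtype", "") or "")
    where = f"collection {name}/{subtype}" if subtype else f"collection {name}"
    raw_fields = raw.get("fields", [])
    if not isinstance(raw_fields, list):
        raise TemplateParseError(f"{where}: 'fields' must be a list", path=path)
    fields = tuple(_parse_field(f, where, path) for f in raw_fields)
    return CollectionSpec(name=name, subtype=subtype, fields=fields)


def _parse_vocabularies(
    raw: object, base: Path, path: str
) -> dict[str, ControlledVocabulary]:
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise TemplateParseError("'vocabularies' must be a mapping", path=path)
    vocabs: dict[str, ControlledVocabulary] = {}
    for name, spec in raw.items():
        if isinstance(spec, str):
            vocabs[str(name)] = load_vocabulary(base / spec, name=str(name))
        elif isinstance(spec, dict) and isinstance(spec.get("terms"), list):
            terms = tuple(
                Term(
                    term_id=str(t["id"]),
                    label=str(t["label"]),
                    synonyms=tuple(str(s) for s in t.get("synonyms", [])),
                    parents=tuple(str(p) for p in t.get("parents", [])),
                )
                for t in spec["terms"]
            )
            vocabs[str(name)] = ControlledVocabulary(name=str(name), terms=terms)
        else:
            raise TemplateParseError(
                f"vocabulary {name!r}: expected a file path or inline term list",
                path=path,
            )
    return vocabs


def _load_yaml(path: Path) -> dict:
    try:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        line = None
        mark = getattr(exc, "problem_mark", None)
        if mark is not None:
            line = mark.line + 1
        raise TemplateParseError(f"YAML syntax error: {exc}", path=str(path), line=line)
    if not isinstance(doc, dict):
        raise TemplateParseError("template document must be a mapping", path=str(path))
    return doc


def load_template(path: str | Path) -> MetadataTemplate:
    """Load a template document (and any referenced vocabulary files).

    Loading is pure: no global registries, no caching.  Vocabulary file
    paths are resolved relative to the template file.
    """
    path = Path(path)
    doc = _load_yaml(path)
    for req in ("name", "version", "collections"):
        if req not in doc:
            raise TemplateParseError(f"template missing {req!r}", path=str(path))
    if not isinstance(doc["collections"], list):
        raise TemplateParseError("'collections' must be a list", path=str(path))
    vocabs = _parse_vocabularies(doc.get("vocabularies"), path.parent, str(path))
    collections = tuple(_parse_collection(c, str(path)) for c in doc["collections"])
    return MetadataTemplate(
        name=str(doc["name"]),
        version=str(doc["version"]),
        collections=collections,
        vocabularies=vocabs,
    )


def load_package(
    path: str | Path,
) -> tuple[CollectionSpec, dict[str, ControlledVocabulary]]:
    """Load a standalone environmental-package document.

    Returns the package collection plus any vocabularies the document
    bundles, ready for :func:`attach_package`.
    """
    path = Path(path)
    doc = _load_yaml(path)
    if "package" not in doc:
        raise TemplateParseError("package document missing 'package'", path=str(path))
    spec = _parse_collection(doc["package"], str(path))
    vocabs = _parse_vocabularies(doc.get("vocabularies"), path.parent, str(path))
    return spec, vocabs


def _field_to_dict(f: FieldDefinition) -> dict:
    out: dict[str, object] = {"key": f.key, "label": f.label, "type": f.data_type}
    if f.required:
        out["required"] = True
    for attr, name in (
        ("definition", "definition"),
        ("vocab_ref", "vocab"),
        ("pattern", "pattern"),
        ("units", "units"),
        ("example", "example"),
    ):
        val = getattr(f, attr)
        if val:
            out[name] = val
    return out


def _collection_to_dict(c: CollectionSpec) -> dict:
    out: dict[str, object] = {"name": c.name}
    if c.subtype:
        out["subtype"] = c.subtype
    out["fields"] = [_field_to_dict(f) for f in c.fields]
    return out


def write_template(template: MetadataTemplate, path: str | Path) -> None:
    """Serialize a template to a single YAML document (vocabularies inline)."""
    doc: dict[str, object] = {"name": template.name, "version": template.version}
    if template.vocabularies:
        doc["vocabularies"] = {
            name: {
                "terms": [
                    {
                        "id": t.term_id,
                        "label": t.label,
                        **({"synonyms": list(t.synonyms)} if t.synonyms else {}),
                        **({"parents": list(t.parents)} if t.parents else {}),
                    }
                    for t in vocab.terms
                ]
            }
            for name, vocab in template.vocabularies.items()
        }
    doc["collections"] = [_collection_to_dict(c) for c in template.collections]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
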