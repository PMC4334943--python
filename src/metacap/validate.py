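"""The two-level validation engine.

Level 1 (:func:`validate_values`) asks, for every filled-in value whose
key the template knows: does the value constrain to the declared data
type?  Level 2 (:func:`validate_structure`) asks: does the metadata
structure conform to the template — are required fields present, are
extra keys flagged, does the project/sample/library hierarchy hold
together?  The two levels emit disjoint issue-code sets by construction,
so :func:`validate_bundle` is their plain, deterministic merge.

Empty values are a level-2 concern only (a blank required cell is
``missing_required``); unknown keys are warnings, never errors — the
capture model deliberately accepts arbitrary extra key-value pairs on
top of the blessed, controlled subset.
"""

from __future__ import annotations

from .bundle import ProjectBundle
from .kvstore import Entity
from .report import (
    BROKEN_LINK,
    EXTRA_EP,
    MISSING_EP,
    MISSING_REQUIRED,
    NO_SAMPLES,
    UNKNOWN_KEY,
    Location,
    ValidationReport,
    issue,
)
from .template import LINK_KEY, CollectionSpec, MetadataTemplate
from .typecheck import validate_value
from .vocab import ControlledVocabulary


def _each_value(v) -> list[str]:
    return list(v) if isinstance(v, tuple) else [v]


def _spec_for(template: MetadataTemplate, ent: Entity) -> CollectionSpec | None:
    try:
        return template.collection(ent.collection)
    except LookupError:
        return None


def validate_values(
    bundle: ProjectBundle,
    template: MetadataTemplate | None = None,
    vocabs: dict[str, ControlledVocabulary] | None = None,
) -> ValidationReport:
    """Level 1: type-check every template-known, non-empty value."""
    template = template or bundle.template
    vocabs = vocabs if vocabs is not None else template.vocabularies
    issues = []
    for ent in bundle.entities():
        spec = _spec_for(template, ent)
        if spec is None:
            continue
        for key, raw in ent.values.items():
            fdef = spec.field(key)
            if fdef is None:
                continue  # unknown keys are a structural concern
            for one in _each_value(raw):
                loc = Location(entity_id=ent.id, collection=ent.collection, key=key)
                _, probs = validate_value(fdef, one, vocabs, location=loc)
                issues.extend(probs)
    return ValidationReport(issues)


def _entity_structure(ent: Entity, spec: CollectionSpec) -> list:
    issues = []
    for fdef in spec.fields:
        raw = ent.values.get(fdef.key)
        present = raw is not None and any(v.strip() for v in _each_value(raw))
        if fdef.required and not present:
            issues.append(
                issue(
                    MISSING_REQUIRED,
                    Location(ent.id, ent.collection, fdef.key),
                    f"required field {fdef.label!r} ({fdef.key}) is missing or blank",
                )
            )
    known = set(spec.keys())
    for key in ent.values:
        if key not in known:
            issues.append(
                issue(
                    UNKNOWN_KEY,
                    Location(ent.id, ent.collection, key),
                    f"key {key!r} is not part of the {spec.ident!r} checklist",
                )
            )
    return issues


def validate_structure(
    bundle: ProjectBundle, template: MetadataTemplate | None = None
) -> ValidationReport:
    """Level 2: required fields, extra keys, and hierarchy integrity."""
    template = template or bundle.template
    issues = []
    for ent in bundle.entities():
        spec = _spec_for(template, ent)
        if spec is not None:
            issues.extend(_entity_structure(ent, spec))
    if not bundle.samples:
        issues.append(
            issue(
                NO_SAMPLES,
                Location(bundle.project.id, "project"),
                "project has no samples",
            )
        )
    sample_ids = bundle.sample_ids()
    for ent in [*bundle.libraries, *bundle.ep_blocks]:
        link = ent.get(LINK_KEY).strip()
        if link and link not in sample_ids:
            issues.append(
                issue(
                    BROKEN_LINK,
                    Location(ent.id, ent.collection, LINK_KEY),
                    f"{LINK_KEY}={link!r} names no sample in this project",
                )
            )
    for sample in bundle.samples:
        blocks = bundle.ep_for(sample.id)
        if not blocks:
            issues.append(
                issue(
                    MISSING_EP,
                    Location(sample.id, "sample"),
                    f"sample {sample.id!r} has no environmental-package block",
                )
            )
        elif len(blocks) > 1:
            issues.append(
                issue(
                    EXTRA_EP,
                    Location(sample.id, "sample"),
                    f"sample {sample.id!r} has {len(blocks)} environmental-package "
                    "blocks, expected exactly one",
                )
            )
    return ValidationReport(issues)


def validate_bundle(
    bundle: ProjectBundle,
    template: MetadataTemplate | None = None,
    vocabs: dict[str, ControlledVocabulary] | None = None,
) -> ValidationReport:
    """Both validation levels, merged into one deterministic report."""
    template = template or bundle.template
    return validate_values(bundle, template, vocabs).merged(
        validate_structure(bundle, template)
    )
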