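"""The three-tier project model.

A metagenomic study is captured as one *project*, any number of *samples*,
and any number of *libraries* (sequencing extractions) per sample; each
sample additionally carries exactly one environmental-package (*ep*)
block describing the sampled environment.  Libraries and ep blocks link
back to their sample through the reserved ``sample_name`` key — the same
flat-spreadsheet convention a hand-edited workbook uses — so the whole
hierarchy survives a round trip through the EAV store or a spreadsheet
without any side tables.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .errors import ConflictError, NotFoundError, SchemaError
from .kvstore import Entity, KVRecord, KVStore
from .template import LINK_KEY, MetadataTemplate


@dataclass(eq=False)
class ProjectBundle:
    """One project with its samples, libraries and ep blocks.

    Entity lists keep insertion order; equality is order-insensitive
    (entities are compared by id).  The template reference is carried for
    convenience and never participates in equality.
    """

    template: MetadataTemplate
    project: Entity
    samples: list[Entity] = field(default_factory=list)
    libraries: list[Entity] = field(default_factory=list)
    ep_blocks: list[Entity] = field(default_factory=list)

    def entities(self) -> list[Entity]:
        return [self.project, *self.samples, *self.libraries, *self.ep_blocks]

    def ids(self) -> set[str]:
        return {e.id for e in self.entities()}

    def sample_ids(self) -> set[str]:
        return {s.id for s in self.samples}

    def ep_for(self, sample_id: str) -> list[Entity]:
        return [e for e in self.ep_blocks if e.get(LINK_KEY) == sample_id]

    def libraries_for(self, sample_id: str) -> list[Entity]:
        return [e for e in self.libraries if e.get(LINK_KEY) == sample_id]

    @staticmethod
    def _norm(entities: list[Entity]) -> list[tuple]:
        return sorted(
            ((e.collection, e.id, dict(e.values)) for e in entities),
            key=lambda t: (t[0], t[1]),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProjectBundle):
            return NotImplemented
        return (
            (self.project.id, self.project.collection, dict(self.project.values))
            == (other.project.id, other.project.collection, dict(other.project.values))
            and self._norm(self.samples) == other._norm(other.samples)
            and self._norm(self.libraries) == other._norm(other.libraries)
            and self._norm(self.ep_blocks) == other._norm(other.ep_blocks)
        )


def new_bundle(template: MetadataTemplate, project_id: str) -> ProjectBundle:
    """A fresh bundle: empty project entity, no samples/libraries/eps."""
    if not project_id:
        raise ValueError("project id must be non-empty")
    return ProjectBundle(
        template=template,
        project=Entity(id=project_id, collection="project"),
    )


def add_sample(
    bundle: ProjectBundle,
    sample_id: str,
    fields: dict[str, str] | None = None,
    package: str = "",
    ep_fields: dict[str, str] | None = None,
    ep_id: str | None = None,
) -> ProjectBundle:
    """Add a sample together with its environmental-package block.

    The two entities are created atomically: a sample never exists
    without its ep block.  ``package`` names an ep subtype registered in
    the template in force.
    """
    if not sample_id:
        raise ValueError("sample id must be non-empty")
    if sample_id in bundle.ids():
        raise ConflictError(f"entity id {sample_id!r} already used in bundle")
    ep_ident = f"ep/{package}"
    if not bundle.template.has_collection(ep_ident):
        raise NotFoundError(f"template has no environmental package {package!r}")
    ep_id = ep_id or f"{sample_id}_ep"
    if ep_id in bundle.ids():
        raise ConflictError(f"entity id {ep_id!r} already used in bundle")
    sample = Entity(id=sample_id, collection="sample", values=dict(fields or {}))
    ep = Entity(id=ep_id, collection=ep_ident, values=dict(ep_fields or {}))
    ep.values[LINK_KEY] = sample_id
    bundle.samples.append(sample)
    bundle.ep_blocks.append(ep)
    return bundle


def add_library(
    bundle: ProjectBundle,
    sample_id: str,
    library_id: str,
    subtype: str,
    fields: dict[str, str] | None = None,
) -> ProjectBundle:
    """Add a sequencing library (extraction) linked to an existing sample."""
    if not library_id:
        raise ValueError("library id must be non-empty")
    if sample_id not in bundle.sample_ids():
        raise NotFoundError(f"no sample {sample_id!r} in bundle")
    if library_id in bundle.ids():
        raise ConflictError(f"entity id {library_id!r} already used in bundle")
    ident = f"library/{subtype}"
    if not bundle.template.has_collection(ident):
        raise NotFoundError(f"template has no library type {subtype!r}")
    lib = Entity(id=library_id, collection=ident, values=dict(fields or {}))
    lib.values[LINK_KEY] = sample_id
    bundle.libraries.append(lib)
    return bundle


def prefill_project(source: ProjectBundle, target: ProjectBundle) -> ProjectBundle:
    """Copy project-level keys from one bundle into another.

    Every project key in ``source`` overwrites the corresponding key in
    ``target`` (stored information wins, as when a saved project
    repopulates a fresh form).  Samples, libraries and ep blocks of the
    target — and the source bundle entirely — are untouched.  Idempotent.
    """
    target.project.values.update(copy.deepcopy(source.project.values))
    return target


# -------------------------------------------------------------------------
# EAV round trip
# -------------------------------------------------------------------------


def to_records(bundle: ProjectBundle) -> list[KVRecord]:
    out: list[KVRecord] = []
    for e in bundle.entities():
        out.extend(e.records())
    return out


def to_store(bundle: ProjectBundle) -> KVStore:
    return KVStore.from_records(to_records(bundle))


def from_store(store: KVStore, template: MetadataTemplate) -> ProjectBundle:
    """Reconstruct a bundle from its flat EAV form.

    The store must contain exactly one project entity, and every
    collection must be known to the template.
    """
    projects = store.entities("project")
    if len(projects) != 1:
        raise SchemaError(f"store has {len(projects)} project entities, expected 1")
    bundle = ProjectBundle(template=template, project=projects[0])
    for ent in store.entities():
        coll = ent.collection
        if coll == "project":
            continue
        if not template.has_collection(coll):
            raise SchemaError(f"store entity {ent.id!r} has unknown collection {coll!r}")
        if coll == "sample":
            bundle.samples.append(ent)
        elif coll.startswith("library/"):
            bundle.libraries.append(ent)
        elif coll.startswith("ep/"):
            bundle.ep_blocks.append(ent)
        else:  # pragma: no cover - template invariants forbid this
            raise SchemaError(f"unsupported collection {coll!r}")
    return bundle
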