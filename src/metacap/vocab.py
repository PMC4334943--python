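"""Controlled vocabularies for CV-bound metadata fields.

A vocabulary is a frozen, offline term set in the style of an ENVO subset:
each term has a CURIE-style identifier, a preferred label, optional
synonyms and optional parent terms.  Four vocabulary names back the
classic environmental descriptors — ``environmental_package``, ``biome``,
``feature`` and ``material`` — but any name can be registered with a
template.

The lookup surface is deliberately narrow (resolve + ranked search) so a
live ontology-service adapter could be swapped in behind the same
interface; everything in this package works from local term tables.

File format: TSV with columns ``term_id``, ``label``, ``synonyms``
(pipe-separated), ``parents`` (pipe-separated term ids).  An importer for
OBO-format ontology files is provided as a convenience.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import SchemaError, TemplateParseError

_COLUMNS = ("term_id", "label", "synonyms", "parents")


@dataclass(frozen=True)
class Term:
    term_id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()


@dataclass(frozen=True)
class ControlledVocabulary:
    """A frozen term set with deterministic label/synonym resolution.

    Invariants enforced at construction: unique term ids, unique
    case-folded labels, parents referencing existing ids.  A synonym that
    collides (case-folded) with another term's label is ignored for
    resolution — the label wins; among colliding synonyms the term with
    the lexicographically smallest label wins.
    """

    name: str
    terms: tuple[Term, ...]
    _by_id: dict = field(default_factory=dict, repr=False, compare=False)
    _by_label: dict = field(default_factory=dict, repr=False, compare=False)
    _by_synonym: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_id: dict[str, Term] = {}
        by_label: dict[str, Term] = {}
        for t in self.terms:
            if t.term_id in by_id:
                raise SchemaError(
                    f"vocabulary {self.name!r}: duplicate term id {t.term_id!r}"
                )
            by_id[t.term_id] = t
            lab = t.label.casefold()
            if lab in by_label:
                raise SchemaError(
                    f"vocabulary {self.name!r}: terms {by_label[lab].term_id!r} and "
                    f"{t.term_id!r} share the label {t.label!r}"
                )
            by_label[lab] = t
        for t in self.terms:
            for p in t.parents:
                if p not in by_id:
                    raise SchemaError(
                        f"vocabulary {self.name!r}: term {t.term_id!r} references "
                        f"unknown parent {p!r}"
                    )
        by_syn: dict[str, Term] = {}
        for t in sorted(self.terms, key=lambda t: t.label.casefold()):
            for s in t.synonyms:
                key = s.strip().casefold()
                if not key or key in by_label:
                    continue  # labels shadow synonyms
                by_syn.setdefault(key, t)
        self._by_id.update(by_id)
        self._by_label.update(by_label)
        self._by_synonym.update(by_syn)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def labels(self) -> list[str]:
        """All preferred labels, sorted case-insensitively."""
        return sorted((t.label for t in self.terms), key=str.casefold)


def resolve_term(vocab: ControlledVocabulary, raw: str) -> Term | None:
    """Resolve a raw string to a term, or ``None``.

    Matching order: exact term id, then case-insensitive label, then
    case-insensitive synonym; the input is whitespace-trimmed first.
    """
    s = raw.strip()
    if not s:
        return None
    if s in vocab._by_id:
        return vocab._by_id[s]
    folded = s.casefold()
    if folded in vocab._by_label:
        return vocab._by_label[folded]
    return vocab._by_synonym.get(folded)


def search_terms(vocab: ControlledVocabulary, query: str, limit: int = 10) -> list[Term]:
    """Ranked prefix/substring search over labels and synonyms.

    Ranking tiers: exact label match, label prefix, label substring, then
    any synonym match; ties break lexicographically by case-folded label.
    An empty query returns the first ``limit`` terms in label order.
    """
    if limit < 1:
        raise ValueError("limit must be >= 1")
    q = query.strip().casefold()
    ordered = sorted(vocab.terms, key=lambda t: (t.label.casefold(), t.term_id))
    if not q:
        return ordered[:limit]
    ranked: list[tuple[int, str, Term]] = []
    for t in ordered:
        lab = t.label.casefold()
        if lab == q:
            tier = 0
        elif lab.startswith(q):
            tier = 1
        elif q in lab:
            tier = 2
        elif any(q in s.casefold() for s in t.synonyms):
            tier = 3
        else:
            continue
        ranked.append((tier, lab, t))
    ranked.sort(key=lambda r: (r[0], r[1], r[2].term_id))
    return [t for _, _, t in ranked[:limit]]


def _split(cell: str) -> tuple[str, ...]:
    return tuple(p.strip() for p in cell.split("|") if p.strip())


def load_vocabulary(path: str | Path, name: str | None = None) -> ControlledVocabulary:
    """Load a vocabulary from its TSV term table.

    The vocabulary name defaults to the file stem.  Duplicate labels and
    dangling parents raise :class:`SchemaError`; a malformed header raises
    :class:`TemplateParseError`.
    """
    path = Path(path)
    name = name or path.stem
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TemplateParseError("empty vocabulary file", path=str(path)) from None
        if tuple(h.strip() for h in header) != _COLUMNS:
            raise TemplateParseError(
                f"vocabulary header must be {' | '.join(_COLUMNS)}",
                path=str(path),
                line=1,
            )
        terms = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise TemplateParseError(
                    "vocabulary row needs term_id and label",
                    path=str(path),
                    line=lineno,
                )
            row = list(row) + [""] * (4 - len(row))
            terms.append(
                Term(
                    term_id=row[0].strip(),
                    label=row[1].strip(),
                    synonyms=_split(row[2]),
                    parents=_split(row[3]),
                )
            )
    return ControlledVocabulary(name=name, terms=tuple(terms))


def write_vocabulary(vocab: ControlledVocabulary, path: str | Path) -> None:
    """Serialize a vocabulary back to its TSV term-table format."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COLUMNS)
        for t in vocab.terms:
            w.writerow([t.term_id, t.label, "|".join(t.synonyms), "|".join(t.parents)])


def load_obo(path: str | Path, name: str | None = None) -> ControlledVocabulary:
    """Import a vocabulary from an OBO-format ontology file.

    Convenience for building local term tables from published ontology
    releases; obsolete terms are skipped.
    """
    import obonet  # imported lazily: only needed for this importer

    graph = obonet.read_obo(str(path))
    named = {tid for tid, data in graph.nodes(data=True) if data.get("name")}
    terms = []
    for term_id, data in sorted(graph.nodes(data=True)):
        label = data.get("name", "")
        if not label:
            continue
        synonyms = []
        for raw in data.get("synonym", []):
            # OBO synonym lines look like: "text" SCOPE [xrefs]
            if raw.startswith('"') and '"' in raw[1:]:
                synonyms.append(raw[1 : raw.index('"', 1)])
        parents = tuple(sorted(p for p in graph.successors(term_id) if p in named))
        terms.append(
            Term(
                term_id=term_id,
                label=label,
                synonyms=tuple(synonyms),
                parents=parents,
            )
        )
    return ControlledVocabulary(
        name=name or Path(path).stem, terms=tuple(terms)
    )
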