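"""Seeded generation of valid bundles and exact error injection.

:func:`make_valid_bundle` produces a bundle that passes both validation
levels with zero issues; :func:`inject_errors` then applies a requested
mix of defects at randomly chosen (seeded) eligible locations and
returns a :class:`CorruptionLedger` listing exactly what was broken and
where.  Because corruption happens *after* generation, the ledger is
exact ground truth: a sound and complete validator must report precisely
the ledger's (location, code) pairs, which is the package's central
self-check.

All randomness flows through one explicitly seeded ``random.Random``; no
global PRNG state is touched.  Generated values are type-valid by
construction (CV terms drawn uniformly from the vocabulary, dates from a
fixed 2005–2020 window, coordinates within range); they make no claim to
biological realism beyond that.
"""

from __future__ import annotations

import copy
import csv
import datetime
import random
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from . import report as rpt
from .bundle import ProjectBundle, add_library, add_sample, new_bundle
from .errors import ConfigurationError, CorruptionError, NotFoundError
from .kvstore import Entity
from .template import LINK_KEY, FieldDefinition, MetadataTemplate
from .typecheck import check_gatekeeper
from .vocab import ControlledVocabulary

_WORDS = (
    "alpha", "bravo", "delta", "echo", "kilo", "lima", "mike", "nova",
    "oscar", "quebec", "sierra", "tango", "victor", "zulu",
)

_DATE_START = datetime.date(2005, 1, 1)
_DATE_DAYS = (datetime.date(2020, 12, 31) - _DATE_START).days + 1
_OFFSETS = ("", "Z", "+02:00", "-05:00")


def _gen_value(
    rng: random.Random,
    fdef: FieldDefinition,
    vocabs: dict[str, ControlledVocabulary],
    package: str,
) -> str:
    tag = fdef.data_type
    if tag == "text":
        return f"{rng.choice(_WORDS)} {rng.choice(_WORDS)}"
    if tag == "integer":
        return str(rng.randrange(0, 100000))
    if tag == "decimal":
        return f"{rng.uniform(0, 1000):.3f}"
    if tag == "date":
        return (_DATE_START + datetime.timedelta(days=rng.randrange(_DATE_DAYS))).isoformat()
    if tag == "time":
        return f"{rng.randrange(24):02d}:{rng.randrange(60):02d}:{rng.randrange(60):02d}"
    if tag == "datetime":
        d = (_DATE_START + datetime.timedelta(days=rng.randrange(_DATE_DAYS))).isoformat()
        t = f"{rng.randrange(24):02d}:{rng.randrange(60):02d}:{rng.randrange(60):02d}"
        return f"{d}T{t}{rng.choice(_OFFSETS)}"
    if tag == "latitude":
        return f"{rng.uniform(-90, 90):.4f}"
    if tag == "longitude":
        return f"{rng.uniform(-180, 180):.4f}"
    if tag == "url":
        return f"https://example.org/{rng.choice(_WORDS)}/{rng.randrange(1000)}"
    if tag == "email":
        return f"{rng.choice(_WORDS)}.{rng.choice(_WORDS)}@example.org"
    if tag == "cv_term":
        vocab = vocabs.get(fdef.vocab_ref)
        if vocab is None:
            raise ConfigurationError(
                f"field {fdef.key!r} needs unregistered vocabulary {fdef.vocab_ref!r}"
            )
        if fdef.vocab_ref == "environmental_package":
            # keep the declared package consistent with the ep block in use
            return package
        return rng.choice(vocab.labels())
    if tag == "pattern":
        if not fdef.example or not check_gatekeeper(fdef.pattern, fdef.example):
            raise ConfigurationError(
                f"pattern field {fdef.key!r} needs an example matching its regex "
                "for synthetic generation"
            )
        return fdef.example
    raise ConfigurationError(f"unknown data type {tag!r}")  # pragma: no cover


def _fill(
    rng: random.Random,
    template: MetadataTemplate,
    collection: str,
    vocabs: dict[str, ControlledVocabulary],
    package: str,
) -> dict[str, str]:
    spec = template.collection(collection)
    return {
        f.key: _gen_value(rng, f, vocabs, package)
        for f in spec.fields
        if f.key != LINK_KEY
    }


def make_valid_bundle(
    template: MetadataTemplate,
    vocabs: dict[str, ControlledVocabulary] | None = None,
    seed: int = 0,
    n_samples: int = 3,
    n_libraries_per_sample: int = 2,
    package: str = "water",
    project_id: str = "p001",
) -> ProjectBundle:
    """Generate a bundle that validates cleanly, deterministically per seed."""
    if n_samples < 0 or n_libraries_per_sample < 0:
        raise ValueError("counts must be >= 0")
    if not template.has_collection(f"ep/{package}"):
        raise NotFoundError(f"template has no environmental package {package!r}")
    vocabs = vocabs if vocabs is not None else template.vocabularies
    rng = random.Random(seed)
    lib_subtype = template.libraries[0].subtype
    bundle = new_bundle(template, project_id)
    bundle.project.values.update(_fill(rng, template, "project", vocabs, package))
    width = max(2, len(str(max(n_samples, 1))))
    for i in range(1, n_samples + 1):
        sid = f"sample_{i:0{width}d}"
        add_sample(
            bundle,
            sid,
            fields=_fill(rng, template, "sample", vocabs, package),
            package=package,
            ep_fields=_fill(rng, template, f"ep/{package}", vocabs, package),
        )
        for j in range(1, n_libraries_per_sample + 1):
            add_library(
                bundle,
                sid,
                f"{sid}_lib{j}",
                lib_subtype,
                fields=_fill(rng, template, f"library/{lib_subtype}", vocabs, package),
            )
    return bundle


# -------------------------------------------------------------------------
# corruption injection
# -------------------------------------------------------------------------


@dataclass(frozen=True)
class LedgerEntry:
    entity_id: str
    collection: str
    key: str | None
    code: str


@dataclass
class CorruptionLedger:
    """Exact record of every injected defect: the validation oracle."""

    entries: list[LedgerEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> set[tuple[str, str, str | None, str]]:
        return {(e.entity_id, e.collection, e.key, e.code) for e in self.entries}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(("entity", "collection", "key", "code"))
            for e in self.entries:
                w.writerow((e.entity_id, e.collection, e.key or "", e.code))


#: codes the injector can produce; every validator code short of extra_ep
#: (unreachable without hand-editing) has an injector.
INJECTABLE_CODES = tuple(
    sorted((rpt.LEVEL1_CODES | rpt.LEVEL2_CODES) - {rpt.EXTRA_EP})
)

_BAD_VALUES = {
    rpt.NOT_INTEGER: "3.5",
    rpt.NOT_DECIMAL: "abc",
    rpt.NOT_ISO_DATE: "12/08/2014",
    rpt.NOT_ISO_TIME: "7 pm",
    rpt.NOT_ISO_DATETIME: "2014-12-08 10:00:00",
    rpt.BAD_URL: "example dot org",
    rpt.BAD_EMAIL: "nobody-at-example.org",
    rpt.CV_VIOLATION: "not_a_real_term",
}

_VALUE_CODE_TAGS = {
    rpt.NOT_INTEGER: ("integer",),
    rpt.NOT_DECIMAL: ("decimal",),
    rpt.NOT_ISO_DATE: ("date",),
    rpt.NOT_ISO_TIME: ("time",),
    rpt.NOT_ISO_DATETIME: ("datetime",),
    rpt.OUT_OF_RANGE: ("latitude", "longitude"),
    rpt.BAD_URL: ("url",),
    rpt.BAD_EMAIL: ("email",),
    rpt.CV_VIOLATION: ("cv_term",),
    rpt.PATTERN_MISMATCH: ("pattern",),
}

_MISMATCH_CANDIDATES = ("???", "!!mismatch!!", "zz mismatch zz")


def _pattern_breaker(pattern: str) -> str | None:
    for cand in _MISMATCH_CANDIDATES:
        try:
            if re.fullmatch(pattern, cand) is None:
                return cand
        except re.error:  # pragma: no cover - template loading forbids this
            return None
    return None


def _value_targets(
    bundle: ProjectBundle, template: MetadataTemplate, code: str, used: set
) -> list[tuple[Entity, str]]:
    tags = _VALUE_CODE_TAGS[code]
    targets = []
    for ent in bundle.entities():
        try:
            spec = template.collection(ent.collection)
        except LookupError:  # pragma: no cover
            continue
        for fdef in spec.fields:
            if fdef.data_type not in tags or fdef.key == LINK_KEY:
                continue
            raw = ent.values.get(fdef.key, "")
            if not isinstance(raw, str) or not raw.strip():
                continue
            if (ent.id, fdef.key) in used:
                continue
            if code == rpt.PATTERN_MISMATCH and _pattern_breaker(fdef.pattern) is None:
                continue
            targets.append((ent, fdef.key))
    return targets


def _corrupt_value(ent: Entity, template: MetadataTemplate, key: str, code: str) -> None:
    if code == rpt.OUT_OF_RANGE:
        tag = template.collection(ent.collection).field(key).data_type
        ent.values[key] = "95.5000" if tag == "latitude" else "191.2500"
    elif code == rpt.PATTERN_MISMATCH:
        pattern = template.collection(ent.collection).field(key).pattern
        ent.values[key] = _pattern_breaker(pattern)
    else:
        ent.values[key] = _BAD_VALUES[code]


def inject_errors(
    bundle: ProjectBundle,
    error_mix: dict[str, int],
    seed: int = 0,
    template: MetadataTemplate | None = None,
) -> tuple[ProjectBundle, CorruptionLedger]:
    """Apply exactly the requested defects to a copy of the bundle.

    ``error_mix`` maps issue codes to counts.  Structural deletions
    (``no_samples``, ``missing_ep``) are applied first so every later
    defect lands on a surviving entity; each (entity, key) location is
    corrupted at most once.  An unsatisfiable request raises
    :class:`CorruptionError` and leaves nothing half-applied.
    """
    template = template or bundle.template
    mix = Counter()
    for code, count in error_mix.items():
        if code not in INJECTABLE_CODES:
            raise CorruptionError(f"no injector for issue code {code!r}")
        if count < 0:
            raise CorruptionError(f"negative count for {code!r}")
        if count:
            mix[code] = count
    # copy entities but share the (immutable) template
    b = ProjectBundle(
        template=bundle.template,
        project=copy.deepcopy(bundle.project),
        samples=copy.deepcopy(bundle.samples),
        libraries=copy.deepcopy(bundle.libraries),
        ep_blocks=copy.deepcopy(bundle.ep_blocks),
    )
    rng = random.Random(seed)
    used: set[tuple[str, str]] = set()
    entries: list[LedgerEntry] = []

    if mix.get(rpt.NO_SAMPLES):
        if mix[rpt.NO_SAMPLES] != 1:
            raise CorruptionError("no_samples can be injected at most once")
        if not b.samples:
            raise CorruptionError("bundle already has no samples")
        b.samples, b.libraries, b.ep_blocks = [], [], []
        entries.append(LedgerEntry(b.project.id, "project", None, rpt.NO_SAMPLES))

    if mix.get(rpt.MISSING_EP):
        eligible = [s for s in b.samples if b.ep_for(s.id)]
        if len(eligible) < mix[rpt.MISSING_EP]:
            raise CorruptionError(
                f"cannot remove {mix[rpt.MISSING_EP]} ep blocks: "
                f"only {len(eligible)} samples have one"
            )
        for sample in rng.sample(eligible, mix[rpt.MISSING_EP]):
            removed = b.ep_for(sample.id)
            b.ep_blocks = [e for e in b.ep_blocks if e not in removed]
            entries.append(LedgerEntry(sample.id, "sample", None, rpt.MISSING_EP))

    if mix.get(rpt.BROKEN_LINK):
        eligible = [
            lib for lib in b.libraries if (lib.id, LINK_KEY) not in used
        ]
        if len(eligible) < mix[rpt.BROKEN_LINK]:
            raise CorruptionError(
                f"cannot break {mix[rpt.BROKEN_LINK]} links: "
                f"only {len(eligible)} libraries available"
            )
        for lib in rng.sample(eligible, mix[rpt.BROKEN_LINK]):
            lib.values[LINK_KEY] = "no_such_sample"
            used.add((lib.id, LINK_KEY))
            entries.append(
                LedgerEntry(lib.id, lib.collection, LINK_KEY, rpt.BROKEN_LINK)
            )

    for code in sorted(_VALUE_CODE_TAGS):
        if not mix.get(code):
            continue
        targets = _value_targets(b, template, code, used)
        if len(targets) < mix[code]:
            raise CorruptionError(
                f"cannot inject {mix[code]} {code} defects: "
                f"only {len(targets)} eligible fields"
            )
        for ent, key in rng.sample(targets, mix[code]):
            _corrupt_value(ent, template, key, code)
            used.add((ent.id, key))
            entries.append(LedgerEntry(ent.id, ent.collection, key, code))

    if mix.get(rpt.MISSING_REQUIRED):
        targets = []
        for ent in b.entities():
            try:
                spec = template.collection(ent.collection)
            except LookupError:  # pragma: no cover
                continue
            for fdef in spec.fields:
                if not fdef.required or fdef.key == LINK_KEY:
                    continue
                raw = ent.values.get(fdef.key, "")
                if isinstance(raw, str) and raw.strip() and (ent.id, fdef.key) not in used:
                    targets.append((ent, fdef.key))
        if len(targets) < mix[rpt.MISSING_REQUIRED]:
            raise CorruptionError(
                f"cannot blank {mix[rpt.MISSING_REQUIRED]} required fields: "
                f"only {len(targets)} eligible"
            )
        for ent, key in rng.sample(targets, mix[rpt.MISSING_REQUIRED]):
            ent.values[key] = ""
            used.add((ent.id, key))
            entries.append(LedgerEntry(ent.id, ent.collection, key, rpt.MISSING_REQUIRED))

    if mix.get(rpt.UNKNOWN_KEY):
        pool = b.entities()
        for n in range(mix[rpt.UNKNOWN_KEY]):
            ent = rng.choice(pool)
            key = f"extra_key_{n}"
            while key in ent.values:  # pragma: no cover - extra_key_N is reserved
                key += "x"
            ent.values[key] = "unexpected value"
            entries.append(LedgerEntry(ent.id, ent.collection, key, rpt.UNKNOWN_KEY))

    ledger = CorruptionLedger(entries)
    if len(ledger.pairs()) != len(entries):  # pragma: no cover - by construction
        raise CorruptionError("duplicate ledger entries")
    return b, ledger


def random_corruption_trial(
    template: MetadataTemplate,
    seed: int,
    max_samples: int = 10,
    max_libraries: int = 4,
    max_defects: int = 6,
    codes: tuple[str, ...] = INJECTABLE_CODES,
) -> tuple[ProjectBundle, ProjectBundle, CorruptionLedger]:
    """One randomized generate-then-corrupt trial (for harnesses and tests).

    Bundle size and the defect mix are drawn from the given seed; code
    mixes that are infeasible for the drawn bundle (e.g. ``no_samples``
    together with sample-tier defects) are re-drawn deterministically.
    Returns (valid bundle, corrupted bundle, ledger).
    """
    rng = random.Random(seed)
    packages = [p.subtype for p in template.packages]
    bundle = make_valid_bundle(
        template,
        seed=rng.randrange(2**31),
        n_samples=rng.randint(1, max_samples),
        n_libraries_per_sample=rng.randint(0, max_libraries),
        package=rng.choice(packages),
    )
    n_defects = rng.randint(1, max_defects)
    for _ in range(1000):
        mix = Counter(rng.choice(codes) for _ in range(n_defects))
        try:
            corrupted, ledger = inject_errors(
                bundle, dict(mix), seed=rng.randrange(2**31)
            )
            return bundle, corrupted, ledger
        except CorruptionError:
            continue
    raise CorruptionError("could not draw a feasible defect mix")  # pragma: no cover
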