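"""Embedded entity–attribute–value store.

The storage model is a flat table of ``id | collection | key | value``
rows: any entity can carry arbitrary key-value pairs, and organizing
entities into named collections is what lets a template impose per-
collection contracts on top.  Values are raw strings throughout — typed
interpretation is the job of the validation layers, never the store.

Persistence is a 4-column TSV (UTF-8, header row) mirroring the schema
literally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class KVRecord:
    id: str
    collection: str
    key: str
    value: str


@dataclass
class Entity:
    """All records sharing an (id, collection) pair, as an ordered mapping.

    Single-valued keys map to ``str``; a key written multi-valued maps to
    a tuple of strings.
    """

    id: str
    collection: str
    values: dict[str, str | tuple[str, ...]] = field(default_factory=dict)

    def get(self, key: str, default: str = "") -> str:
        v = self.values.get(key, default)
        if isinstance(v, tuple):
            return v[0] if v else default
        return v

    def records(self) -> list[KVRecord]:
        out = []
        for key, v in self.values.items():
            for one in v if isinstance(v, tuple) else (v,):
                out.append(KVRecord(self.id, self.collection, key, one))
        return out


class _Absent:
    """Sentinel distinguishing a never-written triple from an empty string."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


ABSENT = _Absent()


class KVStore:
    """In-memory EAV store with deterministic listing order."""

    def __init__(self) -> None:
        # (id, collection, key) -> list of values (len 1 unless multi-valued)
        self._data: dict[tuple[str, str, str], list[str]] = {}

    def __len__(self) -> int:
        return sum(len(v) for v in self._data.values())

    def put(self, id: str, collection: str, key: str, value: str) -> None:
        """Write a value, replacing any prior value(s) for the triple."""
        if not id or not key:
            raise ValueError("entity id and key must be non-empty")
        self._data[(id, collection, key)] = [value]

    def add(self, id: str, collection: str, key: str, value: str) -> None:
        """Append a value to a multi-valued triple."""
        if not id or not key:
            raise ValueError("entity id and key must be non-empty")
        self._data.setdefault((id, collection, key), []).append(value)

    def get(self, id: str, collection: str, key: str):
        """Return the stored value, a tuple for multi-valued keys, or ABSENT."""
        vals = self._data.get((id, collection, key))
        if vals is None:
            return ABSENT
        if len(vals) == 1:
            return vals[0]
        return tuple(vals)

    def delete(self, id: str, collection: str, key: str) -> None:
        self._data.pop((id, collection, key), None)

    def records(self) -> list[KVRecord]:
        """Every record in insertion order (multi-values kept in write order)."""
        out = []
        for (id, coll, key), vals in self._data.items():
            for v in vals:
                out.append(KVRecord(id, coll, key, v))
        return out

    def collections(self) -> list[str]:
        return sorted({coll for (_, coll, _) in self._data})

    def entities(self, collection: str | None = None) -> list[Entity]:
        """Entities (optionally of one collection), sorted by id.

        Within an entity, keys keep their first-write order.
        """
        grouped: dict[tuple[str, str], Entity] = {}
        for (id, coll, key), vals in self._data.items():
            if collection is not None and coll != collection:
                continue
            ent = grouped.setdefault((coll, id), Entity(id=id, collection=coll))
            ent.values[key] = vals[0] if len(vals) == 1 else tuple(vals)
        return [grouped[k] for k in sorted(grouped, key=lambda k: (k[1], k[0]))]

    # -- persistence -------------------------------------------------------

    _COLUMNS = ("id", "collection", "key", "value")

    def dump(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(self._COLUMNS)
            for r in self.records():
                w.writerow([r.id, r.collection, r.key, r.value])

    @classmethod
    def load(cls, path: str | Path) -> "KVStore":
        store = cls()
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader, None)
            if header is None or tuple(header) != cls._COLUMNS:
                raise ValueError(
                    f"store file must start with header {'|'.join(cls._COLUMNS)}"
                )
            for row in reader:
                if not row:
                    continue
                if len(row) != 4:
                    raise ValueError(f"malformed store row: {row!r}")
                store.add(row[0], row[1], row[2], row[3])
        return store

    @classmethod
    def from_records(cls, records) -> "KVStore":
        store = cls()
        for r in records:
            store.add(r.id, r.collection, r.key, r.value)
        return store
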