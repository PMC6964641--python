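"""Canonical domain types, key normalization and the on-disk key/value encoding.

Everything downstream — the streaming ingest adapters, the sorted-chunk map
phase, the ordered store and the query executor — speaks in terms of the types
defined here:

* :class:`DatasetDescriptor` — identity of one dataset (ChEBI, UniProt,
  Ensembl, a taxonomy, a probe set, ...) inside a registry.
* :class:`EntryRecord` — one entry as read from a dataset file: an identifier,
  attributes (genomic coordinates, names, a reviewed flag, ...), outgoing
  cross-references and extra search keywords (gene symbols, species names).
* :class:`EntryPayload` — the merged value stored in the database for one
  (dataset, identifier) pair.

Search keys are case-insensitive: a term is normalized by trimming, collapsing
internal whitespace and upper-casing before it is ever compared or stored, while
the original spelling of an identifier is preserved inside its payload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

__all__ = [
    "RELATION_LABELS",
    "CanonicalKey",
    "DatasetDescriptor",
    "DatasetRegistry",
    "EntryPayload",
    "EntryRecord",
    "InvalidTermError",
    "OversizeError",
    "XRef",
    "decode_kv",
    "decode_value",
    "encode_key",
    "encode_kv",
    "encode_value",
    "entry_key",
    "merge_payload_lists",
    "merge_payloads",
    "normalize_key",
    "term_key",
]

#: Relation-labelled edge types usable as map targets, and the dataset whose
#: entries they point at.  ``taxchild`` links a taxonomy node to a direct child
#: taxon; ``transcript`` links a gene to one of its transcripts.
RELATION_LABELS: dict[str, str] = {
    "taxchild": "taxonomy",
    "transcript": "transcript",
}

#: Hard ceiling on one encoded value; a single key holding more than this is
#: almost certainly a modelling error (e.g. every entry sharing one keyword).
MAX_VALUE_BYTES = 8_000_000

Scalar = str | int | float | bool


class InvalidTermError(ValueError):
    """Raised for empty or whitespace-only search terms."""


class OversizeError(ValueError):
    """Raised when an encoded value exceeds :data:`MAX_VALUE_BYTES`."""


# ---------------------------------------------------------------------------
# key normalization


def normalize_key(term: str) -> str:
    """Return the canonical form of a search term.

    Leading/trailing whitespace is removed, internal whitespace runs collapse
    to a single space, and the result is upper-cased, so ``"202763_at"`` and
    ``"202763_AT"`` address the same database key.  Idempotent by construction.

    Raises :class:`InvalidTermError` for empty / whitespace-only input.
    """
    if not isinstance(term, str):
        raise InvalidTermError(f"search term must be a string, got {type(term).__name__}")
    folded = " ".join(term.split()).upper()
    if not folded:
        raise InvalidTermError("empty or whitespace-only search term")
    return folded


#: Alias used in signatures: a string already passed through normalize_key.
CanonicalKey = str


# ---------------------------------------------------------------------------
# datasets


@dataclass(frozen=True)
class DatasetDescriptor:
    """Identity of one registered dataset."""

    name: str
    numeric_id: int
    format: str = "TSV"

    FORMATS = ("TSV", "CSV", "JSON", "XML", "GFF3")

    def __post_init__(self) -> None:
        if not self.name or self.name != self.name.lower().strip():
            raise ValueError(f"dataset name must be a lowercase token: {self.name!r}")
        if self.format not in self.FORMATS:
            raise ValueError(f"unknown dataset format {self.format!r}")


class DatasetRegistry:
    """Ordered collection of datasets; numeric ids follow registration order.

    The registry also keeps the raw per-dataset configuration mapping (source
    paths, column specs) so a build can be driven entirely from one file.
    """

    def __init__(self) -> None:
        self._by_name: dict[str, DatasetDescriptor] = {}
        self._by_id: dict[int, DatasetDescriptor] = {}
        self.configs: dict[str, dict] = {}

    def register(self, name: str, format: str = "TSV", config: dict | None = None) -> DatasetDescriptor:
        if name in self._by_name:
            raise ValueError(f"dataset {name!r} already registered")
        if name in RELATION_LABELS and RELATION_LABELS[name] != name:
            raise ValueError(f"{name!r} is a reserved relation label")
        ds = DatasetDescriptor(name=name, numeric_id=len(self._by_name) + 1, format=format)
        self._by_name[name] = ds
        self._by_id[ds.numeric_id] = ds
        self.configs[name] = dict(config or {})
        return ds

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def get(self, name: str) -> DatasetDescriptor:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown dataset {name!r}; registered: {sorted(self._by_name)}") from None

    def by_id(self, numeric_id: int) -> DatasetDescriptor:
        return self._by_id[numeric_id]

    def is_map_target(self, name: str) -> bool:
        return name in self._by_name or name in RELATION_LABELS

    def snapshot(self) -> list[dict]:
        """JSON-able snapshot stored in the database metadata."""
        return [
            {"name": d.name, "numeric_id": d.numeric_id, "format": d.format}
            for d in self._by_name.values()
        ]

    @classmethod
    def from_snapshot(cls, snap: Iterable[Mapping]) -> "DatasetRegistry":
        reg = cls()
        for item in sorted(snap, key=lambda d: d["numeric_id"]):
            ds = DatasetDescriptor(item["name"], item["numeric_id"], item["format"])
            reg._by_name[ds.name] = ds
            reg._by_id[ds.numeric_id] = ds
            reg.configs[ds.name] = {}
        return reg


# ---------------------------------------------------------------------------
# records and payloads


@dataclass(frozen=True)
class XRef:
    """Directed cross-reference to an identifier in another dataset.

    ``target_dataset`` is either a registered dataset name or one of the
    relation labels in :data:`RELATION_LABELS`.  ``bidirectional`` is a
    build-time hint only (should the reverse edge be indexed too?); it is not
    part of the stored payload.
    """

    target_dataset: str
    target_id: str
    bidirectional: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if not self.target_id:
            raise ValueError("xref target_id must be non-empty")


@dataclass
class EntryRecord:
    """One dataset entry as emitted by an ingest adapter.

    A record may be *partial*: the merge machinery unions fragments for the
    same (dataset, identifier) pair, so an adapter is free to emit, say, a gene
    entry first and later a fragment adding one transcript cross-reference.
    ``stub=True`` marks such attach-only fragments (a taxonomy parent link, the
    gene side of a transcript edge); stubs never create searchable terms.
    """

    identifier: str
    dataset: str
    attributes: dict[str, Any] = field(default_factory=dict)
    xrefs: list[XRef] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)
    stub: bool = False

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ValueError("entry identifier must be non-empty")
        start, end = self.attributes.get("start"), self.attributes.get("end")
        if start is not None and end is not None and not (1 <= start <= end):
            raise ValueError(
                f"invalid coordinates for {self.identifier}: start={start} end={end}"
            )
        strand = self.attributes.get("strand")
        if strand is not None and strand not in ("+", "-"):
            raise ValueError(f"invalid strand {strand!r} for {self.identifier}")


@dataclass
class EntryPayload:
    """Merged value stored under a canonical key for one (dataset, identifier).

    ``primary`` marks payloads that stem from the dataset's own records; a
    reverse-indexed cross-reference may create a payload for a target that was
    never actually ingested, and such bare stubs must stay invisible to lookup
    and mapping.
    """

    dataset_id: int
    identifier: str
    attributes: dict[str, Any] = field(default_factory=dict)
    xrefs: list[tuple[str, str]] = field(default_factory=list)
    primary: bool = True

    @property
    def identity(self) -> tuple[int, str]:
        """Merge identity: dataset plus case-folded identifier."""
        return (self.dataset_id, self.identifier.upper())

    def to_obj(self) -> dict:
        return {
            "d": self.dataset_id,
            "i": self.identifier,
            "a": self.attributes,
            "x": [list(x) for x in self.xrefs],
            "p": 1 if self.primary else 0,
        }

    @classmethod
    def from_obj(cls, obj: Mapping) -> "EntryPayload":
        return cls(
            dataset_id=obj["d"],
            identifier=obj["i"],
            attributes=dict(obj["a"]),
            xrefs=[(x[0], x[1]) for x in obj["x"]],
            primary=bool(obj.get("p", 1)),
        )


def payload_from_record(record: EntryRecord, registry: DatasetRegistry) -> EntryPayload:
    ds = registry.get(record.dataset)
    return EntryPayload(
        dataset_id=ds.numeric_id,
        identifier=record.identifier,
        attributes=dict(record.attributes),
        xrefs=[(x.target_dataset, x.target_id) for x in record.xrefs],
    )


# ---------------------------------------------------------------------------
# payload merge algebra
#
# Merging must be commutative and associative so that the global result is
# independent of how records were partitioned into chunks and of the order in
# which chunks were merged (the map phase runs concurrently).  Hence:
#   * xref unions are canonically sorted, not first-seen ordered;
#   * a scalar attribute conflict resolves to the JSON-greater value (a max
#     under a total order), counted in `conflicts` when a counter is passed.


def _scalar_rank(value: Any) -> tuple[str, str]:
    return (type(value).__name__, json.dumps(value, sort_keys=True))


def merge_payloads(a: EntryPayload, b: EntryPayload, conflicts: list | None = None) -> EntryPayload:
    """Merge two fragments with the same identity into one payload."""
    if a.identity != b.identity:
        raise ValueError(f"cannot merge payloads {a.identity} and {b.identity}")
    # prefer the spelling of the richer fragment (a bare reverse-xref stub has
    # no attributes and should not override the entry's own casing)
    if bool(a.attributes) == bool(b.attributes):
        ident = min(a.identifier, b.identifier)
    else:
        ident = a.identifier if a.attributes else b.identifier
    attrs: dict[str, Any] = dict(a.attributes)
    for name, value in b.attributes.items():
        if name not in attrs:
            attrs[name] = value
        elif _scalar_rank(attrs[name]) == _scalar_rank(value):
            pass  # identical (type-aware: True vs 1 is a conflict, not a match)
        elif isinstance(attrs[name], list) and isinstance(value, list):
            # conflicting lists: canonical rank-deduplicated union, so the
            # result is independent of merge order
            union = {}
            for v in list(attrs[name]) + list(value):
                union.setdefault(_scalar_rank(v), v)
            attrs[name] = [union[r] for r in sorted(union)]
        else:
            if conflicts is not None:
                conflicts.append((ident, name))
            attrs[name] = max(attrs[name], value, key=_scalar_rank)
    xrefs = sorted(set(a.xrefs) | set(b.xrefs), key=lambda x: (x[0], x[1].upper(), x[1]))
    return EntryPayload(a.dataset_id, ident, attrs, xrefs, primary=a.primary or b.primary)


def merge_payload_lists(
    a: Iterable[EntryPayload], b: Iterable[EntryPayload] = (), conflicts: list | None = None
) -> list[EntryPayload]:
    """Union two payload lists, merging fragments that share an identity.

    The result is sorted by identity, which makes the operation commutative
    and associative on content.
    """
    merged: dict[tuple[int, str], EntryPayload] = {}
    for p in list(a) + list(b):
        key = p.identity
        merged[key] = merge_payloads(merged[key], p, conflicts) if key in merged else p
    return [merged[k] for k in sorted(merged)]


# ---------------------------------------------------------------------------
# storage keys and the on-disk encoding
#
# Two keyspaces are multiplexed through a one-character prefix (unit separator
# as the field delimiter, which sorts below any printable character):
#   e<US><dddd><US><NORMALIZED-ID>  -> [EntryPayload]          (entry rows)
#   t<US><NORMALIZED-TERM>          -> [reference stubs]       (term rows)
# Term rows hold bare (dataset, identifier) stubs; the full payload lives once
# under the entry row, keeping the term index small.

_SEP = "\x1f"
ENTRY_PREFIX = "e" + _SEP
TERM_PREFIX = "t" + _SEP


def term_key(term: str) -> str:
    return TERM_PREFIX + normalize_key(term)


def entry_key(dataset_id: int, identifier: str) -> str:
    return f"{ENTRY_PREFIX}{dataset_id:04d}{_SEP}{normalize_key(identifier)}"


def split_term_key(key: str) -> str:
    return key[len(TERM_PREFIX):]


def encode_key(key: str) -> bytes:
    """UTF-8 encode a storage key; byte order equals code-point order."""
    return key.encode("utf-8")


def decode_key(data: bytes) -> str:
    return data.decode("utf-8")


def encode_value(payloads: list[EntryPayload]) -> bytes:
    """Deterministic encoding: same payload list, same bytes, any process."""
    raw = json.dumps(
        [p.to_obj() for p in payloads], sort_keys=True, separators=(",", ":"), ensure_ascii=True
    ).encode("utf-8")
    if len(raw) > MAX_VALUE_BYTES:
        raise OversizeError(f"encoded value is {len(raw)} bytes (limit {MAX_VALUE_BYTES})")
    return raw


def decode_value(data: bytes) -> list[EntryPayload]:
    return [EntryPayload.from_obj(obj) for obj in json.loads(data.decode("utf-8"))]


def encode_kv(key: str, payloads: list[EntryPayload]) -> tuple[bytes, bytes]:
    if not payloads:
        raise ValueError("payload list must be non-empty")
    return encode_key(key), encode_value(payloads)


def decode_kv(key_bytes: bytes, value_bytes: bytes) -> tuple[str, list[EntryPayload]]:
    return decode_key(key_bytes), decode_value(value_bytes)
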