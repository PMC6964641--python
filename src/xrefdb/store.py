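"""The reduce-phase sink and query-time source: an embedded ordered key-value
store with batch insert of pre-sorted data, exact lookup and paged prefix scan.

The store contract only requires ordered semantics (ascending key iteration,
prefix range scans, O(log n) point reads), so the engine is pluggable:

* :class:`FileBackend` (default) — an SSTable-style layout: one append-only
  data file of ``key TAB value`` lines written in key order, with a sparse
  in-memory index of every Nth key's byte offset, persisted next to the data.
  Point reads binary-search the sparse index then scan at most one block.
* :class:`MemoryBackend` — a bisect-backed in-process ordered map, used by
  tests and tiny builds.

Two keyspaces are multiplexed by a one-character key prefix (see
:mod:`xrefdb.model`): term rows map a normalized search term to lightweight
(dataset, identifier) references; entry rows hold the single merged payload of
one (dataset, identifier).  ``lookup`` resolves a term through both.
"""

from __future__ import annotations

import base64
import bisect
import json
import os
import time
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from . import model
from .model import (
    DatasetRegistry,
    EntryPayload,
    decode_value,
    encode_value,
    normalize_key,
)

__all__ = [
    "OrderingError",
    "Page",
    "StateError",
    "StoreHandle",
    "TokenError",
    "batch_insert",
    "lookup",
    "open_store",
    "prefix_search",
]

META_FILE = "meta.json"
DATA_FILE = "data.kvt"
INDEX_FILE = "index.json"
FORMAT_VERSION = 1
INDEX_EVERY = 64
DEFAULT_PAGE_SIZE = 200


class OrderingError(ValueError):
    """Batch insert received keys that are not strictly ascending."""


class StateError(RuntimeError):
    """Operation not valid in the store's current mode."""


class TokenError(ValueError):
    """Malformed continuation token."""


@dataclass
class Page:
    """One page of results plus an opaque continuation token (None = last)."""

    items: list
    next_token: str | None = None


# ---------------------------------------------------------------------------
# backends


class MemoryBackend:
    """Ordered map over parallel sorted lists; for tests and tiny stores."""

    def __init__(self) -> None:
        self._keys: list[str] = []
        self._values: list[bytes] = []

    def write_sorted(self, pairs: Iterable[tuple[str, bytes]]) -> int:
        prev = None
        for key, value in pairs:
            if prev is not None and key <= prev:
                raise OrderingError(f"key {key!r} not after {prev!r}")
            prev = key
            self._keys.append(key)
            self._values.append(value)
        return len(self._keys)

    def get(self, key: str) -> bytes | None:
        i = bisect.bisect_left(self._keys, key)
        if i < len(self._keys) and self._keys[i] == key:
            return self._values[i]
        return None

    def scan_from(self, start: str) -> Iterator[tuple[str, bytes]]:
        i = bisect.bisect_left(self._keys, start)
        for j in range(i, len(self._keys)):
            yield self._keys[j], self._values[j]

    def close(self) -> None:
        pass


class FileBackend:
    """SSTable-style single-file ordered store with a sparse key index."""

    def __init__(self, directory: str):
        self.directory = directory
        self._fh = None
        self._index_keys: list[str] = []
        self._index_offsets: list[int] = []

    @property
    def data_path(self) -> str:
        return os.path.join(self.directory, DATA_FILE)

    def write_sorted(self, pairs: Iterable[tuple[str, bytes]]) -> int:
        prev = None
        count = 0
        index_keys: list[str] = []
        index_offsets: list[int] = []
        with open(self.data_path, "wb") as fh:
            offset = 0
            for key, value in pairs:
                if prev is not None and key <= prev:
                    raise OrderingError(f"key {key!r} not after {prev!r}")
                prev = key
                if count % INDEX_EVERY == 0:
                    index_keys.append(key)
                    index_offsets.append(offset)
                line = key.encode("utf-8") + b"\t" + value + b"\n"
                fh.write(line)
                offset += len(line)
                count += 1
        with open(os.path.join(self.directory, INDEX_FILE), "w", encoding="utf-8") as fh:
            json.dump({"keys": index_keys, "offsets": index_offsets}, fh)
        return count

    def _open(self) -> None:
        if self._fh is None:
            self._fh = open(self.data_path, "rb")
            with open(os.path.join(self.directory, INDEX_FILE), encoding="utf-8") as fh:
                idx = json.load(fh)
            self._index_keys = idx["keys"]
            self._index_offsets = idx["offsets"]

    def _seek_floor(self, key: str) -> None:
        i = bisect.bisect_right(self._index_keys, key) - 1
        self._fh.seek(self._index_offsets[i] if i >= 0 else 0)

    def get(self, key: str) -> bytes | None:
        self._open()
        if not self._index_keys:
            return None
        self._seek_floor(key)
        target = key.encode("utf-8")
        for line in self._fh:
            k, _, v = line.rstrip(b"\n").partition(b"\t")
            if k == target:
                return v
            if k > target:
                return None
        return None

    def scan_from(self, start: str) -> Iterator[tuple[str, bytes]]:
        # a dedicated handle per scan, so point reads may interleave safely
        self._open()
        if not self._index_keys:
            return
        i = bisect.bisect_right(self._index_keys, start) - 1
        with open(self.data_path, "rb") as fh:
            fh.seek(self._index_offsets[i] if i >= 0 else 0)
            for line in fh:
                k, _, v = line.rstrip(b"\n").partition(b"\t")
                ks = k.decode("utf-8")
                if ks < start:
                    continue
                yield ks, v

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None


# ---------------------------------------------------------------------------
# store handle


@dataclass
class StoreHandle:
    directory: str
    mode: str  # "build" | "read"
    registry: DatasetRegistry
    entry_count: int = 0
    backend: object = None
    counters: dict = field(default_factory=dict)

    def close(self) -> None:
        if self.backend is not None:
            self.backend.close()


def create_store(directory: str, registry: DatasetRegistry, backend: str = "file") -> StoreHandle:
    """Open a new store in build mode (the directory is created)."""
    os.makedirs(directory, exist_ok=True)
    be = FileBackend(directory) if backend == "file" else MemoryBackend()
    return StoreHandle(directory=directory, mode="build", registry=registry, backend=be)


def batch_insert(store: StoreHandle, stream: Iterable[tuple[str, list[EntryPayload]]]) -> StoreHandle:
    """Persist a strictly ascending (key, payload-list) stream and finalize.

    The stream is exactly what :func:`xrefdb.chunks.global_merge` produces.
    Term rows are counted as entries; the store flips to read mode on success.
    """
    if store.mode != "build":
        raise StateError("batch_insert requires a store in build mode")

    term_rows = 0

    def encoded() -> Iterator[tuple[str, bytes]]:
        nonlocal term_rows
        for key, payloads in stream:
            if key.startswith(model.TERM_PREFIX):
                term_rows += 1
            yield key, encode_value(payloads)

    total = store.backend.write_sorted(encoded())
    store.entry_count = term_rows
    store.counters["rows_written"] = total
    _write_meta(store)
    store.mode = "read"
    return store


def _write_meta(store: StoreHandle) -> None:
    meta = {
        "format_version": FORMAT_VERSION,
        "datasets": store.registry.snapshot(),
        "entry_count": store.entry_count,
        "rows_written": store.counters.get("rows_written", 0),
        "built_at": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
    }
    with open(os.path.join(store.directory, META_FILE), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)


def open_store(directory: str) -> StoreHandle:
    """Open an existing store read-only."""
    meta_path = os.path.join(directory, META_FILE)
    if not os.path.exists(meta_path):
        raise StateError(f"no store at {directory!r}")
    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != FORMAT_VERSION:
        raise StateError(f"unsupported store format {meta.get('format_version')}")
    registry = DatasetRegistry.from_snapshot(meta["datasets"])
    return StoreHandle(
        directory=directory,
        mode="read",
        registry=registry,
        entry_count=meta["entry_count"],
        backend=FileBackend(directory),
    )


# ---------------------------------------------------------------------------
# reads


def _require_read(store: StoreHandle) -> None:
    if store.mode != "read":
        raise StateError("store is not open for reading")


def get_entry(store: StoreHandle, dataset_id: int, identifier: str) -> EntryPayload | None:
    """Fetch one entry row by dataset and identifier."""
    _require_read(store)
    raw = store.backend.get(model.entry_key(dataset_id, identifier))
    if raw is None:
        return None
    payloads = decode_value(raw)
    return payloads[0] if payloads else None


def lookup(store: StoreHandle, term: str) -> list[EntryPayload]:
    """All entry payloads indexed under a term (identifier or keyword)."""
    _require_read(store)
    raw = store.backend.get(model.term_key(term))
    if raw is None:
        return []
    out: list[EntryPayload] = []
    for stub in decode_value(raw):
        entry = get_entry(store, stub.dataset_id, stub.identifier)
        out.append(entry if entry is not None else stub)
    return out


def dump(store: StoreHandle) -> Iterator[tuple[str, bytes]]:
    """Every (key, value-bytes) pair in ascending key order."""
    _require_read(store)
    yield from store.backend.scan_from("")


def iter_term_rows(store: StoreHandle) -> Iterator[tuple[str, list[EntryPayload]]]:
    """Every (normalized term, reference stubs) pair in ascending term order."""
    _require_read(store)
    for key, value in store.backend.scan_from(model.TERM_PREFIX):
        if not key.startswith(model.TERM_PREFIX):
            break
        yield model.split_term_key(key), decode_value(value)


def _encode_token(parts: tuple) -> str:
    return base64.urlsafe_b64encode(json.dumps(list(parts)).encode()).decode()


def _decode_token(token: str, arity: int) -> tuple:
    try:
        parts = json.loads(base64.urlsafe_b64decode(token.encode()).decode())
        if not isinstance(parts, list) or len(parts) != arity:
            raise ValueError(parts)
        return tuple(parts)
    except Exception as exc:
        raise TokenError(f"invalid continuation token {token!r}") from exc


def prefix_search(
    store: StoreHandle,
    prefix: str,
    page_size: int = DEFAULT_PAGE_SIZE,
    token: str | None = None,
) -> Page:
    """Terms starting with the normalized prefix, expanded to their entries.

    Items are ``(term, dataset_name, identifier)`` triples in ascending
    (term, dataset, identifier) order; paging is stable and duplicate-free.
    """
    _require_read(store)
    if page_size < 1:
        raise ValueError("page_size must be >= 1")
    norm = normalize_key(prefix)
    after: tuple | None = _decode_token(token, 3) if token is not None else None
    items: list[tuple[str, str, str]] = []
    start_term = after[0] if after is not None else norm
    for term, stubs in _scan_terms_from(store, start_term):
        if not term.startswith(norm):
            break
        triples = sorted(
            (term, store.registry.by_id(s.dataset_id).name, s.identifier) for s in stubs
        )
        for triple in triples:
            if after is not None and triple <= after:
                continue
            items.append(triple)
            if len(items) > page_size:
                return Page(items=items[:page_size], next_token=_encode_token(items[page_size - 1]))
    return Page(items=items, next_token=None)


def _scan_terms_from(store: StoreHandle, term: str) -> Iterator[tuple[str, list[EntryPayload]]]:
    for key, value in store.backend.scan_from(model.TERM_PREFIX + term):
        if not key.startswith(model.TERM_PREFIX):
            break
        yield model.split_term_key(key), decode_value(value)
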