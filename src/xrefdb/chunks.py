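"""Sorted-chunk machinery: the map phase of the build.

Incoming ``(canonical key, payload)`` pairs are buffered in memory; when the
buffer reaches its configured size it is sorted, same-key payloads are merged
and the run is spilled to disk as a *chunk file*.  While ingestion continues,
idle workers recursively merge chunk files of the same generation ``fan_in`` at
a time.  When ingestion finishes, all surviving chunks are merged globally in
one streaming pass — a patience-sort style k-way merge that repeatedly takes
the minimum head across all runs via a tournament heap — yielding every key
exactly once in ascending order with fully merged payload lists.

Chunk files are line-oriented and self-describing: a JSON header line
(format version, record count, min/max key) followed by one
``key<TAB>payload-json`` line per record.  Keys are canonical (whitespace
collapsed), so the TAB framing is safe.
"""

from __future__ import annotations

import heapq
import json
import os
import uuid
from concurrent.futures import Future, ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Iterator

from .model import EntryPayload, merge_payload_lists

__all__ = [
    "ChunkCorruptionError",
    "ChunkFile",
    "ChunkManager",
    "MergePlan",
    "global_merge",
    "merge_chunks",
    "read_chunk",
    "spill_chunk",
]

CHUNK_FORMAT_VERSION = 1


class ChunkCorruptionError(RuntimeError):
    """A chunk file is unreadable or violates its sortedness contract."""


@dataclass
class ChunkFile:
    path: str
    record_count: int
    min_key: str
    max_key: str
    generation: int = 0


@dataclass
class MergePlan:
    """Tuning for the recursive merge: ``fan_in`` chunks per merge, merged as
    soon as that many share a generation, on ``worker_count`` threads."""

    fan_in: int = 8
    worker_count: int = 1

    def __post_init__(self) -> None:
        if self.fan_in < 2:
            raise ValueError("fan_in must be >= 2")
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")


# ---------------------------------------------------------------------------
# chunk file i/o

Pair = tuple[str, EntryPayload]
Row = tuple[str, list[EntryPayload]]


def _write_chunk(path: str, rows: Iterable[Row], record_count: int, min_key: str, max_key: str) -> None:
    tmp = path + ".tmp"
    try:
        with open(tmp, "w", encoding="utf-8") as fh:
            header = {
                "version": CHUNK_FORMAT_VERSION,
                "records": record_count,
                "min": min_key,
                "max": max_key,
            }
            fh.write(json.dumps(header, sort_keys=True) + "\n")
            for key, payloads in rows:
                fh.write(key)
                fh.write("\t")
                fh.write(json.dumps([p.to_obj() for p in payloads], sort_keys=True, separators=(",", ":")))
                fh.write("\n")
        os.replace(tmp, path)
    except OSError:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def read_chunk(chunk: ChunkFile) -> Iterator[Row]:
    """Stream a chunk's rows, verifying the strict key ordering contract."""
    with open(chunk.path, encoding="utf-8") as fh:
        header_line = fh.readline()
        try:
            header = json.loads(header_line)
        except json.JSONDecodeError as exc:
            raise ChunkCorruptionError(f"{chunk.path}: bad header") from exc
        if header.get("version") != CHUNK_FORMAT_VERSION:
            raise ChunkCorruptionError(f"{chunk.path}: unsupported version {header.get('version')}")
        prev: str | None = None
        for line in fh:
            key, _, raw = line.rstrip("\n").partition("\t")
            if prev is not None and key <= prev:
                raise ChunkCorruptionError(
                    f"{chunk.path}: keys out of order ({prev!r} then {key!r})"
                )
            prev = key
            yield key, [EntryPayload.from_obj(o) for o in json.loads(raw)]


def spill_chunk(buffer: list[Pair], directory: str, generation: int = 0) -> ChunkFile:
    """Sort a buffer, merge duplicate keys and write it out as one chunk."""
    if not buffer:
        raise ValueError("cannot spill an empty buffer")
    buffer = sorted(buffer, key=lambda kv: kv[0])
    rows: list[Row] = []
    for key, payload in buffer:
        if rows and rows[-1][0] == key:
            rows[-1][1].append(payload)
        else:
            rows.append((key, [payload]))
    merged: list[Row] = [(k, merge_payload_lists(ps)) for k, ps in rows]
    path = os.path.join(directory, f"chunk-g{generation}-{uuid.uuid4().hex}.run")
    _write_chunk(path, merged, len(merged), merged[0][0], merged[-1][0])
    return ChunkFile(path, len(merged), merged[0][0], merged[-1][0], generation)


# ---------------------------------------------------------------------------
# k-way merge


def _merged_rows(chunks: list[ChunkFile]) -> Iterator[Row]:
    """Tournament-heap merge of sorted runs, combining same-key rows.

    Memory is bounded by one row per input run (the run heads), independent of
    total record count.
    """
    streams = [read_chunk(c) for c in chunks]
    heads = heapq.merge(*streams, key=lambda row: row[0])
    current_key: str | None = None
    current: list[EntryPayload] = []
    for key, payloads in heads:
        if key == current_key:
            current = merge_payload_lists(current, payloads)
        else:
            if current_key is not None:
                yield current_key, current
            current_key, current = key, payloads
    if current_key is not None:
        yield current_key, current


def merge_chunks(chunks: list[ChunkFile], directory: str) -> ChunkFile:
    """Merge sorted chunks into a single chunk; inputs are deleted on success."""
    if not chunks:
        raise ValueError("nothing to merge")
    generation = max(c.generation for c in chunks) + 1
    path = os.path.join(directory, f"chunk-g{generation}-{uuid.uuid4().hex}.run")
    tmp_rows: list[Row] = []
    count = 0
    min_key = max_key = None
    # stream to disk: write rows as they fall out of the heap
    tmp = path + ".tmp"
    try:
        with open(tmp, "w", encoding="utf-8") as fh:
            fh.write("\n")  # header placeholder, fixed width not needed: rewrite below
            for key, payloads in _merged_rows(chunks):
                if min_key is None:
                    min_key = key
                max_key = key
                count += 1
                fh.write(key)
                fh.write("\t")
                fh.write(json.dumps([p.to_obj() for p in payloads], sort_keys=True, separators=(",", ":")))
                fh.write("\n")
        # prepend the real header
        header = json.dumps(
            {"version": CHUNK_FORMAT_VERSION, "records": count, "min": min_key or "", "max": max_key or ""},
            sort_keys=True,
        )
        final_tmp = path + ".tmp2"
        with open(tmp, encoding="utf-8") as src, open(final_tmp, "w", encoding="utf-8") as dst:
            src.readline()
            dst.write(header + "\n")
            for line in src:
                dst.write(line)
        os.replace(final_tmp, path)
        os.remove(tmp)
    except Exception:
        for p in (tmp, path + ".tmp2", path):
            if os.path.exists(p):
                os.remove(p)
        raise
    for c in chunks:
        os.remove(c.path)
    return ChunkFile(path, count, min_key or "", max_key or "", generation)


def global_merge(chunks: list[ChunkFile]) -> Iterator[Row]:
    """Final reduce-phase stream: every key exactly once, strictly ascending,
    payload lists merged and deduplicated across all chunks."""
    if not chunks:
        return iter(())
    return _merged_rows(chunks)


# ---------------------------------------------------------------------------
# the map-phase driver


class ChunkManager:
    """Buffers pairs, spills sorted chunks, and merges them in the background.

    ``add`` never holds more than ``buffer_size`` records in memory; the peak
    is tracked in ``peak_buffered_records``.  With ``worker_count > 1`` merges
    run on a thread pool concurrently with ingestion; correctness does not
    depend on scheduling because payload merging is commutative/associative.
    """

    def __init__(
        self,
        directory: str,
        buffer_size: int = 100_000,
        plan: MergePlan | None = None,
    ) -> None:
        if buffer_size < 1:
            raise ValueError("buffer_size must be >= 1")
        os.makedirs(directory, exist_ok=True)
        self.directory = directory
        self.buffer_size = buffer_size
        self.plan = plan or MergePlan()
        self._buffer: list[Pair] = []
        self._chunks: list[ChunkFile] = []
        self._pending: list[Future] = []
        self._pool = (
            ThreadPoolExecutor(max_workers=self.plan.worker_count)
            if self.plan.worker_count > 1
            else None
        )
        self.peak_buffered_records = 0
        self.chunks_spilled = 0
        self.merges_done = 0

    # -- map side ----------------------------------------------------------
    def add(self, key: str, payload: EntryPayload) -> None:
        self._buffer.append((key, payload))
        if len(self._buffer) > self.peak_buffered_records:
            self.peak_buffered_records = len(self._buffer)
        if len(self._buffer) >= self.buffer_size:
            self.flush()

    def flush(self) -> None:
        if not self._buffer:
            return
        chunk = spill_chunk(self._buffer, self.directory)
        self._buffer = []
        self.chunks_spilled += 1
        self._chunks.append(chunk)
        self._maybe_merge()

    # -- background merging ------------------------------------------------
    def _mergeable_group(self) -> list[ChunkFile] | None:
        by_gen: dict[int, list[ChunkFile]] = {}
        for c in self._chunks:
            by_gen.setdefault(c.generation, []).append(c)
        for gen in sorted(by_gen):
            if len(by_gen[gen]) >= self.plan.fan_in:
                return by_gen[gen][: self.plan.fan_in]
        return None

    def _maybe_merge(self) -> None:
        group = self._mergeable_group()
        if group is None:
            return
        for c in group:
            self._chunks.remove(c)
        if self._pool is not None:
            self._pending.append(self._pool.submit(merge_chunks, group, self.directory))
            self._harvest(block=False)
        else:
            self._chunks.append(merge_chunks(group, self.directory))
            self.merges_done += 1
            self._maybe_merge()

    def _harvest(self, block: bool) -> None:
        still: list[Future] = []
        for fut in self._pending:
            if fut.done() or block:
                self._chunks.append(fut.result())
                self.merges_done += 1
            else:
                still.append(fut)
        self._pending = still
        if block and self._mergeable_group() is not None:
            self._maybe_merge()
            self._harvest(block=True)

    # -- reduce side -------------------------------------------------------
    def finalize(self) -> list[ChunkFile]:
        """Spill any remainder, wait for background merges, return all chunks."""
        self.flush()
        if self._pool is not None:
            self._harvest(block=True)
            self._pool.shutdown(wait=True)
            self._pool = None
        return list(self._chunks)

    def stream(self) -> Iterator[Row]:
        """Finalize and return the globally merged key stream."""
        return global_merge(self.finalize())
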