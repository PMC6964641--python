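"""Streaming adapters turning dataset files into :class:`~xrefdb.model.EntryRecord`s.

Each adapter consumes a byte stream (optionally gzip-compressed — detected from
the magic bytes, decompressed on the fly, never written to disk) and yields one
record per entry with bounded memory: TSV/CSV line by line, JSON either as
JSON-lines or as an incrementally decoded top-level array, XML through
``iterparse`` with processed elements released, GFF3 line by line.

Malformed records are skipped and counted; a stream whose malformed fraction
exceeds ``ColumnSpec.max_error_fraction`` raises :class:`FormatError` once it
is exhausted.
"""

from __future__ import annotations

import csv
import gzip
import io
import json
import urllib.parse
from dataclasses import dataclass, field
from typing import Any, BinaryIO, Iterator
from xml.etree import ElementTree

from .model import EntryRecord, XRef

__all__ = [
    "ColumnSpec",
    "FormatError",
    "StreamStats",
    "XrefRule",
    "ingest_gff3",
    "ingest_json",
    "ingest_tsv",
    "ingest_xml",
    "open_stream",
]


class FormatError(ValueError):
    """Stream is not in the expected format (or too many malformed records)."""


@dataclass
class StreamStats:
    """Counters filled in while a stream is consumed."""

    records_emitted: int = 0
    records_skipped: int = 0
    bytes_consumed: int = 0
    peak_buffered_records: int = 0


@dataclass(frozen=True)
class XrefRule:
    """How one source field maps to cross-references.

    For tabular/JSON sources ``source`` names the column or dotted field whose
    value(s) become target identifiers of dataset ``target``.  For XML sources
    ``source`` names the child element tag; a dbReference-style element carries
    its target dataset in an attribute, declared via ``type_attr`` plus a
    ``targets`` mapping from that attribute's values to dataset names (elements
    with unmapped types are ignored).
    """

    source: str | int
    target: str | None = None
    id_attr: str | None = None
    type_attr: str | None = None
    targets: dict[str, str] | None = field(default=None, hash=False)
    bidirectional: bool = True


@dataclass
class ColumnSpec:
    """Declarative mapping from one dataset's format to entry fields.

    Sources are column indices (0-based) for TSV/CSV, dotted paths for JSON,
    and slash paths for XML (``@attr`` reads an attribute of the element,
    ``child@attr`` of a child, a trailing ``[]`` collects all matches into a
    list, ``*`` matches any child tag).
    """

    identifier: str | int
    attributes: dict[str, str | int] = field(default_factory=dict)
    attr_types: dict[str, str] = field(default_factory=dict)  # int|float|bool|str
    xrefs: list[XrefRule] = field(default_factory=list)
    keywords: list[str | int] = field(default_factory=list)
    header: bool = False
    delimiter: str = "\t"
    list_sep: str | None = None
    max_error_fraction: float = 0.01
    record_path: str | None = None  # JSON: dotted path to the record array
    record_tag: str | None = None  # XML: repeating record element
    parent_relation: tuple[str, str] | None = None  # (source, relation label)


# ---------------------------------------------------------------------------
# stream plumbing


class _CountingReader(io.RawIOBase):
    """Counts compressed bytes as they leave the underlying stream."""

    def __init__(self, raw: BinaryIO, stats: StreamStats):
        self._raw = raw
        self._stats = stats

    def readable(self) -> bool:  # pragma: no cover - io protocol
        return True

    def readinto(self, b) -> int:
        data = self._raw.read(len(b))
        n = len(data)
        b[:n] = data
        self._stats.bytes_consumed += n
        return n


def open_stream(source, stats: StreamStats | None = None) -> BinaryIO:
    """Return a binary reader over *source* (path or file-like), gunzipping
    transparently when the gzip magic bytes are present."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        raw: BinaryIO = open(source, "rb")
    else:
        raw = source
    if stats is not None:
        raw = io.BufferedReader(_CountingReader(raw, stats))
    elif not isinstance(raw, io.BufferedReader):
        raw = io.BufferedReader(raw)
    try:
        magic = raw.peek(2)[:2]
    except Exception as exc:  # unreadable stream
        raise OSError(f"cannot read input stream: {exc}") from exc
    if magic == b"\x1f\x8b":
        return io.BufferedReader(gzip.GzipFile(fileobj=raw))  # type: ignore[arg-type]
    return raw


def _coerce(value: str, kind: str | None):
    if kind is None or kind == "str":
        return value
    if kind == "int":
        return int(value)
    if kind == "float":
        return float(value)
    if kind == "bool":
        return value.strip().lower() in ("1", "true", "yes", "y")
    raise ValueError(f"unknown attribute type {kind!r}")


def _check_error_budget(stats: StreamStats, spec: ColumnSpec) -> None:
    total = stats.records_emitted + stats.records_skipped
    if total and stats.records_skipped / total > spec.max_error_fraction:
        raise FormatError(
            f"{stats.records_skipped}/{total} malformed records exceeds the "
            f"allowed fraction {spec.max_error_fraction}"
        )


def _split_values(value: str, spec: ColumnSpec) -> list[str]:
    if spec.list_sep and spec.list_sep in value:
        return [v for v in (s.strip() for s in value.split(spec.list_sep)) if v]
    return [value] if value else []


# ---------------------------------------------------------------------------
# TSV / CSV


def ingest_tsv(stream, spec: ColumnSpec, stats: StreamStats | None = None) -> Iterator[EntryRecord]:
    """Yield one record per data line of a (possibly gzipped) delimited file."""
    stats = stats if stats is not None else StreamStats()
    reader = open_stream(stream, stats)
    text = io.TextIOWrapper(reader, encoding="utf-8", newline="")
    rows = csv.reader(text, delimiter=spec.delimiter)
    first = spec.header
    for row in rows:
        if first:
            first = False
            continue
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        try:
            record = _record_from_row(row, spec)
        except (IndexError, ValueError):
            stats.records_skipped += 1
            continue
        stats.records_emitted += 1
        yield record
    _check_error_budget(stats, spec)


def _record_from_row(row: list[str], spec: ColumnSpec) -> EntryRecord:
    ident = row[int(spec.identifier)].strip()
    if not ident:
        raise ValueError("missing identifier")
    attrs: dict[str, Any] = {}
    for name, col in spec.attributes.items():
        value = row[int(col)].strip()
        if not value:
            continue
        values = _split_values(value, spec)
        kind = spec.attr_types.get(name)
        coerced = [_coerce(v, kind) for v in values]
        attrs[name] = coerced if len(coerced) > 1 else coerced[0]
    xrefs = []
    for rule in spec.xrefs:
        cell = row[int(rule.source)].strip()
        for tid in _split_values(cell, spec):
            xrefs.append(XRef(rule.target, tid, bidirectional=rule.bidirectional))
    keywords = [row[int(c)].strip() for c in spec.keywords if int(c) < len(row) and row[int(c)].strip()]
    return EntryRecord(ident, dataset="", attributes=attrs, xrefs=xrefs, keywords=keywords)


# ---------------------------------------------------------------------------
# JSON / JSON-lines


def _json_records(reader: BinaryIO, record_path: str | None) -> Iterator[Any]:
    """Yield record objects incrementally.

    JSON-lines streams (first byte ``{``) are decoded line by line; a top-level
    array is decoded element by element from a bounded buffer; only a document
    whose record array is nested under ``record_path`` is loaded whole.
    """
    text = io.TextIOWrapper(reader, encoding="utf-8")
    if record_path is not None:
        doc = json.load(text)
        for part in record_path.split("."):
            doc = doc[part]
        yield from doc
        return
    first = text.read(1)
    while first and first.isspace():
        first = text.read(1)
    if not first:
        return
    if first == "{":  # JSON-lines
        buf = first + text.readline()
        while True:
            line = buf.strip()
            if line:
                try:
                    yield json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"invalid JSON line: {exc}") from exc
            buf = text.readline()
            if not buf:
                return
    elif first == "[":
        decoder = json.JSONDecoder()
        buf = ""
        expecting = True
        while True:
            chunk = text.read(65536)
            buf += chunk
            pos = 0
            while True:
                while pos < len(buf) and buf[pos] in " \t\r\n,":
                    pos += 1
                if pos < len(buf) and buf[pos] == "]":
                    return
                try:
                    obj, pos = decoder.raw_decode(buf, pos)
                except json.JSONDecodeError:
                    break  # need more data
                yield obj
                expecting = False
            buf = buf[pos:]
            if not chunk:
                if buf.strip() and buf.strip() != "]":
                    raise FormatError(f"invalid JSON near byte offset {pos}: {buf[:40]!r}")
                return
    else:
        raise FormatError(f"not a JSON document (starts with {first!r})")


def _json_get(obj: Any, path: str) -> Any:
    cur = obj
    for part in str(path).split("."):
        if not isinstance(cur, dict) or part not in cur:
            return None
        cur = cur[part]
    return cur


def ingest_json(stream, spec: ColumnSpec, stats: StreamStats | None = None) -> Iterator[EntryRecord]:
    """Yield one record per JSON object (JSON-lines or array document)."""
    stats = stats if stats is not None else StreamStats()
    reader = open_stream(stream, stats)
    for obj in _json_records(reader, spec.record_path):
        try:
            record = _record_from_json(obj, spec)
        except (KeyError, ValueError, TypeError):
            stats.records_skipped += 1
            continue
        stats.records_emitted += 1
        yield record
    _check_error_budget(stats, spec)


def _record_from_json(obj: Any, spec: ColumnSpec) -> EntryRecord:
    ident = _json_get(obj, str(spec.identifier))
    if not ident:
        raise ValueError("missing identifier")
    attrs: dict[str, Any] = {}
    for name, path in spec.attributes.items():
        value = _json_get(obj, str(path))
        if value is None:
            continue
        kind = spec.attr_types.get(name)
        if isinstance(value, list):
            attrs[name] = [_coerce(v, kind) if isinstance(v, str) else v for v in value]
        elif isinstance(value, str) and kind:
            attrs[name] = _coerce(value, kind)
        else:
            attrs[name] = value
    xrefs = []
    for rule in spec.xrefs:
        value = _json_get(obj, str(rule.source))
        if value is None:
            continue
        for tid in value if isinstance(value, list) else [value]:
            if tid:
                xrefs.append(XRef(rule.target, str(tid), bidirectional=rule.bidirectional))
    keywords = []
    for path in spec.keywords:
        value = _json_get(obj, str(path))
        if isinstance(value, list):
            keywords.extend(str(v) for v in value if v)
        elif value:
            keywords.append(str(value))
    return EntryRecord(str(ident), dataset="", attributes=attrs, xrefs=xrefs, keywords=keywords)


# ---------------------------------------------------------------------------
# XML


def _xml_resolve(elem: ElementTree.Element, path: str) -> list[str]:
    """Resolve a slash path against one record element; returns text matches."""
    as_list = path.endswith("[]")
    if as_list:
        path = path[:-2]
    parts = path.split("/")
    nodes = [elem]
    for i, part in enumerate(parts):
        attr = None
        if "@" in part:
            part, attr = part.split("@", 1) if part[0] != "@" else ("", part[1:])
        nxt: list = []
        if not part:  # bare @attr on current nodes
            values = [n.get(attr) for n in nodes if n.get(attr) is not None]
            return values if as_list else values[:1]
        for n in nodes:
            children = list(n) if part == "*" else n.findall(part)
            nxt.extend(children)
        if attr is not None:
            values = [c.get(attr) for c in nxt if c.get(attr) is not None]
            return values if as_list else values[:1]
        nodes = nxt
    values = [(n.text or "").strip() for n in nodes if (n.text or "").strip()]
    return values if as_list else values[:1]


def _xml_first(elem: ElementTree.Element, path: str) -> str | None:
    values = _xml_resolve(elem, path if not path.endswith("[]") else path)
    return values[0] if values else None


def ingest_xml(stream, spec: ColumnSpec, stats: StreamStats | None = None) -> Iterator[EntryRecord]:
    """Event-driven ingest of a repeating-record XML document.

    Each ``spec.record_tag`` element is converted to an :class:`EntryRecord`
    and immediately released, so memory stays bounded by one record.  A
    ``parent_relation`` spec additionally emits a stub record on the *parent*
    entry carrying a relation-labelled edge to the record (this is how the
    taxonomy's child links are derived from per-node parent pointers).
    """
    stats = stats if stats is not None else StreamStats()
    if spec.record_tag is None:
        raise ValueError("XML ingest requires ColumnSpec.record_tag")
    reader = open_stream(stream, stats)
    try:
        for event, elem in ElementTree.iterparse(reader, events=("end",)):
            if elem.tag != spec.record_tag:
                continue
            try:
                records = _records_from_xml(elem, spec)
            except (KeyError, ValueError, TypeError):
                stats.records_skipped += 1
                elem.clear()
                continue
            stats.records_emitted += 1
            yield from records
            elem.clear()
    except ElementTree.ParseError as exc:
        raise FormatError(f"malformed XML at line {exc.position[0]}: {exc.msg}") from exc
    _check_error_budget(stats, spec)


def _records_from_xml(elem: ElementTree.Element, spec: ColumnSpec) -> list[EntryRecord]:
    ident = _xml_first(elem, str(spec.identifier))
    if not ident:
        raise ValueError("missing identifier")
    attrs: dict[str, Any] = {}
    for name, path in spec.attributes.items():
        path = str(path)
        kind = spec.attr_types.get(name)
        if path.endswith("[]"):
            values = [_coerce(v, kind) for v in _xml_resolve(elem, path)]
            if values:
                attrs[name] = values
        else:
            value = _xml_first(elem, path)
            if value is not None:
                attrs[name] = _coerce(value, kind)
    xrefs = []
    for rule in spec.xrefs:
        for child in elem.findall(str(rule.source)):
            tid = child.get(rule.id_attr or "id")
            if not tid:
                continue
            if rule.target is not None:
                target = rule.target
            elif rule.type_attr and rule.targets is not None:
                target = rule.targets.get(child.get(rule.type_attr, ""))
                if target is None:
                    continue
            else:
                continue
            xrefs.append(XRef(target, tid, bidirectional=rule.bidirectional))
    keywords = []
    for path in spec.keywords:
        keywords.extend(v for v in _xml_resolve(elem, str(path) + ("" if str(path).endswith("[]") else "")) if v)
    records = [EntryRecord(ident, dataset="", attributes=attrs, xrefs=xrefs, keywords=keywords)]
    if spec.parent_relation is not None:
        source, relation = spec.parent_relation
        parent = _xml_first(elem, source)
        if parent and parent != ident:
            records.append(
                EntryRecord(
                    parent, dataset="",
                    xrefs=[XRef(relation, ident, bidirectional=False)], stub=True,
                )
            )
    return records


# ---------------------------------------------------------------------------
# GFF3

_TRANSCRIPT_TYPES = {"mRNA", "transcript", "tRNA", "rRNA", "ncRNA", "pseudogenic_transcript"}


def _gff3_attrs(col9: str) -> dict[str, str]:
    out = {}
    for part in col9.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = urllib.parse.unquote(v.strip())
    return out


def _strip_prefix(value: str) -> str:
    return value.split(":", 1)[1] if value[:5].lower() in ("gene:", "trans") and ":" in value else value


def ingest_gff3(
    stream,
    dataset: str = "ensembl",
    transcript_dataset: str = "transcript",
    go_dataset: str = "go",
    taxonomy_dataset: str = "taxonomy",
    stats: StreamStats | None = None,
    max_error_fraction: float = 0.01,
) -> Iterator[EntryRecord]:
    """Ingest gene and transcript features from a GFF3 stream.

    Genes become entries of *dataset* with ``seq_region``/``start``/``end``/
    ``strand`` (1-based inclusive coordinates) plus ``name``/``description``
    from column 9; ``Ontology_term`` values become GO cross-references and the
    ``##species`` directive attaches a taxonomy cross-reference.  Transcript
    features become entries of *transcript_dataset* linked both ways to their
    parent gene (relation label ``transcript`` on the gene side).
    """
    stats = stats if stats is not None else StreamStats()
    reader = open_stream(stream, stats)
    text = io.TextIOWrapper(reader, encoding="utf-8")
    taxid: str | None = None
    for line in text:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("##species"):
                tail = line.rsplit("id=", 1)
                if len(tail) == 2 and tail[1].strip().isdigit():
                    taxid = tail[1].strip()
                else:
                    last = line.split()[-1]
                    taxid = last if last.isdigit() else taxid
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            stats.records_skipped += 1
            continue
        ftype = cols[2]
        if ftype != "gene" and ftype not in _TRANSCRIPT_TYPES:
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            stats.records_skipped += 1
            continue
        a9 = _gff3_attrs(cols[8])
        ident = _strip_prefix(a9.get("ID", ""))
        if not ident:
            stats.records_skipped += 1
            continue
        attrs: dict[str, Any] = {"seq_region": cols[0], "start": start, "end": end}
        if cols[6] in ("+", "-"):
            attrs["strand"] = cols[6]
        xrefs: list[XRef] = []
        if taxid:
            xrefs.append(XRef(taxonomy_dataset, taxid))
        if ftype == "gene":
            if "Name" in a9:
                attrs["name"] = a9["Name"]
            if "description" in a9:
                attrs["description"] = a9["description"]
            if "biotype" in a9:
                attrs["biotype"] = a9["biotype"]
            for go_id in a9.get("Ontology_term", "").split(","):
                if go_id.strip():
                    xrefs.append(XRef(go_dataset, go_id.strip()))
            keywords = [a9["Name"]] if "Name" in a9 else []
            stats.records_emitted += 1
            yield EntryRecord(ident, dataset, attrs, xrefs, keywords)
        else:
            parent = _strip_prefix(a9.get("Parent", ""))
            if "Name" in a9:
                attrs["name"] = a9["Name"]
            if parent:
                xrefs.append(XRef(dataset, parent, bidirectional=False))
            stats.records_emitted += 1
            yield EntryRecord(ident, transcript_dataset, attrs, xrefs, [])
            if parent:
                yield EntryRecord(
                    parent, dataset,
                    xrefs=[XRef("transcript", ident, bidirectional=False)], stub=True,
                )
    total = stats.records_emitted + stats.records_skipped
    if total and stats.records_skipped / total > max_error_fraction:
        raise FormatError(
            f"{stats.records_skipped}/{total} malformed GFF3 lines exceeds "
            f"the allowed fraction {max_error_fraction}"
        )
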