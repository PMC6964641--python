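"""Build orchestration, command-line interface and the web service.

``build`` runs the full pipeline — streaming ingest of every registered
dataset, sorted-chunk spilling with background merging, the global merge, and
the ordered batch insert — producing a self-contained store directory.
``query`` executes chain mapping queries against a store and prints an aligned
table (or TSV/JSON).  ``web`` serves the same search and mapping operations
over HTTP as JSON (GET /ws/search, GET /ws/map), stateless between requests.

The registry file (YAML, with JSON as a subset) declares the datasets in a
fixed order — numeric dataset ids follow that order, keeping builds
reproducible — along with each dataset's format, source paths and field
mapping.
"""

from __future__ import annotations

import json
import shutil
import sys
import os
import tempfile
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, urlparse

import click
import yaml

from . import chunks as chunkmod
from . import ingest as ingestmod
from . import model, querylang, store as storemod
from .model import DatasetRegistry, EntryPayload, EntryRecord, RELATION_LABELS

__all__ = ["BuildConfig", "ConfigError", "build", "cli", "main", "make_server"]


class ConfigError(ValueError):
    pass


USER_ERRORS = (
    ConfigError,
    ingestmod.FormatError,
    model.InvalidTermError,
    model.OversizeError,
    querylang.QuerySemanticError,
    querylang.QuerySyntaxError,
    querylang.SelectorError,
    storemod.StateError,
    storemod.TokenError,
    FileNotFoundError,
)


@dataclass
class BuildConfig:
    registry_path: str
    output_dir: str
    datasets: list[str] | None = None  # None = all registered
    taxonomy_ids: list[str] = field(default_factory=list)
    buffer_size: int = 100_000
    fan_in: int = 8
    workers: int = 1
    backend: str = "file"
    log: bool = False


# ---------------------------------------------------------------------------
# registry loading


def load_registry(path: str) -> DatasetRegistry:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "datasets" not in doc:
        raise ConfigError(f"registry file {path!r} must contain a 'datasets' list")
    registry = DatasetRegistry()
    base = os.path.dirname(os.path.abspath(path))
    for item in doc["datasets"]:
        spec = dict(item.get("spec") or {})
        config = {
            "paths": [os.path.join(base, p) for p in item.get("paths", [])],
            "spec": spec,
        }
        registry.register(item["name"], item.get("format", "TSV"), config)
    return registry


def _column_spec(raw: dict) -> ingestmod.ColumnSpec:
    xrefs = [
        ingestmod.XrefRule(
            source=r["source"],
            target=r.get("target"),
            id_attr=r.get("id_attr"),
            type_attr=r.get("type_attr"),
            targets=r.get("targets"),
            bidirectional=r.get("bidirectional", True),
        )
        for r in raw.get("xrefs", [])
    ]
    parent = raw.get("parent_relation")
    return ingestmod.ColumnSpec(
        identifier=raw["identifier"],
        attributes=dict(raw.get("attributes", {})),
        attr_types=dict(raw.get("attr_types", {})),
        xrefs=xrefs,
        keywords=list(raw.get("keywords", [])),
        header=bool(raw.get("header", False)),
        delimiter=raw.get("delimiter", "\t"),
        list_sep=raw.get("list_sep"),
        max_error_fraction=float(raw.get("max_error_fraction", 0.01)),
        record_path=raw.get("record_path"),
        record_tag=raw.get("record_tag"),
        parent_relation=tuple(parent) if parent else None,
    )


def _dataset_records(name: str, registry: DatasetRegistry, stats: ingestmod.StreamStats):
    """Yield EntryRecords (with dataset names filled in) for one dataset."""
    cfg = registry.configs[name]
    fmt = registry.get(name).format
    for path in cfg["paths"]:
        if fmt == "GFF3":
            for record in ingestmod.ingest_gff3(path, dataset=name, stats=stats):
                yield record
            continue
        spec = _column_spec(cfg["spec"])
        if fmt in ("TSV", "CSV"):
            if fmt == "CSV" and "delimiter" not in cfg["spec"]:
                spec.delimiter = ","
            it = ingestmod.ingest_tsv(path, spec, stats)
        elif fmt == "JSON":
            it = ingestmod.ingest_json(path, spec, stats)
        elif fmt == "XML":
            it = ingestmod.ingest_xml(path, spec, stats)
        else:  # pragma: no cover
            raise ConfigError(f"unsupported format {fmt!r} for dataset {name!r}")
        for record in it:
            record.dataset = name
            # adapter-level stubs (e.g. taxonomy parent links) carry only xrefs
            yield record


# ---------------------------------------------------------------------------
# the build pipeline


def _emit_record(
    record: EntryRecord,
    registry: DatasetRegistry,
    manager: chunkmod.ChunkManager,
    allowed_tax: set[str] | None,
) -> bool:
    stub = record.stub
    if allowed_tax is not None and not stub and record.dataset != "taxonomy":
        tax = {x.target_id for x in record.xrefs if x.target_dataset == "taxonomy"}
        if tax and not (tax & allowed_tax):
            return False
    ds = registry.get(record.dataset)
    payload = EntryPayload(
        dataset_id=ds.numeric_id,
        identifier=record.identifier,
        attributes=dict(record.attributes),
        xrefs=sorted(
            {(x.target_dataset, x.target_id) for x in record.xrefs},
            key=lambda x: (x[0], x[1].upper(), x[1]),
        ),
        primary=not stub,
    )
    manager.add(model.entry_key(ds.numeric_id, record.identifier), payload)
    if not stub:
        ref = EntryPayload(dataset_id=ds.numeric_id, identifier=record.identifier)
        manager.add(model.term_key(record.identifier), ref)
        for kw in record.keywords:
            try:
                manager.add(model.term_key(kw), ref)
            except model.InvalidTermError:
                continue
        # reverse indexing: make dataset-level cross-references queryable in
        # both directions (relation-labelled edges stay directional)
        for x in record.xrefs:
            if not x.bidirectional:
                continue
            target_ds = RELATION_LABELS.get(x.target_dataset, x.target_dataset)
            if target_ds not in registry:
                continue
            back = EntryPayload(
                dataset_id=registry.get(target_ds).numeric_id,
                identifier=x.target_id,
                xrefs=[(record.dataset, record.identifier)],
                primary=False,
            )
            manager.add(model.entry_key(back.dataset_id, x.target_id), back)
    return True


def _expand_taxa(registry: DatasetRegistry, taxonomy_ids: list[str]) -> set[str]:
    """Expand the requested taxonomy ids to their full taxchild subtrees."""
    children: dict[str, list[str]] = {}
    stats = ingestmod.StreamStats()
    if "taxonomy" in registry:
        for record in _dataset_records("taxonomy", registry, stats):
            for x in record.xrefs:
                if x.target_dataset == "taxchild":
                    children.setdefault(record.identifier, []).append(x.target_id)
    allowed = set()
    queue = [str(t).strip() for t in taxonomy_ids if str(t).strip()]
    while queue:
        t = queue.pop()
        if t in allowed:
            continue
        allowed.add(t)
        queue.extend(children.get(t, []))
    return allowed


def build(config: BuildConfig) -> storemod.StoreHandle:
    """Run ingest → chunks → global merge → batch insert; returns the store
    opened in read mode.  Deterministic for fixed inputs and registry order."""
    registry = load_registry(config.registry_path)
    selected = config.datasets if config.datasets is not None else [d.name for d in registry]
    if not selected:
        raise ConfigError("empty dataset selection")
    for name in selected:
        if name not in registry:
            raise ConfigError(f"dataset {name!r} is not registered")
    allowed_tax = (
        _expand_taxa(registry, config.taxonomy_ids) if config.taxonomy_ids else None
    )
    os.makedirs(config.output_dir, exist_ok=True)
    chunk_dir = tempfile.mkdtemp(prefix="chunks-", dir=config.output_dir)
    manager = chunkmod.ChunkManager(
        chunk_dir,
        buffer_size=config.buffer_size,
        plan=chunkmod.MergePlan(fan_in=config.fan_in, worker_count=config.workers),
    )
    counters: dict[str, dict] = {}
    try:
        for name in selected:
            stats = ingestmod.StreamStats()
            kept = dropped = 0
            try:
                for record in _dataset_records(name, registry, stats):
                    if _emit_record(record, registry, manager, allowed_tax):
                        kept += 1
                    else:
                        dropped += 1
            except Exception as exc:
                raise type(exc)(f"[ingest:{name}] {exc}") from exc
            counters[name] = {
                "records_emitted": stats.records_emitted,
                "records_skipped": stats.records_skipped,
                "fragments_kept": kept,
                "fragments_dropped": dropped,
            }
            if config.log:
                click.echo(f"[ingest] {name}: {counters[name]}", err=True)
        handle = storemod.create_store(config.output_dir, registry, backend=config.backend)
        handle.counters["ingest"] = counters
        try:
            storemod.batch_insert(handle, manager.stream())
        except Exception as exc:
            raise type(exc)(f"[store] {exc}") from exc
        if config.log:
            click.echo(
                f"[chunks] spilled={manager.chunks_spilled} merges={manager.merges_done} "
                f"peak_buffered={manager.peak_buffered_records}", err=True,
            )
            click.echo(f"[store] terms={handle.entry_count}", err=True)
        handle.counters["chunks"] = {
            "spilled": manager.chunks_spilled,
            "merges": manager.merges_done,
            "peak_buffered_records": manager.peak_buffered_records,
        }
        return handle
    finally:
        shutil.rmtree(chunk_dir, ignore_errors=True)


# ---------------------------------------------------------------------------
# CLI


@click.group()
def cli() -> None:
    """Build and query cross-reference identifier databases."""


@cli.command("build")
@click.option("--registry", "-r", "registry_path", required=True, type=click.Path(exists=True))
@click.option("--out", "-o", "output_dir", required=True, type=click.Path())
@click.option("--datasets", "-d", default=None, help="Comma-separated subset of datasets.")
@click.option("--taxonomy-ids", default=None, help="Comma-separated taxonomy ids to restrict to.")
@click.option("--buffer-size", default=100_000, show_default=True)
@click.option("--fan-in", default=8, show_default=True)
@click.option("--workers", default=1, show_default=True)
@click.option("--verbose", is_flag=True)
def cli_build(registry_path, output_dir, datasets, taxonomy_ids, buffer_size, fan_in, workers, verbose):
    """Build a store directory from a dataset registry."""
    config = BuildConfig(
        registry_path=registry_path,
        output_dir=output_dir,
        datasets=[d.strip() for d in datasets.split(",")] if datasets is not None else None,
        taxonomy_ids=[t.strip() for t in taxonomy_ids.split(",") if t.strip()] if taxonomy_ids else [],
        buffer_size=buffer_size,
        fan_in=fan_in,
        workers=workers,
        log=verbose,
    )
    handle = build(config)
    click.echo(f"built {handle.directory}: {handle.entry_count} search terms")


def _format_rows(result: querylang.MappingResult, fmt: str) -> str:
    header = ["input", "input_dataset", "mapping_id"] + list(result.attr_labels)
    rows = [
        [r.input_term, r.input_dataset, r.mapping_id]
        + [" ".join(map(str, v)) if isinstance(v, list) else str(v) for v in r.attrs]
        for r in result.rows
    ]
    if fmt == "json":
        return json.dumps(
            {
                "rows": [dict(zip(header, row)) for row in rows],
                "next": result.next_token,
            },
            indent=1,
        )
    if fmt == "tsv":
        return "\n".join("\t".join(row) for row in [header] + rows)
    widths = [max(len(str(r[i])) for r in [header] + rows) for i in range(len(header))]
    lines = ["  ".join(str(v).ljust(w) for v, w in zip(row, widths)).rstrip()
             for row in [header] + rows]
    return "\n".join(lines)


@cli.command("query")
@click.argument("store_dir", type=click.Path(exists=True))
@click.argument("terms")
@click.argument("query_text")
@click.option("--source", "-s", default=None)
@click.option("--attrs", "-a", default=None)
@click.option("--fmt", "--format", default="table", type=click.Choice(["table", "tsv", "json"]))
@click.option("--page-size", default=storemod.DEFAULT_PAGE_SIZE, show_default=True)
@click.option("--token", default=None, help="Continuation token from a previous page.")
def cli_query(store_dir, terms, query_text, source, attrs, fmt, page_size, token):
    """Run a chain mapping query against a store."""
    handle = storemod.open_store(store_dir)
    result = querylang.execute_mapping(
        handle, terms, query_text, source=source, attrs=attrs,
        page_size=page_size, token=token,
    )
    click.echo(_format_rows(result, fmt))
    if result.next_token and fmt == "table":
        click.echo(f"# next page: --token {result.next_token}")


# ---------------------------------------------------------------------------
# web service


def _json_response(handler: BaseHTTPRequestHandler, status: int, payload: dict) -> None:
    body = json.dumps(payload).encode("utf-8")
    handler.send_response(status)
    handler.send_header("Content-Type", "application/json")
    handler.send_header("Content-Length", str(len(body)))
    handler.end_headers()
    handler.wfile.write(body)


def make_server(store_dir: str, host: str = "127.0.0.1", port: int = 8085) -> ThreadingHTTPServer:
    """HTTP server over a read-mode store: GET /ws/search and GET /ws/map."""
    handle = storemod.open_store(store_dir)

    class Handler(BaseHTTPRequestHandler):
        def log_message(self, *args):  # quiet
            pass

        def do_GET(self):
            url = urlparse(self.path)
            q = {k: v[0] for k, v in parse_qs(url.query).items()}
            try:
                if url.path == "/ws/search":
                    term = q.get("term", "")
                    page = storemod.prefix_search(
                        handle, term,
                        page_size=int(q.get("size", storemod.DEFAULT_PAGE_SIZE)),
                        token=q.get("page"),
                    )
                    entries = [p.to_obj() for p in storemod.lookup(handle, term)]
                    _json_response(self, 200, {
                        "term": term,
                        "entries": entries,
                        "items": [list(t) for t in page.items],
                        "next": page.next_token,
                    })
                elif url.path == "/ws/map":
                    result = querylang.execute_mapping(
                        handle,
                        q.get("i", ""),
                        q.get("m", ""),
                        source=q.get("s"),
                        attrs=q.get("attrs"),
                        page_size=int(q.get("size", storemod.DEFAULT_PAGE_SIZE)),
                        token=q.get("page"),
                    )
                    header = ["input", "input_dataset", "mapping_id"]
                    _json_response(self, 200, {
                        "rows": [
                            dict(zip(header, [r.input_term, r.input_dataset, r.mapping_id]))
                            | {"attrs": r.attrs}
                            for r in result.rows
                        ],
                        "attr_labels": result.attr_labels,
                        "next": result.next_token,
                    })
                else:
                    _json_response(self, 404, {"error": f"unknown endpoint {url.path}"})
            except USER_ERRORS as exc:
                err = {"error": str(exc)}
                if isinstance(exc, querylang.QuerySyntaxError):
                    err["position"] = exc.position
                _json_response(self, 400, err)
            except Exception as exc:  # internal
                _json_response(self, 500, {"error": f"internal error: {exc}"})

    return ThreadingHTTPServer((host, port), Handler)


@cli.command("web")
@click.argument("store_dir", type=click.Path(exists=True))
@click.option("--host", default="127.0.0.1", show_default=True)
@click.option("--port", default=8085, show_default=True)
def cli_web(store_dir, host, port):
    """Serve search and mapping over HTTP."""
    server = make_server(store_dir, host, port)
    click.echo(f"serving {store_dir} on http://{host}:{port}/ws/…")
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        server.shutdown()


def main() -> None:
    """Console entry point with 0/1/2 exit codes (ok/user error/internal)."""
    try:
        cli.main(standalone_mode=False)
    except click.exceptions.Abort:
        sys.exit(1)
    except click.ClickException as exc:
        exc.show()
        sys.exit(1)
    except USER_ERRORS as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    except SystemExit:
        raise
    except Exception as exc:
        click.echo(f"internal error: {exc}", err=True)
        sys.exit(2)


if __name__ == "__main__":
    main()
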