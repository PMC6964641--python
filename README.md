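# xrefdb

Mapping between bioinformatics identifiers — probe sets to transcripts to
genes to GO terms, species names to genomes to curated proteins — is a routine
step of genomic analyses, and it usually means juggling half a dozen download
formats and one-off join scripts. `xrefdb` turns heterogeneous dataset files
(taxonomy XML, Ensembl-style GFF3, UniProt-style XML, ontology/probe tables in
TSV/CSV, nomenclature JSON) into a single uniform, ordered key-value database
of identifiers, special keywords (gene symbols, species names), attributes and
cross-references, and answers *chain mapping queries* over it from Python, the
command line, or a small web service.

## How it works

**Build (single-node MapReduce).** Dataset files are read as streams —
gzip-decompressed on the fly, never materialized — and each entry becomes a
set of `(canonical key, payload)` pairs: an entry row holding attributes and
cross-references, one term row per identifier and keyword. Pairs are buffered
up to a fixed count, spilled to disk as sorted runs, and idle workers merge
runs recursively while ingestion continues (the map phase). When ingestion
finishes, all surviving runs are globally merged in one streaming pass by
repeatedly taking the minimum head across runs — the merge phase of patience
sort, realized with a tournament heap — and batch-inserted, already in key
order, into an embedded ordered store with a sparse block index (the reduce
phase). Cross-references are indexed in both directions, so a mapping loaded
as protein→gene is also queryable as gene→protein. Merging is commutative and
associative by construction: the same inputs give a byte-identical database
for any buffer size, merge fan-in or worker count.

**Query.** A query is a chain of hops and prunes over the cross-reference
graph:

    map(transcript).map(ensembl).map(go).filter(go.type=="molecular_function")

`map(x)` expands the current frontier one hop along cross-references into
dataset `x` (or a relation label: `taxchild` for taxonomy children,
`transcript` for gene→transcript). `filter(e)` prunes the frontier with a
boolean expression over the active dataset's attributes: comparison operators
`== != < <= > >=`, `&&`/`||`, substring `attr.contains("s")`, bare boolean
attributes (`uniprot.reviewed`), and the genomic-range predicate
`ds.within(a,b)`, equivalent to `ds.start>a && ds.end<b` (strict at both
ends). Input terms are case-insensitive and may be identifiers or keywords —
`"homo sapiens"` resolves to taxonomy node 9606.

## Worked example

The repository ships a deterministic synthetic-universe generator; no network
access or real downloads are needed. Build a database from the worked-example
universe and map a bacterial taxon's subtree to small SopD-annotated genes:

```python
from xrefdb import fixtures, service, execute_mapping, open_store

files, graph = fixtures.worked_example_fixture("data")
store = service.build(service.BuildConfig(registry_path=files["registry"],
                                          output_dir="db"))
result = execute_mapping(
    store, "59201",
    'map(taxchild).map(ensembl).filter(ensembl.start<10000'
    '&&ensembl.description.contains("SopD"))',
    attrs="strand,start,end",
)
for row in result.rows:
    print(row.input_term, row.mapping_id, *row.attrs)
```

which prints:

```
59201 ACH54_23895 + 2525 3484
59201 ACH56_04205 - 27 986
59201 AEW14_05145 - 3410 4369
59201 AEW14_15935 - 1 89
59201 DE27_21250 + 8885 9967
59201 DE87_06330 + 7839 8921
59201 LPMST02_21800 + 8983 10065
```

— seven genes annotated with the SopD effector, starting below position
10 000, found by walking taxonomy→children→genes and filtering on coordinates
and description. The same query runs from the shell
(`xrefdb query db 59201 '…' --attrs strand,start,end`) and over HTTP
(`xrefdb web db`, then `GET /ws/map?i=59201&m=…`).

## Layout

| module | role |
| --- | --- |
| `xrefdb.model` | domain types, key normalization, payload merge algebra, on-disk encoding |
| `xrefdb.ingest` | streaming TSV/CSV/JSON/XML/GFF3 adapters with skip-and-count error policy |
| `xrefdb.chunks` | sorted-run spills, recursive background merging, the global k-way merge |
| `xrefdb.store` | ordered key-value store (file-backed and in-memory), lookup, prefix search |
| `xrefdb.querylang` | query grammar, filter evaluation, the mapping executor |
| `xrefdb.service` | build pipeline, `xrefdb build/query/web` CLI, HTTP endpoints |
| `xrefdb.fixtures` | synthetic universes, ground-truth graph, brute-force oracle |
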