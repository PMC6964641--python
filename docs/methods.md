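# Methods

This note documents the model behind `xrefdb`, the choices made where the
design was genuinely open, and what the synthetic test universes do and do not
establish about real data.

## Data model

Every dataset entry is reduced to four things: an **identifier** (original
case preserved), an **attribute map** (scalars or ordered lists — genomic
`start`/`end` are 1-based inclusive, the GFF3 convention; `strand` is `+`/`-`;
`reviewed` is boolean), a list of **cross-references** `(target dataset or
relation label, target identifier)`, and extra **keywords** under which the
entry is also searchable (gene symbols, species names). Search is
case-insensitive: every key is canonicalized by trimming, collapsing internal
whitespace and upper-casing (`202763_at` ≡ `202763_AT`); canonicalization is
idempotent, and UTF-8 byte order of canonical keys equals their code-point
order, so byte-sorted files and the ordered store agree on ordering.

Two keyspaces share one database, multiplexed by a one-character prefix: a
*term* row maps a canonical term to lightweight `(dataset, identifier)`
references, and an *entry* row holds the single merged payload of one
`(dataset, identifier)`. This keeps the term index small — a keyword shared by
many entries stores references, not copies — and makes entry fetch during
mapping a single point read.

### Bidirectional cross-reference indexing

Public resources record most mappings in one direction only (a protein entry
references its gene; a probe table references transcripts). Queries need both
directions, so the build emits, for every dataset-target cross-reference, a
reverse fragment on the target entry. Relation-labelled edges stay
directional: `taxchild` (taxonomy parent → child, derived from per-node parent
pointers) and the structural gene↔transcript pair, which the GFF3 adapter
already emits explicitly in both directions. Reverse fragments are marked
non-primary; a target that was never actually ingested therefore exists only
as an invisible stub — it is not searchable and mapping hops treat it as
unresolved (counted, never an error).

## Merge algebra

The map phase may partition records into buffers arbitrarily and merge runs in
any order on any number of workers, so payload merging must be commutative and
associative or builds would depend on scheduling. Consequences:

* Fragments merge by identity `(dataset, case-folded identifier)`; attribute
  maps union key-wise.
* A **scalar conflict** (two fragments disagree on one attribute) resolves to
  the greater value under a total order on `(type name, canonical JSON)` — a
  deterministic, order-independent max — and is counted. A last-writer rule
  was rejected because "last" is undefined once merging is concurrent.
* Conflicting **list attributes** take the rank-deduplicated sorted union.
  This can reorder a name list, which would matter for `names[1]` selection —
  but only fires when two fragments disagree, which well-formed inputs (one
  record per entry per file) never trigger.
* **Cross-reference lists** union into canonical `(dataset, identifier)` order
  rather than first-seen order, for the same reason.
* Equality is type-aware (`True` vs `1`, `0.0` vs `-0.0` are conflicts, not
  matches), otherwise associativity breaks on mixed-type inputs.

The value encoding (canonical JSON, sorted keys, payload lists sorted by
identity) is deterministic, which is what makes "same inputs ⇒ byte-identical
database" testable; the acceptance script verifies it across buffer sizes
{10, 10³, 10⁵}, fan-in {2, 8} and worker counts {1, 4}.

## Pipeline parameters

| parameter | default | meaning |
| --- | --- | --- |
| `buffer_size` | 100 000 records | in-memory records before a sorted run is spilled; the only unbounded-input memory knob |
| `fan_in` | 8 | runs merged per recursive merge, triggered when that many share a generation |
| `workers` | 1 | threads merging runs concurrently with ingestion |
| `max_error_fraction` | 1 % | malformed records are skipped and counted; exceeding this fraction fails the stream |
| page size | 200 | default result-page length; continuation tokens are opaque and stateless |

The recursive merge is the merge phase of patience sort: sorted runs are the
piles, and a tournament (min-heap) repeatedly extracts the minimum head,
O(log k) per record with memory proportional to the number of runs, never the
number of records. A deliberately naive scan-the-minimum implementation serves
as its oracle in the tests.

The store engine is pluggable behind an ordered-map contract (ascending
iteration, point reads, prefix scans, sequential batch insert). The default
backend is an SSTable-style single file — `key TAB value` lines in key order
with a sparse index of every 64th key's byte offset — chosen because
pre-sorted batch insertion and read-only serving need nothing more; an
in-memory backend backs small tests. Rebuilds replace the store; there are no
in-place updates, matching the periodic-release cycle of the source datasets.

## Query semantics

* `map(x)`: one hop along cross-references labelled `x`; results are
  deduplicated and sorted by identifier. Unresolvable targets are dropped
  silently with a counter.
* `filter(e)`: only valid immediately after a map, and its attribute prefixes
  must name that map's active dataset (grammar-level check; relation labels
  activate their underlying dataset). Filtering before any map is expressible
  as an initial map into the same dataset.
* `within(a,b)` is strict on both ends — `start>a && end<b` — matching the
  documented equivalence of the original query language; the boundary grid
  test pins all nine cases.
* `contains` and string `==` are case-sensitive; missing attributes make a
  comparison false rather than raising; ordering operators between a string
  literal and a numeric attribute raise an evaluation error; numeric literals
  coerce numeric-looking string attributes.
* `taxchild` returns direct children per hop, so consecutive `map(taxchild)`
  steps compose; a `transitive_taxchild` flag (default off) switches to the
  cycle-safe transitive closure, since "all children" is ambiguous between the
  two readings.
* Result rows always carry the input term and input dataset columns, grouped
  by input term; terms that resolve to nothing contribute zero rows.

## Synthetic universes

`fixtures.generate_universe` emulates the *shape* of the real resources: a
taxonomy tree (complete tree of configurable depth/branching; species at the
leaves, names indexed as keywords), per-species annotation GFF3 (genes with
coordinates, strands and descriptions; transcripts), one protein per gene with
a reviewed flag (default probability 0.7, the approximate curated fraction of
a mixed knowledgebase slice), GO terms drawn from a pool with the three
ontology namespaces, probe→transcript tables and nomenclature JSON. Default
scale (~650 entries, 4 species × 25 genes × 2 transcripts) keeps a full build
plus 500 oracle-checked queries under a second while still exercising every
adapter, keyspace and edge label; the streaming and merge checks scale the
record count (10⁵–10⁶) instead, where volume is what matters. The generator is
seed-deterministic to the byte.

What it does **not** emulate: sequence content, realistic genome sizes,
ontology DAG structure (terms are flat), many-to-many probe mappings, or dirty
real-world records beyond the malformed-line policy. Passing tests therefore
demonstrate the correctness of the machinery — parsing, merging, storage,
query evaluation — on faithful formats, not robustness to the full messiness
of live releases.

`fixtures.worked_example_fixture` hand-encodes the three published worked-example
result tables (the probe→GO sets of 14 and 7 molecular-function terms, the
nine reviewed proteins behind an X-chromosome window, the seven SopD genes
under taxon 59201) with plausible invented intermediate identifiers, plus
decoys sitting exactly on each filter boundary: a biological-process GO term
on both genes, genes at `start==a` and `end==b` of the window, an off-
chromosome gene, an unreviewed protein, a SopD gene at `start==10000`, and a
SopD gene outside the taxon subtree. Only the published endpoints are
asserted; every decoy must be excluded.

## Numerical and degenerate-input choices

Dataset numeric ids follow registry order, so registry files are part of the
reproducibility contract. Ties in payload identity prefer the attribute-
bearing fragment's identifier spelling (then the lexicographic minimum). Empty
buffers cannot spill; an empty chunk list globally merges to an empty stream;
an empty dataset selection is a configuration error, while an empty input
stream is a valid empty dataset. Continuation tokens encode position only —
results are recomputed per page, trading work for statelessness. Values larger
than 8 MB per key are rejected as modelling errors rather than stored.

## Known limitations

Single machine only (multi-core, not distributed). JSON documents whose record
array is nested under a path are loaded whole; top-level arrays and JSON-lines
stream incrementally. The taxonomy-restricted build keeps the whole taxonomy
tree and filters other datasets by their direct taxonomy cross-references;
entries with no taxonomy link (ontologies, probe sets) are always kept. The
web service is plain HTTP without authentication, intended for localhost use.
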