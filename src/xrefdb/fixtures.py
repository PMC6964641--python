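"""Deterministic synthetic dataset universes with a known cross-reference graph.

Real identifier-mapping resources (taxonomies, genome annotation, curated
protein knowledgebases, ontologies, probe sets) are far too large to ship, so
this module generates small stand-ins *in the same file formats the ingest
adapters read* — taxonomy XML, HGNC-style JSON, UniProt-style XML, GO TSV,
Ensembl-style GFF3 and probe TSV — together with the exact ground-truth graph
the built database must reproduce, and a deliberately simple brute-force
traversal oracle over that graph which shares no code with the chunk/store
query path.

Two universes are provided:

* :func:`generate_universe` — a seeded random universe (taxonomy tree, species,
  genes with coordinates, transcripts, proteins with reviewed flags and GO
  terms, probes) for property and equivalence testing.
* :func:`worked_example_fixture` — a hand-written universe whose graph encodes the
  published worked examples (probe→GO chains, an X-chromosome window mapped to
  reviewed proteins, a taxonomy subtree with genes filtered by position and
  description), plus decoy records that every filter must exclude.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field
from typing import Iterable

from .model import normalize_key
from .querylang import (
    And,
    BoolAttr,
    Compare,
    Contains,
    FilterStep,
    MappingQuery,
    MapStep,
    Or,
    Within,
    parse_attrs,
    parse_query,
)

__all__ = [
    "GroundTruthGraph",
    "UniverseParams",
    "generate_universe",
    "worked_example_fixture",
    "random_queries",
]


# ---------------------------------------------------------------------------
# ground truth graph


@dataclass(frozen=True)
class NodeKey:
    dataset: str
    norm_id: str


class GroundTruthGraph:
    """Adjacency-list view of the synthetic universe.

    Nodes are (dataset, identifier) pairs with attribute dicts; edges carry the
    map-target label under which the hop is queryable (a dataset name, or a
    relation label such as ``taxchild``/``transcript``).  The term index maps
    normalized identifiers *and* special keywords (gene symbols, species
    names) to nodes — mirroring exactly what the built database indexes.
    """

    def __init__(self) -> None:
        self.nodes: dict[NodeKey, dict] = {}
        self.identifiers: dict[NodeKey, str] = {}
        self.edges: dict[NodeKey, set[tuple[str, NodeKey]]] = {}
        self.terms: dict[str, set[NodeKey]] = {}

    # construction ----------------------------------------------------------
    def add_node(self, dataset: str, identifier: str, attributes: dict | None = None) -> NodeKey:
        key = NodeKey(dataset, normalize_key(identifier))
        if key not in self.nodes:
            self.nodes[key] = {}
            self.identifiers[key] = identifier
            self.edges[key] = set()
            self.terms.setdefault(key.norm_id, set()).add(key)
        if attributes:
            self.nodes[key].update(attributes)
        return key

    def add_keyword(self, term: str, key: NodeKey) -> None:
        self.terms.setdefault(normalize_key(term), set()).add(key)

    def add_edge(
        self, src: NodeKey, label: str, dst: NodeKey, bidirectional: bool = True
    ) -> None:
        self.edges[src].add((label, dst))
        if bidirectional:
            self.edges[dst].add((src.dataset, src))

    # queries ---------------------------------------------------------------
    def resolve(self, term: str, source: str | None = None) -> list[NodeKey]:
        keys = self.terms.get(normalize_key(term), set())
        if source is not None:
            keys = {k for k in keys if k.dataset == source}
        return sorted(keys, key=lambda k: (k.dataset, k.norm_id))

    def neighbors(self, key: NodeKey, label: str) -> set[NodeKey]:
        return {dst for lab, dst in self.edges.get(key, ()) if lab == label}

    def datasets(self) -> set[str]:
        return {k.dataset for k in self.nodes}

    def edge_labels(self, dataset: str) -> set[str]:
        labels: set[str] = set()
        for key, adj in self.edges.items():
            if key.dataset == dataset:
                labels.update(lab for lab, _ in adj)
        return labels

    # the oracle ------------------------------------------------------------
    def oracle_map(
        self,
        terms: str,
        query: str | MappingQuery,
        source: str | None = None,
        attrs: str | None = None,
        transitive_taxchild: bool = False,
    ) -> list[tuple]:
        """Literal breadth-wise traversal with inline filter evaluation.

        Returns ``(input_term, mapping_id)`` rows (plus an attribute tuple when
        *attrs* is given), independent of the chunk/store implementation.
        """
        parsed = parse_query(query) if isinstance(query, str) else query
        selector = parse_attrs(attrs) if attrs else None
        rows: list[tuple] = []
        for raw in terms.split(","):
            raw = raw.strip()
            if not raw:
                continue
            frontier = set(self.resolve(raw, source))
            for step in parsed.steps:
                if isinstance(step, MapStep):
                    frontier = self._hop(frontier, step.target, transitive_taxchild)
                else:
                    frontier = {k for k in frontier if _oracle_eval(step.expr, self.nodes[k])}
            for key in sorted(frontier, key=lambda k: (self.identifiers[k], k.dataset)):
                row = (normalize_key(raw), self.identifiers[key])
                if selector is not None:
                    row += (tuple(_oracle_select(self.nodes[key], selector)),)
                rows.append(row)
        return rows

    def _hop(self, frontier: set[NodeKey], target: str, transitive: bool) -> set[NodeKey]:
        reached: set[NodeKey] = set()
        queue = list(frontier)
        visited = set(frontier)
        while queue:
            key = queue.pop()
            for nxt in self.neighbors(key, target):
                if nxt in reached:
                    continue
                reached.add(nxt)
                if transitive and target == "taxchild" and nxt not in visited:
                    visited.add(nxt)
                    queue.append(nxt)
        return reached

    # serialization ---------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "nodes": [
                {
                    "dataset": k.dataset,
                    "id": self.identifiers[k],
                    "attributes": self.nodes[k],
                    "edges": sorted(
                        [lab, dst.dataset, self.identifiers[dst]] for lab, dst in self.edges[k]
                    ),
                }
                for k in sorted(self.nodes, key=lambda k: (k.dataset, k.norm_id))
            ],
            "terms": {
                t: sorted([k.dataset, self.identifiers[k]] for k in keys)
                for t, keys in sorted(self.terms.items())
            },
        }


def _oracle_eval(expr, attrs: dict) -> bool:
    """Independent, spelled-out filter semantics for the oracle."""
    if isinstance(expr, And):
        return _oracle_eval(expr.left, attrs) and _oracle_eval(expr.right, attrs)
    if isinstance(expr, Or):
        return _oracle_eval(expr.left, attrs) or _oracle_eval(expr.right, attrs)
    if isinstance(expr, Within):
        s, e = attrs.get("start"), attrs.get("end")
        return s is not None and e is not None and s > expr.low and e < expr.high
    if isinstance(expr, Contains):
        v = attrs.get(expr.attr)
        if isinstance(v, list):
            return any(expr.needle in x for x in v if isinstance(x, str))
        return isinstance(v, str) and expr.needle in v
    if isinstance(expr, BoolAttr):
        return attrs.get(expr.attr) is True
    v = attrs.get(expr.attr)
    if v is None:
        return False
    lit = expr.literal
    if isinstance(lit, (int, float)) and not isinstance(lit, bool):
        if isinstance(v, str):
            try:
                v = float(v) if "." in v else int(v)
            except ValueError:
                return expr.op == "!="
        if isinstance(v, bool):
            return expr.op == "!="
    elif isinstance(lit, str) and not isinstance(v, str):
        v = str(v)
    table = {
        "==": v == lit, "!=": v != lit,
        "<": v < lit if not isinstance(lit, str) or isinstance(v, str) else False,
        "<=": v <= lit if not isinstance(lit, str) or isinstance(v, str) else False,
        ">": v > lit if not isinstance(lit, str) or isinstance(v, str) else False,
        ">=": v >= lit if not isinstance(lit, str) or isinstance(v, str) else False,
    }
    return table[expr.op]


def _oracle_select(attrs: dict, selector) -> list:
    out = []
    for name, idx in selector.parts:
        v = attrs.get(name)
        if idx is not None:
            out.append(v[idx - 1] if isinstance(v, list) and 1 <= idx <= len(v) else "-")
        else:
            out.append(v if v is not None else "-")
    return out


# ---------------------------------------------------------------------------
# file writers


def _write(path: str, text: str) -> str:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)
    return path


def _taxonomy_xml(nodes: list[dict]) -> str:
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<taxonomySet>"]
    for n in nodes:
        lines.append(
            f'  <taxon id="{n["id"]}" parent="{n["parent"]}" name="{n["name"]}" rank="{n["rank"]}"/>'
        )
    lines.append("</taxonomySet>\n")
    return "\n".join(lines)


def _gff3(taxid: str, features: list[str]) -> str:
    head = [
        "##gff-version 3",
        f"##species http://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?id={taxid}",
    ]
    return "\n".join(head + features) + "\n"


def _gene_line(seq: str, start: int, end: int, strand: str, gid: str, extra: str = "") -> str:
    return f"{seq}\tsynth\tgene\t{start}\t{end}\t.\t{strand}\t.\tID=gene:{gid}{extra}"


def _mrna_line(seq: str, start: int, end: int, strand: str, tid: str, gid: str) -> str:
    return f"{seq}\tsynth\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID=transcript:{tid};Parent=gene:{gid}"


def _uniprot_xml(entries: list[dict]) -> str:
    out = ['<?xml version="1.0" encoding="UTF-8"?>', "<uniprot>"]
    for e in entries:
        out.append(f'  <entry reviewed="{"true" if e["reviewed"] else "false"}">')
        out.append(f"    <accession>{e['accession']}</accession>")
        out.append("    <protein>")
        for name in e["names"]:
            out.append(f"      <fullName>{name}</fullName>")
        out.append("    </protein>")
        out.append(f'    <organism taxid="{e["taxid"]}"/>')
        for target_type, tid in e["xrefs"]:
            out.append(f'    <dbReference type="{target_type}" id="{tid}"/>')
        out.append("  </entry>")
    out.append("</uniprot>\n")
    return "\n".join(out)


_REGISTRY_TEMPLATE: list[dict] = [
    {
        "name": "taxonomy",
        "format": "XML",
        "paths": ["taxonomy.xml"],
        "spec": {
            "record_tag": "taxon",
            "identifier": "@id",
            "attributes": {"name": "@name", "rank": "@rank"},
            "keywords": ["@name"],
            "parent_relation": ["@parent", "taxchild"],
        },
    },
    {"name": "ensembl", "format": "GFF3", "paths": []},
    {"name": "transcript", "format": "GFF3", "paths": []},
    {
        "name": "go",
        "format": "TSV",
        "paths": ["go.tsv"],
        "spec": {"header": True, "identifier": 0, "attributes": {"name": 1, "type": 2}},
    },
    {
        "name": "uniprot",
        "format": "XML",
        "paths": ["uniprot.xml"],
        "spec": {
            "record_tag": "entry",
            "identifier": "accession",
            "attributes": {"reviewed": "@reviewed", "names": "protein/*[]"},
            "attr_types": {"reviewed": "bool"},
            "xrefs": [
                {"source": "dbReference", "type_attr": "type",
                 "targets": {"Ensembl": "ensembl", "GO": "go"}},
                {"source": "organism", "id_attr": "taxid", "target": "taxonomy"},
            ],
        },
    },
    {
        "name": "hgnc",
        "format": "JSON",
        "paths": ["hgnc.json"],
        "spec": {
            "identifier": "hgnc_id",
            "attributes": {"symbol": "symbol", "name": "name"},
            "keywords": ["symbol"],
            "xrefs": [{"source": "ensembl_gene_id", "target": "ensembl"}],
        },
    },
    {
        "name": "affy_hg_u133_plus_2",
        "format": "TSV",
        "paths": ["probes.tsv"],
        "spec": {"header": False, "identifier": 0,
                 "xrefs": [{"source": 1, "target": "transcript"}]},
    },
]


def _write_registry(directory: str, gff3_paths: list[str]) -> str:
    import copy

    registry = copy.deepcopy(_REGISTRY_TEMPLATE)
    for ds in registry:
        if ds["name"] == "ensembl":
            ds["paths"] = list(gff3_paths)
    # plain YAML emitted by hand would be fragile; registry files may be YAML
    # or JSON and JSON is a YAML subset
    path = os.path.join(directory, "registry.yml")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"datasets": registry}, fh, indent=1)
    return path


# ---------------------------------------------------------------------------
# random universe


@dataclass
class UniverseParams:
    """Knobs of the random universe; defaults give ~600 entries, enough for
    exhaustive oracle comparison while keeping full builds under a second."""

    seed: int = 7
    taxonomy_depth: int = 3
    taxonomy_branching: int = 2
    species_count: int = 4
    genes_per_species: int = 25
    transcripts_per_gene: int = 2
    protein_reviewed_prob: float = 0.7
    go_terms_per_protein: int = 3
    probes_per_transcript: int = 1
    go_pool_size: int = 40
    chromosome_length: tuple[int, int] = (200_000, 5_000_000)

    def __post_init__(self) -> None:
        for name in (
            "taxonomy_depth", "taxonomy_branching", "species_count", "genes_per_species",
            "transcripts_per_gene", "go_terms_per_protein", "probes_per_transcript",
            "go_pool_size",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.protein_reviewed_prob <= 1.0:
            raise ValueError("protein_reviewed_prob must be in [0, 1]")


_WORDS = [
    "ATP-binding cassette transporter", "Secreted effector protein SopD",
    "serine/threonine kinase", "zinc finger protein", "ribosomal protein",
    "heat shock chaperone", "membrane permease", "DNA gyrase subunit",
    "transcriptional regulator", "outer membrane porin",
]
_GO_TYPES = ["molecular_function", "biological_process", "cellular_component"]


def generate_universe(params: UniverseParams, directory: str) -> tuple[dict, GroundTruthGraph]:
    """Write one random universe into *directory*; byte-identical per seed.

    Returns ``(files, graph)`` where *files* maps logical names to paths
    (including ``registry`` and a ``graph`` sidecar JSON).
    """
    rng = random.Random(params.seed)
    os.makedirs(directory, exist_ok=True)
    graph = GroundTruthGraph()
    files: dict[str, str] = {}

    # taxonomy tree: complete tree, species are the leaves
    tax_nodes = [{"id": "1", "parent": "", "name": "root", "rank": "no rank"}]
    next_id = 2
    level = [("1", 0)]
    leaves: list[str] = []
    while level:
        nid, depth = level.pop(0)
        if depth >= params.taxonomy_depth:
            leaves.append(nid)
            continue
        for _ in range(params.taxonomy_branching):
            cid = str(next_id)
            next_id += 1
            tax_nodes.append({"id": cid, "parent": nid, "name": f"clade {cid}", "rank": "clade"})
            level.append((cid, depth + 1))
    species = leaves[: params.species_count]
    for i, sid in enumerate(species):
        for n in tax_nodes:
            if n["id"] == sid:
                n["name"] = f"Synthetica species{i + 1}"
                n["rank"] = "species"
    files["taxonomy"] = _write(os.path.join(directory, "taxonomy.xml"), _taxonomy_xml(tax_nodes))
    for n in tax_nodes:
        key = graph.add_node("taxonomy", n["id"], {"name": n["name"], "rank": n["rank"]})
        graph.add_keyword(n["name"], key)
    for n in tax_nodes:
        if n["parent"]:
            graph.add_edge(
                graph.add_node("taxonomy", n["parent"]), "taxchild",
                graph.add_node("taxonomy", n["id"]), bidirectional=False,
            )

    # GO pool
    go_rows = ["id\tname\ttype"]
    go_ids = []
    for i in range(params.go_pool_size):
        gid = f"GO:{7000000 + i:07d}"
        go_ids.append(gid)
        gtype = _GO_TYPES[i % 3]
        name = f"synthetic process {i}"
        go_rows.append(f"{gid}\t{name}\t{gtype}")
        graph.add_node("go", gid, {"name": name, "type": gtype})
    files["go"] = _write(os.path.join(directory, "go.tsv"), "\n".join(go_rows) + "\n")

    gff3_paths: list[str] = []
    probe_rows: list[str] = []
    uniprot_entries: list[dict] = []
    hgnc_records: list[dict] = []
    probe_n = 1000

    for si, taxid in enumerate(species):
        chrom_len = rng.randint(*params.chromosome_length)
        features: list[str] = []
        tax_key = graph.add_node("taxonomy", taxid)
        for gi in range(params.genes_per_species):
            gid = f"ENSG{int(taxid):04d}{gi:04d}"
            length = rng.randint(300, 9000)
            start = rng.randint(1, max(2, chrom_len - length - 1))
            end = start + length
            strand = rng.choice("+-")
            name = f"GN{taxid}X{gi}"
            desc = rng.choice(_WORDS)
            seq = "chr1"
            features.append(
                _gene_line(seq, start, end, strand, gid, f";Name={name};description={desc}")
            )
            g_attrs = {
                "seq_region": seq, "start": start, "end": end, "strand": strand,
                "name": name, "description": desc,
            }
            g_key = graph.add_node("ensembl", gid, g_attrs)
            graph.add_keyword(name, g_key)
            graph.add_edge(g_key, "taxonomy", tax_key)

            for ti in range(params.transcripts_per_gene):
                tid = f"ENST{int(taxid):04d}{gi:04d}{ti}"
                features.append(_mrna_line(seq, start, end, strand, tid, gid))
                t_attrs = {"seq_region": seq, "start": start, "end": end, "strand": strand}
                t_key = graph.add_node("transcript", tid, t_attrs)
                graph.add_edge(g_key, "transcript", t_key, bidirectional=False)
                graph.add_edge(t_key, "ensembl", g_key, bidirectional=False)
                graph.add_edge(t_key, "taxonomy", tax_key)
                for _ in range(params.probes_per_transcript):
                    pid = f"{probe_n}_at"
                    probe_n += 1
                    probe_rows.append(f"{pid}\t{tid}")
                    p_key = graph.add_node("affy_hg_u133_plus_2", pid)
                    graph.add_edge(p_key, "transcript", t_key)

            # one protein per gene
            acc = f"P{int(taxid):02d}{si:01d}{gi:04d}"[:10]
            reviewed = rng.random() < params.protein_reviewed_prob
            names = [f"Synthetic protein {acc}", f"SP-{gi}"]
            gos = rng.sample(go_ids, min(params.go_terms_per_protein, len(go_ids)))
            uniprot_entries.append(
                {
                    "accession": acc, "reviewed": reviewed, "names": names,
                    "taxid": taxid,
                    "xrefs": [("Ensembl", gid)] + [("GO", g) for g in gos],
                }
            )
            u_key = graph.add_node(
                "uniprot", acc, {"reviewed": reviewed, "names": names}
            )
            graph.add_edge(u_key, "ensembl", g_key)
            graph.add_edge(u_key, "taxonomy", tax_key)
            for g in gos:
                graph.add_edge(u_key, "go", graph.add_node("go", g))

            if si == 0:  # nomenclature records for the first species only
                hid = f"HGNC:{9000 + gi}"
                hgnc_records.append(
                    {
                        "hgnc_id": hid, "symbol": name,
                        "name": f"synthetic gene {gi}", "ensembl_gene_id": gid,
                    }
                )
                h_key = graph.add_node(
                    "hgnc", hid, {"symbol": name, "name": f"synthetic gene {gi}"}
                )
                graph.add_keyword(name, h_key)
                graph.add_edge(h_key, "ensembl", g_key)

        path = os.path.join(directory, f"ensembl_{taxid}.gff3")
        _write(path, _gff3(taxid, features))
        gff3_paths.append(os.path.basename(path))
        files[f"ensembl_{taxid}"] = path

    files["probes"] = _write(os.path.join(directory, "probes.tsv"), "\n".join(probe_rows) + "\n" if probe_rows else "")
    files["uniprot"] = _write(os.path.join(directory, "uniprot.xml"), _uniprot_xml(uniprot_entries))
    files["hgnc"] = _write(
        os.path.join(directory, "hgnc.json"),
        json.dumps(hgnc_records, indent=0, sort_keys=True),
    )
    files["registry"] = _write_registry(directory, gff3_paths)
    files["graph"] = _write(
        os.path.join(directory, "graph.json"), json.dumps(graph.to_json(), sort_keys=True)
    )
    return files, graph


# ---------------------------------------------------------------------------
# worked-example universe

# probe → GO identifier sets of the first worked example, with term names
_UC1_GO_A = {
    "GO:0002020": "protease binding",
    "GO:0004190": "aspartic-type endopeptidase activity",
    "GO:0004197": "cysteine-type endopeptidase activity",
    "GO:0004861": "cyclin-dependent protein serine/threonine kinase inhibitor activity",
    "GO:0005123": "death receptor binding",
    "GO:0005515": "protein binding",
    "GO:0008233": "peptidase activity",
    "GO:0008234": "cysteine-type peptidase activity",
    "GO:0016005": "phospholipase A2 activator activity",
    "GO:0016787": "hydrolase activity",
    "GO:0044877": "protein-containing complex binding",
    "GO:0097153": "cysteine-type endopeptidase activity involved in apoptotic process",
    "GO:0097199": "cysteine-type endopeptidase activity involved in apoptotic signaling pathway",
    "GO:0097200": "cysteine-type endopeptidase activity involved in execution phase of apoptosis",
}
_UC1_GO_B = {
    "GO:0004197": "cysteine-type endopeptidase activity",
    "GO:0005515": "protein binding",
    "GO:0008233": "peptidase activity",
    "GO:0008234": "cysteine-type peptidase activity",
    "GO:0016787": "hydrolase activity",
    "GO:0050700": "CARD domain binding",
    "GO:0097199": "cysteine-type endopeptidase activity involved in apoptotic signaling pathway",
}

# reviewed protein accessions and primary names of the second worked example
_UC2_PROTEINS = [
    ("O43657", "Tetraspanin-6"),
    ("Q9H2S6", "Tenomodulin"),
    ("Q9Y5S8", "NADPH oxidase 1"),
    ("P33240", "Cleavage stimulation factor subunit 2"),
    ("O60687", "Sushi repeat-containing protein SRPX2"),
    ("Q96C24", "Synaptotagmin-like protein 4"),
    ("Q8TAB3", "Protocadherin-19"),
    ("Q5H913", "ADP-ribosylation factor-like protein 13A"),
    ("Q6PP77", "XK-related protein 2"),
]

# bacterial gene rows (strand, start, end) of the third worked example
_UC3_GENES = {
    "ACH54_23895": ("+", 2525, 3484),
    "ACH56_04205": ("-", 27, 986),
    "AEW14_05145": ("-", 3410, 4369),
    "AEW14_15935": ("-", 1, 89),
    "DE27_21250": ("+", 8885, 9967),
    "DE87_06330": ("+", 7839, 8921),
    "LPMST02_21800": ("+", 8983, 10065),
}
_UC3_TAXA = {
    "ACH54_23895": "595", "ACH56_04205": "595",
    "AEW14_05145": "984254", "AEW14_15935": "984254",
    "DE27_21250": "465517", "DE87_06330": "465517",
    "LPMST02_21800": "1249525",
}
_SOPD = "Secreted effector protein SopD"


def worked_example_fixture(directory: str) -> tuple[dict, GroundTruthGraph]:
    """Write the worked-example universe into *directory*.

    The graph encodes exactly the three published result tables (probe→GO with
    14 and 7 molecular-function terms, nine reviewed proteins behind an
    X-chromosome window, seven SopD genes under taxon 59201) plus decoys that
    every filter must exclude: a biological-process GO term on both genes, a
    start==boundary gene, an off-chromosome gene, an unreviewed protein, a
    SopD gene at start==10000 and a SopD gene outside the taxon subtree.
    """
    os.makedirs(directory, exist_ok=True)
    graph = GroundTruthGraph()
    files: dict[str, str] = {}

    # taxonomy -------------------------------------------------------------
    tax_nodes = [
        {"id": "1", "parent": "", "name": "root", "rank": "no rank"},
        {"id": "9606", "parent": "1", "name": "Homo sapiens", "rank": "species"},
        {"id": "590", "parent": "1", "name": "Salmonella", "rank": "genus"},
        {"id": "59201", "parent": "590",
         "name": "Salmonella enterica subsp. enterica", "rank": "subspecies"},
        {"id": "595", "parent": "59201", "name": "Salmonella enterica strain A", "rank": "strain"},
        {"id": "984254", "parent": "59201", "name": "Salmonella enterica strain B", "rank": "strain"},
        {"id": "465517", "parent": "59201", "name": "Salmonella enterica strain C", "rank": "strain"},
        {"id": "1249525", "parent": "59201", "name": "Salmonella enterica strain D", "rank": "strain"},
        # decoy: a sibling taxon NOT under 59201, carrying a SopD gene
        {"id": "28901", "parent": "590", "name": "Salmonella decoyii", "rank": "species"},
    ]
    files["taxonomy"] = _write(os.path.join(directory, "taxonomy.xml"), _taxonomy_xml(tax_nodes))
    for n in tax_nodes:
        key = graph.add_node("taxonomy", n["id"], {"name": n["name"], "rank": n["rank"]})
        graph.add_keyword(n["name"], key)
    for n in tax_nodes:
        if n["parent"]:
            graph.add_edge(
                graph.add_node("taxonomy", n["parent"]), "taxchild",
                graph.add_node("taxonomy", n["id"]), bidirectional=False,
            )

    # GO -------------------------------------------------------------------
    go_all = dict(_UC1_GO_A)
    go_all.update(_UC1_GO_B)
    go_all["GO:0006915"] = "apoptotic process"  # decoy: biological_process
    go_rows = ["id\tname\ttype"]
    for gid in sorted(go_all):
        gtype = "biological_process" if gid == "GO:0006915" else "molecular_function"
        go_rows.append(f"{gid}\t{go_all[gid]}\t{gtype}")
        graph.add_node("go", gid, {"name": go_all[gid], "type": gtype})
    files["go"] = _write(os.path.join(directory, "go.tsv"), "\n".join(go_rows) + "\n")

    # human genome ---------------------------------------------------------
    human_features: list[str] = []
    tax9606 = graph.add_node("taxonomy", "9606")

    def add_gene(gid, seq, start, end, strand, name=None, desc=None, go_terms=()):
        extra = ""
        if name:
            extra += f";Name={name}"
        if desc:
            extra += f";description={desc}"
        if go_terms:
            extra += ";Ontology_term=" + ",".join(sorted(go_terms))
        human_features.append(_gene_line(seq, start, end, strand, gid, extra))
        attrs = {"seq_region": seq, "start": start, "end": end, "strand": strand}
        if name:
            attrs["name"] = name
        if desc:
            attrs["description"] = desc
        key = graph.add_node("ensembl", gid, attrs)
        if name:
            graph.add_keyword(name, key)
        graph.add_edge(key, "taxonomy", tax9606)
        for g in go_terms:
            graph.add_edge(key, "go", graph.add_node("go", g))
        return key

    def add_transcript(tid, gid_key, seq, start, end, strand):
        human_features.append(_mrna_line(seq, start, end, strand, tid, graph.identifiers[gid_key]))
        t_key = graph.add_node(
            "transcript", tid,
            {"seq_region": seq, "start": start, "end": end, "strand": strand},
        )
        graph.add_edge(gid_key, "transcript", t_key, bidirectional=False)
        graph.add_edge(t_key, "ensembl", gid_key, bidirectional=False)
        graph.add_edge(t_key, "taxonomy", tax9606)
        return t_key

    # probe chains: the two caspase-like genes with their GO annotations
    gene_a = add_gene(
        "ENSG00000064012", "2", 201233443, 201287711, "-", name="CASP8",
        desc="caspase 8", go_terms=set(_UC1_GO_A) | {"GO:0006915"},
    )
    gene_b = add_gene(
        "ENSG00000196954", "11", 104813593, 104840163, "-", name="CASP4",
        desc="caspase 4", go_terms=set(_UC1_GO_B) | {"GO:0006915"},
    )
    t_a = add_transcript("ENST00000358485", gene_a, "2", 201233443, 201287711, "-")
    t_b = add_transcript("ENST00000444739", gene_b, "11", 104813593, 104840163, "-")

    # X-window genes, one per reviewed protein of the second worked example
    x_gene_keys = []
    for i, (acc, _name) in enumerate(_UC2_PROTEINS):
        start = 100_100_000 + i * 90_000
        end = start + 40_000
        gid = f"ENSGX{3000 + i:05d}"
        key = add_gene(gid, "X", start, end, "+" if i % 2 == 0 else "-")
        add_transcript(f"ENSTX{3000 + i:05d}", key, "X", start, end, "+")
        x_gene_keys.append(key)
    # decoys around the window and the reviewed flag
    decoy_bound = add_gene("ENSGXBOUND1", "X", 100_000_000, 100_040_000, "+")  # start == a
    decoy_end = add_gene("ENSGXBOUND2", "X", 100_900_001, 101_000_000, "+")  # end == b
    decoy_chr7 = add_gene("ENSG7INNER", "7", 100_200_000, 100_240_000, "+")  # wrong seq_region
    decoy_unrev = add_gene("ENSGXUNREV", "X", 100_500_123, 100_530_123, "-")  # unreviewed protein

    files["ensembl_9606"] = _write(
        os.path.join(directory, "ensembl_9606.gff3"), _gff3("9606", human_features)
    )

    # bacterial genomes ----------------------------------------------------
    gff3_paths = ["ensembl_9606.gff3"]
    bact_features: dict[str, list[str]] = {}
    for gid, (strand, start, end) in _UC3_GENES.items():
        taxid = _UC3_TAXA[gid]
        bact_features.setdefault(taxid, []).append(
            _gene_line("Chromosome", start, end, strand, gid, f";description={_SOPD}")
        )
        key = graph.add_node(
            "ensembl", gid,
            {"seq_region": "Chromosome", "start": start, "end": end,
             "strand": strand, "description": _SOPD},
        )
        graph.add_edge(key, "taxonomy", graph.add_node("taxonomy", taxid))
    # decoys: start not < 10000; a non-SopD product; a SopD gene outside the subtree
    for gid, taxid, start, end, desc in [
        ("DECOY_BOUND_10000", "595", 10000, 10900, _SOPD),
        ("DECOY_NOSOPD", "595", 500, 1400, "Secreted effector protein SopE"),
        ("DECOY_FAR", "984254", 20000, 20900, _SOPD),
        ("DECOY_OUTSIDE", "28901", 100, 999, _SOPD),
    ]:
        bact_features.setdefault(taxid, []).append(
            _gene_line("Chromosome", start, end, "+", gid, f";description={desc}")
        )
        key = graph.add_node(
            "ensembl", gid,
            {"seq_region": "Chromosome", "start": start, "end": end,
             "strand": "+", "description": desc},
        )
        graph.add_edge(key, "taxonomy", graph.add_node("taxonomy", taxid))
    for taxid, feats in sorted(bact_features.items()):
        name = f"ensembl_{taxid}.gff3"
        files[f"ensembl_{taxid}"] = _write(os.path.join(directory, name), _gff3(taxid, feats))
        gff3_paths.append(name)

    # proteins -------------------------------------------------------------
    uniprot_entries = []
    for (acc, name), key in zip(_UC2_PROTEINS, x_gene_keys):
        uniprot_entries.append(
            {
                "accession": acc, "reviewed": True, "names": [name, f"{acc} short"],
                "taxid": "9606", "xrefs": [("Ensembl", graph.identifiers[key])],
            }
        )
        u_key = graph.add_node("uniprot", acc, {"reviewed": True, "names": [name, f"{acc} short"]})
        graph.add_edge(u_key, "ensembl", key)
        graph.add_edge(u_key, "taxonomy", tax9606)
    for acc, reviewed, gene_key in [
        ("DECOYU1", False, decoy_unrev),  # unreviewed, in-window gene
        ("DECOYR7", True, decoy_chr7),  # reviewed, wrong chromosome
        ("DECOYRB", True, decoy_bound),  # reviewed, boundary gene
        ("DECOYRE", True, decoy_end),  # reviewed, end-boundary gene
    ]:
        uniprot_entries.append(
            {
                "accession": acc, "reviewed": reviewed,
                "names": [f"Decoy protein {acc}"], "taxid": "9606",
                "xrefs": [("Ensembl", graph.identifiers[gene_key])],
            }
        )
        u_key = graph.add_node(
            "uniprot", acc, {"reviewed": reviewed, "names": [f"Decoy protein {acc}"]}
        )
        graph.add_edge(u_key, "ensembl", gene_key)
        graph.add_edge(u_key, "taxonomy", tax9606)
    files["uniprot"] = _write(os.path.join(directory, "uniprot.xml"), _uniprot_xml(uniprot_entries))

    # nomenclature + probes -------------------------------------------------
    hgnc_records = [
        {"hgnc_id": "HGNC:1509", "symbol": "CASP8", "name": "caspase 8",
         "ensembl_gene_id": "ENSG00000064012"},
        {"hgnc_id": "HGNC:1505", "symbol": "CASP4", "name": "caspase 4",
         "ensembl_gene_id": "ENSG00000196954"},
    ]
    for rec in hgnc_records:
        h_key = graph.add_node(
            "hgnc", rec["hgnc_id"], {"symbol": rec["symbol"], "name": rec["name"]}
        )
        graph.add_keyword(rec["symbol"], h_key)
        graph.add_edge(h_key, "ensembl", graph.add_node("ensembl", rec["ensembl_gene_id"]))
    files["hgnc"] = _write(
        os.path.join(directory, "hgnc.json"), json.dumps(hgnc_records, indent=0, sort_keys=True)
    )

    probe_rows = [
        "202763_at\tENST00000358485",
        "209310_s_at\tENST00000444739",
        "99999_at\tENSTX03000",  # decoy probe into the X-window chain
    ]
    for row in probe_rows:
        pid, tid = row.split("\t")
        p_key = graph.add_node("affy_hg_u133_plus_2", pid)
        graph.add_edge(p_key, "transcript", graph.add_node("transcript", tid))
    files["probes"] = _write(os.path.join(directory, "probes.tsv"), "\n".join(probe_rows) + "\n")

    files["registry"] = _write_registry(directory, gff3_paths)
    files["graph"] = _write(
        os.path.join(directory, "graph.json"), json.dumps(graph.to_json(), sort_keys=True)
    )
    return files, graph


# ---------------------------------------------------------------------------
# random query generation (for oracle-equivalence testing)


def random_queries(graph: GroundTruthGraph, rng: random.Random, n: int) -> Iterable[tuple]:
    """Yield ``(terms, query_text, source)`` triples of grammar-valid queries.

    Chains have 1–4 map steps whose targets follow the edge labels actually
    present from the active dataset (with occasional dead-end targets mixed
    in), and random filters drawn from the active dataset's attribute
    vocabulary after roughly half the map steps.
    """
    terms_pool = sorted(graph.terms)
    datasets = sorted(graph.datasets())
    label_cache = {ds: sorted(graph.edge_labels(ds)) for ds in datasets}

    def filter_for(ds: str) -> str | None:
        choices: list[str] = []
        if ds in ("ensembl", "transcript"):
            a = rng.randrange(0, 4_000_000)
            b = a + rng.randrange(1, 2_000_000)
            choices += [
                f"{ds}.within({a},{b})",
                f"{ds}.start<{rng.randrange(1, 5_000_000)}",
                f"{ds}.end>={rng.randrange(1, 5_000_000)}",
                f'{ds}.seq_region=="chr1"',
                f'{ds}.strand=="{rng.choice("+-")}"',
            ]
            if ds == "ensembl":
                word = rng.choice(["SopD", "kinase", "protein", "zebra"])
                choices.append(f'{ds}.description.contains("{word}")')
                choices.append(
                    f'{ds}.start<{rng.randrange(1, 5_000_000)} && {ds}.strand=="+"'
                )
                choices.append(
                    f'{ds}.seq_region=="chr1" || {ds}.end<{rng.randrange(1, 5_000_000)}'
                )
        elif ds == "go":
            choices.append(f'go.type=="{rng.choice(_GO_TYPES)}"')
            choices.append('go.name.contains("synthetic")')
        elif ds == "uniprot":
            choices += ["uniprot.reviewed", 'uniprot.names.contains("Synthetic")']
        elif ds == "taxonomy":
            choices.append('taxonomy.rank=="species"')
            choices.append('taxonomy.name.contains("Synthetica")')
        return rng.choice(choices) if choices else None

    for _ in range(n):
        term = rng.choice(terms_pool)
        keys = graph.resolve(term)
        source = None
        if keys and rng.random() < 0.3:
            source = rng.choice(sorted({k.dataset for k in keys}))
        active = rng.choice(sorted({k.dataset for k in keys})) if keys else rng.choice(datasets)
        parts: list[str] = []
        for _step in range(rng.randint(1, 4)):
            labels = label_cache.get(active) or datasets
            target = rng.choice(labels) if rng.random() < 0.9 else rng.choice(datasets)
            parts.append(f"map({target})")
            from .model import RELATION_LABELS

            active = RELATION_LABELS.get(target, target)
            if rng.random() < 0.5:
                f = filter_for(active)
                if f:
                    parts.append(f"filter({f})")
        yield term, ".".join(parts), source
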