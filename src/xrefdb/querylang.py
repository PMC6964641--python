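"""The chain mapping query language.

A query is a dot-chained sequence of steps over the cross-reference graph::

    map(transcript).map(ensembl).map(go).filter(go.type=="molecular_function")

``map(x)`` hops every entry in the current frontier along its cross-references
into dataset *x* (or along a relation label such as ``taxchild`` or
``transcript``); ``filter(expr)`` prunes the frontier with a boolean expression
over the active dataset's attributes.  Filter expressions support
``== != < <= > >= && ||``, the genomic-range predicate
``ds.within(a,b)`` — equivalent to ``ds.start>a && ds.end<b``, strict at both
ends — substring ``ds.attr.contains("s")`` and bare boolean attributes
(``uniprot.reviewed``).

Execution starts from comma-separated search terms resolved through the term
index (identifiers or special keywords such as gene or species names), walks
the steps left to right and returns one row per (input term, reached
identifier) with optionally selected attributes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

from .model import RELATION_LABELS, EntryPayload, InvalidTermError, normalize_key
from .store import DEFAULT_PAGE_SIZE, StoreHandle, TokenError, get_entry, lookup
from .store import _decode_token, _encode_token  # shared token codec

__all__ = [
    "AttrSelector",
    "BoolAttr",
    "Compare",
    "Contains",
    "FilterEvalError",
    "FilterStep",
    "MapStep",
    "MappingQuery",
    "MappingResult",
    "MappingRow",
    "QuerySemanticError",
    "QuerySyntaxError",
    "SelectorError",
    "UnknownDatasetError",
    "Within",
    "eval_filter",
    "execute_mapping",
    "map_step",
    "parse_attrs",
    "parse_query",
    "select_attrs",
]

EMPTY_MARKER = "-"


class QuerySyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


class QuerySemanticError(ValueError):
    pass


class UnknownDatasetError(QuerySemanticError):
    pass


class FilterEvalError(ValueError):
    """Operator/literal type mismatch during filter evaluation."""


class SelectorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class Compare:
    dataset: str
    attr: str
    op: str  # == != < <= > >=
    literal: str | int | float | bool

    def to_text(self) -> str:
        lit = f'"{self.literal}"' if isinstance(self.literal, str) else repr(self.literal).lower() if isinstance(self.literal, bool) else repr(self.literal)
        return f"{self.dataset}.{self.attr}{self.op}{lit}"


@dataclass(frozen=True)
class Contains:
    dataset: str
    attr: str
    needle: str

    def to_text(self) -> str:
        return f'{self.dataset}.{self.attr}.contains("{self.needle}")'


@dataclass(frozen=True)
class Within:
    dataset: str
    low: float
    high: float

    def to_text(self) -> str:
        def num(x):
            return repr(int(x)) if isinstance(x, float) and x.is_integer() else repr(x)

        return f"{self.dataset}.within({num(self.low)},{num(self.high)})"


@dataclass(frozen=True)
class BoolAttr:
    dataset: str
    attr: str

    def to_text(self) -> str:
        return f"{self.dataset}.{self.attr}"


@dataclass(frozen=True)
class And:
    left: object
    right: object

    def to_text(self) -> str:
        return f"{self.left.to_text()} && {self.right.to_text()}"


@dataclass(frozen=True)
class Or:
    left: object
    right: object

    def to_text(self) -> str:
        return f"({self.left.to_text()} || {self.right.to_text()})"


FilterExpr = Compare | Contains | Within | BoolAttr | And | Or


@dataclass(frozen=True)
class MapStep:
    target: str

    def to_text(self) -> str:
        return f"map({self.target})"


@dataclass(frozen=True)
class FilterStep:
    expr: FilterExpr

    def to_text(self) -> str:
        return f"filter({self.expr.to_text()})"


@dataclass(frozen=True)
class MappingQuery:
    steps: tuple

    def to_text(self) -> str:
        return ".".join(s.to_text() for s in self.steps)


# ---------------------------------------------------------------------------
# tokenizer / parser

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<op>==|!=|<=|>=|&&|\|\||[<>().,])
      | (?P<string>"(?:[^"\\]|\\.)*")
      | (?P<number>-?\d+(?:\.\d+)?)
      | (?P<ident>[A-Za-z_][A-Za-z0-9_:]*)
    )""",
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == m.start():
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            at = len(text) - len(stripped)
            raise QuerySyntaxError(f"unexpected character {stripped[0]!r}", at)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    @property
    def cur(self):
        return self.tokens[self.i]

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, pos = self.cur
        if val != value:
            raise QuerySyntaxError(f"expected {value!r}, found {val or 'end of query'!r}", pos)
        return self.advance()

    # steps -----------------------------------------------------------------
    def parse(self) -> MappingQuery:
        steps: list = [self.step()]
        while self.cur[1] == ".":
            self.advance()
            steps.append(self.step())
        kind, val, pos = self.cur
        if kind != "eof":
            raise QuerySyntaxError(f"unexpected {val!r} after query", pos)
        if not any(isinstance(s, MapStep) for s in steps):
            raise QuerySyntaxError("query needs at least one map step", 0)
        if not isinstance(steps[0], MapStep):
            raise QuerySyntaxError("a filter may only follow a map step", 0)
        for prev, cur in zip(steps, steps[1:]):
            if isinstance(cur, FilterStep) and not isinstance(prev, MapStep):
                raise QuerySyntaxError("a filter may only follow a map step", 0)
        for prev, cur in zip(steps, steps[1:]):
            if isinstance(cur, FilterStep):
                active = RELATION_LABELS.get(prev.target, prev.target)
                for ds in _expr_datasets(cur.expr):
                    if ds != active:
                        raise QuerySemanticError(
                            f"filter attribute prefix {ds!r} does not name the active "
                            f"dataset {active!r} of the preceding map step"
                        )
        return MappingQuery(steps=tuple(steps))

    def step(self):
        kind, val, pos = self.advance()
        if kind != "ident" or val not in ("map", "filter"):
            raise QuerySyntaxError(f"expected 'map' or 'filter', found {val!r}", pos)
        self.expect("(")
        if val == "map":
            tkind, tval, tpos = self.cur
            if tkind != "ident":
                raise QuerySyntaxError("empty or invalid map target", tpos)
            self.advance()
            self.expect(")")
            return MapStep(target=tval)
        expr = self.or_expr()
        self.expect(")")
        return FilterStep(expr=expr)

    # expressions -----------------------------------------------------------
    def or_expr(self):
        left = self.and_expr()
        while self.cur[1] == "||":
            self.advance()
            left = Or(left, self.and_expr())
        return left

    def and_expr(self):
        left = self.unary()
        while self.cur[1] == "&&":
            self.advance()
            left = And(left, self.unary())
        return left

    def unary(self):
        if self.cur[1] == "(":
            self.advance()
            expr = self.or_expr()
            self.expect(")")
            return expr
        return self.predicate()

    def predicate(self):
        kind, dataset, pos = self.advance()
        if kind != "ident":
            raise QuerySyntaxError(f"expected an attribute path, found {dataset!r}", pos)
        path = [dataset]
        while self.cur[1] == ".":
            self.advance()
            k2, part, p2 = self.advance()
            if k2 != "ident":
                raise QuerySyntaxError(f"expected attribute name, found {part!r}", p2)
            path.append(part)
            if self.cur[1] == "(":
                return self.call(path, p2)
        if len(path) < 2:
            raise QuerySyntaxError(f"attribute path needs a dataset prefix: {dataset!r}", pos)
        kind, op, pos = self.cur
        if op in ("==", "!=", "<", "<=", ">", ">="):
            self.advance()
            literal = self.literal()
            return Compare(path[0], ".".join(path[1:]), op, literal)
        return BoolAttr(path[0], ".".join(path[1:]))

    def call(self, path: list[str], pos: int):
        func = path[-1]
        self.expect("(")
        if func == "within":
            if len(path) != 2:
                raise QuerySyntaxError("within applies to a dataset, e.g. ensembl.within(a,b)", pos)
            low = self.number()
            self.expect(",")
            high = self.number()
            self.expect(")")
            return Within(path[0], low, high)
        if func == "contains":
            if len(path) != 3:
                raise QuerySyntaxError(
                    "contains applies to an attribute, e.g. ensembl.description.contains(\"s\")", pos
                )
            kind, val, spos = self.advance()
            if kind != "string":
                raise QuerySyntaxError("contains takes a quoted string", spos)
            self.expect(")")
            return Contains(path[0], path[1], _unquote(val))
        raise QuerySyntaxError(f"unknown filter function {func!r}", pos)

    def literal(self):
        kind, val, pos = self.advance()
        if kind == "string":
            return _unquote(val)
        if kind == "number":
            return float(val) if "." in val else int(val)
        if kind == "ident" and val in ("true", "false"):
            return val == "true"
        raise QuerySyntaxError(f"expected a literal, found {val!r}", pos)

    def number(self) -> float:
        kind, val, pos = self.advance()
        if kind != "number":
            raise QuerySyntaxError(f"expected a number, found {val!r}", pos)
        return float(val) if "." in val else int(val)


def _unquote(raw: str) -> str:
    return raw[1:-1].replace('\\"', '"').replace("\\\\", "\\")


def _expr_datasets(expr: FilterExpr) -> set[str]:
    if isinstance(expr, (And, Or)):
        return _expr_datasets(expr.left) | _expr_datasets(expr.right)
    return {expr.dataset}


def parse_query(text: str) -> MappingQuery:
    """Parse query text into a :class:`MappingQuery` AST.

    Raises :class:`QuerySyntaxError` (with position) on malformed input and
    :class:`QuerySemanticError` when a filter's attribute prefix does not name
    the active dataset of its preceding map step.
    """
    if not text or not text.strip():
        raise QuerySyntaxError("empty query", 0)
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# filter evaluation


def _as_number(value):
    if isinstance(value, bool):
        return None
    if isinstance(value, (int, float)):
        return value
    if isinstance(value, str):
        try:
            return float(value) if "." in value else int(value)
        except ValueError:
            return None
    return None


def eval_filter(expr: FilterExpr, entry: EntryPayload) -> bool:
    """Evaluate a filter expression against one entry's attributes.

    Missing attributes make a comparison false, never an error; an ordering
    operator applied with a string literal to a numeric attribute raises
    :class:`FilterEvalError`.
    """
    if isinstance(expr, And):
        return eval_filter(expr.left, entry) and eval_filter(expr.right, entry)
    if isinstance(expr, Or):
        return eval_filter(expr.left, entry) or eval_filter(expr.right, entry)
    attrs = entry.attributes
    if isinstance(expr, Within):
        start = _as_number(attrs.get("start"))
        end = _as_number(attrs.get("end"))
        if start is None or end is None:
            return False
        return start > expr.low and end < expr.high
    if isinstance(expr, Contains):
        value = attrs.get(expr.attr)
        if isinstance(value, list):
            return any(isinstance(v, str) and expr.needle in v for v in value)
        return isinstance(value, str) and expr.needle in value
    if isinstance(expr, BoolAttr):
        return attrs.get(expr.attr) is True
    if isinstance(expr, Compare):
        value = attrs.get(expr.attr)
        if value is None:
            return False
        return _compare(value, expr.op, expr.literal)
    raise TypeError(f"not a filter expression: {expr!r}")


def _compare(value, op: str, literal) -> bool:
    ordering = op in ("<", "<=", ">", ">=")
    if isinstance(literal, bool):
        equal = isinstance(value, bool) and value == literal
        if ordering:
            raise FilterEvalError("ordering comparison with a boolean literal")
        return equal if op == "==" else not equal
    if isinstance(literal, (int, float)):
        num = _as_number(value)
        if num is None:
            return op == "!="
        return _apply(num, op, literal)
    # string literal
    if ordering and isinstance(value, (int, float)) and not isinstance(value, bool):
        raise FilterEvalError(
            f"ordering operator {op!r} with a quoted string against numeric attribute value {value!r}"
        )
    if not isinstance(value, str):
        value = str(value)
    return _apply(value, op, literal)


def _apply(a, op, b) -> bool:
    if op == "==":
        return a == b
    if op == "!=":
        return a != b
    if op == "<":
        return a < b
    if op == "<=":
        return a <= b
    if op == ">":
        return a > b
    return a >= b


# ---------------------------------------------------------------------------
# attribute selection


_SELECTOR_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)(?:\[(\d+)\])?$")


@dataclass(frozen=True)
class AttrSelector:
    """Parsed ``attrs`` selector: attribute names, optionally 1-based indexed."""

    parts: tuple  # of (name, index | None)

    @property
    def labels(self) -> list[str]:
        return [f"{n}[{i}]" if i is not None else n for n, i in self.parts]


def parse_attrs(selector: str | AttrSelector | None) -> AttrSelector:
    if selector is None:
        return AttrSelector(parts=())
    if isinstance(selector, AttrSelector):
        return selector
    parts = []
    for raw in selector.split(","):
        raw = raw.strip()
        if not raw:
            continue
        m = _SELECTOR_RE.match(raw)
        if m is None:
            raise SelectorError(f"malformed attribute selector {raw!r}")
        name, idx = m.group(1), m.group(2)
        if idx is not None and int(idx) < 1:
            raise SelectorError(f"attribute index must be >= 1 in {raw!r}")
        parts.append((name, int(idx) if idx is not None else None))
    if not parts:
        raise SelectorError(f"empty attribute selector {selector!r}")
    return AttrSelector(parts=tuple(parts))


def select_attrs(entry: EntryPayload, selector: str | AttrSelector) -> list:
    """Values in selector order; ``name[i]`` picks the i-th list element
    (1-based); anything missing yields the empty marker ``-``."""
    sel = parse_attrs(selector)
    out = []
    for name, idx in sel.parts:
        value = entry.attributes.get(name)
        if idx is not None:
            if isinstance(value, list) and 1 <= idx <= len(value):
                out.append(value[idx - 1])
            else:
                out.append(EMPTY_MARKER)
        else:
            out.append(value if value is not None else EMPTY_MARKER)
    return out


# ---------------------------------------------------------------------------
# execution


@dataclass
class MappingRow:
    input_term: str
    input_dataset: str
    mapping_id: str
    attrs: list = field(default_factory=list)

    def as_tuple(self) -> tuple:
        return (self.input_term, self.input_dataset, self.mapping_id, tuple(self.attrs))


@dataclass
class MappingResult:
    rows: list[MappingRow]
    next_token: str | None = None
    unresolved_xrefs: int = 0
    attr_labels: list[str] = field(default_factory=list)


def map_step(
    store: StoreHandle,
    entries: Iterable[EntryPayload],
    target: str,
    transitive_taxchild: bool = False,
    counters: dict | None = None,
) -> list[EntryPayload]:
    """One hop: all entries reachable from *entries* along *target* edges.

    *target* is a dataset name or a relation label; the result is deduplicated
    and sorted by identifier.  Cross-references whose target identifier is not
    in the store are dropped silently (counted under ``unresolved``).
    """
    registry = store.registry
    if not registry.is_map_target(target):
        valid = sorted({d.name for d in registry} | set(RELATION_LABELS))
        raise UnknownDatasetError(f"unknown map target {target!r}; valid targets: {valid}")
    entry_ds = RELATION_LABELS.get(target, target)
    if entry_ds not in registry:
        valid = sorted({d.name for d in registry} | set(RELATION_LABELS))
        raise UnknownDatasetError(f"unknown map target {target!r}; valid targets: {valid}")
    ds_id = registry.get(entry_ds).numeric_id
    counters = counters if counters is not None else {}
    out: dict[tuple[int, str], EntryPayload] = {}
    frontier = list(entries)
    seen: set[tuple[int, str]] = {e.identity for e in frontier}
    while frontier:
        nxt: list[EntryPayload] = []
        for entry in frontier:
            for tds, tid in entry.xrefs:
                if tds != target:
                    continue
                hit = get_entry(store, ds_id, tid)
                if hit is None or not hit.primary:
                    counters["unresolved"] = counters.get("unresolved", 0) + 1
                    continue
                if hit.identity not in out:
                    out[hit.identity] = hit
                    if transitive_taxchild and target == "taxchild" and hit.identity not in seen:
                        seen.add(hit.identity)
                        nxt.append(hit)
        frontier = nxt if (transitive_taxchild and target == "taxchild") else []
    return [out[k] for k in sorted(out, key=lambda k: (out[k].identifier, k))]


def _apply_steps(
    store: StoreHandle,
    entries: list[EntryPayload],
    query: MappingQuery,
    transitive_taxchild: bool,
    counters: dict,
) -> list[EntryPayload]:
    frontier = entries
    for step in query.steps:
        if isinstance(step, MapStep):
            frontier = map_step(
                store, frontier, step.target,
                transitive_taxchild=transitive_taxchild, counters=counters,
            )
        else:
            frontier = [e for e in frontier if eval_filter(step.expr, e)]
    return frontier


def execute_mapping(
    store: StoreHandle,
    terms: str,
    query: str | MappingQuery,
    source: str | None = None,
    attrs: str | AttrSelector | None = None,
    page_size: int = DEFAULT_PAGE_SIZE,
    token: str | None = None,
    transitive_taxchild: bool = False,
) -> MappingResult:
    """Run a chain mapping query for comma-separated input terms.

    Each term is resolved through the term index (restricted to *source* when
    given), the steps are applied left to right, and one row is produced per
    (term, final identifier) with the attributes named by *attrs*.  A term that
    resolves to nothing simply contributes no rows.
    """
    parsed = parse_query(query) if isinstance(query, str) else query
    selector = parse_attrs(attrs) if attrs is not None else None
    if source is not None and source not in store.registry:
        raise UnknownDatasetError(f"unknown source dataset {source!r}")
    source_id = store.registry.get(source).numeric_id if source is not None else None
    counters: dict = {}
    rows: list[MappingRow] = []
    for raw_term in terms.split(","):
        raw_term = raw_term.strip()
        if not raw_term:
            continue
        try:
            norm = normalize_key(raw_term)
        except InvalidTermError:
            continue
        resolved = lookup(store, raw_term)
        if source_id is not None:
            resolved = [e for e in resolved if e.dataset_id == source_id]
        if not resolved:
            continue
        input_ds = source or ",".join(
            sorted({store.registry.by_id(e.dataset_id).name for e in resolved})
        )
        final = _apply_steps(store, resolved, parsed, transitive_taxchild, counters)
        for entry in final:
            rows.append(
                MappingRow(
                    input_term=norm,
                    input_dataset=input_ds,
                    mapping_id=entry.identifier,
                    attrs=select_attrs(entry, selector) if selector else [],
                )
            )
    offset = 0
    if token is not None:
        try:
            (offset,) = _decode_token(token, 1)
            offset = int(offset)
        except (TokenError, ValueError, TypeError):
            raise TokenError(f"invalid continuation token {token!r}")
    page = rows[offset : offset + page_size]
    next_token = _encode_token((offset + page_size,)) if offset + page_size < len(rows) else None
    return MappingResult(
        rows=page,
        next_token=next_token,
        unresolved_xrefs=counters.get("unresolved", 0),
        attr_labels=selector.labels if selector else [],
    )
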