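"""Ontology I/O and DAG traversal.

Parses OBO 1.2 flat files into an :class:`OntologyGraph` — GO terms plus typed
parent edges forming a DAG per namespace — and provides the traversal
primitives (ancestors, descendants, depth) that slim mapping builds on.
A subset writer re-emits OBO with parent links contracted to the nearest kept
ancestors, which is how a slim OBO file is published.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional

import networkx as nx

logger = logging.getLogger(__name__)

TERM_ID_PATTERN = re.compile(r"^GO:\d{7}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class OntologyError(Exception):
    """Base class for ontology parsing/validation failures."""


class OboParseError(OntologyError):
    """Malformed OBO content; message names the offending line."""


class CycleError(OntologyError):
    """The graph has a directed cycle under the checked relations."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("cycle detected under {is_a, part_of}: " + " -> ".join(cycle + [cycle[0]]))


class UnknownTermError(OntologyError, KeyError):
    """Lookup of a TermID absent from the graph."""


def validate_term_id(term_id: str) -> str:
    """Return *term_id* unchanged if it is a well-formed GO CURIE, else raise."""
    if not TERM_ID_PATTERN.match(term_id):
        raise OntologyError(f"not a valid GO term id: {term_id!r}")
    return term_id


class RelationType(str, Enum):
    """Edge types between ontology terms.

    Unknown relationship tags parse to ``OTHER``; traversal operations take an
    explicit allowed-relation set, so unmodelled relations are simply inert.
    """

    IS_A = "is_a"
    PART_OF = "part_of"
    REGULATES = "regulates"
    POSITIVELY_REGULATES = "positively_regulates"
    NEGATIVELY_REGULATES = "negatively_regulates"
    OTHER = "other"

    @classmethod
    def from_tag(cls, tag: str) -> "RelationType":
        try:
            return cls(tag)
        except ValueError:
            return cls.OTHER


#: Default traversal relations: the hierarchy edges a slim mapper follows.
#: regulates-family edges are parsed but excluded by default, matching
#: standard slimming practice.
DEFAULT_RELATIONS: frozenset[RelationType] = frozenset({RelationType.IS_A, RelationType.PART_OF})


@dataclass
class OntologyTerm:
    id: str
    name: str = ""
    namespace: str = ""
    definition: str = ""
    synonyms: list[str] = field(default_factory=list)
    is_obsolete: bool = False
    replaced_by: Optional[str] = None
    subsets: list[str] = field(default_factory=list)


Edge = tuple[str, RelationType, str]  # (child, relation, parent)


class OntologyGraph:
    """GO terms plus typed child->parent edges.

    Edges point from child to parent (the direction annotations are mapped
    "up"). The subgraph under {is_a, part_of} is validated acyclic. Obsolete
    terms are retained in the term table (so ``replaced_by`` redirection is
    possible) but carry no edges and are never traversed.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm], edges: Iterable[Edge]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self.edges: set[Edge] = set(edges)
        for child, _rel, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise OntologyError(f"edge endpoint not in term table: ({child}, {parent})")
        # parent adjacency by relation, and the reverse (children) index
        self._parents: dict[str, list[tuple[RelationType, str]]] = {}
        self._children: dict[str, list[tuple[RelationType, str]]] = {}
        for child, rel, parent in sorted(self.edges):
            self._parents.setdefault(child, []).append((rel, parent))
            self._children.setdefault(parent, []).append((rel, child))
        self.roots: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
        for tid, term in self.terms.items():
            if term.is_obsolete:
                continue
            has_hier_parent = any(
                rel in DEFAULT_RELATIONS for rel, _ in self._parents.get(tid, ())
            )
            if not has_hier_parent and term.namespace in self.roots:
                self.roots[term.namespace].add(tid)

    # -- basic accessors -------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"unknown term id: {term_id}") from None

    def parents(self, term_id: str, relations: frozenset[RelationType] = DEFAULT_RELATIONS) -> set[str]:
        self.term(term_id)
        return {p for rel, p in self._parents.get(term_id, ()) if rel in relations}

    def children(self, term_id: str, relations: frozenset[RelationType] = DEFAULT_RELATIONS) -> set[str]:
        self.term(term_id)
        return {c for rel, c in self._children.get(term_id, ()) if rel in relations}

    def all_roots(self) -> set[str]:
        return set().union(*self.roots.values()) if self.roots else set()

    def is_root(self, term_id: str) -> bool:
        return any(term_id in r for r in self.roots.values())

    # -- traversal -------------------------------------------------------

    def ancestors(self, term_id: str, relations: Iterable[RelationType] = DEFAULT_RELATIONS) -> set[str]:
        """All terms reachable from *term_id* via >=1 allowed edge (transitively).

        Excludes the term itself. Mixed-relation composition is permitted: a
        path may chain any edges whose relation is in *relations*.
        """
        relations = frozenset(relations)
        self.term(term_id)
        out: set[str] = set()
        stack = [term_id]
        while stack:
            current = stack.pop()
            for rel, parent in self._parents.get(current, ()):
                if rel in relations and parent not in out:
                    out.add(parent)
                    stack.append(parent)
        return out

    def descendants(self, term_id: str, relations: Iterable[RelationType] = DEFAULT_RELATIONS) -> set[str]:
        """All terms from which *term_id* is reachable (transitive children)."""
        relations = frozenset(relations)
        self.term(term_id)
        out: set[str] = set()
        stack = [term_id]
        while stack:
            current = stack.pop()
            for rel, child in self._children.get(current, ()):
                if rel in relations and child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    def depth(self, term_id: str, relations: frozenset[RelationType] = DEFAULT_RELATIONS) -> int:
        """Longest is_a/part_of path length from *term_id* up to a root.

        The longest path (rather than shortest) scores specificity: a term is
        as deep as its most specific lineage. Roots have depth 0.
        """
        memo: dict[str, int] = {}

        def longest(tid: str) -> int:
            if tid in memo:
                return memo[tid]
            ps = [p for rel, p in self._parents.get(tid, ()) if rel in relations]
            memo[tid] = 0 if not ps else 1 + max(longest(p) for p in ps)
            return memo[tid]

        self.term(term_id)
        return longest(term_id)

    def validate_acyclic(self, relations: frozenset[RelationType] = DEFAULT_RELATIONS) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, rel, p in self.edges if rel in relations)
        try:
            cycle_edges = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return
        raise CycleError([edge[0] for edge in cycle_edges])


# ----------------------------------------------------------------------
# OBO 1.2 parsing

_KNOWN_TAGS = {
    "id", "name", "namespace", "def", "is_a", "relationship", "is_obsolete",
    "replaced_by", "synonym", "subset",
    # common OBO tags we accept but do not model
    "alt_id", "comment", "xref", "consider", "created_by", "creation_date",
    "property_value", "intersection_of", "disjoint_from", "exact_synonym",
}

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _strip_comment(line: str) -> str:
    # OBO trailing comments start with " ! "
    idx = line.find(" ! ")
    if idx >= 0:
        return line[:idx]
    return line[:-2] if line.endswith(" !") else line


def _iter_stanzas(lines: Iterable[str]) -> Iterator[tuple[str, int, list[tuple[int, str, str]]]]:
    """Yield (stanza_type, start_line, [(lineno, tag, value), ...])."""
    stanza_type = ""  # header
    start = 0
    buf: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.startswith("["):
            yield stanza_type, start, buf
            stanza_type = line.strip().strip("[]")
            start, buf = lineno, []
            continue
        line = _strip_comment(line).strip()
        if not line or line.startswith("!"):
            continue
        if ":" not in line:
            raise OboParseError(f"line {lineno}: expected 'tag: value', got {line!r}")
        tag, value = line.split(":", 1)
        buf.append((lineno, tag.strip(), value.strip()))
    yield stanza_type, start, buf


def parse_obo(stream: Iterable[str] | str, strict: bool = False) -> OntologyGraph:
    """Parse OBO 1.2 text into an :class:`OntologyGraph`.

    Parameters
    ----------
    stream:
        OBO text, or any iterable of lines.
    strict:
        When true, unknown tags and dangling edge endpoints raise
        :class:`OboParseError`; otherwise they are ignored with a warning.

    Raises
    ------
    OboParseError
        Stanza without an ``id:`` line (names the stanza's line number).
    CycleError
        The is_a/part_of subgraph has a directed cycle.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()

    terms: dict[str, OntologyTerm] = {}
    raw_edges: list[tuple[str, RelationType, str, int]] = []

    for stanza_type, start, tag_lines in _iter_stanzas(stream):
        if stanza_type != "Term":
            continue
        term = OntologyTerm(id="")
        edges_here: list[tuple[str, RelationType, str, int]] = []
        for lineno, tag, value in tag_lines:
            if tag not in _KNOWN_TAGS:
                if strict:
                    raise OboParseError(f"line {lineno}: unknown tag {tag!r}")
                logger.warning("line %d: ignoring unknown tag %r", lineno, tag)
                continue
            if tag == "id":
                term.id = validate_term_id(value)
            elif tag == "name":
                term.name = value
            elif tag == "namespace":
                term.namespace = value
            elif tag == "def":
                m = _SYNONYM_RE.match(value)
                term.definition = m.group("text") if m else value
            elif tag == "synonym":
                m = _SYNONYM_RE.match(value)
                if m:
                    term.synonyms.append(m.group("text"))
            elif tag == "subset":
                term.subsets.append(value)
            elif tag == "is_obsolete":
                term.is_obsolete = value.lower() == "true"
            elif tag == "replaced_by":
                term.replaced_by = value
            elif tag == "is_a":
                edges_here.append((term.id, RelationType.IS_A, value.split()[0], lineno))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) < 2:
                    raise OboParseError(f"line {lineno}: malformed relationship {value!r}")
                edges_here.append((term.id, RelationType.from_tag(parts[0]), parts[1], lineno))
        if not term.id:
            raise OboParseError(f"line {start}: [Term] stanza has no id")
        # the edge child may have been recorded before the id line appeared
        edges_here = [(term.id, rel, parent, ln) for _c, rel, parent, ln in edges_here]
        if term.is_obsolete:
            edges_here = []  # obsolete terms are edge-less
        terms[term.id] = term
        raw_edges.extend(edges_here)

    edges: set[Edge] = set()
    for child, rel, parent, lineno in raw_edges:
        if parent not in terms:
            if strict:
                raise OboParseError(f"line {lineno}: edge parent {parent} is not a [Term] in this file")
            logger.warning("line %d: dropping edge to undeclared term %s", lineno, parent)
            continue
        if terms[parent].is_obsolete:
            logger.warning("line %d: dropping edge to obsolete term %s", lineno, parent)
            continue
        edges.add((child, rel, parent))

    graph = OntologyGraph(terms, edges)
    graph.validate_acyclic()
    return graph


# ----------------------------------------------------------------------
# OBO subset writing

DEFAULT_SUBSET_NAME = "chembl_protein_target_slim"


def nearest_kept_ancestors(
    graph: OntologyGraph,
    keep: set[str],
    term_id: str,
    relations: frozenset[RelationType] = DEFAULT_RELATIONS,
) -> dict[str, RelationType]:
    """Kept ancestors of *term_id* reachable by a path with no kept interior term.

    Returns {ancestor: composite relation}; the composite is ``is_a`` when some
    qualifying path uses only is_a edges, else ``part_of``.
    """
    out: dict[str, RelationType] = {}
    # state: (node, any part_of on the path so far); prefer all-is_a paths
    seen: dict[tuple[str, bool], None] = {}
    stack: list[tuple[str, bool]] = [(term_id, False)]
    while stack:
        node, mixed = stack.pop()
        for rel, parent in sorted(graph._parents.get(node, ())):
            if rel not in relations:
                continue
            pmixed = mixed or rel != RelationType.IS_A
            if parent in keep and parent != term_id:
                composite = RelationType.PART_OF if pmixed else RelationType.IS_A
                if parent not in out or composite == RelationType.IS_A:
                    out[parent] = composite
                continue  # path interior must stay slim-free
            if (parent, pmixed) not in seen:
                seen[(parent, pmixed)] = None
                stack.append((parent, pmixed))
    return out


def write_obo_subset(
    graph: OntologyGraph,
    keep: set[str],
    subset_name: str = DEFAULT_SUBSET_NAME,
) -> str:
    """Emit OBO 1.2 containing exactly the kept terms.

    Parent links are rewritten to the nearest kept ancestor(s) under
    {is_a, part_of}, skipping dropped intermediates; every kept term is tagged
    with *subset_name*. Term order is sorted by TermID for reproducibility.
    """
    offenders = sorted(
        t for t in keep if t not in graph.terms or graph.terms[t].is_obsolete
    )
    if offenders:
        raise OntologyError(
            "keep set contains unknown or obsolete terms: " + ", ".join(offenders)
        )
    lines = [
        "format-version: 1.2",
        f"subsetdef: {subset_name} \"{subset_name}\"",
        "ontology: go",
    ]
    for tid in sorted(keep):
        term = graph.terms[tid]
        lines += ["", "[Term]", f"id: {tid}", f"name: {term.name}"]
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        if term.definition:
            lines.append(f'def: "{term.definition}" []')
        for syn in term.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        lines.append(f"subset: {subset_name}")
        ancestors = nearest_kept_ancestors(graph, keep, tid)
        for parent in sorted(ancestors):
            rel = ancestors[parent]
            if rel == RelationType.IS_A:
                lines.append(f"is_a: {parent} ! {graph.terms[parent].name}")
            else:
                lines.append(f"relationship: part_of {parent} ! {graph.terms[parent].name}")
    return "\n".join(lines) + "\n"
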