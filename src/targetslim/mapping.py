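"""map2slim semantics: map annotated terms to their slim ancestors and tally
proteins per slim term ("count mode").

The direct mapping rule: a term maps to every slim term reachable by a
directed path (under the slim's relation set) with **no slim term strictly
between** the term and the target. A term already in the slim maps to itself
and nothing else — this is what keeps a granular slim member such as
GO:0017124 "SH3 domain binding" from being generalized up to GO:0005515
"protein binding" when both are in the slim: the more specific term absorbs
its own annotations and information content is preserved.

The inclusive mapping is simpler: every slim term among {self} ∪ ancestors.
A term with multiple qualifying slim ancestors keeps all of them; dropping
co-parents would silently bias the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotations import AnnotationSet
from .ontology import (
    DEFAULT_RELATIONS,
    OntologyError,
    OntologyGraph,
    RelationType,
)


@dataclass
class SlimSet:
    """A named high-level subset of ontology terms, spanning any namespaces."""

    name: str
    terms: set[str]
    relations: frozenset[RelationType] = DEFAULT_RELATIONS

    def validate(self, graph: OntologyGraph) -> None:
        missing = sorted(t for t in self.terms if t not in graph.terms)
        if missing:
            raise OntologyError(f"slim terms not in ontology: {', '.join(missing)}")
        obsolete = sorted(t for t in self.terms if graph.terms[t].is_obsolete)
        if obsolete:
            raise OntologyError(f"slim contains obsolete terms: {', '.join(obsolete)}")

    def content_key(self) -> tuple:
        return (frozenset(self.terms), self.relations)


@dataclass
class SlimMapping:
    """Per-term direct and inclusive slim mappings.

    Invariant: ``direct[t] ⊆ inclusive[t]``; for t in the slim,
    ``direct[t] == {t}``; ``inclusive[t] == slim ∩ ({t} ∪ ancestors(t))``.
    """

    direct: dict[str, set[str]] = field(default_factory=dict)
    inclusive: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class SlimCounts:
    """Distinct-protein tallies per slim term, under both mapping semantics."""

    per_term_direct: dict[str, int] = field(default_factory=dict)
    per_term_inclusive: dict[str, int] = field(default_factory=dict)
    per_term_proteins: dict[str, set[str]] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)  # accessions with no slim mapping


class SlimMapper:
    """Memoized mapper for one (graph, slim) pair.

    Memoization is keyed by slim content, so a mapper built for a refined slim
    never reuses stale results; with memoization disabled the results are
    identical (checked by the self-consistency tests).
    """

    def __init__(self, graph: OntologyGraph, slim: SlimSet, memoize: bool = True):
        slim.validate(graph)
        self.graph = graph
        self.slim = slim
        self.memoize = memoize
        self._direct_cache: dict[str, frozenset[str]] = {}

    def map_term(self, term: str) -> set[str]:
        """Direct slim mapping of *term* (see module docstring for the rule)."""
        self.graph.term(term)
        # a per-call memo keeps single-call work linear; only the persistent
        # cross-call cache is governed by the memoize flag
        memo = self._direct_cache if self.memoize else {}
        return set(self._direct(term, memo))

    def _direct(self, term: str, memo: dict[str, frozenset[str]]) -> frozenset[str]:
        if term in memo:
            return memo[term]
        if term in self.slim.terms:
            result = frozenset({term})
        else:
            out: set[str] = set()
            for parent in self.graph.parents(term, self.slim.relations):
                if parent in self.slim.terms:
                    out.add(parent)  # path ends here; interior stays slim-free
                else:
                    out |= self._direct(parent, memo)
            result = frozenset(out)
        memo[term] = result
        return result

    def map_inclusive(self, term: str) -> set[str]:
        """All slim terms among {term} ∪ ancestors(term)."""
        self.graph.term(term)
        reachable = {term} | self.graph.ancestors(term, self.slim.relations)
        return reachable & self.slim.terms

    def map_all(self, terms: Iterable[str]) -> SlimMapping:
        mapping = SlimMapping()
        for t in terms:
            mapping.direct[t] = self.map_term(t)
            mapping.inclusive[t] = self.map_inclusive(t)
        return mapping


def map_term(graph: OntologyGraph, slim: SlimSet, term: str) -> set[str]:
    """Direct slim mapping of a single term (convenience wrapper)."""
    return SlimMapper(graph, slim).map_term(term)


def map_all(graph: OntologyGraph, slim: SlimSet, terms: Iterable[str]) -> SlimMapping:
    """Direct and inclusive mappings for every input term, one traversal each."""
    return SlimMapper(graph, slim).map_all(terms)


def count_mode(
    graph: OntologyGraph,
    slim: SlimSet,
    annotations: AnnotationSet,
    mapper: Optional[SlimMapper] = None,
) -> SlimCounts:
    """Tally distinct proteins per slim term.

    ``per_term_direct[s]``: proteins with ≥1 annotation whose direct mapping
    contains s; ``per_term_inclusive[s]``: same under the inclusive mapping.
    Slim terms nobody maps to appear with count 0; accessions mapping to no
    slim term at all are tracked in ``unmapped`` for coverage reporting.
    """
    mapper = mapper or SlimMapper(graph, slim)
    direct_proteins: dict[str, set[str]] = {s: set() for s in slim.terms}
    inclusive_proteins: dict[str, set[str]] = {s: set() for s in slim.terms}
    unmapped: set[str] = set()
    mapping = mapper.map_all(annotations.terms())
    for accession, terms in annotations.terms_by_accession().items():
        hit = False
        for t in terms:
            for s in mapping.direct[t]:
                direct_proteins[s].add(accession)
            for s in mapping.inclusive[t]:
                inclusive_proteins[s].add(accession)
                hit = True
        if not hit:
            unmapped.add(accession)
    return SlimCounts(
        per_term_direct={s: len(p) for s, p in direct_proteins.items()},
        per_term_inclusive={s: len(p) for s, p in inclusive_proteins.items()},
        per_term_proteins=inclusive_proteins,
        unmapped=unmapped,
    )


# ----------------------------------------------------------------------
# Slim file I/O: OBO subset files or plain term lists

def read_slim_text(stream: Iterable[str] | str, name: str = "slim") -> SlimSet:
    """Read a plain-text slim: one TermID per line, '#' comments."""
    if isinstance(stream, str):
        stream = stream.splitlines()
    terms: set[str] = set()
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if line:
            terms.add(line)
    return SlimSet(name=name, terms=terms)


def slim_from_obo_subset(graph: OntologyGraph, subset_name: str) -> SlimSet:
    """Collect the terms carrying *subset_name* in their ``subset:`` tags."""
    terms = {t.id for t in graph.terms.values() if subset_name in t.subsets and not t.is_obsolete}
    return SlimSet(name=subset_name, terms=terms)
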