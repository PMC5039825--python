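"""Browsable slim tree with per-node protein counts and keyword search.

The slim, restricted to its own members, induces a hierarchy: slim term *s*
is a child of slim term *p* when *p* is a slim ancestor of *s* with no slim
term strictly between them (the same nearest-ancestor rule the mapper uses).
A DAG node with several slim parents is rendered under each of them —
navigation trees cannot show a node once — with counts computed once and
shared between occurrences.

Displayed counts are cumulative (node plus slim descendants), so the number
next to e.g. "response to toxic substance" includes proteins annotated only
to its child "response to antibiotic"; the direct tallies are retained on
each node for side-by-side reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .annotations import AnnotationSet
from .mapping import SlimMapper, SlimSet
from .ontology import NAMESPACES, OntologyGraph, UnknownTermError


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    term: str
    name: str
    namespace: str
    children: list["TreeNode"] = field(default_factory=list)
    direct_proteins: set[str] = field(default_factory=set)
    cumulative_proteins: set[str] = field(default_factory=set)

    @property
    def cumulative_count(self) -> int:
        return len(self.cumulative_proteins)

    @property
    def direct_count(self) -> int:
        return len(self.direct_proteins)


@dataclass
class TargetTree:
    roots: dict[str, TreeNode]  # namespace -> synthetic root node
    index: dict[str, set[str]]  # lowercase token -> term ids
    names: dict[str, str]  # term -> display name
    synonyms: dict[str, list[str]]
    cumulative: dict[str, set[str]]  # term -> cumulative protein set (shared)

    def node_terms(self) -> set[str]:
        return set(self.cumulative)


def _slim_parents(graph: OntologyGraph, slim: SlimSet, term: str) -> set[str]:
    """Slim ancestors of *term* with no slim term strictly between (computed
    against slim ∖ {term}, so a slim member still finds its own parents)."""
    others = SlimSet(name=slim.name, terms=slim.terms - {term}, relations=slim.relations)
    return SlimMapper(graph, others).map_term(term) - {term}


def build_tree(graph: OntologyGraph, slim: SlimSet, annotations: AnnotationSet) -> TargetTree:
    """Build the slim-induced protein target tree.

    ``direct_proteins`` of a slim term are the accessions with ≥1 annotation
    whose direct slim mapping contains it; cumulative sets are unions down
    each subtree. Slim terms with no slim ancestor attach to their namespace
    root node. Children sort by (descending cumulative count, TermID).
    """
    if not slim.terms:
        raise TreeError("cannot build a tree from an empty slim")
    slim.validate(graph)
    mapper = SlimMapper(graph, slim)

    direct: dict[str, set[str]] = {s: set() for s in slim.terms}
    inclusive: dict[str, set[str]] = {s: set() for s in slim.terms}
    for accession, terms in annotations.terms_by_accession().items():
        for t in terms:
            for s in mapper.map_term(t):
                direct[s].add(accession)
            for s in mapper.map_inclusive(t):
                inclusive[s].add(accession)

    parents: dict[str, set[str]] = {s: _slim_parents(graph, slim, s) for s in slim.terms}
    children: dict[str, set[str]] = {s: set() for s in slim.terms}
    for s, ps in parents.items():
        for p in ps:
            children[p].add(s)

    # cumulative protein sets over the slim hierarchy (computed once, shared
    # between duplicated occurrences of multi-parent terms)
    cumulative: dict[str, set[str]] = {}

    def cum(s: str, seen: frozenset[str]) -> set[str]:
        if s in cumulative:
            return cumulative[s]
        out = set(direct[s])
        for c in sorted(children[s]):
            if c not in seen:  # defensive; slim hierarchy is acyclic
                out |= cum(c, seen | {s})
        cumulative[s] = out
        return out

    for s in sorted(slim.terms):
        cum(s, frozenset())

    def make_node(s: str) -> TreeNode:
        node = TreeNode(
            term=s,
            name=graph.terms[s].name,
            namespace=graph.terms[s].namespace,
            direct_proteins=set(direct[s]),
            cumulative_proteins=cumulative[s],
        )
        kids = [make_node(c) for c in children[s]]
        kids.sort(key=lambda n: (-n.cumulative_count, n.term))
        node.children = kids
        return node

    roots: dict[str, TreeNode] = {}
    top_by_ns: dict[str, list[str]] = {}
    for s in sorted(slim.terms):
        if not parents[s]:
            top_by_ns.setdefault(graph.terms[s].namespace, []).append(s)
    for ns in NAMESPACES:
        if ns not in top_by_ns:
            continue
        root_terms = sorted(graph.roots.get(ns, set()))
        root_id = root_terms[0] if root_terms else ns
        root_name = graph.terms[root_id].name if root_id in graph.terms else ns
        root = TreeNode(term=root_id, name=root_name, namespace=ns)
        root.children = [make_node(s) for s in top_by_ns[ns]]
        root.children.sort(key=lambda n: (-n.cumulative_count, n.term))
        for child in root.children:
            root.cumulative_proteins |= child.cumulative_proteins
        roots[ns] = root

    index: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    for s in slim.terms:
        term = graph.terms[s]
        names[s] = term.name
        synonyms[s] = list(term.synonyms)
        for text in [term.name, *term.synonyms]:
            for token in text.lower().split():
                index.setdefault(token, set()).add(s)

    return TargetTree(roots=roots, index=index, names=names, synonyms=synonyms, cumulative=cumulative)


def search(tree: TargetTree, query: str) -> list[tuple[str, str, int]]:
    """Case-insensitive substring search over node names and synonyms.

    Returns (TermID, name, cumulative_count) rows sorted by descending count,
    then TermID.
    """
    q = query.strip().lower()
    if not q:
        raise TreeError("search query is empty")
    hits = []
    for term, name in tree.names.items():
        haystacks = [name.lower()] + [s.lower() for s in tree.synonyms.get(term, [])]
        if any(q in h for h in haystacks):
            hits.append((term, name, len(tree.cumulative[term])))
    hits.sort(key=lambda row: (-row[2], row[0]))
    return hits


def proteins_for_node(tree: TargetTree, term: str) -> set[str]:
    """Accessions annotated to *term* or any slim descendant (cumulative set).

    Namespace root nodes return every covered protein in that namespace.
    """
    if term in tree.cumulative:
        return set(tree.cumulative[term])
    for root in tree.roots.values():
        if root.term == term:
            return set(root.cumulative_proteins)
    raise UnknownTermError(f"term not in tree: {term}")


def _node_to_dict(node: TreeNode) -> dict:
    return {
        "term": node.term,
        "name": node.name,
        "namespace": node.namespace,
        "direct_count": node.direct_count,
        "cumulative_count": node.cumulative_count,
        "direct_proteins": sorted(node.direct_proteins),
        "cumulative_proteins": sorted(node.cumulative_proteins),
        "children": [_node_to_dict(c) for c in node.children],
    }


def _node_from_dict(d: dict) -> TreeNode:
    return TreeNode(
        term=d["term"],
        name=d["name"],
        namespace=d["namespace"],
        direct_proteins=set(d["direct_proteins"]),
        cumulative_proteins=set(d["cumulative_proteins"]),
        children=[_node_from_dict(c) for c in d["children"]],
    )


def export_tree(tree: TargetTree) -> str:
    """Canonical JSON serialization: sorted keys, fixed separators, stable
    node order — byte-identical across repeated exports."""
    payload = {
        "roots": {ns: _node_to_dict(tree.roots[ns]) for ns in sorted(tree.roots)},
        "names": tree.names,
        "synonyms": tree.synonyms,
        "cumulative": {t: sorted(p) for t, p in tree.cumulative.items()},
    }
    return json.dumps(payload, sort_keys=True, indent=1, separators=(",", ": ")) + "\n"


def import_tree(text: str) -> TargetTree:
    """Reload a tree exported by :func:`export_tree`."""
    payload = json.loads(text)
    tree = TargetTree(
        roots={ns: _node_from_dict(d) for ns, d in payload["roots"].items()},
        index={},
        names=payload["names"],
        synonyms={t: list(s) for t, s in payload["synonyms"].items()},
        cumulative={t: set(p) for t, p in payload["cumulative"].items()},
    )
    for term, name in tree.names.items():
        for text_ in [name, *tree.synonyms.get(term, [])]:
            for token in text_.lower().split():
                tree.index.setdefault(token, set()).add(term)
    return tree


def trees_equal(a: TargetTree, b: TargetTree) -> bool:
    """Structural equality of two trees (export canonical forms)."""
    return export_tree(a) == export_tree(b)
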