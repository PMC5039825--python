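"""Shared fixtures and independent oracles.

The oracles here deliberately use naive algorithms (all-paths enumeration,
boolean-matrix transitive closure, power-set tallies) so they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest

from targetslim import (
    AnnotationSet,
    OntologyGraph,
    OntologyTerm,
    RelationType,
    SlimSet,
    motif_fixture,
    parse_gaf,
    parse_obo,
)

# ----------------------------------------------------------------------
# Hand-built toy DAG used throughout: D is_a C is_a B is_a A,
# F is_a E, F part_of C, E is_a B (all biological_process).

TOY_EDGES = [
    ("D", RelationType.IS_A, "C"),
    ("C", RelationType.IS_A, "B"),
    ("B", RelationType.IS_A, "A"),
    ("F", RelationType.IS_A, "E"),
    ("F", RelationType.PART_OF, "C"),
    ("E", RelationType.IS_A, "B"),
]

TOY_IDS = {name: f"GO:000000{i}" for i, name in enumerate("ABCDEF", start=1)}


def toy_graph() -> OntologyGraph:
    terms = {
        tid: OntologyTerm(id=tid, name=f"toy term {letter}", namespace="biological_process")
        for letter, tid in TOY_IDS.items()
    }
    edges = [(TOY_IDS[c], rel, TOY_IDS[p]) for c, rel, p in TOY_EDGES]
    return OntologyGraph(terms, edges)


def toy_slim(letters: str = "BC") -> SlimSet:
    return SlimSet(name="toy", terms={TOY_IDS[x] for x in letters})


def toy_annotations(assignments: dict[str, str]) -> AnnotationSet:
    """assignments: accession -> toy letter; builds a minimal AnnotationSet."""
    from targetslim.annotations import Annotation

    records = [
        Annotation(
            db="UniProtKB", accession=acc, symbol=acc, qualifiers=frozenset(),
            term=TOY_IDS[letter], evidence="IDA", aspect="P", taxon=9606,
            date="2016-01-01", assigned_by="test",
        )
        for acc, letter in sorted(assignments.items())
    ]
    return AnnotationSet(records=records, provenance="toy")


@pytest.fixture(scope="session")
def toy():
    return toy_graph()


@pytest.fixture(scope="session")
def motif():
    """Parsed hand-written motif ontology + annotations."""
    obo_text, gaf_text = motif_fixture()
    graph = parse_obo(obo_text)
    annotations = parse_gaf(gaf_text, graph)
    return graph, annotations


# ----------------------------------------------------------------------
# Random DAG construction (independent of the fixtures module)

def random_dag(
    rng: random.Random,
    n_terms: int = 30,
    max_parents: int = 3,
    part_of_fraction: float = 0.3,
) -> OntologyGraph:
    """Random rooted DAG: term i's parents are drawn among terms < i, so the
    child->parent direction can never close a cycle."""
    ids = [f"GO:90{i:05d}" for i in range(n_terms)]
    terms = {
        tid: OntologyTerm(id=tid, name=f"random term {i}", namespace="biological_process")
        for i, tid in enumerate(ids)
    }
    edges = []
    for i in range(1, n_terms):
        for parent in rng.sample(ids[:i], min(i, rng.randint(1, max_parents))):
            rel = RelationType.PART_OF if rng.random() < part_of_fraction else RelationType.IS_A
            edges.append((ids[i], rel, parent))
    return OntologyGraph(terms, set(edges))


# ----------------------------------------------------------------------
# Oracles

def oracle_map_term(graph: OntologyGraph, slim: SlimSet, term: str) -> set[str]:
    """Literal all-paths map2slim oracle: enumerate every directed path from
    *term* and keep slim endpoints reached with a slim-free interior."""
    if term in slim.terms:
        return {term}
    out: set[str] = set()
    stack: list[list[str]] = [[term]]
    while stack:
        path = stack.pop()
        for parent in graph.parents(path[-1], slim.relations):
            if any(x in slim.terms for x in path[1:]):
                continue  # interior already contains a slim term
            if parent in slim.terms:
                out.add(parent)
                # any longer path through this parent has it in the interior,
                # so no endpoint beyond it can qualify
                continue
            stack.append(path + [parent])
    return out


def oracle_ancestors(graph: OntologyGraph, term: str, relations) -> set[str]:
    """Transitive closure by repeated boolean-matrix squaring."""
    ids = sorted(graph.terms)
    pos = {t: i for i, t in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for child, rel, parent in graph.edges:
        if rel in relations:
            adj[pos[child], pos[parent]] = True
    closure = adj.copy()
    for _ in range(int(np.ceil(np.log2(max(n, 2))))):
        closure = closure | (closure @ closure)
    return {ids[j] for j in np.nonzero(closure[pos[term]])[0]}


def oracle_venn(per_drug: dict[str, frozenset[str]], categories: list[str]) -> dict[frozenset[str], int]:
    """Power-set brute force over category subsets."""
    out: dict[frozenset[str], int] = {}
    for r in range(1, len(categories) + 1):
        for combo in itertools.combinations(sorted(categories), r):
            region = frozenset(combo)
            count = sum(1 for covered in per_drug.values() if covered == region)
            if count:
                out[region] = count
    return out
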