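"""Coverage measurement and iterative slim refinement.

The published workflow for building a protein-target slim is a loop: tally
proteins per candidate slim term, drop terms that map nobody, add terms that
would capture the still-unmapped proteins, and repeat until the slim covers a
target fraction (90% by default) of the annotated protein set. Curators ran
that loop by hand; this module automates it as a reproducible greedy
heuristic and keeps a report-only path for human-in-the-loop use.

A protein counts as *covered* when at least one of its annotations maps
inclusively to a non-root slim term — crediting namespace roots would make
100% coverage trivially achievable with zero information.

The information-content report flags overly generic slim terms:
ic(s) = −log2(fraction of annotated proteins inclusively mapped to s).
A near-zero ic marks a term like "protein binding" that absorbs almost
everything; the curatorial response is to keep its granular children in the
slim instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .annotations import AnnotationSet
from .mapping import SlimCounts, SlimMapper, SlimSet, count_mode
from .ontology import OntologyGraph


class ValidationError(ValueError):
    pass


@dataclass
class NamespaceCoverage:
    n_proteins: int
    n_covered: int

    @property
    def coverage(self) -> float:
        return self.n_covered / self.n_proteins if self.n_proteins else 0.0


@dataclass
class CoverageReport:
    target_coverage: float
    per_namespace: dict[str, NamespaceCoverage]
    overall_coverage: float
    n_proteins: int
    n_covered: int
    unmapped: set[str]
    zero_count_terms: set[str]
    counts: SlimCounts

    @property
    def at_target(self) -> bool:
        return self.overall_coverage >= self.target_coverage


@dataclass(frozen=True)
class TermSuggestion:
    term: str
    gain: int  # currently-unmapped proteins newly covered
    depth: int  # longest is_a/part_of path to a root
    n_descendant_terms_absorbed: int


@dataclass
class InformationReport:
    per_term: dict[str, float]  # slim term -> ic, zero-count terms omitted
    low_ic_terms: set[str]
    threshold: float


def _covering_terms(graph: OntologyGraph, slim: SlimSet, term: str) -> set[str]:
    """Non-root slim terms that inclusively cover an annotation to *term*."""
    reachable = {term} | graph.ancestors(term, slim.relations)
    return {t for t in reachable & slim.terms if not graph.is_root(t)}


def coverage(
    graph: OntologyGraph,
    slim: SlimSet,
    annotations: AnnotationSet,
    target: float = 0.90,
    mapper: Optional[SlimMapper] = None,
) -> CoverageReport:
    """Measure how much of the annotated protein set the slim covers.

    Per-namespace coverage counts a protein in each namespace where it has
    ≥1 annotation; overall coverage is over distinct accessions.
    """
    if not 0.0 <= target <= 1.0:
        raise ValidationError(f"target coverage must be in [0, 1], got {target}")
    slim.validate(graph)
    counts = count_mode(graph, slim, annotations, mapper=mapper)

    non_root_slim = {s for s in slim.terms if not graph.is_root(s)}
    covered: set[str] = set()
    per_ns_proteins: dict[str, set[str]] = {}
    per_ns_covered: dict[str, set[str]] = {}
    by_accession = annotations.terms_by_accession()
    incl_cache: dict[str, set[str]] = {}
    for accession, terms in by_accession.items():
        for t in terms:
            if t not in incl_cache:
                reachable = {t} | graph.ancestors(t, slim.relations)
                incl_cache[t] = reachable & non_root_slim
            ns = graph.terms[t].namespace
            per_ns_proteins.setdefault(ns, set()).add(accession)
            if incl_cache[t]:
                covered.add(accession)
                per_ns_covered.setdefault(ns, set()).add(accession)

    n_proteins = len(by_accession)
    per_namespace = {
        ns: NamespaceCoverage(
            n_proteins=len(prots), n_covered=len(per_ns_covered.get(ns, set()))
        )
        for ns, prots in sorted(per_ns_proteins.items())
    }
    zero_count = {s for s in slim.terms if counts.per_term_inclusive[s] == 0}
    return CoverageReport(
        target_coverage=target,
        per_namespace=per_namespace,
        overall_coverage=len(covered) / n_proteins if n_proteins else 0.0,
        n_proteins=n_proteins,
        n_covered=len(covered),
        unmapped=set(by_accession) - covered,
        zero_count_terms=zero_count,
        counts=counts,
    )


def prune_zero_terms(slim: SlimSet, report: CoverageReport) -> SlimSet:
    """Drop slim terms with inclusive count 0; coverage is unchanged by
    construction (the removed terms covered nobody)."""
    return SlimSet(
        name=slim.name,
        terms=slim.terms - report.zero_count_terms,
        relations=slim.relations,
    )


def suggest_terms(
    graph: OntologyGraph,
    slim: SlimSet,
    annotations: AnnotationSet,
    target: float = 0.90,
    max_suggestions: int = 100,
) -> list[TermSuggestion]:
    """Greedy high-yield additions to the slim.

    Repeats until coverage reaches *target*, no candidate gains ≥1 protein, or
    *max_suggestions* picks: among all non-slim, non-root, non-obsolete terms,
    pick the one covering the most currently-unmapped proteins; ties break to
    the greater depth (prefer the more specific term), then the smaller
    TermID. Each pick is committed before the next iteration.
    """
    if not 0.0 <= target <= 1.0:
        raise ValidationError(f"target coverage must be in [0, 1], got {target}")
    report = coverage(graph, slim, annotations, target)
    n_proteins = report.n_proteins
    if n_proteins == 0:
        return []

    # for each unmapped protein: every non-root term whose addition covers it
    protein_candidates: dict[str, set[str]] = {}
    by_accession = annotations.terms_by_accession()
    self_up_cache: dict[str, set[str]] = {}
    for accession in sorted(report.unmapped):
        cands: set[str] = set()
        for t in by_accession[accession]:
            if t not in self_up_cache:
                up = {t} | graph.ancestors(t, slim.relations)
                self_up_cache[t] = {
                    c for c in up
                    if not graph.is_root(c) and not graph.terms[c].is_obsolete
                }
            cands |= self_up_cache[t]
        protein_candidates[accession] = cands - slim.terms

    suggestions: list[TermSuggestion] = []
    n_covered = report.n_covered
    uncovered = set(protein_candidates)
    while uncovered and len(suggestions) < max_suggestions:
        if n_proteins and n_covered / n_proteins >= target:
            break
        gains: dict[str, int] = {}
        for accession in uncovered:
            for c in protein_candidates[accession]:
                gains[c] = gains.get(c, 0) + 1
        if not gains:
            break
        best = min(gains, key=lambda c: (-gains[c], -graph.depth(c, slim.relations), c))
        gained = {a for a in uncovered if best in protein_candidates[a]}
        suggestions.append(
            TermSuggestion(
                term=best,
                gain=gains[best],
                depth=graph.depth(best, slim.relations),
                n_descendant_terms_absorbed=len(graph.descendants(best, slim.relations)),
            )
        )
        uncovered -= gained
        n_covered += len(gained)
    return suggestions


def information_report(
    graph: OntologyGraph,
    slim: SlimSet,
    annotations: AnnotationSet,
    ic_threshold: float,
) -> InformationReport:
    """Annotation-frequency information content per slim term (base-2 log)."""
    if ic_threshold < 0:
        raise ValidationError(f"ic_threshold must be >= 0, got {ic_threshold}")
    counts = count_mode(graph, slim, annotations)
    n = len(annotations.accessions())
    per_term: dict[str, float] = {}
    for s in sorted(slim.terms):
        k = counts.per_term_inclusive[s]
        if k == 0 or n == 0:
            continue  # ic undefined for zero-count terms
        per_term[s] = -math.log2(k / n)
    return InformationReport(
        per_term=per_term,
        low_ic_terms={s for s, ic in per_term.items() if ic < ic_threshold},
        threshold=ic_threshold,
    )


def refine(
    graph: OntologyGraph,
    slim0: SlimSet,
    annotations: AnnotationSet,
    target: float = 0.90,
    max_rounds: int = 10,
    max_suggestions_per_round: int = 100,
) -> tuple[SlimSet, list[CoverageReport]]:
    """Iterative slim refinement: alternate pruning and greedy addition.

    Each round prunes zero-count terms, then commits a batch of suggested
    terms. Stops when coverage reaches *target*, a round changes nothing, or
    *max_rounds* is exhausted. Returns the final slim and the per-round
    coverage trail (non-decreasing by construction).
    """
    if max_rounds < 1:
        raise ValidationError(f"max_rounds must be >= 1, got {max_rounds}")
    slim = SlimSet(name=slim0.name, terms=set(slim0.terms), relations=slim0.relations)
    report = coverage(graph, slim, annotations, target)
    trail = [report]
    if report.at_target:
        return slim, trail
    for _ in range(max_rounds):
        before = set(slim.terms)
        slim = prune_zero_terms(slim, report)
        suggestions = suggest_terms(
            graph, slim, annotations, target, max_suggestions=max_suggestions_per_round
        )
        slim.terms.update(s.term for s in suggestions)
        report = coverage(graph, slim, annotations, target)
        trail.append(report)
        if report.at_target or slim.terms == before:
            break
    return slim, trail
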