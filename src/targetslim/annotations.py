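"""GAF annotation parsing, filtering and summarization.

A GAF (Gene Association File) row is an evidence-tagged assertion linking a
protein accession to a GO term. The parser accepts the 17-column GAF 2.1/2.2
tab-separated dialect, applies configurable filters (NOT-qualified rows,
evidence whitelists, obsolete-term redirection via ``replaced_by``), and
collapses exact duplicates on (accession, qualifiers, term, evidence, taxon).

Protein identity is the column-2 accession alone; isoform suffixes in
column 17 are ignored, matching accession-keyed single-protein targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .ontology import OntologyGraph, UnknownTermError

logger = logging.getLogger(__name__)

GAF_COLUMNS = 17

#: GAF aspect letter -> ontology namespace
ASPECT_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class GafParseError(Exception):
    """Malformed GAF content; message carries the line number."""


@dataclass(frozen=True)
class Annotation:
    db: str
    accession: str
    symbol: str
    qualifiers: frozenset[str]
    term: str
    evidence: str
    aspect: str
    taxon: int
    date: str
    assigned_by: str

    @property
    def key(self) -> tuple:
        """Duplicate-collapse identity (evidence-inclusive, symbol-exclusive)."""
        return (self.accession, self.qualifiers, self.term, self.evidence, self.taxon)


@dataclass
class AnnotationSet:
    records: list[Annotation]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def accessions(self) -> set[str]:
        return {r.accession for r in self.records}

    def terms(self) -> set[str]:
        return {r.term for r in self.records}

    def terms_by_accession(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(r.accession, set()).add(r.term)
        return out


@dataclass
class AnnotationSummary:
    n_proteins: int
    n_terms: int
    n_annotations: int
    n_proteins_with_annotation: int
    per_taxon: dict[int, int] = field(default_factory=dict)


def _parse_taxon(value: str) -> int:
    # e.g. "taxon:9606" or "taxon:9606|taxon:10090" -> 9606
    first = value.split("|")[0].strip()
    if first.lower().startswith("taxon:"):
        first = first[6:]
    return int(first) if first else 0


def _normalize_date(value: str) -> str:
    v = value.strip()
    if len(v) == 8 and v.isdigit():  # GAF native YYYYMMDD
        return f"{v[0:4]}-{v[4:6]}-{v[6:8]}"
    return v


def parse_gaf(
    stream: Iterable[str] | str,
    graph: OntologyGraph,
    drop_not: bool = True,
    evidence_whitelist: Optional[set[str]] = None,
    remap_obsolete: bool = True,
    strict: bool = False,
    provenance: str = "",
) -> AnnotationSet:
    """Parse GAF 2.1/2.2 text into a validated :class:`AnnotationSet`.

    Filters applied per row, in a commuting order:

    * rows whose qualifier set contains ``NOT`` are dropped when *drop_not*
      (negative assertions must not feed slim counts);
    * rows failing *evidence_whitelist* are dropped; the default (``None``)
      keeps every evidence code;
    * rows annotating obsolete terms are redirected through ``replaced_by``
      when *remap_obsolete* and a replacement exists, else dropped with a
      warning;
    * rows to terms absent from *graph* are dropped with a warning
      (:class:`UnknownTermError` in strict mode);
    * exact duplicates on (accession, qualifiers, term, evidence, taxon)
      collapse to one record.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()

    records: list[Annotation] = []
    seen: set[tuple] = set()
    filters = [f"drop_not={drop_not}", f"evidence_whitelist={sorted(evidence_whitelist) if evidence_whitelist else None}",
               f"remap_obsolete={remap_obsolete}"]

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) not in (GAF_COLUMNS, GAF_COLUMNS - 2):  # tolerate 15-col GAF 1.0
            raise GafParseError(
                f"line {lineno}: expected {GAF_COLUMNS} tab-separated columns, got {len(cols)}"
            )
        qualifiers = frozenset(q for q in cols[3].split("|") if q)
        if drop_not and "NOT" in qualifiers:
            continue
        evidence = cols[6].strip()
        if evidence_whitelist is not None and evidence not in evidence_whitelist:
            continue
        term_id = cols[4].strip()
        if term_id not in graph.terms:
            if strict:
                raise UnknownTermError(f"line {lineno}: unknown term {term_id}")
            logger.warning("line %d: dropping annotation to unknown term %s", lineno, term_id)
            continue
        term = graph.terms[term_id]
        if term.is_obsolete:
            if remap_obsolete and term.replaced_by and term.replaced_by in graph.terms:
                term_id = term.replaced_by
            else:
                logger.warning(
                    "line %d: dropping annotation to obsolete term %s (no replacement)",
                    lineno, term_id,
                )
                continue
        aspect = cols[8].strip()
        expected_ns = ASPECT_NAMESPACE.get(aspect)
        if expected_ns and graph.terms[term_id].namespace and graph.terms[term_id].namespace != expected_ns:
            # tolerate upstream aspect/namespace inconsistencies without data loss
            logger.warning(
                "line %d: aspect %s conflicts with namespace %s of %s",
                lineno, aspect, graph.terms[term_id].namespace, term_id,
            )
        record = Annotation(
            db=cols[0],
            accession=cols[1],
            symbol=cols[2],
            qualifiers=qualifiers,
            term=term_id,
            evidence=evidence,
            aspect=aspect,
            taxon=_parse_taxon(cols[12]) if len(cols) > 12 else 0,
            date=_normalize_date(cols[13]) if len(cols) > 13 else "",
            assigned_by=cols[14] if len(cols) > 14 else "",
        )
        if not record.accession:
            raise GafParseError(f"line {lineno}: empty accession column")
        if record.key in seen:
            continue
        seen.add(record.key)
        records.append(record)

    return AnnotationSet(records=records, provenance=f"{provenance} [{'; '.join(filters)}]".strip())


def write_gaf(annotations: AnnotationSet) -> str:
    """Emit the records back as GAF 2.1 (fixture round-trips)."""
    lines = ["!gaf-version: 2.1"]
    for r in annotations.records:
        cols = [
            r.db, r.accession, r.symbol, "|".join(sorted(r.qualifiers)), r.term,
            "GO_REF:0000000", r.evidence, "", r.aspect, "", "", "protein",
            f"taxon:{r.taxon}", r.date.replace("-", ""), r.assigned_by, "", "",
        ]
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def summarize(annotations: AnnotationSet) -> AnnotationSummary:
    """Count distinct proteins, terms and records, plus per-taxon protein tallies."""
    accessions = annotations.accessions()
    per_taxon_sets: dict[int, set[str]] = {}
    for r in annotations.records:
        per_taxon_sets.setdefault(r.taxon, set()).add(r.accession)
    return AnnotationSummary(
        n_proteins=len(accessions),
        n_terms=len(annotations.terms()),
        n_annotations=len(annotations.records),
        n_proteins_with_annotation=len(accessions),
        per_taxon={t: len(s) for t, s in sorted(per_taxon_sets.items())},
    )
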