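"""Link drugs to GO slim categories of their mechanism-of-action targets.

Reproduces the case-study computation: select drugs by ATC class (WHO
Anatomical Therapeutic Chemical codes, hierarchical with levels of 1, 3, 4,
5 and 7 characters), collect their curated efficacy (mechanism-of-action)
targets, map each target's annotations into chosen slim categories, and
report Venn-style disjoint region counts — each drug lands in exactly the
region equal to the full set of categories its targets cover — plus the
mechanism-of-action breakdown of any drug subset.

Inputs are flat tab-separated tables (drugs, mechanisms, targets), not a
live database; attribution goes through mechanism targets only, never all
assayed targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .annotations import AnnotationSet
from .mapping import SlimMapper, SlimSet
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

#: Valid ATC code/prefix lengths (classification level boundaries).
ATC_LEVEL_LENGTHS = (1, 3, 4, 5, 7)


class AtcError(ValueError):
    pass


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    atc_codes: frozenset[str]


@dataclass(frozen=True)
class MechanismRecord:
    drug_id: str
    target_accession: str
    action: str


@dataclass
class CategoryMembership:
    categories: list[str]
    per_drug: dict[str, frozenset[str]]  # drug -> covered category set (non-empty)
    per_region: dict[frozenset[str], int]  # exact covered set -> drug count


# ----------------------------------------------------------------------
# Table I/O (tab-separated, single header row)

def read_drug_table(path_or_buf) -> list[DrugRecord]:
    """Read the drugs table: drug_id, name, pipe-separated ATC codes."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        codes = frozenset(c.strip().upper() for c in row.atc_codes.split("|") if c.strip())
        records.append(DrugRecord(drug_id=row.drug_id, name=row.name, atc_codes=codes))
    return records


def read_mechanism_table(path_or_buf) -> list[MechanismRecord]:
    """Read the mechanisms table: drug_id, accession, action."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str, keep_default_na=False)
    return [
        MechanismRecord(drug_id=r.drug_id, target_accession=r.accession, action=r.action)
        for r in df.itertuples(index=False)
    ]


def read_target_table(path_or_buf) -> pd.DataFrame:
    """Read the targets table: accession, taxid, organism."""
    return pd.read_csv(path_or_buf, sep="\t", dtype={"accession": str, "organism": str, "taxid": int},
                       keep_default_na=False)


# ----------------------------------------------------------------------

def validate_atc_prefix(atc_prefix: str) -> str:
    prefix = atc_prefix.strip().upper()
    if len(prefix) not in ATC_LEVEL_LENGTHS:
        raise AtcError(
            f"ATC prefix {atc_prefix!r} has length {len(prefix)}; "
            f"valid level lengths are {ATC_LEVEL_LENGTHS}"
        )
    return prefix


def drugs_for_atc(drugs: Iterable[DrugRecord], atc_prefix: str) -> set[str]:
    """Drug ids having ≥1 ATC code starting with *atc_prefix*."""
    prefix = validate_atc_prefix(atc_prefix)
    return {
        d.drug_id for d in drugs if any(code.startswith(prefix) for code in d.atc_codes)
    }


def targets_for_atc(
    drugs: Iterable[DrugRecord],
    mechanisms: Iterable[MechanismRecord],
    atc_prefix: str,
) -> set[str]:
    """Accessions of mechanism targets of drugs in the given ATC class.

    Prefix matching respects ATC level boundaries (lengths 1/3/4/5/7), so
    "L" selects the whole antineoplastic/immunomodulating class while "L0"
    is rejected rather than silently over-matching.
    """
    selected = drugs_for_atc(drugs, atc_prefix)
    return {m.target_accession for m in mechanisms if m.drug_id in selected}


def category_membership(
    target_accessions: set[str],
    annotations: AnnotationSet,
    graph: OntologyGraph,
    slim: SlimSet,
    categories: list[str],
    mechanisms: Iterable[MechanismRecord],
) -> CategoryMembership:
    """Assign drugs to Venn regions over the chosen slim categories.

    A target covers category *c* iff *c* is in the inclusive slim mapping of
    ≥1 of its annotation terms; a drug's covered set is the union over its
    mechanism targets (restricted to *target_accessions*); each drug with a
    non-empty covered set is counted in exactly one region — the one equal to
    its full covered set — so region counts partition the categorized drugs.
    """
    missing = sorted(set(categories) - slim.terms)
    if missing:
        raise ValueError(f"categories not in slim: {', '.join(missing)}")
    mapper = SlimMapper(graph, slim)
    category_set = set(categories)

    target_categories: dict[str, set[str]] = {}
    for accession, terms in annotations.terms_by_accession().items():
        if accession not in target_accessions:
            continue
        covered: set[str] = set()
        for t in terms:
            covered |= mapper.map_inclusive(t) & category_set
        target_categories[accession] = covered

    per_drug_all: dict[str, set[str]] = {}
    for m in mechanisms:
        if m.target_accession in target_accessions:
            per_drug_all.setdefault(m.drug_id, set()).update(
                target_categories.get(m.target_accession, set())
            )

    per_drug = {d: frozenset(c) for d, c in per_drug_all.items() if c}
    per_region: dict[frozenset[str], int] = {}
    for covered in per_drug.values():
        per_region[covered] = per_region.get(covered, 0) + 1
    return CategoryMembership(
        categories=list(categories), per_drug=per_drug, per_region=per_region
    )


def mechanism_breakdown(
    drug_ids: set[str], mechanisms: Iterable[MechanismRecord]
) -> dict[str, int]:
    """Distinct drugs per mechanism-of-action label among *drug_ids*.

    A drug with two actions counts once per action; drugs absent from the
    mechanisms table contribute nothing (logged).
    """
    per_action: dict[str, set[str]] = {}
    seen: set[str] = set()
    for m in mechanisms:
        if m.drug_id in drug_ids:
            per_action.setdefault(m.action, set()).add(m.drug_id)
            seen.add(m.drug_id)
    for missing in sorted(drug_ids - seen):
        logger.warning("drug %s has no mechanism records", missing)
    return {action: len(ds) for action, ds in sorted(per_action.items())}


def format_venn(membership: CategoryMembership, names: Mapping[str, str]) -> str:
    """Venn regions as TSV: one row per region, category names '+'-joined."""
    lines = ["region\tn_drugs"]
    rows = []
    for region, count in membership.per_region.items():
        label = "+".join(sorted(names.get(c, c) for c in region))
        rows.append((label, count))
    for label, count in sorted(rows, key=lambda r: (-r[1], r[0])):
        lines.append(f"{label}\t{count}")
    return "\n".join(lines) + "\n"
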