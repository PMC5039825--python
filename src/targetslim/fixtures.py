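"""Synthetic ontologies, GAF files and drug tables with controllable shape.

Every other module is testable without any download: the generator emits a
valid OBO 1.2 ontology (a rooted DAG per namespace), a GAF 2.1 annotation
file over synthetic proteins, and the three drug-link tables. One seeded
generator drives all randomness — identical spec + seed gives byte-identical
outputs — and synthetic TermIDs use a reserved prefix ("GO:9" + 6 digits) so
they can never collide with real GO identifiers.

:func:`motif_fixture` is the exception: a small hand-written ontology that
reuses real GO identifiers verbatim (protein binding / SH3 domain binding;
response to toxic substance / response to antibiotic; a diamond; a mixed
is_a/part_of path) so worked examples read like the live ontology.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .ontology import NAMESPACES, OntologyGraph

NS_OFFSET = {"biological_process": 0, "molecular_function": 1, "cellular_component": 2}

EVIDENCE_CODES = ("IEA", "IDA", "IMP", "ISS", "TAS", "IPI")

ACTION_VOCABULARY = (
    "protein kinase inhibitor",
    "growth factor receptor antagonist",
    "enzyme inhibitor",
    "receptor agonist",
    "receptor antagonist",
    "ion channel blocker",
)


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Shape parameters for synthetic inputs.

    Defaults emulate a desk-scale slice of an annotated drug-target corpus:
    a few hundred terms per namespace, ~1000 proteins averaging 4 annotations
    each and biased toward specific (leaf) terms, a human-dominated taxon
    mix, and a drug set slanted toward the antineoplastic ATC class L.
    """

    seed: int = 0
    n_terms: int = 200  # per namespace
    max_depth: int = 8
    branching: float = 3.0  # mean children per term
    multiparent_fraction: float = 0.2
    n_proteins: int = 1000
    annotations_per_protein: float = 4.0  # Poisson mean, min 1
    specificity_bias: float = 0.7  # fraction of annotations to leaf terms
    taxa: list[tuple[int, float]] = field(
        default_factory=lambda: [(9606, 0.55), (10116, 0.15), (10090, 0.15), (562, 0.1), (4932, 0.05)]
    )
    n_drugs: int = 50
    targets_per_drug: float = 2.0  # mean, min 1
    atc_classes: list[tuple[str, float]] = field(
        default_factory=lambda: [("L01XE01", 0.4), ("L04AB02", 0.2), ("N02BA01", 0.2), ("C07AB03", 0.1), ("P01BA02", 0.1)]
    )
    namespaces: tuple[str, ...] = NAMESPACES

    def validate(self) -> None:
        if self.n_terms < 1:
            raise FixtureError("n_terms must be >= 1 per namespace")
        if self.branching <= 0 and self.n_terms > 1 and self.max_depth > 1:
            raise FixtureError("impossible shape: branching 0 with n_terms > 1 and max_depth > 1")
        for frac in (self.multiparent_fraction, self.specificity_bias):
            if not 0.0 <= frac <= 1.0:
                raise FixtureError(f"fraction out of [0,1]: {frac}")
        for count in (self.n_proteins, self.n_drugs):
            if count < 0:
                raise FixtureError(f"negative count: {count}")


def _term_id(namespace: str, index: int) -> str:
    # reserved synthetic prefix GO:9 + namespace digit + 5-digit index
    return f"GO:9{NS_OFFSET[namespace]}{index:05d}"


def _poisson_min1(rng: random.Random, mean: float) -> int:
    # inversion sampling keeps the only RNG the one seeded generator
    import math

    if mean <= 1:
        return 1
    l_exp = math.exp(-(mean - 1))
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= l_exp:
            return 1 + k
        k += 1


def _weighted_choice(rng: random.Random, options: list[tuple]) -> object:
    total = sum(w for _, w in options)
    x = rng.random() * total
    for value, w in options:
        x -= w
        if x <= 0:
            return value
    return options[-1][0]


def make_ontology(spec: FixtureSpec) -> str:
    """Generate OBO 1.2 text: one rooted DAG per namespace.

    Terms are laid down level by level; each non-root term gets one is_a
    parent drawn from shallower terms, and a ``multiparent_fraction`` of
    terms get an extra is_a or part_of parent, producing the diamonds that
    exercise multi-path mapping.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    lines = ["format-version: 1.2", "ontology: go-synthetic"]

    for ns in spec.namespaces:
        ids = [_term_id(ns, i) for i in range(spec.n_terms)]
        depth = {ids[0]: 0}
        parents: dict[str, list[tuple[str, str]]] = {ids[0]: []}
        for i in range(1, spec.n_terms):
            tid = ids[i]
            eligible = [t for t in ids[:i] if depth[t] < spec.max_depth - 1]
            if not eligible:
                eligible = [ids[0]]
            parent = rng.choice(eligible)
            parents[tid] = [("is_a", parent)]
            depth[tid] = depth[parent] + 1
            if rng.random() < spec.multiparent_fraction and i >= 2:
                extra_pool = [t for t in ids[:i] if t != parent]
                if extra_pool:
                    extra = rng.choice(extra_pool)
                    rel = "is_a" if rng.random() < 0.5 else "part_of"
                    # avoid a cycle: only link to strictly shallower or equal
                    # depth terms generated earlier (indices only go up, so the
                    # child->parent direction can never close a loop)
                    parents[tid].append((rel, extra))
        for i, tid in enumerate(ids):
            lines += ["", "[Term]", f"id: {tid}"]
            lines.append(f"name: synthetic {ns.replace('_', ' ')} term {i}")
            lines.append(f"namespace: {ns}")
            for rel, parent in parents[tid]:
                if rel == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: part_of {parent}")
    return "\n".join(lines) + "\n"


def make_gaf(spec: FixtureSpec, graph: OntologyGraph) -> str:
    """Generate GAF 2.1 annotating synthetic proteins to terms of *graph*.

    Accessions run P000001... ; each protein draws Poisson(min 1) annotation
    terms, with ``specificity_bias`` of draws taken from leaves; taxa are
    sampled by weight per protein.
    """
    spec.validate()
    rng = random.Random(spec.seed + 1)
    aspect = {"biological_process": "P", "molecular_function": "F", "cellular_component": "C"}
    non_root = sorted(t for t in graph.terms if not graph.is_root(t) and not graph.terms[t].is_obsolete)
    leaves = sorted(t for t in non_root if not graph.children(t))
    if not non_root:
        non_root = sorted(graph.terms)
        leaves = non_root
    if not leaves:
        leaves = non_root

    lines = ["!gaf-version: 2.1", "!generated synthetic annotation fixture"]
    for i in range(1, spec.n_proteins + 1):
        accession = f"P{i:06d}"
        taxon = _weighted_choice(rng, spec.taxa)
        n_ann = _poisson_min1(rng, spec.annotations_per_protein)
        chosen: set[str] = set()
        for _ in range(n_ann):
            pool = leaves if rng.random() < spec.specificity_bias else non_root
            chosen.add(rng.choice(pool))
        for term in sorted(chosen):
            ns = graph.terms[term].namespace
            cols = [
                "UniProtKB", accession, f"GENE{i}", "", term, "GO_REF:0000002",
                rng.choice(EVIDENCE_CODES), "", aspect.get(ns, "P"),
                f"synthetic protein {i}", "", "protein", f"taxon:{taxon}",
                "20160101", "SynthDB", "", "",
            ]
            lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def make_drug_tables(spec: FixtureSpec, accessions: set[str]) -> tuple[str, str, str]:
    """Generate (drugs, mechanisms, targets) TSV texts.

    Each drug gets ≥1 ATC code sampled by weight and Poisson(min 1)
    mechanism rows over the given accessions, with action labels from a
    small fixed vocabulary.
    """
    spec.validate()
    if spec.n_drugs >= 1 and not accessions:
        raise FixtureError("accessions must be non-empty when n_drugs >= 1")
    rng = random.Random(spec.seed + 2)
    pool = sorted(accessions)

    drug_lines = ["drug_id\tname\tatc_codes"]
    mech_lines = ["drug_id\taccession\taction"]
    used: set[str] = set()
    for i in range(1, spec.n_drugs + 1):
        drug_id = f"D{i:04d}"
        codes = {_weighted_choice(rng, spec.atc_classes)}
        if rng.random() < 0.2:
            codes.add(_weighted_choice(rng, spec.atc_classes))
        drug_lines.append(f"{drug_id}\tsynthetic drug {i}\t{'|'.join(sorted(codes))}")
        n_targets = min(_poisson_min1(rng, spec.targets_per_drug), len(pool))
        for accession in sorted(rng.sample(pool, n_targets)):
            mech_lines.append(f"{drug_id}\t{accession}\t{rng.choice(ACTION_VOCABULARY)}")
            used.add(accession)

    target_lines = ["accession\ttaxid\torganism"]
    organism = {9606: "Homo sapiens", 10116: "Rattus norvegicus", 10090: "Mus musculus",
                562: "Escherichia coli", 4932: "Saccharomyces cerevisiae"}
    for accession in sorted(used):
        taxid = _weighted_choice(rng, spec.taxa)
        target_lines.append(f"{accession}\t{taxid}\t{organism.get(taxid, 'synthetic organism')}")
    return (
        "\n".join(drug_lines) + "\n",
        "\n".join(mech_lines) + "\n",
        "\n".join(target_lines) + "\n",
    )


MOTIF_OBO = """\
format-version: 1.2
ontology: go-motif

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0050896
name: response to stimulus
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0042221
name: response to chemical
namespace: biological_process
is_a: GO:0050896

[Term]
id: GO:0009636
name: response to toxic substance
namespace: biological_process
synonym: "response to toxin" EXACT []
is_a: GO:0042221

[Term]
id: GO:0046677
name: response to antibiotic
namespace: biological_process
is_a: GO:0009636

[Term]
id: GO:0098754
name: detoxification
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0097237
name: cellular response to toxic substance
namespace: biological_process
is_a: GO:0009636
relationship: part_of GO:0098754

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0005488
name: binding
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0005515
name: protein binding
namespace: molecular_function
is_a: GO:0005488

[Term]
id: GO:0017124
name: SH3 domain binding
namespace: molecular_function
is_a: GO:0005515

[Term]
id: GO:0019899
name: enzyme binding
namespace: molecular_function
is_a: GO:0005515

[Term]
id: GO:0019900
name: kinase binding
namespace: molecular_function
is_a: GO:0019899
is_a: GO:0005515

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0005622
name: intracellular anatomical structure
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0005634
name: nucleus
namespace: cellular_component
relationship: part_of GO:0005622
"""

_MOTIF_ROWS = [
    # (accession, symbol, term, evidence, aspect, taxon)
    ("P12931", "SRC", "GO:0017124", "IDA", "F", 9606),
    ("P00519", "ABL1", "GO:0005515", "IPI", "F", 9606),
    ("P00519", "ABL1", "GO:0005634", "IDA", "C", 9606),
    ("P04040", "CAT", "GO:0009636", "IDA", "P", 9606),
    ("P04040", "CAT", "GO:0098754", "IDA", "P", 9606),
    ("P08263", "GSTA1", "GO:0097237", "IDA", "P", 9606),
    ("P0A9Q5", "AMPC", "GO:0046677", "IEA", "P", 562),
    ("Q9UNE7", "STUB1", "GO:0019900", "IDA", "F", 9606),
    ("P62993", "GRB2", "GO:0017124", "IPI", "F", 9606),
]


def motif_gaf() -> str:
    lines = ["!gaf-version: 2.1"]
    for accession, symbol, term, evidence, aspect, taxon in _MOTIF_ROWS:
        cols = [
            "UniProtKB", accession, symbol, "", term, "GO_REF:0000002",
            evidence, "", aspect, symbol, "", "protein", f"taxon:{taxon}",
            "20160101", "UniProt", "", "",
        ]
        lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def motif_fixture() -> tuple[str, str]:
    """Hand-written ~16-term motif ontology and matching GAF.

    Contains the classic slimming motifs: GO:0005515 "protein binding" with
    granular child GO:0017124 "SH3 domain binding" (the information-content
    guard case), GO:0009636 "response to toxic substance" with child
    GO:0046677 "response to antibiotic" (the keyword-search case), a diamond
    (GO:0019900 under both GO:0019899 and GO:0005515) and a mixed
    is_a/part_of path (GO:0097237 part_of GO:0098754).
    """
    return MOTIF_OBO, motif_gaf()
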