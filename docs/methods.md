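# Methods

## The slimming model

A GO slim is a small, high-level subset of the Gene Ontology used to
summarize an annotation corpus: each fine-grained annotated term is "mapped
up" to slim ancestors and gene products are tallied per slim term. This
package implements that workflow for a drug-target setting — the annotated
entities are protein accessions (single-protein targets), and the slim's
purpose is to give a browsable, searchable categorisation of target biology
and to join those categories to drug classifications (ATC) and curated
mechanism-of-action targets.

The ontology is modelled as a DAG per namespace with typed child→parent
edges. Traversal operations take an explicit allowed-relation set; the
default is `{is_a, part_of}`, the hierarchy relations conventional slimming
tools follow. `regulates`-family edges are parsed and retained but excluded
from default traversal: following them would conflate regulation with
subsumption and inflate counts. The flag `--relations` overrides this.

### The direct (map2slim) mapping rule

For a slim S and annotated term t, the *direct* mapping of t is

* `{t}` if t ∈ S — a slim member absorbs its own annotations and is never
  generalized further. This is the information-content guard: with both
  "SH3 domain binding" (GO:0017124) and "protein binding" (GO:0005515) in
  the slim, SH3-binding proteins stay at the granular term;
* otherwise, every s ∈ S reachable from t by a directed path (allowed
  relations only) whose *interior* contains no slim term. A term with
  several qualifying slim ancestors keeps all of them; collapsing to an
  arbitrary single parent would silently bias counts.

The implementation is the recursive nearest-slim-ancestor decomposition
(direct(t) = ∪ over parents p of `{p}` if p ∈ S else direct(p)), memoized
per slim content so refinement loops stay fast; the memo is an optimization
only and results are identical with it disabled. Tests compare it against a
literal all-paths oracle on thousands of random DAGs.

The *inclusive* mapping is `S ∩ ({t} ∪ ancestors(t))`. Count mode reports
distinct-protein tallies per slim term under both semantics side by side —
the direct count is never larger than the inclusive one — because published
per-term counts do not always say which convention they use.

## Coverage and refinement

A protein is *covered* when at least one of its annotations maps
inclusively to a **non-root** slim term. Crediting namespace roots would
make 100% coverage trivial and meaningless, so roots never count. Coverage
is reported per namespace (over proteins annotated in that namespace) and
overall (over distinct accessions); the 0.90 default target is interpreted
as overall coverage.

Slim refinement automates what is normally a curatorial loop, as a
reproducible greedy heuristic. Each round:

1. **prune** slim terms with inclusive count 0 (coverage provably
   unchanged);
2. **suggest & commit** additions greedily: among all non-slim, non-root,
   non-obsolete terms, repeatedly pick the term covering the most
   currently-unmapped proteins; ties break to the greater depth — depth
   being the *longest* is_a/part_of path to a root, preferring the more
   specific term — then to the lexicographically smaller TermID. Each pick
   is committed before gains are recomputed.

The loop stops at the coverage target, on a fixed point, or at
`max_rounds`. The per-round coverage trail is non-decreasing by
construction. When every annotated protein has at least one non-root
ancestor the greedy provably reaches any target ≤ 1.0 given enough rounds
(each iteration covers ≥ 1 protein). A report-only mode emits suggestions
without committing them, for human-in-the-loop curation.

The information-content report flags overly generic slim terms:
ic(s) = −log₂(k/n) with k = distinct proteins inclusively mapped to s and
n = distinct annotated proteins. ic = 0 exactly when every protein maps to
the term; ic is undefined (omitted) for zero-count terms. Base 2 is a
presentation choice — any base is equivalent up to scale — so thresholds
are documented in bits.

## Target tree and search

The slim induces a hierarchy by the same nearest-ancestor rule: slim term p
is a parent of slim term s when p is a slim ancestor of s reachable with no
slim term strictly between (computed against S ∖ {s}). A multi-parent slim
term is rendered under *each* slim parent — a navigation tree cannot
display a DAG node once — with protein sets computed once and shared, so
duplicated occurrences always show identical counts. Terms with no slim
ancestor attach to their namespace root node.

Displayed counts are cumulative (node ∪ slim descendants), matching the
convention that the number next to a category includes its children; direct
counts are kept alongside. Search is case-insensitive substring match over
names and synonyms — deterministic and testable, no stemming or fuzziness.
The serialization is canonical JSON (sorted keys, fixed separators, stable
child order by descending cumulative count then TermID), byte-identical
across exports and reloadable to an equal tree.

## Drug links

Drugs carry WHO ATC codes (levels at 1/3/4/5/7 characters); selection by
class is prefix match restricted to those lengths, so "L" is valid but "L0"
is rejected rather than over-matching. Drug→category attribution goes only
through curated mechanism-of-action targets, not all assayed targets. A
drug's covered set is the union of categories covered by its mechanism
targets (a target covers a category iff the category is in the inclusive
mapping of ≥ 1 of its annotations); Venn regions are the standard disjoint
counts — each categorized drug lands in exactly the region equal to its
full covered set, so region counts partition the categorized drugs. The
five categories are a required user parameter, never hard-coded: which five
process categories to display is an analytical choice, not a property of
the method.

## Synthetic fixtures

The generator emulates a desk-scale slice of an annotated target corpus:

* ontology: per namespace a rooted DAG built by attaching each new term to
  a random shallower parent (is_a), with a `multiparent_fraction` (default
  0.2) of terms given a second is_a/part_of parent to create diamonds;
  defaults 200 terms/namespace, max depth 8;
* annotations: 1000 proteins, Poisson(4, min 1) annotation terms each,
  with 70% of draws biased to leaves (real annotation corpora skew
  specific); taxa sampled from a human-dominated weight table; evidence
  codes drawn uniformly from a small set including IEA;
* drug tables: 50 drugs, ≥ 1 ATC code each sampled from a weight table
  slanted to class L, Poisson(2, min 1) mechanism targets with action
  labels from a fixed vocabulary including "protein kinase inhibitor".

What the generator does **not** model: realistic GO topology (term-depth
and fan-in distributions), realistic evidence-code mixes, annotation
redundancy along lineages, or correlated drug polypharmacology. Passing
tests therefore demonstrate the algorithms' correctness and invariants, not
quantitative agreement with any specific GO/ChEMBL release — release-level
figures (total targets, per-species tallies, specific Venn counts) depend
on database snapshots and are out of scope.

All randomness flows from one `random.Random(seed)` per artifact; identical
spec + seed gives byte-identical files. Synthetic TermIDs use the reserved
prefix `GO:9…` so they cannot collide with the real GO IDs used in the
hand-written motif fixture.

## Numerical and edge-case choices

* Coverage of an empty protein set is 0, not NaN.
* Obsolete terms are kept in the term table (enabling `replaced_by`
  redirection of annotations) but are edge-less, never traversed, and
  rejected in slims and subset exports.
* GAF duplicate collapse key is (accession, qualifiers, term, evidence,
  taxon): the same assertion with two evidence codes is two annotations,
  one protein, one term.
* Aspect/namespace conflicts in GAF rows are kept but logged — upstream
  inconsistencies should not silently drop data.
* Subset export contracts parent links to nearest kept ancestors; the
  contracted edge is `is_a` when some qualifying path is all-is_a, else
  `part_of` (is_a∘part_of composes to part_of). Only is_a/part_of edges are
  emitted; term order is sorted by TermID for bit-reproducibility.
* All tabular outputs are tab-separated with one header row; all CLI output
  is byte-deterministic given fixed inputs and seed.

## Problem sizes

The verification suite and `scripts/acceptance.py` use: 1000 (tests) / 400
(script) random DAGs of ≤ 50 terms with slims of ≤ 10 terms for
mapper-oracle equivalence; 500 proteins for count-mode tallies; 3 × 200
terms and 1000 proteins for refinement to the 0.90 target; 100 random-term
trials for coverage monotonicity; 5 categories × 50 drugs for the Venn
partition. These sizes give exhaustive per-term checking while keeping the
whole suite under a minute of compute.

## Known limitations

* The greedy refinement is not a minimum set cover; it reproduces the
  *procedure* (rounds of pruning and high-yield addition to a coverage
  target), not any particular published slim's term list, which embodies
  manual curation decisions that are not recoverable from rules.
* The IC report operationalizes "loss of information content" as a
  threshold on annotation-frequency IC; where a curator draws that line is
  a judgement call, so the threshold is a parameter.
* `intersection_of` logical definitions, GPAD/GPI, annotation extensions
  (GAF column 16) and taxon constraints are out of scope.
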