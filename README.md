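# targetslim

GO-slim construction and browsing for drug target space.

Protein drug targets are annotated with Gene Ontology (GO) terms of wildly
varying specificity, which makes it hard to compare, group, or search a
target database by biology. The standard remedy is a **GO slim**: a small
set of high-level terms onto which every fine-grained annotation is mapped
via the ontology's `is_a`/`part_of` hierarchy. `targetslim` implements that
workflow end to end for drug-discovery target sets:

* parse OBO 1.2 ontologies and GAF 2.1/2.2 annotation files;
* map annotated terms to slim ancestors with **map2slim semantics** — a
  term maps directly to every slim term reachable by a path with no slim
  term strictly in between, and a slim member maps only to itself (so a
  granular slim term such as *SH3 domain binding* is never generalized up
  to *protein binding* and its information content is preserved);
* tally distinct proteins per slim term ("count mode"), under both direct
  and inclusive semantics;
* **refine** a slim iteratively — prune terms that map no proteins, greedily
  add the terms that capture the most unmapped proteins — until the slim
  covers a target fraction (default 90%) of the annotated protein set;
* expose the result as a **searchable protein-target tree** with per-node
  cumulative protein counts;
* link GO category groupings of targets to **drug ATC classes and
  mechanisms of action**: select drugs by ATC prefix, map their curated
  efficacy targets into chosen slim categories, and report disjoint
  Venn-region drug counts and mechanism breakdowns.

It is aimed at cheminformaticians and ontology engineers who maintain or
analyze annotated target corpora, and everything runs from flat text files
(OBO, GAF, TSV) — no database or web service required. A seeded fixtures
module generates realistic synthetic inputs so the whole pipeline is
testable offline.

## The core rule

For a slim S, ontology DAG G and annotated term t (relations restricted to
an allowed set, default `{is_a, part_of}`):

```
direct(t)    = {t}                                        if t ∈ S
             = { s ∈ S : ∃ path t → … → s in G with
                 no slim term strictly between t and s }  otherwise
inclusive(t) = S ∩ ({t} ∪ ancestors(t))
```

Count mode reports, per slim term s, the number of distinct protein
accessions with ≥ 1 annotation whose direct (resp. inclusive) mapping
contains s. A protein is *covered* by the slim when some annotation maps
inclusively to a non-root slim term; refinement drives overall coverage to
the target. Slim-term information content is ic(s) = −log₂(k/n) over
inclusively mapped (k) vs all annotated (n) proteins, flagging overly
generic terms.

## Worked example

The package ships a small hand-written ontology/annotation fixture built
around two classic motifs: *protein binding* ⊃ *SH3 domain binding* and
*response to toxic substance* ⊃ *response to antibiotic*.

```sh
python - <<'EOF'
from targetslim.fixtures import motif_fixture
obo, gaf = motif_fixture()
open('motif.obo','w').write(obo); open('motif.gaf','w').write(gaf)
open('slim.txt','w').write(
    "GO:0009636\nGO:0046677\nGO:0005515\nGO:0017124\nGO:0005634\n")
EOF
targetslim slim-count --obo motif.obo --gaf motif.gaf --slim slim.txt
```

prints

```
term	name	namespace	direct_count	inclusive_count
GO:0005515	protein binding	molecular_function	2	4
GO:0005634	nucleus	cellular_component	1	1
GO:0009636	response to toxic substance	biological_process	2	3
GO:0017124	SH3 domain binding	molecular_function	2	2
GO:0046677	response to antibiotic	biological_process	1	1
```

Read this as: the two SH3-binding proteins stay counted at GO:0017124 (its
direct count equals its inclusive count — they are never mapped up), while
GO:0005515's inclusive count of 4 absorbs them plus the kinase-binding
protein; GO:0009636's inclusive count of 3 includes the protein annotated
only to its child GO:0046677. Coverage and search:

```sh
targetslim slim-coverage --obo motif.obo --gaf motif.gaf --slim slim.txt
# n_proteins 7, overall_coverage 1.0000, at_target true, ...
targetslim tree-build --obo motif.obo --gaf motif.gaf --slim slim.txt --out tree.json
targetslim tree-search --tree tree.json --query "toxic substance"
```

```
term	name	cumulative_count
GO:0009636	response to toxic substance	3
```

— the cumulative count of 3 includes the antibiotic-response protein in the
child node. Other subcommands: `slim-map`, `slim-refine` (iterative
refinement to `--target` coverage, or `--report-only` suggestions),
`drug-venn --atc L --categories GO:...,GO:...` (drug counts per category
region), and `fixtures make` (synthetic inputs).

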