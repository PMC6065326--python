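# tptnp — targets–(pathways)–targets network pharmacology

`tptnp` identifies candidate therapeutic targets of a multi-component
intervention (typically a herbal formula with hundreds of putative protein
targets) from two flat tables: target–pathway annotations and
pathway–disease links. Instead of inspecting a hairball of
targets–pathways–diseases relations directly, the method:

1. **projects** the bipartite target–pathway annotation onto a one-mode
   **TPT network** — targets are nodes, and an edge joins two targets
   annotated to at least one common pathway (the edge carries the set of
   shared pathways; its weight is their count);
2. **partitions** the network into modules with the Louvain modularity
   algorithm (default resolution 1.0, seedable);
3. **scores** each module's contribution to each disease. If pathway
   *p<sub>w</sub>* is incident to *u<sub>w</sub>* modules, each incident
   module receives 1/*u<sub>w</sub>* of it; if disease *d<sub>j</sub>* is
   linked to *v<sub>j</sub>* pathways, each carries 1/*v<sub>j</sub>* of
   the disease. The **contribution score** is

   CS(*m<sub>i</sub>*, *d<sub>j</sub>*) = Σ<sub>p<sub>w</sub> ∈ X<sub>ij</sub></sub> (1/*u<sub>w</sub>*)(1/*v<sub>j</sub>*),

   where X<sub>ij</sub> is the set of pathways incident to *m<sub>i</sub>*
   and relevant to *d<sub>j</sub>*. CS ∈ [0, 1] and sums to exactly 1 over
   modules for every disease whose pathways are present in the network;
   a chi-square test on the module × disease pathway-link counts validates
   the module–disease association;
4. **ranks** the targets of the selected module by the integrated
   **target importance**

   TI<sub>i</sub> = ¼ (DC<sub>i</sub>/max DC + BC<sub>i</sub>/max BC + CC<sub>i</sub>/max CC + EC<sub>i</sub>/max EC),

   the mean of degree, betweenness, closeness and eigenvector centrality,
   each normalised by its maximum over the module, and keeps the top
   fraction (default 10 %, ceiling rounding). Approved-drug ATC level-1
   classes and predicted compound–target pairs can be attached for
   validation and interpretation.

An optional hypergeometric over-representation stage (Benjamini–Hochberg
FDR < 0.01 by default) filters the annotation to significantly enriched
pathways first.

## Worked example

The package ships the small three-module worked example used to
demonstrate the scoring algorithm: 24 targets in groups of 9/8/7, pathways
p1–p2 private to group 1, p3 and p4 single edges joining group 1 to groups
2 and 3, p5 touching all three groups, and disease d1 linked to p1–p5.

```sh
tptnp simulate --fig7 --out demo/data
tptnp run --annotation demo/data/annotation.tsv \
          --pathway-disease demo/data/pathway_disease.tsv \
          --relevant-diseases d1 --seed 42 --out demo/out
cat demo/out/contribution_scores.tsv
```

```
module_id	d1
1	0.6666666666666666
2	0.16666666666666666
3	0.16666666666666666
```

Module 1 carries two private pathways (1/u = 1 each), half of p3 and p4
and a third of p5, each scaled by 1/v = 1/5: CS(m1, d1) = 2/3. Modules 2
and 3 each get 1/6, and the three scores sum to 1 — the whole of d1's
pathway support, split between modules. Module 1 is therefore selected,
and its nine targets are ranked by TI (`demo/out/ti_ranking.tsv`):

```
rank	target_id	dc	bc	cc	ec	ti
1	T-A1	8.0	0.0	1.0	0.3333333333333333	0.75
2	T-A2	8.0	0.0	1.0	0.3333333333333333	0.75
...
```

Group 1's induced subgraph is a 9-clique, so all four centralities tie
(betweenness is 0 everywhere and contributes 0 while the denominator
stays 4, hence TI = 0.75 for every node) and the top-10 % selection keeps
ceil(0.1 × 9) = 1 target.

The same stages are importable as a library (`tptnp.build_tpt`,
`tptnp.detect_modules`, `tptnp.contribution_scores`,
`tptnp.target_importance`, …) and individually as subcommands
(`simulate`, `enrich`, `network`, `modules`, `score`, `rank`).

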