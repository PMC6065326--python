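# Methods

## Model and procedure

The pipeline treats a target–pathway annotation as a bipartite graph and
analyses its one-mode projection, the TPT network: nodes are protein
targets; an edge joins two targets iff they share at least one pathway,
labelled with the shared-pathway set and weighted by its size. Targets
annotated only to singleton pathways remain as isolated nodes — they are
kept (as singleton modules after partitioning) so that the contribution
normalisation below stays exact.

Modules are found by Louvain modularity optimisation (networkx
implementation). Edge weights (shared-pathway counts) are used by default;
an unweighted mode is provided since either convention is defensible for
projected graphs. Module labels are canonicalised — consecutive integers
ordered by descending module size, ties by smallest member id — so
partitions from different runs and seeds are directly comparable.

The contribution score distributes each disease's pathway support over
modules. A pathway p incident to u[p] modules gives 1/u[p] to each;
a disease d linked to v[d] pathways receives 1/v[d] from each; hence

    CS(m, d) = sum over p in X(m, d) of (1/u[p]) * (1/v[d])

with X(m, d) the pathways incident to m and relevant to d. Incidence is
defined by *membership* (module m touches p iff some target of m is
annotated to p), not by intra-module edges: a pathway realised as a single
inter-module edge is incident to both endpoint modules, which is what the
worked example's arithmetic requires. u is indexed by pathway only — the
count of incident modules does not depend on the focal module. CS is
computed in exact rational arithmetic (`fractions.Fraction`); floats
appear only at export. Consequently the conservation property
Σ_m CS(m, d) = 1 is exact (not a tolerance) whenever all of d's pathways
are present in the network; pathways absent from the network keep their
slot in v but contribute nothing, so such diseases sum below 1, and a
disease none of whose pathways map is omitted with a warning.

Coarsening note: merging two modules adds their CS values exactly only
when they share no pathway. If they do, u drops for the shared pathways
and *every* incident module's share changes, so CS is not additive under
arbitrary coarsening; the test suite asserts the disjoint-incidence case.

Module–disease association is validated with a Pearson chi-square test of
independence. Chi-square needs count data, and the natural integer
backbone of the score is the pathway-link count |X(m, d)|, so the default
contingency table holds those counts (the builder is pluggable). Rows and
columns with zero margins are dropped; a resulting table smaller than 2×2
is reported as infeasible rather than tested. Yates continuity correction
is off by default (uncorrected Pearson is the usual choice for m×n
tables) and available as a flag for 2×2 tables.

Drug-based validation abbreviates each approved drug's ATC code to
level 1 (the first character, A–V: the organ/system class) and counts, per
module and per class, the distinct network targets with at least one drug
of that class. A target with drugs in several classes counts once in each
class — the class tallies are reported independently. A chi-square on the
module × class table tests whether drugged targets concentrate in
particular modules.

Within the selected module (largest mean CS over the diseases of
interest; ties go to the smallest module id), targets are ranked by

    TI_i = (DC_i/max_DC + BC_i/max_BC + CC_i/max_CC + EC_i/max_EC) / 4

with maxima taken over the module's targets. TI ∈ [0, 1], reaching 1 iff
a target attains all four maxima, and is invariant under rescaling any one
raw centrality column. A centrality whose module-wide maximum is 0
(e.g. betweenness on a clique) contributes 0 for every node while the
denominator stays 4, keeping TI defined on degenerate modules. The final
selection keeps the first ceil(fraction × n) targets (so 199 targets at
10 % give 20).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `resolution` | 1.0 | Louvain resolution; 1.0 is plain modularity |
| `random_seed` | 0 | seeds Louvain node order and data generation |
| `fdr_threshold` | 0.01 | BH FDR cutoff of the enrichment filter (strict `<`) |
| `top_fraction` | 0.1 | fraction of module targets kept, ceiling rounding |
| `edge_weighting` | shared_pathway_count | Louvain edge weights; `unweighted` available |
| `centrality_scope` | module_subgraph | graph on which centralities are computed |

Centralities default to the module-induced subgraph because TI normalises
by the maximum *within the therapeutic module* and the ranking concerns
that module's internal topology; `full_network` scope is provided because
computing them on the whole TPT network before within-module
normalisation is equally coherent, and the two can disagree for targets
carrying inter-module edges. Centralities treat edges as unweighted by
default; the weighted mode uses the shared-pathway count as connection
strength (degree, eigenvector) and its reciprocal as distance (closeness,
betweenness). Closeness is the inverse mean shortest-path distance within
a node's connected component; eigenvector centrality is power iteration
to tolerance 1e-8, at most 1000 iterations, with a convergence error
otherwise.

The over-representation stage is a one-sided hypergeometric test (upper
tail, P(overlap ≥ observed)) with BH correction across all tested
pathways. The universe defaults to the annotated targets; a larger
`universe_size` models unannotated background genes. The stage is
optional — a pre-filtered annotation can be supplied directly.

## Synthetic data

Two generators make every stage testable without database downloads.

`fig7_fixture` is the worked example: 24 targets in groups of 9/8/7.
Pathways p1 (all of group 1) and p2 (five group-1 targets) are private to
group 1; p3 is a single edge joining one group-1 and one group-2 target;
p4 a single edge joining one group-1 and one group-3 target; p5 touches
one target of each group; disease d1 is linked to p1–p5, giving
u = (1, 1, 2, 2, 3), v[d1] = 5 and CS = (2/3, 1/6, 1/6). The exact
within-group wiring is a free choice — CS depends only on module–pathway
incidence — so the fixture adds two group-private backbone pathways (p6
for group 2, p7 for group 3, not linked to d1) that make each group an
internal clique. This keeps every group internally connected and cleanly
recoverable by Louvain at resolution 1.0 without altering the incidence
of p1–p5 or v[d1].

`generate_planted` emits random instances with planted structure: each of
`n_modules` modules gets `pathways_per_module` private pathways — the
first annotates every module target (a backbone guaranteeing internal
connectedness, as a hub pathway does in real annotations), the rest
random subsets of ≥ 2 targets — plus `round(cross_pathway_rate ×
n_modules × pathways_per_module)` cross-module pathways spanning one or
two targets from each of two random modules. Each disease is owned by one
module (cycling through modules) and draws `pathways_per_module` pathway
links, each hitting a private pathway of the owner with probability
`propensity` and any other pathway otherwise. Everything is reproducible
from the seed. Recovery test conditions — 50 instances of 5 modules × 20
targets, cross-pathway rate 0.1, propensity 0.9, with the planted owner
recovered as the argmax-CS module in ≥ 90 % of disease columns — match
the planted-propensity regime the scoring is designed to detect.

What the generators do *not* emulate: the heavy-tailed pathway-size
distribution of real annotation databases, overlapping/nested pathways
(hierarchies), annotation noise and incompleteness, and any compound
chemistry or target-prediction behaviour. Passing tests therefore show
the algorithmic machinery is correct and well-calibrated on idealised
modular structure, not that real KEGG/STRING snapshots would yield any
particular module count or CS values — those depend on database versions
and are out of scope.

## Numerical and design choices

* Rational arithmetic for CS; conservation asserted exactly (1e-12 only
  where floats enter via export).
* Louvain is stochastic: fixed seed ⇒ bit-reproducible partition; the
  worked example is additionally checked across many seeds and certified
  as a local modularity optimum by exhaustive single-node moves
  (exhaustive enumeration over all partitions of 24 nodes is infeasible).
* Enrichment rows sort by ascending p-value with lexicographic pathway-id
  tie-break; module selection ties go to the smallest module id; TI ties
  to the lexicographically smallest target id. All outputs are sorted so
  repeated runs are byte-identical.
* Degenerate inputs: empty tables and header-only files are errors;
  duplicate rows collapse with a warning; a single-target module cannot
  be ranked (degenerate-module error); a contingency table below 2×2
  after margin trimming is reported as infeasible, not forced.

## Limitations

* Whether the original analysis's chi-square used link counts, the CS
  matrix or another table is unknowable from the description; the
  link-count builder is the package's documented default.
* The method inherits Louvain's resolution limit: very small genuine
  modules can be absorbed at resolution 1.0.
* CS treats every pathway and every pathway–disease link equally; no
  evidence weighting is attempted.
* Identifiers are opaque strings; no gene-symbol/accession normalisation
  or multi-mapping resolution is performed.
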