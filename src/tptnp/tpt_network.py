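"""One-mode TPT network construction and Louvain module detection.

The targets-(pathways)-targets network is the one-mode projection of the
bipartite target-pathway annotation: nodes are targets, and an edge joins
two targets iff they are annotated to at least one common pathway.  Each
edge carries the set of shared pathways; its weight is the size of that set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

import networkx as nx

from tptnp.errors import EmptyInputError, UsageError
from tptnp.io_model import AnnotationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TPTNetwork:
    """G = (N, E): targets as nodes, shared-pathway edges.

    ``edges`` maps a sorted node pair to the nonempty frozenset of pathways
    the two targets share; the edge weight is ``len(shared_pathways)``.
    No self-loops can arise by construction.
    """

    nodes: frozenset[str]
    edges: dict[tuple[str, str], frozenset[str]]

    def weight(self, a: str, b: str) -> int:
        return len(self.edges[tuple(sorted((a, b)))])

    def to_networkx(self, weighting: str = "shared_pathway_count") -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (a, b), shared in self.edges.items():
            w = len(shared) if weighting == "shared_pathway_count" else 1
            g.add_edge(a, b, weight=w, shared_pathways=frozenset(shared))
        return g

    def subgraph(self, nodes) -> "TPTNetwork":
        keep = frozenset(nodes) & self.nodes
        return TPTNetwork(
            nodes=keep,
            edges={
                (a, b): s for (a, b), s in self.edges.items() if a in keep and b in keep
            },
        )

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass(frozen=True)
class ModulePartition:
    """Hard assignment of every node to one module.

    Module ids are consecutive integers starting at 1, ordered by
    descending module size with ties broken by the smallest member node id,
    so partitions from different runs are directly comparable.
    """

    assignment: dict[str, int]
    resolution: float
    seed: int
    modularity: float

    @property
    def modules(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.assignment.values())))

    def members(self, module_id: int) -> frozenset[str]:
        return frozenset(n for n, m in self.assignment.items() if m == module_id)

    def as_sets(self) -> list[frozenset[str]]:
        return [self.members(m) for m in self.modules]


def build_tpt(annotation: AnnotationTable) -> TPTNetwork:
    """Project the bipartite annotation onto the one-mode TPT network.

    Every annotated target becomes a node (targets whose pathways are
    singletons end up isolated); for each pathway all pairs of its member
    targets are joined, and an edge's label is the union of the pathways
    the pair shares.
    """
    if len(annotation) == 0:
        raise EmptyInputError("annotation table is empty")
    edges: dict[tuple[str, str], set[str]] = {}
    for pathway, members in annotation.pathway_members().items():
        for a, b in combinations(sorted(members), 2):
            edges.setdefault((a, b), set()).add(pathway)
    return TPTNetwork(
        nodes=frozenset(annotation.targets),
        edges={k: frozenset(v) for k, v in edges.items()},
    )


def _canonical_relabel(communities: list[set[str]]) -> dict[str, int]:
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    return {node: i + 1 for i, comm in enumerate(ordered) for node in comm}


def detect_modules(
    network: TPTNetwork,
    resolution: float = 1.0,
    seed: int = 0,
    weighting: Literal["unweighted", "shared_pathway_count"] = "shared_pathway_count",
) -> ModulePartition:
    """Partition the TPT network by Louvain modularity optimisation.

    The node-visit order is shuffled by ``seed``; for a fixed seed the run
    is reproducible.  Isolated nodes each form a singleton module.  Module
    labels are canonicalised (size-descending, then smallest member id).
    """
    if len(network) == 0:
        raise EmptyInputError("network has no nodes")
    if weighting not in ("unweighted", "shared_pathway_count"):
        raise UsageError(f"unknown weighting {weighting!r}")
    g = network.to_networkx(weighting)
    weight_key = "weight" if weighting == "shared_pathway_count" else None
    communities = nx.community.louvain_communities(
        g, weight=weight_key, resolution=resolution, seed=seed
    )
    communities = [set(c) for c in communities]
    if g.number_of_edges() > 0:
        q = nx.community.modularity(
            g, communities, weight=weight_key, resolution=resolution
        )
    else:
        q = 0.0
    return ModulePartition(
        assignment=_canonical_relabel(communities),
        resolution=resolution,
        seed=seed,
        modularity=q,
    )


def module_pathway_incidence(
    partition: ModulePartition, annotation: AnnotationTable
) -> tuple[dict[tuple[int, str], bool], dict[str, int]]:
    """Module-pathway incidence and the per-pathway module count u.

    A module is incident to a pathway iff at least one of its member
    targets is annotated to that pathway; ``u[p]`` is the number of
    incident modules.  Membership (not intra-module edges) defines
    incidence, so a pathway realised as a single inter-module edge still
    counts both endpoint modules.  Pathways annotating only targets absent
    from the partition get ``u = 0`` and are excluded downstream.
    """
    incidence: dict[tuple[int, str], bool] = {}
    u: dict[str, int] = {}
    module_ids = partition.modules
    for pathway, members in annotation.pathway_members().items():
        hit = {partition.assignment[t] for t in members if t in partition.assignment}
        for m in module_ids:
            incidence[(m, pathway)] = m in hit
        u[pathway] = len(hit)
        if not hit:
            logger.warning(
                "pathway %s annotates no target present in the partition (u=0)",
                pathway,
            )
    return incidence, u
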