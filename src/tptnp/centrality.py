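"""Centrality analysis and the integrated target-importance (TI) indicator.

Four node centralities — degree (DC), betweenness (BC), closeness (CC) and
eigenvector (EC) — measure a target's topological importance from different
angles.  TI integrates them on a common scale by normalising each by its
maximum over the therapeutic module's targets:

    TI_i = (DC_i/max_DC + BC_i/max_BC + CC_i/max_CC + EC_i/max_EC) / 4

so TI is in [0, 1] and equals 1 exactly for a target that attains all four
maxima.  A centrality whose maximum is 0 over the module (e.g. betweenness
on a complete subgraph of size <= 2 components) contributes 0 for every
node while the averaging denominator stays 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

from tptnp.errors import ConvergenceError, DegenerateModuleError, UsageError
from tptnp.io_model import CompoundTargetTable
from tptnp.tpt_network import TPTNetwork

CENTRALITY_COLUMNS = ("dc", "bc", "cc", "ec")


@dataclass(frozen=True)
class TIRanking:
    """Per-target centralities and TI, sorted by descending TI.

    ``frame`` has columns (dc, bc, cc, ec, ti) indexed by target id, rows
    sorted descending by ti with ties broken by target id.
    """

    frame: pd.DataFrame
    module_id: int | None
    scope: str

    @property
    def targets(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


def compute_centralities(
    network: TPTNetwork,
    module_targets: Iterable[str],
    scope: Literal["full_network", "module_subgraph"] = "module_subgraph",
    weighted: bool = False,
) -> pd.DataFrame:
    """Raw (dc, bc, cc, ec) for each module target.

    With ``scope="module_subgraph"`` (default) centralities are computed on
    the module-induced subgraph; with ``"full_network"`` they are computed
    on the whole TPT network and then restricted to the module's targets.
    By default the graph is treated as unweighted; in weighted mode the
    shared-pathway count acts as connection strength for degree and
    eigenvector centrality and its reciprocal as distance for closeness
    and betweenness.

    Closeness is the inverse mean shortest-path distance within the node's
    connected component (isolated nodes get 0); eigenvector centrality uses
    power iteration to tolerance 1e-8 with at most 1000 iterations.
    """
    module_targets = sorted(set(module_targets))
    missing = [t for t in module_targets if t not in network.nodes]
    if missing:
        raise UsageError(f"module targets absent from network: {missing[:5]}")
    if len(module_targets) < 2:
        raise DegenerateModuleError(
            f"need at least 2 targets, got {len(module_targets)}"
        )
    if scope == "module_subgraph":
        g = network.subgraph(module_targets).to_networkx()
    elif scope == "full_network":
        g = network.to_networkx()
    else:
        raise UsageError(f"unknown scope {scope!r}")

    if weighted:
        for _a, _b, data in g.edges(data=True):
            data["distance"] = 1.0 / data["weight"]
        strength_key, dist_key = "weight", "distance"
    else:
        strength_key, dist_key = None, None

    dc = dict(g.degree(weight=strength_key))
    bc = nx.betweenness_centrality(g, normalized=False, weight=dist_key)
    cc = nx.closeness_centrality(g, distance=dist_key, wf_improved=False)
    if g.number_of_edges() == 0:
        ec = {n: 0.0 for n in g.nodes}
    else:
        try:
            ec = nx.eigenvector_centrality(
                g, max_iter=1000, tol=1e-8, weight=strength_key
            )
        except nx.PowerIterationFailedConvergence as exc:
            raise ConvergenceError(
                f"eigenvector power iteration did not converge: {exc}"
            ) from exc

    return pd.DataFrame(
        {
            "dc": [float(dc[t]) for t in module_targets],
            "bc": [float(bc[t]) for t in module_targets],
            "cc": [float(cc[t]) for t in module_targets],
            "ec": [float(ec[t]) for t in module_targets],
        },
        index=module_targets,
    )


def target_importance(
    centralities: pd.DataFrame,
    module_id: int | None = None,
    scope: str = "module_subgraph",
) -> TIRanking:
    """Integrate the four centralities into the TI score and rank targets."""
    if len(centralities) < 2:
        raise DegenerateModuleError(
            f"TI is undefined on a module of {len(centralities)} target(s)"
        )
    frame = centralities[list(CENTRALITY_COLUMNS)].copy()
    ti = pd.Series(0.0, index=frame.index)
    for col in CENTRALITY_COLUMNS:
        cmax = frame[col].max()
        if cmax > 0:
            ti = ti + frame[col] / cmax / 4.0
    frame["ti"] = ti
    order = sorted(frame.index, key=lambda t: (-frame.at[t, "ti"], t))
    frame = frame.loc[order]
    return TIRanking(frame=frame, module_id=module_id, scope=scope)


def top_fraction(ranking: TIRanking, fraction: float = 0.1) -> list[str]:
    """First ceil(fraction * n) targets of the TI ranking."""
    if not (0 < fraction <= 1):
        raise UsageError(f"fraction must be in (0, 1], got {fraction}")
    k = math.ceil(fraction * len(ranking))
    return ranking.targets[:k]


def attach_compounds(
    selection: Sequence[str], compounds: CompoundTargetTable
) -> dict[str, list[tuple[str, bool]]]:
    """Join selected targets with their predicted compounds.

    Preserves the selection order; targets absent from the compound table
    get empty lists.  The boolean marks compounds whose similarity score
    exceeded the predictor's threshold.
    """
    by_target: dict[str, list[tuple[str, bool]]] = {}
    for c, t, flag in compounds.rows:
        by_target.setdefault(t, []).append((c, flag))
    return {t: sorted(by_target.get(t, [])) for t in selection}
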