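"""Hypergeometric over-representation analysis of pathways in a target set.

For a query of n targets drawn from a universe of M, a pathway with K
members and k of them in the query gets the one-sided upper-tail
hypergeometric p-value P(overlap >= k).  Benjamini-Hochberg correction
across all tested pathways yields the FDR, and pathways with FDR strictly
below the threshold (default 0.01) pass.  This stage is optional: the
pipeline also accepts a pre-filtered annotation directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from tptnp.errors import EmptyInputError, UsageError
from tptnp.io_model import AnnotationTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway test results, sorted by ascending p-value.

    ``frame`` columns: pathway_id, overlap_count, pathway_size, query_size,
    universe_size, p_value, fdr, passed.  After BH correction fdr >= p_value
    for every row and passed <=> fdr < threshold.
    """

    frame: pd.DataFrame
    threshold: float

    def passed_pathways(self) -> frozenset[str]:
        return frozenset(self.frame.loc[self.frame["passed"], "pathway_id"])

    def __len__(self) -> int:
        return len(self.frame)


def enrich(
    query_targets: frozenset[str] | set[str],
    universe_annotation: AnnotationTable,
    universe_size: int | None = None,
    fdr_threshold: float = 0.01,
) -> EnrichmentResult:
    """Test every annotated pathway for over-representation in the query.

    ``universe_size`` defaults to the number of annotated targets; a larger
    value models a background of unannotated genes.
    """
    query = set(query_targets)
    if not query:
        raise EmptyInputError("empty query target set")
    if not (0 < fdr_threshold <= 1):
        raise UsageError(f"fdr_threshold must be in (0,1], got {fdr_threshold}")
    universe_targets = set(universe_annotation.targets)
    stray = query - universe_targets
    if stray:
        raise UsageError(
            f"query targets absent from universe annotation: {sorted(stray)[:5]}"
        )
    m = len(universe_targets) if universe_size is None else int(universe_size)
    if m < len(universe_targets):
        raise UsageError(
            f"universe_size {m} smaller than the {len(universe_targets)} "
            "annotated targets"
        )

    rows = []
    for pathway, members in sorted(universe_annotation.pathway_members().items()):
        size = len(members)
        if size == 0:
            logger.warning("pathway %s has no members in the universe; excluded", pathway)
            continue
        overlap = len(members & query)
        p = float(hypergeom.sf(overlap - 1, m, size, len(query)))
        p = min(p, 1.0)
        rows.append((pathway, overlap, size, len(query), m, p))
    frame = pd.DataFrame(
        rows,
        columns=[
            "pathway_id",
            "overlap_count",
            "pathway_size",
            "query_size",
            "universe_size",
            "p_value",
        ],
    )
    _reject, fdr, _a, _b = multipletests(frame["p_value"], method="fdr_bh")
    frame["fdr"] = fdr
    frame["passed"] = frame["fdr"] < fdr_threshold
    frame = frame.sort_values(
        ["p_value", "pathway_id"], kind="mergesort", ignore_index=True
    )
    return EnrichmentResult(frame=frame, threshold=fdr_threshold)


def filter_annotation(
    annotation: AnnotationTable, result: EnrichmentResult
) -> AnnotationTable:
    """Restrict the annotation to pathways that passed the FDR cutoff.

    Targets left with no retained pathway drop out of the table (and hence
    out of the downstream network).
    """
    keep = result.passed_pathways()
    return AnnotationTable(
        pairs=frozenset((t, p) for t, p in annotation.pairs if p in keep)
    )
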