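"""Contribution scoring of network modules toward diseases, with validation.

The contribution score (CS) distributes each disease's pathway support over
the network modules.  If a pathway p is incident to u[p] modules, each of
them receives 1/u[p] of p; if a disease d is linked to v[d] pathways, each
pathway carries 1/v[d] of d.  The CS of module m toward disease d is

    CS(m, d) = sum over p in X(m, d) of (1 / u[p]) * (1 / v[d])

where X(m, d) is the set of pathways incident to m and relevant to d.  For
a disease whose relevant pathways are all present in the network the CS
values of all modules sum to exactly 1, so CS is the module's share of the
disease's pathway support.  Scores are computed in exact rational
arithmetic and exposed both as fractions and as floats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from tptnp.errors import (
    EmptyInputError,
    InvalidCodeError,
    LookupError_,
    TestInfeasibleError,
)
from tptnp.io_model import ATC_LEVEL1_RANGE, DrugTargetTable, PathwayDiseaseTable
from tptnp.tpt_network import ModulePartition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContributionMatrix:
    """CS values for all module-disease pairs plus the supporting counts.

    ``cs`` holds exact fractions; ``u[p]`` is the number of modules
    incident to pathway p, ``v[d]`` the number of pathways relevant to
    disease d, and ``X[(m, d)]`` the pathways relevant to both m and d.
    """

    cs: dict[tuple[int, str], Fraction]
    modules: tuple[int, ...]
    diseases: tuple[str, ...]
    u: dict[str, int]
    v: dict[str, int]
    X: dict[tuple[int, str], frozenset[str]]

    def to_frame(self) -> pd.DataFrame:
        """CS as a float DataFrame, modules in rows, diseases in columns."""
        data = {
            d: [float(self.cs[(m, d)]) for m in self.modules] for d in self.diseases
        }
        return pd.DataFrame(data, index=list(self.modules))

    def column(self, disease: str) -> dict[int, Fraction]:
        if disease not in self.diseases:
            raise LookupError_(f"unknown disease id {disease!r}")
        return {m: self.cs[(m, disease)] for m in self.modules}


@dataclass(frozen=True)
class AssociationTestResult:
    """Pearson chi-square test of independence on a contingency table."""

    statistic: float
    dof: int
    p_value: float
    table: pd.DataFrame


def contribution_scores(
    incidence_u: tuple[dict[tuple[int, str], bool], dict[str, int]],
    pathway_disease: PathwayDiseaseTable,
) -> ContributionMatrix:
    """Compute CS(m, d) for every module-disease pair.

    ``incidence_u`` is the (incidence, u) pair from
    :func:`tptnp.tpt_network.module_pathway_incidence`.  Pathways with
    u = 0 (no annotated target in the partition) contribute nothing; a
    disease all of whose pathways have u = 0 is omitted with a warning.
    """
    incidence, u = incidence_u
    modules = tuple(sorted({m for (m, _p) in incidence}))
    if len(pathway_disease) == 0:
        logger.warning("pathway-disease table is empty; contribution matrix is empty")
        return ContributionMatrix(
            cs={}, modules=modules, diseases=(), u=dict(u), v={}, X={}
        )

    cs: dict[tuple[int, str], Fraction] = {}
    X: dict[tuple[int, str], frozenset[str]] = {}
    v: dict[str, int] = {}
    kept: list[str] = []
    for disease, rel_pathways in sorted(pathway_disease.disease_pathways().items()):
        v_d = len(rel_pathways)
        usable = {p for p in rel_pathways if u.get(p, 0) >= 1}
        if not usable:
            logger.warning(
                "disease %s: none of its %d pathway(s) map to the network; omitted",
                disease,
                v_d,
            )
            continue
        if len(usable) < v_d:
            logger.warning(
                "disease %s: %d of %d relevant pathway(s) absent from the network",
                disease,
                v_d - len(usable),
                v_d,
            )
        kept.append(disease)
        v[disease] = v_d
        for m in modules:
            x_md = frozenset(p for p in usable if incidence[(m, p)])
            X[(m, disease)] = x_md
            cs[(m, disease)] = sum(
                (Fraction(1, u[p]) * Fraction(1, v_d) for p in x_md),
                start=Fraction(0),
            )
    return ContributionMatrix(
        cs=cs, modules=modules, diseases=tuple(kept), u=dict(u), v=v, X=X
    )


def _link_count_table(cm: ContributionMatrix) -> pd.DataFrame:
    data = {
        d: [len(cm.X[(m, d)]) for m in cm.modules] for d in cm.diseases
    }
    return pd.DataFrame(data, index=list(cm.modules))


_TABLE_BUILDERS = {"pathway_link_counts": _link_count_table}


def _chisquare_on_table(
    table: pd.DataFrame, correction: bool = False
) -> AssociationTestResult:
    # drop all-zero margins; chi-square is undefined there
    table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise TestInfeasibleError(
            f"contingency table is {table.shape[0]}x{table.shape[1]}; "
            "need at least 2x2 with nonzero margins"
        )
    res = stats.chi2_contingency(table.to_numpy(), correction=correction)
    return AssociationTestResult(
        statistic=float(res.statistic),
        dof=int(res.dof),
        p_value=float(res.pvalue),
        table=table,
    )


def module_disease_chisquare(
    cm: ContributionMatrix,
    table_builder: str = "pathway_link_counts",
    correction: bool = False,
) -> AssociationTestResult:
    """Chi-square test of module x disease independence.

    The default contingency table holds the integer pathway-link counts
    |X(m, d)| — the number of pathways joining module m and disease d —
    which are valid count data, unlike the real-valued CS matrix.  The
    builder is pluggable via ``table_builder``.  ``correction`` applies the
    Yates continuity correction (only meaningful for 2x2 tables).
    """
    if table_builder not in _TABLE_BUILDERS:
        raise TestInfeasibleError(f"unknown table builder {table_builder!r}")
    table = _TABLE_BUILDERS[table_builder](cm)
    return _chisquare_on_table(table, correction=correction)


def atc_level1(atc_code: str) -> str:
    """Abbreviate an ATC code to level 1 (the anatomical main group).

    Level 1 is the code's first character, the organ or system the drug
    acts on (e.g. "L01XE06" -> "L", antineoplastic and immunomodulating).
    """
    code = atc_code.strip()
    if not code:
        raise InvalidCodeError("empty ATC code")
    letter = code[0].upper()
    if letter not in ATC_LEVEL1_RANGE:
        raise InvalidCodeError(
            f"ATC code {atc_code!r} does not start with a letter A-V"
        )
    return letter


def drug_target_validation(
    partition: ModulePartition,
    drugs: DrugTargetTable,
    classes: frozenset[str] | set[str],
) -> tuple[dict[str, dict[int, int]], AssociationTestResult | None]:
    """Count drugged targets per module for each ATC level-1 class.

    For every class letter in ``classes``, counts the distinct network
    targets having at least one approved drug of that class, grouped by
    module.  A target with drugs in several classes counts once in each
    class's tally (the classes are reported independently).  Returns the
    per-class counts and a chi-square test on the module x class table
    (restricted to modules with a nonzero margin), or ``None`` when the
    restricted table is degenerate.
    """
    if not partition.assignment:
        raise EmptyInputError("partition is empty")
    classes = {c.upper() for c in classes}
    # class letter -> set of in-network targets with >=1 drug of that class
    class_targets: dict[str, set[str]] = {c: set() for c in sorted(classes)}
    any_hit = False
    for target, _drug, code in drugs.rows:
        if target not in partition.assignment:
            continue
        letter = atc_level1(code)
        if letter in class_targets:
            class_targets[letter].add(target)
            any_hit = True
    modules = partition.modules
    counts: dict[str, dict[int, int]] = {}
    for letter, targets in class_targets.items():
        per_module = {m: 0 for m in modules}
        for t in targets:
            per_module[partition.assignment[t]] += 1
        counts[letter] = per_module
    if not any_hit:
        logger.warning("no drugged target of the requested classes is in the network")
        return counts, None
    table = pd.DataFrame(
        {c: [counts[c][m] for m in modules] for c in sorted(classes)},
        index=list(modules),
    )
    try:
        test = _chisquare_on_table(table)
    except TestInfeasibleError as exc:
        logger.warning("module x class chi-square infeasible: %s", exc)
        test = None
    return counts, test


def relevant_disease_ratio(
    cm: ContributionMatrix, relevant: frozenset[str] | set[str]
) -> tuple[pd.DataFrame, int]:
    """Restrict the CS matrix to the diseases of interest and pick a module.

    Returns the per-disease CS columns for the relevant diseases (each
    column already sums to 1 over modules when all its pathways are in the
    network) and the id of the module with the largest mean CS over those
    diseases, ties broken by the smallest module id.
    """
    unknown = sorted(set(relevant) - set(cm.diseases))
    if unknown:
        raise LookupError_(f"unknown disease id(s): {unknown}")
    if not relevant:
        raise EmptyInputError("no relevant diseases supplied")
    cols = sorted(relevant)
    frame = cm.to_frame()[cols]
    mean_cs = frame.mean(axis=1)
    # idxmax on a Series of module-id index: ties resolved by smallest id
    best = min(m for m in cm.modules if mean_cs[m] == mean_cs.max())
    return frame, int(best)
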