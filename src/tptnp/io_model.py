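"""Typed data model and readers/writers for the pipeline's tabular inputs.

All tables are tab-separated UTF-8 files with a header row; lines starting
with ``#`` are treated as comments.  Identifiers (UniProt accessions, KEGG
``hsa…`` pathway ids, disease-category labels) are opaque, case-sensitive
strings; leading/trailing whitespace is trimmed on load.  Duplicate pairs
are collapsed with a logged warning — merged multi-source annotation files
routinely repeat pairs, so repetition is not an error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx
import pandas as pd
import yaml

from tptnp.errors import EmptyInputError, SchemaError, UsageError

logger = logging.getLogger(__name__)

#: First character of an ATC code: anatomical main group, A through V.
ATC_LEVEL1_RANGE = tuple(chr(c) for c in range(ord("A"), ord("V") + 1))


@dataclass(frozen=True)
class AnnotationTable:
    """Bipartite target <-> pathway incidence, the raw input of the method.

    ``pairs`` is the set of (target_id, pathway_id) annotations; ``targets``
    and ``pathways`` are the sorted unique ids on each side.
    """

    pairs: frozenset[tuple[str, str]]

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(sorted({t for t, _ in self.pairs}))

    @property
    def pathways(self) -> tuple[str, ...]:
        return tuple(sorted({p for _, p in self.pairs}))

    def pathway_members(self) -> dict[str, set[str]]:
        """Map pathway id -> set of annotated targets."""
        members: dict[str, set[str]] = {}
        for t, p in self.pairs:
            members.setdefault(p, set()).add(t)
        return members

    def target_pathways(self) -> dict[str, set[str]]:
        """Map target id -> set of pathways it is annotated to."""
        ann: dict[str, set[str]] = {}
        for t, p in self.pairs:
            ann.setdefault(t, set()).add(p)
        return ann

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PathwayDiseaseTable:
    """Set of (pathway_id, disease_id) links; source of the v_j denominators."""

    pairs: frozenset[tuple[str, str]]

    @property
    def pathways(self) -> tuple[str, ...]:
        return tuple(sorted({p for p, _ in self.pairs}))

    @property
    def diseases(self) -> tuple[str, ...]:
        return tuple(sorted({d for _, d in self.pairs}))

    def disease_pathways(self) -> dict[str, set[str]]:
        """Map disease id -> set of pathways relevant to it."""
        rel: dict[str, set[str]] = {}
        for p, d in self.pairs:
            rel.setdefault(d, set()).add(p)
        return rel

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DrugTargetTable:
    """Approved-drug annotation: one row per (target, drug) with its ATC code."""

    rows: tuple[tuple[str, str, str], ...]  # (target_id, drug_name, atc_code)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class CompoundTargetTable:
    """Predicted compound-target pairs with the predictor's threshold flag.

    ``above_threshold`` marks pairs whose chemical-similarity score exceeded
    the upstream predictor's cutoff (e.g. SEA's Tc threshold).
    """

    rows: tuple[tuple[str, str, bool], ...]  # (compound_id, target_id, flag)

    def compounds_for(self, target_id: str) -> list[tuple[str, bool]]:
        return [(c, f) for c, t, f in self.rows if t == target_id]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class PipelineConfig:
    """Run parameters; serialisable to/from YAML or JSON.

    resolution
        Louvain resolution parameter (1.0 reproduces the standard
        modularity objective).
    random_seed
        Seed for every stochastic stage (Louvain node-visit order, data
        generation).
    fdr_threshold
        Benjamini-Hochberg FDR cutoff for the over-representation stage.
    top_fraction
        Fraction of module targets kept in the final TI ranking.
    edge_weighting
        ``shared_pathway_count`` weights each TPT edge by the number of
        shared pathways; ``unweighted`` ignores weights.
    centrality_scope
        Whether centralities are computed on the module-induced subgraph or
        on the full TPT network.
    """

    resolution: float = 1.0
    random_seed: int = 0
    fdr_threshold: float = 0.01
    top_fraction: float = 0.1
    edge_weighting: Literal["unweighted", "shared_pathway_count"] = (
        "shared_pathway_count"
    )
    centrality_scope: Literal["full_network", "module_subgraph"] = "module_subgraph"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise UsageError(f"resolution must be positive, got {self.resolution}")
        if not (0 < self.fdr_threshold <= 1):
            raise UsageError(f"fdr_threshold must be in (0,1], got {self.fdr_threshold}")
        if not (0 < self.top_fraction <= 1):
            raise UsageError(f"top_fraction must be in (0,1], got {self.top_fraction}")
        if self.edge_weighting not in ("unweighted", "shared_pathway_count"):
            raise UsageError(f"unknown edge_weighting {self.edge_weighting!r}")
        if self.centrality_scope not in ("full_network", "module_subgraph"):
            raise UsageError(f"unknown centrality_scope {self.centrality_scope!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise SchemaError(f"config file {path} does not contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


_SCHEMAS: dict[str, tuple[str, ...]] = {
    "annotation": ("target_id", "pathway_id"),
    "pathway_disease": ("pathway_id", "disease_id"),
    "drug_target": ("target_id", "drug_name", "atc_code"),
    "compound_target": ("compound_id", "target_id", "above_threshold"),
}

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value: str, *, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise SchemaError(f"cannot parse boolean {value!r} in column {context}")


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype=str, skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file contains no data")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise EmptyInputError(f"{path}: header only, no data rows")
    df = df[list(required)].apply(lambda col: col.str.strip())
    if (df == "").any().any() or df.isna().any().any():
        raise SchemaError(f"{path}: empty identifier after whitespace trimming")
    return df


def read_pairs_table(
    path: str | Path,
    kind: Literal["annotation", "pathway_disease", "drug_target", "compound_target"],
) -> AnnotationTable | PathwayDiseaseTable | DrugTargetTable | CompoundTargetTable:
    """Load and validate one of the pipeline's TSV tables.

    Duplicate rows are collapsed (a warning reports how many); for the
    drug-target table duplication is judged on the (target, drug) pair.
    """
    if kind not in _SCHEMAS:
        raise UsageError(f"unknown table kind {kind!r}")
    df = _read_tsv(path, _SCHEMAS[kind])

    if kind == "annotation":
        pairs = list(zip(df["target_id"], df["pathway_id"]))
        unique = frozenset(pairs)
        _warn_dupes(path, len(pairs) - len(unique))
        return AnnotationTable(pairs=unique)

    if kind == "pathway_disease":
        pairs = list(zip(df["pathway_id"], df["disease_id"]))
        unique = frozenset(pairs)
        _warn_dupes(path, len(pairs) - len(unique))
        return PathwayDiseaseTable(pairs=unique)

    if kind == "drug_target":
        rows: list[tuple[str, str, str]] = []
        seen: set[tuple[str, str]] = set()
        n_dupes = 0
        for t, drug, code in zip(df["target_id"], df["drug_name"], df["atc_code"]):
            code = code.upper()
            if not (1 <= len(code) <= 7):
                raise SchemaError(f"{path}: ATC code {code!r} not 1-7 characters")
            if code[0] not in ATC_LEVEL1_RANGE:
                raise SchemaError(
                    f"{path}: ATC code {code!r} does not start with a letter A-V"
                )
            key = (t, drug)
            if key in seen:
                n_dupes += 1
                continue
            seen.add(key)
            rows.append((t, drug, code))
        _warn_dupes(path, n_dupes)
        return DrugTargetTable(rows=tuple(rows))

    # compound_target
    crows: list[tuple[str, str, bool]] = []
    seenc: set[tuple[str, str]] = set()
    n_dupes = 0
    for c, t, flag in zip(df["compound_id"], df["target_id"], df["above_threshold"]):
        key = (c, t)
        if key in seenc:
            n_dupes += 1
            continue
        seenc.add(key)
        crows.append((c, t, _parse_bool(flag, context="above_threshold")))
    _warn_dupes(path, n_dupes)
    return CompoundTargetTable(rows=tuple(crows))


def _warn_dupes(path: str | Path, n: int) -> None:
    if n > 0:
        logger.warning("%s: collapsed %d duplicate row(s)", path, n)


def write_pairs_table(
    table: AnnotationTable | PathwayDiseaseTable | DrugTargetTable | CompoundTargetTable,
    path: str | Path,
) -> None:
    """Write a table back to TSV in a deterministic (sorted) row order."""
    path = Path(path)
    if isinstance(table, AnnotationTable):
        df = pd.DataFrame(sorted(table.pairs), columns=["target_id", "pathway_id"])
    elif isinstance(table, PathwayDiseaseTable):
        df = pd.DataFrame(sorted(table.pairs), columns=["pathway_id", "disease_id"])
    elif isinstance(table, DrugTargetTable):
        df = pd.DataFrame(
            sorted(table.rows), columns=["target_id", "drug_name", "atc_code"]
        )
    elif isinstance(table, CompoundTargetTable):
        df = pd.DataFrame(
            [(c, t, str(f).lower()) for c, t, f in sorted(table.rows)],
            columns=["compound_id", "target_id", "above_threshold"],
        )
    else:
        raise UsageError(f"cannot write object of type {type(table).__name__}")
    df.to_csv(path, sep="\t", index=False)


# --- graph I/O --------------------------------------------------------------

_PATHWAY_SEP = "|"


def _to_nx(network) -> nx.Graph:
    """Materialise a TPTNetwork as a networkx Graph with serialisable attrs."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for (a, b), shared in network.edges.items():
        g.add_edge(
            a,
            b,
            shared_pathways=_PATHWAY_SEP.join(sorted(shared)),
            weight=len(shared),
        )
    return g


def write_network(
    network,
    path: str | Path,
    format: Literal["graphml", "gexf", "edge_tsv"] = "graphml",
) -> None:
    """Export a TPT network; the shared-pathway label is a ``|``-joined list."""
    path = Path(path)
    g = _to_nx(network)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "gexf":
        nx.write_gexf(g, path)
    elif format == "edge_tsv":
        rows = [
            (a, b, g.edges[a, b]["shared_pathways"], g.edges[a, b]["weight"])
            for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges))
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "shared_pathways", "weight"])
        # isolated nodes are kept on comment lines so the file round-trips
        with open(path, "w") as fh:
            for node in sorted(n for n in g.nodes if g.degree[n] == 0):
                fh.write(f"#node\t{node}\n")
            df.to_csv(fh, sep="\t", index=False)
    else:
        raise UsageError(f"unknown network format {format!r}")


def read_network(path: str | Path, format: Literal["graphml", "gexf", "edge_tsv"]):
    """Read a network written by :func:`write_network` (round-trip inverse)."""
    from tptnp.tpt_network import TPTNetwork  # local import avoids a cycle

    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "gexf":
        g = nx.read_gexf(path)
    elif format == "edge_tsv":
        g = nx.Graph()
        with open(path) as fh:
            header_seen = False
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#node\t"):
                    g.add_node(line.split("\t", 1)[1])
                    continue
                if not line or line.startswith("#"):
                    continue
                if not header_seen:
                    header_seen = True  # column names fixed by write_network
                    continue
                a, b, shared, weight = line.split("\t")
                g.add_edge(a, b, shared_pathways=shared, weight=int(weight))
    else:
        raise UsageError(f"unknown network format {format!r}")

    edges = {}
    for a, b, data in g.edges(data=True):
        shared = frozenset(data["shared_pathways"].split(_PATHWAY_SEP))
        edges[frozenset((a, b))] = shared
    return TPTNetwork(
        nodes=frozenset(g.nodes),
        edges={tuple(sorted(k)): v for k, v in edges.items()},
    )
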