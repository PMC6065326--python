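"""Synthetic instances: the worked toy example and planted-module generators.

Every pipeline stage is testable offline against instances with known
ground truth.  Two generators are provided:

* :func:`fig7_fixture` — the 24-target, three-module worked example used
  to demonstrate the contribution-scoring algorithm, with its exact
  module/pathway incidence (u[p1] = u[p2] = 1, u[p3] = u[p4] = 2,
  u[p5] = 3, v[d1] = 5) and hence exact CS values 2/3, 1/6, 1/6.
* :func:`generate_planted` — random bipartite annotations with planted
  target modules and diseases preferentially linked to one module's
  pathways, for parameter-recovery and conservation tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from tptnp.errors import UsageError
from tptnp.io_model import AnnotationTable, PathwayDiseaseTable

# Prefix used for cross-module pathways emitted by generate_planted.
CROSS_PATHWAY_PREFIX = "PX"


@dataclass(frozen=True)
class PlantedInstance:
    """A generated instance together with its ground truth.

    ``truth_assignment`` maps each target to its planted module (1-based);
    ``disease_owner`` maps each disease to the module whose pathways it was
    preferentially linked to; ``propensity`` is that preference probability.
    """

    annotation: AnnotationTable
    pathway_disease: PathwayDiseaseTable
    truth_assignment: dict[str, int]
    disease_owner: dict[str, int]
    propensity: float
    seed: int

    def planted_modules(self) -> list[frozenset[str]]:
        mods: dict[int, set[str]] = {}
        for t, m in self.truth_assignment.items():
            mods.setdefault(m, set()).add(t)
        return [frozenset(mods[m]) for m in sorted(mods)]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit annotation/pathway-disease/truth TSVs readable by the pipeline."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "annotation": outdir / "annotation.tsv",
            "pathway_disease": outdir / "pathway_disease.tsv",
            "truth": outdir / "truth.tsv",
        }
        pd.DataFrame(
            sorted(self.annotation.pairs), columns=["target_id", "pathway_id"]
        ).to_csv(paths["annotation"], sep="\t", index=False)
        pd.DataFrame(
            sorted(self.pathway_disease.pairs), columns=["pathway_id", "disease_id"]
        ).to_csv(paths["pathway_disease"], sep="\t", index=False)
        truth_rows = [("target", t, str(m)) for t, m in sorted(self.truth_assignment.items())]
        truth_rows += [("disease_owner", d, str(m)) for d, m in sorted(self.disease_owner.items())]
        pd.DataFrame(truth_rows, columns=["kind", "id", "module"]).to_csv(
            paths["truth"], sep="\t", index=False
        )
        return paths


def fig7_fixture() -> PlantedInstance:
    """The three-module worked example of the contribution-scoring algorithm.

    24 targets in three groups — T-A1..T-A9 (module 1), T-B1..T-B8
    (module 2), T-C1..T-C7 (module 3).  Pathways p1 and p2 annotate only
    group-1 targets; p3 joins one group-1 and one group-2 target; p4 joins
    one group-1 and one group-3 target; p5 touches one target from every
    group; disease d1 is relevant to p1-p5.  Two further group-private
    pathways (p6 for group 2, p7 for group 3) make every group internally
    connected without altering the incidence of p1-p5 or v[d1] = 5, so the
    CS values are exactly 2/3, 1/6 and 1/6.
    """
    group_a = [f"T-A{i}" for i in range(1, 10)]
    group_b = [f"T-B{i}" for i in range(1, 9)]
    group_c = [f"T-C{i}" for i in range(1, 8)]

    pathway_members = {
        "p1": group_a,                       # group 1 only -> u = 1
        "p2": group_a[:5],                   # group 1 only -> u = 1
        "p3": ["T-A9", "T-B1"],              # single edge spanning m1, m2 -> u = 2
        "p4": ["T-A5", "T-C1"],              # single edge spanning m1, m3 -> u = 2
        "p5": ["T-A1", "T-B4", "T-C4"],      # one target per group -> u = 3
        "p6": group_b,                       # group-2 backbone (not linked to d1)
        "p7": group_c,                       # group-3 backbone (not linked to d1)
    }
    pairs = frozenset(
        (t, p) for p, members in pathway_members.items() for t in members
    )
    pathway_disease = frozenset((f"p{w}", "d1") for w in range(1, 6))
    truth = (
        {t: 1 for t in group_a} | {t: 2 for t in group_b} | {t: 3 for t in group_c}
    )
    return PlantedInstance(
        annotation=AnnotationTable(pairs=pairs),
        pathway_disease=PathwayDiseaseTable(pairs=pathway_disease),
        truth_assignment=truth,
        disease_owner={"d1": 1},
        propensity=1.0,
        seed=0,
    )


def generate_planted(
    n_modules: int = 5,
    targets_per_module: int = 20,
    pathways_per_module: int = 6,
    cross_pathway_rate: float = 0.1,
    diseases: int = 5,
    propensity: float = 0.9,
    seed: int = 0,
) -> PlantedInstance:
    """Random annotation with planted modules and module-owned diseases.

    Each planted module gets ``pathways_per_module`` private pathways: the
    first annotates every module target (a backbone keeping the module
    internally connected), the rest annotate random subsets of >= 2
    targets.  Cross-module pathways — ``round(cross_pathway_rate *
    n_modules * pathways_per_module)`` of them — each span two random
    modules with one or two random targets from each.  Every disease is
    owned by one module (cycling through modules) and each of its
    ``pathways_per_module`` link draws picks a private pathway of the
    owner with probability ``propensity`` and any other pathway otherwise.
    Fully reproducible from ``seed``.
    """
    if min(n_modules, targets_per_module, pathways_per_module, diseases) < 1:
        raise UsageError("all counts must be positive")
    if targets_per_module < 2:
        raise UsageError("need at least 2 targets per module")
    if not (0 <= cross_pathway_rate <= 1):
        raise UsageError(f"cross_pathway_rate must be in [0,1], got {cross_pathway_rate}")
    if not (0 < propensity <= 1):
        raise UsageError(f"propensity must be in (0,1], got {propensity}")

    rng = np.random.default_rng(seed)
    module_targets = {
        i: [f"M{i}-T{k:02d}" for k in range(1, targets_per_module + 1)]
        for i in range(1, n_modules + 1)
    }
    truth = {t: i for i, ts in module_targets.items() for t in ts}

    pairs: set[tuple[str, str]] = set()
    private: dict[int, list[str]] = {i: [] for i in module_targets}
    for i, ts in module_targets.items():
        for w in range(1, pathways_per_module + 1):
            pw = f"M{i}-P{w:02d}"
            private[i].append(pw)
            if w == 1:
                chosen = ts  # backbone pathway covers the whole module
            else:
                size = int(rng.integers(2, targets_per_module + 1))
                chosen = [ts[j] for j in rng.choice(len(ts), size=size, replace=False)]
            pairs.update((t, pw) for t in chosen)

    n_cross = round(cross_pathway_rate * n_modules * pathways_per_module)
    cross: list[str] = []
    for c in range(1, n_cross + 1):
        pw = f"{CROSS_PATHWAY_PREFIX}{c:02d}"
        cross.append(pw)
        if n_modules >= 2:
            mods = rng.choice(n_modules, size=2, replace=False) + 1
        else:
            mods = np.array([1])
        for i in mods:
            ts = module_targets[int(i)]
            k = int(rng.integers(1, min(2, targets_per_module) + 1))
            chosen = [ts[j] for j in rng.choice(len(ts), size=k, replace=False)]
            pairs.update((t, pw) for t in chosen)

    all_pathways = [p for ps in private.values() for p in ps] + cross
    pd_pairs: set[tuple[str, str]] = set()
    owner: dict[str, int] = {}
    for j in range(1, diseases + 1):
        d = f"D{j:02d}"
        own = (j - 1) % n_modules + 1
        owner[d] = own
        others = [p for p in all_pathways if p not in private[own]]
        for _ in range(pathways_per_module):
            if rng.random() < propensity or not others:
                pw = private[own][int(rng.integers(len(private[own])))]
            else:
                pw = others[int(rng.integers(len(others)))]
            pd_pairs.add((pw, d))

    return PlantedInstance(
        annotation=AnnotationTable(pairs=frozenset(pairs)),
        pathway_disease=PathwayDiseaseTable(pairs=frozenset(pd_pairs)),
        truth_assignment=truth,
        disease_owner=owner,
        propensity=propensity,
        seed=seed,
    )
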